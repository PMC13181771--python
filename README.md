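# ringorder

Hydrogen-bond ring statistics and order metrics for simulated water.

Liquid, supercooled and crystalline water differ most visibly in the
topology of their hydrogen-bond network. `ringorder` builds the directed
donor→acceptor H-bond graph of a water configuration, exhaustively
enumerates its closed H-bond paths (rings) under periodic boundaries,
reduces them to primitive rings, and condenses the result into order
metrics that track structure, proton ordering and crystallization. It is
aimed at molecular-simulation practitioners analysing GROMACS/PDB/XYZ
water configurations, and ships an ice-lattice factory so every
crystal-based number is reproducible without external structure files.

## What it computes

* **H-bond graph** — geometric (Luzar–Chandler) definition: O···O ≤ 3.5 Å
  and ∠OOH < 30°, donor identified by the covalent hydrogen, minimum-image
  periodic handling with per-edge lattice image shifts.
* **Rings** — all simple cycles of the undirected connectivity with
  3 ≤ n ≤ 10 members and zero net image shift, each counted once (the 2n
  traversal degeneracy is removed during the depth-first search). A ring is
  *directional* when its H-bonds can be oriented head-to-tail in one
  rotational sense.
* **Primitive rings** — commonality pruning: a ring is eliminated when it
  shares a run of k sequential waters with a smaller retained ring, with
  k = 1, 2, 3, 4 for the common-vertex (CV), common-edge (CE),
  common-angle (CA, the Speedy-style criterion) and common-dihedral (CD)
  variants; DCV…DCD prune within the directional subset.
* **Tetrahedrality** — the Errington–Debenedetti order parameter
  q = 1 − ⅜ Σ_{j<k} (cos ψ_jk + ⅓)², with an H-bond-prioritized neighbour
  mode that repairs q in dense interpenetrating lattices (ice VII).
* **Ring summation factor** — RSF = (primitive rings, CA) / (2 N_water),
  1.0 in a defect-free crystal and 0 in a gas.
* **Directional-ring probabilities** — predicted P_D(n) = 2·(2/3)ⁿ versus
  the fraction observed among unpruned rings.
* **Ice factory** — ideal oxygen lattices for ice Ic, Ih, VII plus
  ferroelectric/antiferroelectric ice XI proton ordering and uniformly
  randomized Bernal–Fowler ice-rules states (loop Monte Carlo), all
  seed-reproducible.

## Worked example

```python
from ringorder import (CrystalSpec, PruneSpec, detect_hbonds,
                       enumerate_rings, make_ice, prune, rsf)

frame = make_ice(CrystalSpec("Ih", (8, 4, 4), seed=1))   # 1024 waters
graph = detect_hbonds(frame)                              # 2048 H-bonds
rings = enumerate_rings(graph, max_ring=10)
pruned = prune(rings, PruneSpec("CA"))
print(pruned.counts_by_size())   # {3: 0, 4: 0, 5: 0, 6: 2048, 7: 0, ...}
print(rsf(pruned, frame.n_waters))  # 1.0
print(rings.directional_counts_by_size()[6])  # 348 for this seed
```

The 1024-water proton-disordered crystal carries exactly 2048 primitive
hexagons — two per water, so RSF = 1.0 — while the number of *directional*
hexagons (348 here) fluctuates around P_D(6)·2048 ≈ 360 because proton
disorder randomizes ring orientations. The `examples/` scripts walk
through each capability (polymorph fingerprints, P_D vs observed
fractions, a crystallization monitor, file-based analysis) and print the
numbers they compute.

A thin CLI wraps the same library:

```bash
ringorder generate --polymorph xi-antiferro --cells 8 4 4 --out xi.gro
ringorder analyze --input xi.gro --prune CA --out report/
ringorder probe
```

## Scope

Orthorhombic boxes only; water-only H-bond chemistry; ring sizes capped at
10 (primitive rings rarely exceed heptagons, but CD pruning near the cap
is flagged because larger rings that would prune survivors are invisible).
High-pressure polymorphs (III, VI, IX, XII, XIV, XV, …) are analysed from
user-supplied coordinate files rather than generated natively. Running
molecular dynamics is out of scope — the package analyses configurations
it is given (or builds ideal lattices itself).
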