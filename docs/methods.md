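# Methods

## Hydrogen-bond definition

A directed H-bond runs from the donor (the water owning the covalent
hydrogen) to the acceptor. Two geometric criteria must hold under the
minimum-image convention in an orthorhombic box: the O···O separation is at
most the cutoff (default 3.5 Å, **inclusive**) and the ∠OOH angle —
measured at the donor oxygen between the O_d→O_a minimum-image vector and
the covalent O_d→H vector — is strictly below the cone angle (default
30°, **exclusive**). The inclusive/exclusive split fixes the boundary
behaviour the geometric definition itself leaves open; geometries within
1e-9 (Å or degrees) of a threshold are resolved as if they sat exactly on
it, so boundary cases are deterministic across platforms. Both hydrogens
of a donor are tested independently, so a pair may in principle carry two
antiparallel edges; rings of size ≥ 3 exclude such 2-cycles from every
statistic. Each edge stores the integer image shift from donor to the
bonded acceptor image. Boxes smaller than twice the cutoff in any
direction are rejected (minimum image would be ambiguous), as are
triclinic cells.

## Ring enumeration

Rings are simple cycles of the *undirected* H-bond connectivity with
3 ≤ n ≤ `max_ring` (default 10) members. Edge direction is ignored for
path existence and retained for directionality. The depth-first search
starts at every water and extends only to higher-indexed waters; at
closure the traversal whose second member is smaller than its last is the
canonical one, so each undirected cycle is produced exactly once and the
2n start/direction degeneracy (ten instances for a pentagon) never
materialises. Correctness of this pruned search is locked against an
independent exhaustive simple-cycle oracle (networkx) on a seeded sweep of
random graphs.

Periodic artifacts are removed by the zero-winding rule: per-step image
shifts are accumulated (encoded in a single integer with base-64 fields,
exact for paths up to length 10 in each component) and a closure only
counts when the net shift is zero — every wall crossing must be matched by
a return through the same wall. Cycles that wind around the torus are
therefore rejected, and replicating a supercell exactly doubles every ring
count. A ring is **directional** when all its edges can be oriented
head-to-tail in one rotational sense; both senses count. The optional
directed traversal mode follows only orientable continuations and yields
exactly the directional subset at reduced cost.

Ring centers are computed on image-shift-unwrapped member coordinates and
wrapped back into the box, so rings straddling a periodic wall sit at the
wall in exports (CSV and POV-Ray fingerprint scenes).

## Commonality pruning

A ring is eliminated when it shares a run of k sequential members with a
strictly smaller *retained* ring: k = 1 (CV), 2 (CE), 3 (CA), 4 (CD). Runs
are compared irrespective of rotation and traversal direction. Processing
is smallest-size-first; equal-size rings sharing a run are **both**
retained (necessary for crystals, where all 2N hexagons of hexagonal ice
share edges with each other), and an eliminated ring never eliminates
anything. This ordering makes pruning idempotent and reproduces the
classic fused-ring reference cases: a 5- and 6-ring sharing one edge give
survivors {5} under CV/CE and {5, 6} under CA/CD, with the 9-membered
perimeter pruned. Because longer required runs prune less, survivor counts
always order CV ≤ CE ≤ CA ≤ CD. With the default size cap, CD survivors
can be inflated — rings larger than the cap that would prune them are
invisible — so CD runs emit a warning. D-variants (DCV…DCD) first restrict
the input to directional rings and prune within that subset, which is less
aggressive than taking the directional members of a plain pruning run.

## Order metrics

**Tetrahedrality.** q = 1 − ⅜ Σ_{j<k} (cos ψ_jk + ⅓)² over the six angles
subtended at a water by its four neighbours (oxygen positions only).
q = 1 iff all six angles are arccos(−1/3); uniformly random shells average
0; a fully collinear shell gives −3. Neighbour selection is either
`nearest4` (four nearest oxygens, ties broken by index) or `hbond_first`
(H-bonded partners in either direction first, sorted by distance, padded
with nearest non-bonded). The latter matters for ice VII, where eight
equidistant neighbours make `nearest4` essentially arbitrary and depress
⟨q⟩ to ~0.4, while `hbond_first` recovers the tetrahedral value.

**Ring summation factor.** RSF = (CA-pruned rings of sizes 3..10) /
(2 N_water). The denominator is the maximum possible number of H-bonds
(each water donates at most two), so a defect-free crystal in which every
potential H-bond participates in primitive-ring formation reaches exactly
1.0 and an ideal-gas-like system 0. Other criteria are accepted but
flagged non-standard. Values above 1 are reported with a warning rather
than clipped silently.

**Directional probabilities.** P_D(n) = 2·(2/3)ⁿ: a water that accepts an
H-bond from the previous ring member continues the head-to-tail chain
through 2 of its 3 remaining bonding sites, and the factor 2 counts the
two rotational senses. The observed counterpart is the directional
fraction of **unpruned** rings per size — pruning preferentially removes
large nondirectional rings and would bias the fraction upward. Sizes with
zero enumerated rings report NaN (undefined), with the raw count exposed
so "absent in this lattice" is distinguishable from "never directional".

**Time series.** One record per frame (⟨q⟩, per-molecule q, RSF, per-size
counts); trajectory summaries use unweighted frame means with standard
errors of the mean across frames. For ensembles of independently seeded
crystals the same SEM convention applies across crystals.

## The ice factory

All lattices are ideal: the nearest-neighbour O–O distance (default
2.75 Å, the typical ice Ih experimental value) sets the scale, hydrogens
sit exactly on the O–O axis at the covalent length 0.9572 Å, and every
O–O link carries exactly one hydrogen. Because the geometry is perfect,
4-coordinated polymorphs report q = 1 exactly — real or thermalized
crystals carry slight distortions and land a fraction of a percent lower.
Topological results (ring counts, directional fingerprints, RSF) are
insensitive to the length choice for any value below the H-bond cutoff.

* **Ic** — cubic diamond, 8 waters per conventional cell.
* **Ih** — hexagonal diamond (lonsdaleite) in its 8-water orthorhombic
  setting, crystallographic c along z.
* **VII** — two interpenetrating cubic-diamond sublattices (bcc oxygen
  arrangement, 16 waters per cell); each sublattice keeps its own H-bond
  network and its own ice-rules state, and the detection geometry
  guarantees no cross-sublattice bonds arise (the smallest inter-network
  OOH angle is ~54.7°).
* **Ice XI (ordered)** — per-cell donation tables selected by exhaustive
  enumeration of all 114 ice-rules states of the periodic 8-water cell.
  The ferroelectric table has every molecular dipole sharing the same
  positive c component with the net cell dipole purely along c; every
  ring then contains a double-donor and a double-acceptor water
  (a percolating loop), so no ring of any size is directional. The
  antiferroelectric table has a zero-dipole 8-water cell and yields
  exactly one directional hexagon per two waters, with no directional
  octagons. Ice VIII (ordered VII) is not generated natively — its
  proton arrangement is accepted only via coordinate files.
* **Proton disorder** — each O–O link starts with a random hydrogen
  placement; loop-erased path reversals annihilate the ice-rule defects;
  4 × n_links rejection-free loop-reversal Monte Carlo moves (the
  standard loop algorithm for ice models) then decorrelate the state
  toward a uniform sample of the ice manifold. The move count was fixed
  by comparing against an independently implemented long-loop sampler;
  both give statistically identical directional-ring fractions. A single
  integer seed controls the whole assignment and is recorded in the
  frame metadata. Net-dipole zeroing is **not** part of the uniform
  ensemble; an optional flag greedily drives the cell dipole toward zero
  for users who want GenIce-like cells.

On these uniform ice-rules ensembles the directional-hexagon fraction of
ice Ih computes to ≈ 0.173–0.174, slightly below the independence
estimate P_D(6) = 0.1756: closing a hexagon within the lattice correlates
the member orientations weakly. Both values round into the commonly
quoted 0.176(6).

## What the generated data does and does not show

The factory emulates defect-free, unthermalised crystals; passing tests on
them validate the graph/ring/pruning/metric machinery and the proton-order
statistics exactly, but say nothing about thermal disorder, density
fluctuations, interfaces or defects in real trajectories. Liquid-state
behaviour is exercised structurally (noise-perturbed lattices drive q and
RSF down monotonically and keep RSF in [0, 1]) without claiming liquid
state points: quantitative liquid values require long MD trajectories,
which this package analyses but does not produce.

## Numerical choices and problem sizes

Neighbour searches use periodic k-d trees; equal-distance ties are broken
by water index (distances within 1e-9 Å count as tied). Shift encoding,
tie tolerances and the boundary epsilons above are the only magic numbers.
Default analysis sizes in the test-suite and acceptance script are
1024-water crystals (the standard simulation-cell size for these
fingerprints: the counts 2048 and 512 scale linearly with N); property
sweeps use 128–216 waters and ≤ 14-node random graphs, where exhaustive
oracles are feasible. The full acceptance recomputation takes ~30 s on one
CPU.

## Known limitations

Orthorhombic cells only; no energetic H-bond definitions; no analysis of
rings larger than the configured cap; ordered proton patterns provided
only for ice XI (others via input files); the `hbond_first` q mode needs
at least the H-bond graph of the frame; GRO files are read at their
0.001 nm format precision.
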