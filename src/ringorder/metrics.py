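"""Order metrics: tetrahedrality q, ring summation factor, directional-ring
probabilities, and their per-frame time series.

The tetrahedral order parameter (Errington-Debenedetti form) of water i is

    q_i = 1 - 3/8 * sum_{j<k} (cos(psi_jk) + 1/3)^2

over the six angles psi_jk subtended at i by its four nearest neighbours.
q = 1 for a regular tetrahedron, averages 0 over uniformly random
neighbour directions, and is unbounded below (a fully collinear shell gives
-3).  The ring summation factor

    RSF = (number of primitive rings) / (2 * number of waters)

counts CA-pruned rings of sizes 3..10 against the maximum possible number
of H-bonds (each water can donate two), so a defect-free crystal in which
every H-bond participates in ring formation reaches 1 and an ideal-gas-like
system sits at 0.

The probability that a randomly oriented ice-rules ring of n H-bonds is
directional is P_D = 2*(2/3)^n: each successive water continues the
head-to-tail chain through 2 of its 3 remaining bonding sites, and the
factor two counts the two rotational senses.  The observed counterpart
P_n,obs is the directional fraction of *unpruned* rings of each size
(pruning preferentially removes large nondirectional rings and would bias
the fraction upward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import WaterFrame
from .hbonds import HBondGraph, neighbor_candidates
from .pruning import PruneSpec, PrunedRingSet, prune
from .rings import DEFAULT_MAX_RING, MIN_RING, RingSet, enumerate_rings

__all__ = [
    "NeighborShell",
    "OrderRecord",
    "DirectionalStats",
    "tetrahedrality",
    "select_neighbors",
    "q_per_molecule",
    "rsf",
    "predicted_directional_probability",
    "observed_directional_fraction",
    "order_timeseries",
]


@dataclass
class NeighborShell:
    """Four neighbour vectors around one water, minimum-image, Angstrom."""

    center: int
    neighbors: tuple[int, int, int, int]
    vectors: np.ndarray  # (4, 3)


@dataclass
class OrderRecord:
    frame_index: int
    q_per_molecule: np.ndarray
    q_mean: float
    rsf: float
    criterion: str
    n_waters: int
    ring_counts: dict[int, int]


@dataclass
class DirectionalStats:
    """Per-size directional statistics on UNPRUNED rings.

    ``observed[n]`` is NaN for sizes with zero enumerated rings (undefined,
    not zero); consult ``total[n]`` to distinguish the two cases.
    """

    sizes: tuple[int, ...]
    total: dict[int, int]
    directional: dict[int, int]
    observed: dict[int, float]
    predicted: dict[int, float]


def tetrahedrality(shell: NeighborShell | np.ndarray) -> float:
    """Tetrahedral order parameter q of a 4-neighbour shell."""
    vec = shell.vectors if isinstance(shell, NeighborShell) else np.asarray(shell, dtype=float)
    if vec.shape != (4, 3):
        raise ValueError("a neighbour shell is four 3-vectors")
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms == 0):
        raise ValueError("neighbour coincides with the central water")
    u = vec / norms[:, None]
    q = 1.0
    for j in range(3):
        for k in range(j + 1, 4):
            q -= 3.0 / 8.0 * (np.dot(u[j], u[k]) + 1.0 / 3.0) ** 2
    return float(q)


def _q_from_units(u: np.ndarray) -> np.ndarray:
    """Vectorized q for an (n, 4, 3) array of unit neighbour vectors."""
    acc = np.zeros(len(u))
    for j in range(3):
        for k in range(j + 1, 4):
            acc += (np.einsum("ij,ij->i", u[:, j], u[:, k]) + 1.0 / 3.0) ** 2
    return 1.0 - 3.0 / 8.0 * acc


def select_neighbors(
    frame: WaterFrame, graph: HBondGraph | None = None, mode: str = "nearest4"
) -> list[NeighborShell]:
    """Pick the 4-neighbour shell of every water.

    ``nearest4`` takes the four nearest oxygens.  ``hbond_first`` takes
    H-bonded partners (either direction) sorted by distance first and pads
    with the nearest non-bonded oxygens — the appropriate choice for dense
    interpenetrating lattices such as ice VII, where the four H-bonded
    partners sit among eight equidistant neighbours.
    """
    if frame.n_waters < 5:
        raise ValueError("need at least 5 waters to build 4-neighbour shells")
    idx, _ = neighbor_candidates(frame, min(frame.n_waters - 1, 16))
    pos = frame.oxygen_positions % frame.box
    box = frame.box
    if mode == "nearest4":
        chosen = idx[:, :4]
    elif mode == "hbond_first":
        if graph is None:
            raise ValueError("hbond_first needs the H-bond graph")
        partners: list[set] = [set() for _ in range(frame.n_waters)]
        for hb in graph.edges:
            partners[hb.donor].add(hb.acceptor)
            partners[hb.acceptor].add(hb.donor)
        chosen = np.empty((frame.n_waters, 4), dtype=int)
        for i in range(frame.n_waters):
            ranked = [j for j in idx[i] if j in partners[i]]
            ranked += [j for j in idx[i] if j not in partners[i]]
            chosen[i] = ranked[:4]
    else:
        raise ValueError("mode must be 'nearest4' or 'hbond_first'")
    vec = pos[chosen] - pos[:, None, :]
    vec -= box * np.round(vec / box)
    return [
        NeighborShell(i, tuple(int(j) for j in chosen[i]), vec[i])
        for i in range(frame.n_waters)
    ]


def q_per_molecule(
    frame: WaterFrame, graph: HBondGraph | None = None, mode: str = "nearest4"
) -> np.ndarray:
    shells = select_neighbors(frame, graph, mode)
    vec = np.stack([s.vectors for s in shells])
    u = vec / np.linalg.norm(vec, axis=2)[:, :, None]
    return _q_from_units(u)


def rsf(pruned: PrunedRingSet, n_waters: int) -> float:
    """Ring summation factor: primitive rings / (2 * n_waters)."""
    if n_waters <= 0:
        raise ValueError("n_waters must be positive")
    if pruned.spec.criterion != "CA":
        import logging

        logging.getLogger(__name__).warning(
            "RSF is defined with CA pruning; using %s is non-standard", pruned.spec.name
        )
    value = len(pruned.rings) / (2.0 * n_waters)
    if value > 1.0:
        import logging

        logging.getLogger(__name__).warning("RSF %.4f exceeds 1", value)
    return value


def predicted_directional_probability(n: int) -> float:
    """P_D = 2*(2/3)^n, the chance a random ice-rules n-ring is directional."""
    if n < MIN_RING:
        raise ValueError(f"ring size must be >= {MIN_RING}")
    return 2.0 * (2.0 / 3.0) ** n


def observed_directional_fraction(rings: RingSet) -> DirectionalStats:
    """Directional fraction per ring size, computed on unpruned rings."""
    sizes = tuple(range(MIN_RING, rings.max_ring + 1))
    total = rings.counts_by_size()
    direct = rings.directional_counts_by_size()
    observed = {
        n: (direct[n] / total[n]) if total[n] else float("nan") for n in sizes
    }
    predicted = {n: predicted_directional_probability(n) for n in sizes}
    return DirectionalStats(sizes, total, direct, observed, predicted)


def order_record(
    frame: WaterFrame,
    cutoff: float = 3.5,
    angle_max: float = 30.0,
    criterion: str = "CA",
    max_ring: int = DEFAULT_MAX_RING,
    q_mode: str = "nearest4",
) -> OrderRecord:
    """Compute q and RSF for a single frame."""
    from .hbonds import detect_hbonds

    graph = detect_hbonds(frame, cutoff, angle_max)
    rings = enumerate_rings(graph, max_ring)
    pruned = prune(rings, PruneSpec(criterion=criterion, max_ring=max_ring))
    q = q_per_molecule(frame, graph, q_mode)
    return OrderRecord(
        frame_index=frame.frame_index,
        q_per_molecule=q,
        q_mean=float(q.mean()),
        rsf=rsf(pruned, frame.n_waters),
        criterion=criterion,
        n_waters=frame.n_waters,
        ring_counts=pruned.counts_by_size(),
    )


def order_timeseries(frames, **kwargs) -> list[OrderRecord]:
    """One OrderRecord per frame of a trajectory (any WaterFrame iterable)."""
    records = [order_record(f, **kwargs) for f in frames]
    if not records:
        raise ValueError("empty trajectory")
    return records


def timeseries_summary(records: list[OrderRecord]) -> dict:
    """Trajectory means with standard errors of the mean across frames."""
    q = np.array([r.q_mean for r in records])
    r_ = np.array([r.rsf for r in records])
    nf = len(records)
    sem = lambda x: float(x.std(ddof=1) / np.sqrt(nf)) if nf > 1 else 0.0
    return {
        "n_frames": nf,
        "q_mean": float(q.mean()),
        "q_sem": sem(q),
        "rsf_mean": float(r_.mean()),
        "rsf_sem": sem(r_),
    }
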