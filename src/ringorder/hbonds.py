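"""Directed donor->acceptor hydrogen-bond graph construction.

A hydrogen bond is defined geometrically (Luzar-Chandler): donor-acceptor
oxygen separation at most 3.5 A and an OOH cone angle, measured at the donor
oxygen between the O_d->O_a and O_d->H vectors, strictly below 30 degrees.
The distance criterion is inclusive and the angle criterion exclusive.
Periodic boundaries are handled with the minimum-image convention in
orthorhombic boxes; each edge records the integer lattice translation
(image shift) crossed from donor to acceptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .frames import WaterFrame

__all__ = ["HBond", "HBondGraph", "detect_hbonds", "neighbor_candidates"]

DEFAULT_CUTOFF = 3.5  # Angstrom, inclusive
DEFAULT_ANGLE_MAX = 30.0  # degrees, exclusive
# boundary tie tolerance: geometries within 1e-9 (A or deg) of a threshold
# are resolved as if they sat exactly on it
_EPS = 1e-9


@dataclass(frozen=True)
class HBond:
    """One directed hydrogen bond."""

    donor: int
    acceptor: int
    hydrogen: int  # 0 or 1 within the donor water
    image_shift: tuple[int, int, int]  # acceptor_pos + shift*box is the bonded image
    oo_distance: float
    ooh_angle: float


@dataclass
class HBondGraph:
    """Directed donor->acceptor multigraph over the waters of one frame."""

    n_waters: int
    edges: list[HBond]
    box: np.ndarray
    out_edges: list[list[int]] = field(default_factory=list)  # edge indices per donor
    in_edges: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.out_edges:
            self.out_edges = [[] for _ in range(self.n_waters)]
            self.in_edges = [[] for _ in range(self.n_waters)]
            for e, hb in enumerate(self.edges):
                self.out_edges[hb.donor].append(e)
                self.in_edges[hb.acceptor].append(e)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def out_degree(self) -> np.ndarray:
        return np.array([len(o) for o in self.out_edges])

    def in_degree(self) -> np.ndarray:
        return np.array([len(i) for i in self.in_edges])

    def undirected_adjacency(self) -> list[list[tuple[int, tuple[int, int, int], bool, bool]]]:
        """Per-water neighbour list ``(nbr, shift, forward, backward)``.

        ``forward`` means a donor->acceptor edge exists from the water to the
        neighbour (at that image shift), ``backward`` the reverse.  A pair
        donating to each other yields a single entry with both flags set.
        """
        adj: list[dict] = [dict() for _ in range(self.n_waters)]
        for hb in self.edges:
            s = hb.image_shift
            rs = (-s[0], -s[1], -s[2])
            key = (hb.acceptor, s)
            f, b = adj[hb.donor].get(key, (False, False))
            adj[hb.donor][key] = (True, b)
            key = (hb.donor, rs)
            f, b = adj[hb.acceptor].get(key, (False, False))
            adj[hb.acceptor][key] = (f, True)
        return [
            sorted((n, s, f, b) for (n, s), (f, b) in d.items()) for d in adj
        ]


def _validate_frame(frame: WaterFrame, cutoff: float) -> None:
    if np.any(frame.box < 2.0 * cutoff):
        raise ValueError(
            f"box {frame.box.round(3)} A too small for the minimum-image "
            f"convention; every edge must be >= {2 * cutoff} A"
        )
    frame.validate_covalent_geometry()


def detect_hbonds(
    frame: WaterFrame,
    cutoff: float = DEFAULT_CUTOFF,
    angle_max: float = DEFAULT_ANGLE_MAX,
) -> HBondGraph:
    """Build the directed H-bond graph of one frame.

    Both hydrogens of each candidate donor are tested independently against
    every oxygen within ``cutoff``, so a water pair may carry two
    antiparallel edges.  Edges are emitted in a deterministic order (sorted
    by donor, hydrogen, acceptor).
    """
    _validate_frame(frame, cutoff)
    wf = frame.wrapped()
    pos, box = wf.oxygen_positions, wf.box
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(cutoff + _EPS, output_type="ndarray")
    if len(pairs) == 0:
        return HBondGraph(frame.n_waters, [], box)
    # evaluate both directions of every close pair
    di = np.concatenate([pairs[:, 0], pairs[:, 1]])
    ai = np.concatenate([pairs[:, 1], pairs[:, 0]])
    voo = pos[ai] - pos[di]
    shift = -np.round(voo / box)
    voo += shift * box
    roo = np.linalg.norm(voo, axis=1)
    keep = (roo <= cutoff + _EPS) & (roo > 1e-6)  # guard coincident images
    di, ai, voo, shift, roo = di[keep], ai[keep], voo[keep], shift[keep], roo[keep]
    uoo = voo / roo[:, None]
    voh = wf.hydrogen_positions[di] - pos[di][:, None, :]  # (m, 2, 3)
    uoh = voh / np.linalg.norm(voh, axis=2)[:, :, None]
    cosang = np.einsum("mj,mhj->mh", uoo, uoh)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    edges = []
    for h in range(2):
        ok = ang[:, h] < angle_max - _EPS
        for m in np.nonzero(ok)[0]:
            edges.append(
                HBond(
                    donor=int(di[m]),
                    acceptor=int(ai[m]),
                    hydrogen=h,
                    image_shift=tuple(int(x) for x in shift[m]),
                    oo_distance=float(roo[m]),
                    ooh_angle=float(ang[m, h]),
                )
            )
    edges.sort(key=lambda e: (e.donor, e.hydrogen, e.acceptor))
    return HBondGraph(frame.n_waters, edges, box)


def neighbor_candidates(frame: WaterFrame, k: int) -> tuple[np.ndarray, np.ndarray]:
    """The ``k`` nearest oxygen neighbours of every water (minimum image).

    Returns ``(indices, distances)`` of shape (n, k), sorted ascending by
    distance with exact ties broken by water index (distances equal within
    1e-9 A count as tied).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= frame.n_waters:
        raise ValueError(f"k={k} must be smaller than n_waters={frame.n_waters}")
    pos = frame.oxygen_positions % frame.box
    tree = cKDTree(pos, boxsize=frame.box)
    # over-query to make index tie-breaking stable at shell boundaries
    kq = min(frame.n_waters, k + 8)
    dist, idx = tree.query(pos, k=kq)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    order = np.lexsort((idx, np.round(dist / 1e-9).astype(np.int64)), axis=1)
    rows = np.arange(frame.n_waters)[:, None]
    return idx[rows, order][:, :k], dist[rows, order][:, :k]
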