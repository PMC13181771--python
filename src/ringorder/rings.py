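"""Exhaustive enumeration of closed H-bond paths (rings) under PBC.

Rings are simple cycles of the *undirected* H-bond connectivity with
3 <= n <= max_ring members and zero net periodic image shift: a path that
crosses a box wall must cross back through the same wall before closing, so
cycles that wind around the torus are rejected.  Edge direction is ignored
for path existence but retained for the directionality classification: a
ring is directional when all its H-bonds can be oriented head-to-tail
(donor->acceptor) in one rotational sense.

The depth-first search starts from every water and only extends to
higher-indexed waters, which removes the "n starting points" part of the
2n traversal degeneracy during the search; the remaining factor two (the
two rotational senses) is removed by requiring the second member to be
smaller than the last at closure.  Each undirected ring is therefore
produced exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import WaterFrame
from .hbonds import HBondGraph

__all__ = ["RingPath", "RingSet", "enumerate_rings", "classify_directional", "ring_centers"]

DEFAULT_MAX_RING = 10
MIN_RING = 3

# image shifts are encoded as (dx*64 + dy)*64 + dz; path lengths <= max_ring
# keep every accumulated component within +-max_ring, so the encoded sum is
# zero iff the shift triple is zero
_M = 64
_M2 = _M * _M


def _encode(shift: tuple[int, int, int]) -> int:
    return (shift[0] * _M + shift[1]) * _M + shift[2]


@dataclass(frozen=True)
class RingPath:
    """One undirected ring, stored in canonical orientation.

    ``members`` starts at the lowest water index; the traversal direction is
    the one whose second member is smaller than its last.  ``step_shifts[i]``
    is the image shift crossed from ``members[i]`` to ``members[i+1]``
    (cyclically); the shifts sum to zero.
    """

    members: tuple[int, ...]
    step_shifts: tuple[tuple[int, int, int], ...]
    directional: bool

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def canonical_key(self) -> tuple:
        return self.members + (self.step_shifts,)


@dataclass
class RingSet:
    rings: list[RingPath]
    max_ring: int = DEFAULT_MAX_RING
    frame_index: int = 0

    def __len__(self) -> int:
        return len(self.rings)

    def counts_by_size(self) -> dict[int, int]:
        counts = {n: 0 for n in range(MIN_RING, self.max_ring + 1)}
        for r in self.rings:
            counts[r.n] += 1
        return counts

    def directional_counts_by_size(self) -> dict[int, int]:
        counts = {n: 0 for n in range(MIN_RING, self.max_ring + 1)}
        for r in self.rings:
            if r.directional:
                counts[r.n] += 1
        return counts

    def directional_subset(self) -> "RingSet":
        return RingSet(
            [r for r in self.rings if r.directional], self.max_ring, self.frame_index
        )


def enumerate_rings(
    graph: HBondGraph, max_ring: int = DEFAULT_MAX_RING, directed_traversal: bool = False
) -> RingSet:
    """Enumerate every ring of the graph exactly once.

    With ``directed_traversal`` the search follows only head-to-tail
    orientable continuations, yielding exactly the directional subset at a
    fraction of the cost.
    """
    if max_ring < MIN_RING:
        raise ValueError(f"max_ring must be >= {MIN_RING}")
    adj_full = graph.undirected_adjacency()
    # flat per-vertex arrays: neighbour, encoded shift, decoded shift, fwd, bwd
    adj = [
        [(n, _encode(s), s, f, b) for (n, s, f, b) in nbrs] for nbrs in adj_full
    ]
    n_waters = graph.n_waters
    rings: list[RingPath] = []
    visited = bytearray(n_waters)
    path: list[int] = []
    shifts: list[tuple[int, int, int]] = []

    def extend(v: int, acc: int, fwd: bool, bwd: bool, start: int, depth: int) -> None:
        for (u, es, s, f, b) in adj[v]:
            if u == start:
                if depth >= MIN_RING and acc + es == 0 and path[1] < v:
                    dirf = fwd and f
                    dirb = bwd and b
                    if directed_traversal and not (dirf or dirb):
                        continue
                    rings.append(
                        RingPath(tuple(path), tuple(shifts) + (s,), dirf or dirb)
                    )
            elif u > start and not visited[u] and depth < max_ring:
                nf = fwd and f
                nb = bwd and b
                if directed_traversal and not (nf or nb):
                    continue
                visited[u] = 1
                path.append(u)
                shifts.append(s)
                extend(u, acc + es, nf, nb, start, depth + 1)
                path.pop()
                shifts.pop()
                visited[u] = 0

    for start in range(n_waters):
        if not adj[start]:
            continue
        visited[start] = 1
        path.append(start)
        extend(start, 0, True, True, start, 1)
        path.pop()
        visited[start] = 0
    return RingSet(rings, max_ring)


def classify_directional(ring: RingPath, graph: HBondGraph) -> bool:
    """Re-derive the directionality of a ring from the graph edges.

    True iff all n H-bonds can be oriented head-to-tail around the loop in
    one rotational sense (either sense counts).
    """
    adj = {  # (a, b, shift) -> (forward, backward)
    }
    for nbrs, a in zip(graph.undirected_adjacency(), range(graph.n_waters)):
        for (n, s, f, b) in nbrs:
            adj[(a, n, s)] = (f, b)
    fwd = bwd = True
    m = ring.members
    for i in range(ring.n):
        a, b = m[i], m[(i + 1) % ring.n]
        f, bk = adj[(a, b, ring.step_shifts[i])]
        fwd = fwd and f
        bwd = bwd and bk
    return fwd or bwd


def ring_centers(rings: RingSet, frame: WaterFrame) -> np.ndarray:
    """Geometric centers of the member oxygens, PBC-unwrapped then wrapped.

    Member coordinates are unwrapped by accumulating the per-step image
    shifts, so a ring straddling a periodic wall gets its center near the
    wall rather than in the middle of the box.
    """
    wf = frame.wrapped()
    pos, box = wf.oxygen_positions, wf.box
    centers = np.empty((len(rings.rings), 3))
    for k, r in enumerate(rings.rings):
        acc = np.zeros(3)
        pts = [pos[r.members[0]]]
        for i in range(r.n - 1):
            acc += r.step_shifts[i]
            pts.append(pos[r.members[i + 1]] + acc * box)
        centers[k] = np.mean(pts, axis=0)
    return centers % box
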