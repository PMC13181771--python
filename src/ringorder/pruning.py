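"""Commonality-based primitive-ring pruning (CV, CE, CA, CD and D-variants).

A ring is eliminated when it shares a run of k sequential members with a
strictly smaller *retained* ring, where k = 1 (common vertex), 2 (common
edge), 3 (common angle) or 4 (common dihedral).  Runs are compared as
unordered sequences: rotation and traversal direction are ignored.  Rings
are processed smallest-first, equal-size rings sharing a run are both
retained, and an eliminated ring never eliminates anything itself.  The CA
criterion reproduces the classic Speedy-style primitive-ring counting.

The directional variants (DCV/DCE/DCA/DCD) first restrict the input to
directional rings and prune within that subset only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .rings import DEFAULT_MAX_RING, MIN_RING, RingPath, RingSet

__all__ = ["PruneSpec", "PrunedRingSet", "RingDistribution", "prune", "ring_distribution"]

log = logging.getLogger(__name__)

CRITERIA = ("CV", "CE", "CA", "CD")
RUN_LENGTH = {"CV": 1, "CE": 2, "CA": 3, "CD": 4}


@dataclass(frozen=True)
class PruneSpec:
    criterion: str = "CA"
    directional_only: bool = False
    max_ring: int = DEFAULT_MAX_RING

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")

    @property
    def run_length(self) -> int:
        return RUN_LENGTH[self.criterion]

    @property
    def name(self) -> str:
        return ("D" if self.directional_only else "") + self.criterion


@dataclass
class PrunedRingSet:
    rings: list[RingPath]
    spec: PruneSpec
    provenance: int  # number of input rings considered

    def __len__(self) -> int:
        return len(self.rings)

    def counts_by_size(self) -> dict[int, int]:
        counts = {n: 0 for n in range(MIN_RING, self.spec.max_ring + 1)}
        for r in self.rings:
            counts[r.n] += 1
        return counts


@dataclass
class RingDistribution:
    """Per-size ring counts with the 2N (max H-bond) normalization."""

    counts: dict[int, int]
    normalized: dict[int, float]
    n_waters: int
    spec: PruneSpec


def _runs(ring: RingPath, k: int):
    """Canonicalized k-long sequential member runs of a ring (cyclic)."""
    m = ring.members
    n = ring.n
    if k == 1:
        return m
    out = []
    for i in range(n):
        seq = tuple(m[(i + j) % n] for j in range(k))
        rev = seq[::-1]
        out.append(seq if seq <= rev else rev)
    return out


def prune(rings: RingSet, spec: PruneSpec = PruneSpec()) -> PrunedRingSet:
    """Reduce a deduplicated ring set to its primitive rings."""
    if spec.criterion == "CD" and rings.max_ring <= DEFAULT_MAX_RING:
        log.warning(
            "CD pruning with max_ring=%d may retain inflatable survivors: "
            "rings larger than the cap that would prune them are invisible",
            rings.max_ring,
        )
    items = rings.directional_subset().rings if spec.directional_only else rings.rings
    k = spec.run_length
    by_size: dict[int, list[RingPath]] = {}
    for r in items:
        by_size.setdefault(r.n, []).append(r)
    seen: set = set()  # runs of retained rings of strictly smaller sizes
    survivors: list[RingPath] = []
    for size in sorted(by_size):
        retained_here = []
        for r in by_size[size]:
            if any(run in seen for run in _runs(r, k)):
                continue
            retained_here.append(r)
        for r in retained_here:
            seen.update(_runs(r, k))
        survivors.extend(retained_here)
    return PrunedRingSet(survivors, spec, provenance=len(items))


def ring_distribution(pruned: PrunedRingSet, n_waters: int) -> RingDistribution:
    """Per-size counts normalized by the maximum H-bond count 2 * n_waters."""
    if n_waters <= 0:
        raise ValueError("n_waters must be positive")
    counts = pruned.counts_by_size()
    norm = {n: c / (2.0 * n_waters) for n, c in counts.items()}
    return RingDistribution(counts, norm, n_waters, pruned.spec)
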