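"""Commonality pruning: fused-ring reference cases and criterion properties."""

import numpy as np
import pytest

from oracles import graph_from_directed_edges, random_hbond_graph

from ringorder import (
    PruneSpec,
    detect_hbonds,
    enumerate_rings,
    prune,
    ring_distribution,
)


def fused_rings_graph(shared_edges: int):
    """A 5-ring and a 6-ring sharing a path of ``shared_edges`` bonds.

    With one shared edge the simple cycles are {5, 6, 9}; with two shared
    edges, {5, 6, 7} (the perimeter shrinks by two).
    """
    five = [0, 1, 2, 3, 4]
    arcs = [(five[i], five[(i + 1) % 5]) for i in range(5)]
    # attach the 6-ring along the shared path 0..shared_edges
    extra = 6 - 1 - shared_edges  # new vertices needed
    new = list(range(5, 5 + extra))
    chain = [shared_edges] + new + [0]
    arcs += [(chain[i], chain[i + 1]) for i in range(len(chain) - 1)]
    return graph_from_directed_edges(5 + extra, arcs)


def survivors_by_size(rings, criterion, directional_only=False):
    p = prune(rings, PruneSpec(criterion, directional_only, rings.max_ring))
    return sorted(r.n for r in p.rings)


class TestFusedRingReferenceCases:
    def test_one_shared_edge_all_rings(self):
        rings = enumerate_rings(fused_rings_graph(1))
        assert sorted(r.n for r in rings.rings) == [5, 6, 9]

    def test_one_shared_edge_criteria(self):
        rings = enumerate_rings(fused_rings_graph(1))
        assert survivors_by_size(rings, "CV") == [5]
        assert survivors_by_size(rings, "CE") == [5]
        assert survivors_by_size(rings, "CA") == [5, 6]  # share only an edge
        assert survivors_by_size(rings, "CD") == [5, 6]  # 9 shares 4 waters with 5

    def test_two_shared_edges_prunes_seven_perimeter(self):
        rings = enumerate_rings(fused_rings_graph(2))
        assert sorted(r.n for r in rings.rings) == [5, 6, 7]
        # the 6-ring shares three sequential waters with the 5-ring
        assert survivors_by_size(rings, "CA") == [5]
        # CD only eliminates the perimeter ring
        assert survivors_by_size(rings, "CD") == [5, 6]

    def test_disjoint_hexagons_all_retained(self):
        arcs = [(i, (i + 1) % 6) for i in range(6)]
        arcs += [(6 + i, 6 + (i + 1) % 6) for i in range(6)]
        rings = enumerate_rings(graph_from_directed_edges(12, arcs))
        for crit in ("CV", "CE", "CA", "CD"):
            assert survivors_by_size(rings, crit) == [6, 6]

    def test_equal_size_rings_sharing_a_run_both_retained(self):
        # two hexagons sharing one edge: neither can prune the other
        five = [(i, (i + 1) % 6) for i in range(6)]
        arcs = five + [(1, 6), (6, 7), (7, 8), (8, 9), (9, 0)]
        rings = enumerate_rings(graph_from_directed_edges(10, arcs))
        assert sorted(r.n for r in rings.rings) == [6, 6, 10]
        assert survivors_by_size(rings, "CV") == [6, 6]


class TestCriterionProperties:
    @pytest.mark.parametrize("seed", range(40))
    def test_aggressiveness_ordering(self, seed):
        """CV <= CE <= CA <= CD survivor totals on every input."""
        rings = enumerate_rings(random_hbond_graph(seed + 500))
        counts = [len(prune(rings, PruneSpec(c)).rings) for c in ("CV", "CE", "CA", "CD")]
        assert counts == sorted(counts)

    @pytest.mark.parametrize("criterion", ["CV", "CE", "CA", "CD"])
    def test_idempotence(self, criterion, ih_small):
        from ringorder.rings import RingSet

        rings = enumerate_rings(detect_hbonds(ih_small), max_ring=8)
        once = prune(rings, PruneSpec(criterion, max_ring=8))
        twice = prune(RingSet(once.rings, 8), PruneSpec(criterion, max_ring=8))
        assert [r.canonical_key for r in twice.rings] == [r.canonical_key for r in once.rings]

    @pytest.mark.parametrize("criterion", ["CV", "CE", "CA", "CD"])
    def test_directional_variants_prune_less(self, criterion):
        """D-variants retain >= the directional survivors of the plain run."""
        for seed in range(20):
            rings = enumerate_rings(random_hbond_graph(seed + 900))
            plain = prune(rings, PruneSpec(criterion))
            directional_survivors = {
                r.canonical_key for r in plain.rings if r.directional
            }
            dvar = prune(rings, PruneSpec(criterion, directional_only=True))
            assert directional_survivors <= {r.canonical_key for r in dvar.rings}

    def test_survivors_are_subset_of_input(self, ih_small):
        rings = enumerate_rings(detect_hbonds(ih_small), max_ring=8)
        keys = {r.canonical_key for r in rings.rings}
        for crit in ("CV", "CE", "CA", "CD"):
            assert {r.canonical_key for r in prune(rings, PruneSpec(crit)).rings} <= keys


class TestDistribution:
    def test_ih_ca_distribution_is_pure_hexagons(self, ih_small):
        rings = enumerate_rings(detect_hbonds(ih_small))
        dist = ring_distribution(prune(rings, PruneSpec("CA")), ih_small.n_waters)
        assert dist.counts[6] == 2 * ih_small.n_waters
        assert sum(dist.counts.values()) == dist.counts[6]
        assert dist.normalized[6] == pytest.approx(1.0)

    def test_hbond_conservation(self, ih_small):
        """Every H-bond participates in CA-retained hexagons (none wasted)."""
        g = detect_hbonds(ih_small)
        pruned = prune(enumerate_rings(g), PruneSpec("CA"))
        used = set()
        for r in pruned.rings:
            for i in range(r.n):
                a, b = r.members[i], r.members[(i + 1) % r.n]
                used.add((min(a, b), max(a, b)))
        assert len(used) == g.n_edges
        # where every H-bond lies in exactly ONE retained ring (two disjoint
        # hexagons), survivors * mean(size) equals the H-bond count
        arcs = [(i, (i + 1) % 6) for i in range(6)] + [
            (6 + i, 6 + (i + 1) % 6) for i in range(6)
        ]
        iso = prune(enumerate_rings(graph_from_directed_edges(12, arcs)), PruneSpec("CA"))
        assert sum(r.n for r in iso.rings) == 12

    def test_empty_ring_set(self):
        from ringorder.rings import RingSet

        dist = ring_distribution(prune(RingSet([], 10), PruneSpec("CA")), 100)
        assert all(v == 0 for v in dist.counts.values())

    def test_zero_waters_rejected(self):
        from ringorder.rings import RingSet

        with pytest.raises(ValueError):
            ring_distribution(prune(RingSet([], 10), PruneSpec("CA")), 0)

    def test_cd_cap_warning_logged(self, caplog):
        from ringorder.rings import RingSet

        with caplog.at_level("WARNING"):
            prune(RingSet([], 10), PruneSpec("CD"))
        assert any("CD" in r.message for r in caplog.records)
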