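"""Order metrics: tetrahedrality limits, RSF, directional probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from oracles import graph_from_directed_edges

from ringorder import (
    CrystalSpec,
    PruneSpec,
    detect_hbonds,
    enumerate_rings,
    make_ice,
    observed_directional_fraction,
    order_record,
    order_timeseries,
    predicted_directional_probability,
    prune,
    q_per_molecule,
    rsf,
    select_neighbors,
    tetrahedrality,
    timeseries_summary,
)

TET = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)


class TestTetrahedrality:
    def test_regular_tetrahedron_gives_one(self):
        assert tetrahedrality(TET) == pytest.approx(1.0, abs=1e-12)

    def test_collinear_shell_gives_minus_three(self):
        coll = np.tile([[2.0, 0.0, 0.0]], (4, 1))
        assert tetrahedrality(coll) == pytest.approx(-3.0, abs=1e-12)

    def test_random_shells_average_zero(self):
        rng = np.random.default_rng(2024)
        v = rng.normal(size=(100_000, 4, 3))
        u = v / np.linalg.norm(v, axis=2, keepdims=True)
        from ringorder.metrics import _q_from_units

        q = _q_from_units(u)
        assert abs(q.mean()) < 0.02
        assert q.max() <= 1.0 + 1e-12  # Eq-bound: q never exceeds 1

    def test_scale_invariance(self):
        assert tetrahedrality(3.7 * TET) == pytest.approx(1.0, abs=1e-12)

    @given(
        vec=hnp.arrays(
            float,
            (4, 3),
            elements=st.floats(-5.0, 5.0, allow_nan=False),
        ).filter(lambda v: bool(np.all(np.linalg.norm(v, axis=1) > 1e-3)))
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_q_never_exceeds_one(self, vec):
        assert tetrahedrality(vec) <= 1.0 + 1e-9

    def test_coincident_neighbor_rejected(self):
        bad = TET.copy()
        bad[2] = 0.0
        with pytest.raises(ValueError):
            tetrahedrality(bad)


class TestPredictedProbability:
    def test_closed_form_values(self):
        assert predicted_directional_probability(3) == pytest.approx(16 / 27)
        assert predicted_directional_probability(6) == pytest.approx(128 / 729)
        assert round(predicted_directional_probability(3), 3) == 0.593
        assert round(predicted_directional_probability(6), 3) == 0.176

    def test_monotone_decreasing(self):
        vals = [predicted_directional_probability(n) for n in range(3, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            predicted_directional_probability(2)


class TestNeighborSelection:
    def test_ic_modes_agree(self, ic_small):
        g = detect_hbonds(ic_small)
        q4 = q_per_molecule(ic_small, g, "nearest4")
        qh = q_per_molecule(ic_small, g, "hbond_first")
        assert np.allclose(q4, qh)
        assert np.allclose(q4, 1.0, atol=1e-9)  # ideal lattice

    def test_vii_needs_hbond_priority(self, vii_small):
        """8 equidistant neighbours wreck q unless H-bonded ones are picked."""
        g = detect_hbonds(vii_small)
        q4 = q_per_molecule(vii_small, g, "nearest4").mean()
        qh = q_per_molecule(vii_small, g, "hbond_first").mean()
        assert qh == pytest.approx(1.0, abs=1e-9)
        assert q4 < 0.7

    def test_hbond_first_shells_are_bonded_partners(self, vii_small):
        g = detect_hbonds(vii_small)
        partners = [set() for _ in range(vii_small.n_waters)]
        for hb in g.edges:
            partners[hb.donor].add(hb.acceptor)
            partners[hb.acceptor].add(hb.donor)
        for shell in select_neighbors(vii_small, g, "hbond_first")[:32]:
            assert set(shell.neighbors) == partners[shell.center]

    def test_too_few_waters_rejected(self):
        from conftest import water_pair

        with pytest.raises(ValueError):
            select_neighbors(water_pair(3.0, 0.0), None, "nearest4")


class TestRSF:
    def test_crystal_reaches_one(self, ih_small):
        pruned = prune(enumerate_rings(detect_hbonds(ih_small)), PruneSpec("CA"))
        assert rsf(pruned, ih_small.n_waters) == pytest.approx(1.0)

    def test_no_rings_gives_zero(self):
        from ringorder.rings import RingSet

        assert rsf(prune(RingSet([], 10), PruneSpec("CA")), 64) == 0.0

    def test_non_ca_warns(self, caplog):
        from ringorder.rings import RingSet

        with caplog.at_level("WARNING"):
            rsf(prune(RingSet([], 10), PruneSpec("CV")), 64)
        assert any("non-standard" in r.message for r in caplog.records)


class TestObservedDirectionalFraction:
    def test_all_directional_fixture(self):
        g = graph_from_directed_edges(6, [(i, (i + 1) % 6) for i in range(6)])
        stats = observed_directional_fraction(enumerate_rings(g))
        assert stats.observed[6] == 1.0
        assert np.isnan(stats.observed[5])  # no pentagons: undefined, not 0
        assert stats.total[5] == 0

    def test_disordered_ice_matches_prediction(self, ih_small):
        """Ice-rules randomized hexagon orientation fraction tracks P_D."""
        rings = enumerate_rings(detect_hbonds(ih_small), max_ring=6)
        stats = observed_directional_fraction(rings)
        n6 = stats.total[6]
        p = stats.predicted[6]
        ci = 3 * np.sqrt(p * (1 - p) / n6)
        # one crystal: binomial-scale agreement (correlations inflate this a bit)
        assert abs(stats.observed[6] - p) < max(ci, 0.03)

    def test_synthetic_random_network_converges_to_prediction(self):
        """On a random (locally tree-like) 4-regular network with uniformly
        randomized 2-out/2-in orientations, the directional fraction of
        hexagons converges to P_D within a binomial confidence interval."""
        import networkx as nx

        from ringorder import random_ice_orientation

        rng_graph = nx.random_regular_graph(4, 500, seed=7)
        edges = [tuple(e) for e in rng_graph.edges()]
        direct_total = 0
        total = 0
        for seed in range(40):
            orient = random_ice_orientation(edges, 500, seed=seed)
            arcs = [
                (a, b) if o == 0 else (b, a) for (a, b), o in zip(edges, orient)
            ]
            rs = enumerate_rings(graph_from_directed_edges(500, arcs), max_ring=6)
            direct_total += rs.directional_counts_by_size()[6]
            total += rs.counts_by_size()[6]
        assert total > 300
        p = predicted_directional_probability(6)
        ci = 3 * np.sqrt(p * (1 - p) / total)
        assert abs(direct_total / total - p) < ci


class TestTimeseries:
    def _noisy(self, frame, sigma, seed):
        rng = np.random.default_rng(seed)
        shift = rng.normal(scale=sigma, size=(frame.n_waters, 3)) if sigma else 0.0
        out = frame.copy()
        out.oxygen_positions = out.oxygen_positions + shift
        out.hydrogen_positions = out.hydrogen_positions + (
            np.asarray(shift)[:, None, :] if sigma else 0.0
        )
        return out

    def test_identical_frames_constant_series(self, ic_small):
        records = order_timeseries([ic_small, ic_small, ic_small], max_ring=6)
        s = timeseries_summary(records)
        assert s["q_sem"] == 0.0 and s["rsf_sem"] == 0.0
        assert s["rsf_mean"] == pytest.approx(records[0].rsf)

    def test_order_decreases_with_positional_noise(self, ic_small):
        """Rigid-molecule noise melts the network: q and RSF fall together."""
        frames = [self._noisy(ic_small, s, seed=4) for s in (0.0, 0.25, 0.6, 1.2)]
        records = order_timeseries(frames, max_ring=8)
        q = [r.q_mean for r in records]
        r_ = [r.rsf for r in records]
        assert all(a >= b - 1e-12 for a, b in zip(q, q[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(r_, r_[1:]))
        assert q[0] > q[-1] and r_[0] > r_[-1]
        assert all(0.0 <= v <= 1.0 for v in r_)
        assert q[0] == pytest.approx(1.0) and r_[0] == pytest.approx(1.0)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            order_timeseries([])

    def test_record_fields(self, ic_small):
        rec = order_record(ic_small, max_ring=6)
        assert rec.n_waters == ic_small.n_waters
        assert len(rec.q_per_molecule) == ic_small.n_waters
        assert rec.rsf == pytest.approx(1.0)
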