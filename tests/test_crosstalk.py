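"""Correlation strength and pathway-pair crosstalk scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crosspath.crosstalk import (
    EPS,
    build_crosstalk_network,
    correlation_strength,
    pearson_p,
)
from crosspath.datatypes import InteractionNetwork
from conftest import make_risk_pathway, random_crosstalk_fixture
from oracles import brute_force_crosstalk, pearson_p_closed_form


class TestCorrelationStrength:
    def test_log_powers_of_e(self):
        assert correlation_strength(math.exp(-1), math.exp(-2), math.exp(-3)) == pytest.approx(6.0)

    def test_all_ones_is_zero(self):
        assert correlation_strength(1.0, 1.0, 1.0) == 0.0

    def test_zero_clamped_finite(self):
        assert correlation_strength(0.0, 1.0, 1.0) == pytest.approx(-math.log(EPS))

    @pytest.mark.parametrize("bad", [(-0.1, 0.5, 0.5), (0.5, 1.2, 0.5)])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            correlation_strength(*bad)

    @settings(deadline=None, max_examples=100)
    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    def test_always_nonnegative(self, a, b, c):
        assert correlation_strength(a, b, c) >= 0.0


class TestPearsonP:
    def test_identity_perfect(self):
        x = np.arange(10.0)
        r, p = pearson_p(x, x)
        assert r == pytest.approx(1.0) and p < 1e-10

    def test_negation_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_five_point_fixture_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 2.0, 3.0])
        r, p = pearson_p(x, y)
        r0, p0 = pearson_p_closed_form(x, y)
        assert r == pytest.approx(r0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)

    def test_near_zero_correlation_p_near_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([3.0, 1.0, 5.0, 2.0, 4.0])  # r = 0.3 at n=5 -> p ~ 0.62
        r, p = pearson_p(x, y)
        assert p > 0.5

    def test_constant_vector_convention(self):
        with pytest.warns(UserWarning, match="constant"):
            r, p = pearson_p(np.ones(5), np.arange(5.0))
        assert (r, p) == (0.0, 1.0)


def _simple_instance():
    """Two pathways, one PPI edge crossing them."""
    pa = make_risk_pathway("PA", {"g1", "g2"})
    pb = make_risk_pathway("PB", {"g3", "g4"})
    network = InteractionNetwork(ppi_edges={("g1", "g3")})
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(
        rng.normal(size=(4, 12)), index=["g1", "g2", "g3", "g4"],
        columns=[f"s{i}" for i in range(12)],
    )
    diff_p = {"g1": 0.01, "g2": 0.5, "g3": 0.02, "g4": 0.9}
    return [pa, pb], network, diff_p, expr


class TestBuildNetwork:
    def test_no_cross_edges_zero_score(self):
        pathways, _, diff_p, expr = _simple_instance()
        net = build_crosstalk_network(pathways, InteractionNetwork(), diff_p, expr, set())
        assert net.total_crosstalk == 0.0
        assert net.entries[("PA", "PB")].pairs == []

    def test_singleton_pair_score(self):
        pathways, network, diff_p, expr = _simple_instance()
        net = build_crosstalk_network(pathways, network, diff_p, expr, set())
        entry = net.entries[("PA", "PB")]
        assert len(entry.pairs) == 1
        _, p_ab = pearson_p_closed_form(expr.loc["g1"].values, expr.loc["g3"].values)
        expected = -(math.log(0.01) + math.log(0.02) + math.log(p_ab))
        assert entry.score == pytest.approx(expected, abs=1e-9)

    def test_pair_count_combinatorics(self):
        rng = np.random.default_rng(1)
        pathways, network, diff_p, expr, mirna_ids = random_crosstalk_fixture(rng)
        net = build_crosstalk_network(pathways, network, diff_p, expr, mirna_ids)
        k = len(pathways)
        assert len(net.entries) == k * (k - 1) // 2

    def test_pathway_order_invariance(self):
        rng = np.random.default_rng(2)
        pathways, network, diff_p, expr, mirna_ids = random_crosstalk_fixture(rng)
        a = build_crosstalk_network(pathways, network, diff_p, expr, mirna_ids)
        b = build_crosstalk_network(pathways[::-1], network, diff_p, expr, mirna_ids)
        assert {k: v.score for k, v in a.entries.items()} == {k: v.score for k, v in b.entries.items()}

    def test_fewer_than_two_pathways_warns_empty(self):
        pathways, network, diff_p, expr = _simple_instance()
        with pytest.warns(UserWarning, match="fewer than 2"):
            net = build_crosstalk_network(pathways[:1], network, diff_p, expr, set())
        assert net.entries == {}

    def test_shared_feature_never_self_pairs(self):
        pa = make_risk_pathway("PA", {"g1", "g2"})
        pb = make_risk_pathway("PB", {"g1", "g3"})
        network = InteractionNetwork(ppi_edges={("g1", "g3"), ("g1", "g2")})
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(3, 10)), index=["g1", "g2", "g3"])
        diff_p = {"g1": 0.1, "g2": 0.1, "g3": 0.1}
        net = build_crosstalk_network([pa, pb], network, diff_p, expr, set())
        for pair in net.entries[("PA", "PB")].pairs:
            assert pair.a != pair.b

    def test_removing_edge_never_increases_score(self):
        rng = np.random.default_rng(4)
        pathways, network, diff_p, expr, mirna_ids = random_crosstalk_fixture(rng)
        full = build_crosstalk_network(pathways, network, diff_p, expr, mirna_ids)
        for edge in sorted(network.ppi_edges)[:5]:
            reduced = InteractionNetwork(
                ppi_edges=network.ppi_edges - {edge},
                mirna_target_edges=set(network.mirna_target_edges),
            )
            smaller = build_crosstalk_network(pathways, reduced, diff_p, expr, mirna_ids)
            for key in full.entries:
                assert smaller.entries[key].score <= full.entries[key].score + 1e-12

    def test_matches_brute_force_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pathways, network, diff_p, expr, mirna_ids = random_crosstalk_fixture(rng)
            net = build_crosstalk_network(pathways, network, diff_p, expr, mirna_ids)
            oracle = brute_force_crosstalk(
                {rp.id: rp.pathway.features for rp in pathways},
                network.ppi_edges,
                network.mirna_target_edges,
                diff_p,
                {f: expr.loc[f].to_numpy() for f in expr.index},
                mirna_ids,
            )
            for key, expected in oracle.items():
                assert net.entries[key].score == pytest.approx(expected, abs=1e-9)

    def test_tumor_only_sample_restriction(self, default_cohort, default_pipeline):
        bundle, network, *_ = default_cohort
        res = default_pipeline
        from crosspath.diffexp import differential_p_map

        diff_p = differential_p_map(res.diff_table)
        sub = res.risk_pathways[:2]
        all_net = build_crosstalk_network(
            sub, network, diff_p, bundle.combined_log2(), bundle.mirna_ids
        )
        tumor_net = build_crosstalk_network(
            sub, network, diff_p, bundle.combined_log2(), bundle.mirna_ids,
            samples=bundle.tumor_samples,
        )
        assert all_net.total_crosstalk != tumor_net.total_crosstalk
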