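"""Destruction scores, cascade removal and the combination screen."""

import numpy as np
import pytest

import crosspath as cp
from crosspath.datatypes import (
    CrosstalkNetwork,
    DrugTargetMap,
    DrugTargets,
    InteractingPair,
    InteractionNetwork,
    PathwayPairCrosstalk,
)
from crosspath.drug_perturb import (
    crosstalk_after_removal,
    destruction_score,
    optimize_combinations,
    remove_targets,
    screen_single_drugs,
)
from conftest import make_risk_pathway, random_crosstalk_fixture
from crosspath.crosstalk import build_crosstalk_network


def _hand_network():
    """Two pathways; two contributing pairs with cs 6 and 3 (hand-set)."""
    pa = make_risk_pathway("PA", {"a1", "a2"})
    pb = make_risk_pathway("PB", {"b1", "b2"})
    entry = PathwayPairCrosstalk(
        "PA", "PB", 9.0,
        [
            InteractingPair("a1", "b1", "mRNA-mRNA", 0.1, 0.1, 0.1, 0.5, 6.0),
            InteractingPair("a2", "b2", "mRNA-mRNA", 0.3, 0.3, 0.3, 0.2, 3.0),
        ],
    )
    net = CrosstalkNetwork(entries={("PA", "PB"): entry})
    return [pa, pb], net


class TestRemoveTargets:
    def test_empty_targets_identity(self):
        pathways, _ = _hand_network()
        reduced = remove_targets(pathways, set())
        assert [r.features for r in reduced] == [p.pathway.features for p in pathways]

    def test_remove_everything(self):
        pathways, _ = _hand_network()
        reduced = remove_targets(pathways, {"a1", "a2", "b1", "b2"})
        assert all(not r.features for r in reduced)

    def test_cascade_removes_orphaned_mirna(self):
        rp = make_risk_pathway(
            "P", {"t1", "t2", "other"}, mirnas={"mi"}, mirna_edges={("mi", "t1"), ("mi", "t2")}
        )
        with_cascade = remove_targets([rp], {"t1", "t2"}, cascade=True)[0]
        without = remove_targets([rp], {"t1", "t2"}, cascade=False)[0]
        assert "mi" not in with_cascade.features
        assert "mi" in without.features

    def test_partial_removal_keeps_mirna(self):
        rp = make_risk_pathway(
            "P", {"t1", "t2"}, mirnas={"mi"}, mirna_edges={("mi", "t1"), ("mi", "t2")}
        )
        reduced = remove_targets([rp], {"t1"}, cascade=True)[0]
        assert "mi" in reduced.features
        assert reduced.mirna_edges == {("mi", "t2")}

    def test_unknown_ids_ignored(self):
        pathways, _ = _hand_network()
        reduced = remove_targets(pathways, {"nonexistent"})
        assert [r.features for r in reduced] == [p.pathway.features for p in pathways]


class TestDestructionScore:
    def test_disjoint_targets_zero(self):
        pathways, net = _hand_network()
        assert destruction_score(net, pathways, {"zz"}).ds == 0.0

    def test_full_removal_one(self):
        pathways, net = _hand_network()
        assert destruction_score(net, pathways, {"a1", "a2", "b1", "b2"}).ds == 1.0

    def test_two_pair_fixture_two_thirds(self):
        """Removing only the cs=6 pair's endpoint leaves 3/9 -> DS = 2/3."""
        pathways, net = _hand_network()
        score = destruction_score(net, pathways, {"a1"})
        assert score.ds == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert score.removed_features == {"a1"}

    def test_zero_crosstalk_errors(self):
        pathways, _ = _hand_network()
        empty = CrosstalkNetwork(entries={("PA", "PB"): PathwayPairCrosstalk("PA", "PB", 0.0, [])})
        with pytest.raises(ValueError, match="no crosstalk"):
            destruction_score(empty, pathways, {"a1"})

    def test_monotone_in_target_set(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pathways, network, diff_p, expr, mirna_ids = random_crosstalk_fixture(rng)
            net = build_crosstalk_network(pathways, network, diff_p, expr, mirna_ids)
            if net.total_crosstalk == 0:
                continue
            features = sorted({f for rp in pathways for f in rp.pathway.features})
            t1 = set(features[: len(features) // 3])
            t2 = t1 | set(features[len(features) // 3: 2 * len(features) // 3])
            for cascade in (False, True):
                d1 = destruction_score(net, pathways, t1, cascade=cascade).ds
                d2 = destruction_score(net, pathways, t2, cascade=cascade).ds
                assert d1 <= d2 + 1e-12

    def test_ds_in_unit_interval(self):
        rng = np.random.default_rng(11)
        pathways, network, diff_p, expr, mirna_ids = random_crosstalk_fixture(rng)
        net = build_crosstalk_network(pathways, network, diff_p, expr, mirna_ids)
        if net.total_crosstalk == 0:
            pytest.skip("degenerate fixture")
        features = sorted({f for rp in pathways for f in rp.pathway.features})
        for k in range(0, len(features), 3):
            ds = destruction_score(net, pathways, set(features[:k])).ds
            assert 0.0 <= ds <= 1.0


class TestScreenAndCombos:
    def test_screen_sorted_and_flagged(self):
        pathways, net = _hand_network()
        drugs = DrugTargetMap(
            {
                "strong": DrugTargets({"a1"}),
                "weak": DrugTargets({"a2"}),
                "dud": DrugTargets({"zz"}),
            }
        )
        scores = screen_single_drugs(drugs, net, pathways)
        assert [s.drug for s in scores] == ["strong", "weak", "dud"]
        assert [s.passes_single for s in scores] == [True, True, False]

    def test_threshold_zero_passes_any_positive(self):
        pathways, net = _hand_network()
        drugs = DrugTargetMap({"d": DrugTargets({"a2"}), "dud": DrugTargets({"zz"})})
        scores = screen_single_drugs(drugs, net, pathways, ds_threshold=0.0)
        assert {s.drug: s.passes_single for s in scores} == {"d": True, "dud": False}

    def test_disjoint_pair_exactly_additive_and_selected(self):
        pathways, net = _hand_network()
        drugs = DrugTargetMap({"d1": DrugTargets({"a1"}), "d2": DrugTargets({"a2"})})
        scores = screen_single_drugs(drugs, net, pathways, cascade=False)
        combos = optimize_combinations(scores, drugs, net, pathways, cascade=False)
        combo = combos[0]
        assert combo.ds_combo == pytest.approx(combo.ds1 + combo.ds2, abs=1e-12)
        assert combo.selected

    def test_identical_targets_rejected(self):
        pathways, net = _hand_network()
        drugs = DrugTargetMap({"d1": DrugTargets({"a1"}), "d2": DrugTargets({"a1"})})
        scores = screen_single_drugs(drugs, net, pathways)
        combo = optimize_combinations(scores, drugs, net, pathways)[0]
        assert combo.ds_combo == pytest.approx(combo.ds1)
        assert not combo.selected

    def test_enumeration_order_invariance(self):
        pathways, net = _hand_network()
        drugs = DrugTargetMap(
            {"d1": DrugTargets({"a1"}), "d2": DrugTargets({"a2"}), "d3": DrugTargets({"b1"})}
        )
        scores = screen_single_drugs(drugs, net, pathways)
        a = optimize_combinations(scores, drugs, net, pathways)
        b = optimize_combinations(scores[::-1], drugs, net, pathways)
        assert [c.to_dict() for c in a] == [c.to_dict() for c in b]

    def test_needs_two_passing_drugs(self):
        pathways, net = _hand_network()
        drugs = DrugTargetMap({"d1": DrugTargets({"a1"})})
        scores = screen_single_drugs(drugs, net, pathways)
        with pytest.raises(ValueError):
            optimize_combinations(scores, drugs, net, pathways)


class TestCascadeSuperadditivity:
    def test_superadditive_with_cascade_only(self):
        from conftest import make_cascade_instance

        pathways, net, drugs = make_cascade_instance()
        scores = screen_single_drugs(drugs, net, pathways, cascade=True, ds_threshold=0.0)
        combo_on = optimize_combinations(scores, drugs, net, pathways, cascade=True)[0]
        assert combo_on.synergy_margin > 1e-6
        assert combo_on.selected

        scores_off = screen_single_drugs(drugs, net, pathways, cascade=False, ds_threshold=0.0)
        combo_off = optimize_combinations(scores_off, drugs, net, pathways, cascade=False)[0]
        assert combo_off.synergy_margin <= 1e-9

    def test_planted_pair_recovered_on_synthetic(self, default_cohort, default_pipeline):
        truth = default_cohort[5]
        res = default_pipeline
        from crosspath.evaluation import combo_recovery

        rec = combo_recovery(res.combos, truth)
        assert rec["planted_selected"]
        assert rec["planted_margin"] > 0

    def test_planted_strong_drug_leads_non_cascade_drugs(self, default_cohort, default_pipeline):
        truth = default_cohort[5]
        cascade_drugs = set(truth.superadditive_pairs[0])
        ranking = [s.drug for s in default_pipeline.drug_scores if s.drug not in cascade_drugs]
        assert ranking[0] == truth.strong_drug
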