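"""Co-expression modules: adjacency, TOM, clustering, trait correlation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import crosspath as cp
from crosspath.coexpression import (
    GREY,
    build_adjacency,
    detect_modules,
    extract_risk_factors,
    module_eigengene,
    module_trait,
    pick_soft_power,
    tom_similarity,
)
from crosspath.datatypes import CoexModule


def _expr(rows, columns=None):
    rows = {k: np.asarray(v, dtype=float) for k, v in rows.items()}
    return pd.DataFrame(rows).T if columns is None else pd.DataFrame(rows, index=columns).T


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        e = _expr({"a": [1, 2, 3, 4], "b": [2, 4, 6, 8]})
        adj = build_adjacency(e, power=6)
        assert adj[0, 1] == pytest.approx(1.0)

    def test_zero_correlation_gives_zero(self):
        e = _expr({"a": [1, -1, 1, -1], "b": [1, 1, -1, -1]})
        adj = build_adjacency(e, power=6)
        assert adj[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_signed_anticorrelation_power2(self):
        e = _expr({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]})
        adj = build_adjacency(e, power=2, signed=True)
        assert adj[0, 1] == pytest.approx(0.0, abs=1e-12)  # ((1-1)/2)^2

    def test_constant_feature_warns_and_zeroes(self):
        e = _expr({"a": [1, 2, 3, 4], "b": [5, 5, 5, 5]})
        with pytest.warns(UserWarning, match="constant"):
            adj = build_adjacency(e, power=6)
        assert adj[0, 1] == 0.0 and adj[1, 1] == 1.0


class TestTom:
    def test_bounds_symmetry_diagonal(self):
        rng = np.random.default_rng(0)
        cor = np.corrcoef(rng.normal(size=(15, 30)))
        adj = np.abs(cor) ** 6
        np.fill_diagonal(adj, 1.0)
        tom = tom_similarity(adj)
        assert np.all((tom >= 0) & (tom <= 1))
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)

    def test_perfect_block_is_one(self):
        adj = np.ones((5, 5))
        assert np.allclose(tom_similarity(adj), 1.0)


class TestDetectModules:
    def test_two_perfect_blocks_recovered(self):
        n = 24
        adj = np.zeros((n, n))
        adj[:12, :12] = 1.0
        adj[12:, 12:] = 1.0
        ids = [f"f{i}" for i in range(n)]
        modules, grey = detect_modules(adj, ids, min_module_size=10, cut_height=0.9)
        assert len(modules) == 2 and not grey
        assert {frozenset(m.members) for m in modules} == {
            frozenset(ids[:12]),
            frozenset(ids[12:]),
        }

    def test_identity_adjacency_all_grey(self):
        ids = [f"f{i}" for i in range(15)]
        modules, grey = detect_modules(np.eye(15), ids, min_module_size=10)
        assert modules == [] and grey == set(ids)

    def test_small_block_goes_grey(self):
        adj = np.eye(12)
        adj[:5, :5] = 1.0
        ids = [f"f{i}" for i in range(12)]
        modules, grey = detect_modules(adj, ids, min_module_size=10)
        assert modules == [] and set(ids[:5]) <= grey

    def test_fewer_features_than_min_size(self):
        ids = ["a", "b", "c"]
        modules, grey = detect_modules(np.eye(3), ids, min_module_size=10)
        assert modules == [] and grey == set(ids)


class TestModuleTrait:
    def _phenotype(self, n_t, n_n):
        idx = [f"t{i}" for i in range(n_t)] + [f"n{i}" for i in range(n_n)]
        return pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=idx)

    def test_phenotype_module_has_unit_correlation(self):
        pheno = self._phenotype(10, 10)
        rng = np.random.default_rng(1)
        base = (pheno == "tumor").astype(float).to_numpy()
        rows = {f"g{i}": base + rng.normal(scale=1e-3, size=20) for i in range(5)}
        expr = pd.DataFrame(rows, index=pheno.index).T
        mods = module_trait([CoexModule("M1", set(expr.index))], expr, pheno)
        assert abs(mods[0].trait_r) > 0.99
        assert mods[0].trait_p < 1e-10

    def test_null_module_uncorrelated(self):
        pheno = self._phenotype(40, 40)
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(6, 80)), index=[f"g{i}" for i in range(6)],
                            columns=pheno.index)
        mods = module_trait([CoexModule("M1", set(expr.index))], expr, pheno)
        assert abs(mods[0].trait_r) < 0.3
        assert mods[0].trait_p > 0.05

    def test_identical_members_eigengene_matches_series(self):
        pheno = self._phenotype(5, 5)
        series = np.arange(10, dtype=float)
        expr = pd.DataFrame({f"g{i}": series for i in range(4)}, index=pheno.index).T
        eig = module_eigengene(expr, set(expr.index))
        z = (series - series.mean()) / series.std()
        norm = np.linalg.norm
        assert min(norm(eig / norm(eig) - z / norm(z)), norm(eig / norm(eig) + z / norm(z))) < 1e-9

    def test_singleton_module_is_standardized_feature(self):
        pheno = self._phenotype(3, 3)
        expr = pd.DataFrame({"g0": [1.0, 2, 3, 4, 5, 6]}, index=pheno.index).T
        eig = module_eigengene(expr, {"g0"})
        assert np.allclose(eig.mean(), 0, atol=1e-12)
        assert np.allclose(eig.std(), 1, atol=1e-12)


class TestExtractRiskFactors:
    def _mods(self):
        return [
            CoexModule("M1", {"a", "b", "mi1"}, None, 0.9, 1e-6),
            CoexModule("M2", {"c", "d"}, None, -0.5, 0.01),
            CoexModule("M3", {"e"}, None, 0.2, 0.4),
        ]

    def test_top_selects_highest_abs_correlation(self):
        risk = extract_risk_factors(self._mods(), {"mi1"}, select="top")
        assert risk.risk_mrnas == {"a", "b"} and risk.risk_mirnas == {"mi1"}

    def test_all_significant_takes_union(self):
        risk = extract_risk_factors(self._mods(), {"mi1"}, select="all-significant")
        assert risk.risk_mrnas == {"a", "b", "c", "d"}

    def test_alpha_zero_empty_with_warning(self):
        with pytest.warns(UserWarning):
            risk = extract_risk_factors(self._mods(), {"mi1"}, alpha=0.0)
        assert not risk.all_factors

    def test_order_invariance(self):
        mods = self._mods()
        a = extract_risk_factors(mods, {"mi1"}, select="all-significant")
        b = extract_risk_factors(mods[::-1], {"mi1"}, select="all-significant")
        assert a.to_dict() == b.to_dict()


class TestSoftPower:
    def test_single_candidate(self):
        rng = np.random.default_rng(0)
        e = pd.DataFrame(rng.normal(size=(10, 20)), index=[f"g{i}" for i in range(10)])
        assert pick_soft_power(e, candidate_powers=[6], target_r2=1.01) == 6.0

    def test_heterogeneous_factor_reaches_criterion(self):
        rng = np.random.default_rng(0)
        n, m = 60, 50
        u = rng.uniform(0.1, 1.0, n) ** 2
        x = np.outer(u, rng.normal(size=m)) + rng.normal(size=(n, m))
        e = pd.DataFrame(x, index=[f"g{i}" for i in range(n)])
        power = pick_soft_power(e)
        from crosspath.coexpression import scale_free_fit_r2

        assert power <= 20
        assert scale_free_fit_r2(build_adjacency(e, power=power)) >= 0.8

    def test_fallback_warns(self):
        rng = np.random.default_rng(3)
        e = pd.DataFrame(rng.normal(size=(40, 30)), index=[f"g{i}" for i in range(40)])
        with pytest.warns(UserWarning, match="scale-free"):
            assert pick_soft_power(e, candidate_powers=[1, 2]) == 6.0


def test_planted_modules_recovered(default_pipeline, default_cohort):
    """On the default synthetic cohort the detected partition matches the
    planted one (clustered features labelled by module, grey vs. solo)."""
    truth = default_cohort[5]
    res = default_pipeline
    features = sorted(set().union(*(m.members for m in res.modules)) | res.grey)
    pred = {f: m.id for m in res.modules for f in m.members}
    labels_pred = [pred.get(f, GREY) for f in features]
    labels_true = [truth.modules.get(f, "background") for f in features]
    assert adjusted_rand_score(labels_true, labels_pred) >= 0.8
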