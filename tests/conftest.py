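"""Shared fixtures: tiny hand-built objects plus cached synthetic cohorts."""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd
import pytest

import crosspath as cp
from crosspath.datatypes import (
    ExpressionBundle,
    InteractionNetwork,
    PathwayGraph,
    ReconstructedPathway,
    RiskPathway,
)

# ---------------------------------------------------------------------------
# cached synthetic cohorts / pipeline runs (generation is cheap, the cache
# just avoids repeating the full pipeline across test modules)

_COHORT_CACHE: Dict[int, tuple] = {}
_PIPELINE_CACHE: Dict[int, cp.PipelineResult] = {}


def cohort_for_seed(seed: int) -> tuple:
    if seed not in _COHORT_CACHE:
        _COHORT_CACHE[seed] = cp.generate_cohort(cp.SyntheticConfig(seed=seed))
    return _COHORT_CACHE[seed]


def pipeline_for_seed(seed: int) -> cp.PipelineResult:
    if seed not in _PIPELINE_CACHE:
        bundle, net, pathways, drugs, surv, _ = cohort_for_seed(seed)
        _PIPELINE_CACHE[seed] = cp.run_cohort(bundle, net, pathways, drugs, surv)
    return _PIPELINE_CACHE[seed]


@pytest.fixture(scope="session")
def default_cohort():
    return cohort_for_seed(1)


@pytest.fixture(scope="session")
def default_pipeline():
    return pipeline_for_seed(1)


# ---------------------------------------------------------------------------
# tiny hand-built bundles


def make_bundle(mrna: dict, mirna: dict, phenotype: dict, **kw) -> ExpressionBundle:
    samples = sorted(phenotype)
    return ExpressionBundle(
        mrna=pd.DataFrame(mrna, index=samples).T if mrna else pd.DataFrame(columns=samples),
        mirna=pd.DataFrame(mirna, index=samples).T if mirna else pd.DataFrame(columns=samples),
        phenotype=pd.Series({s: phenotype[s] for s in samples}),
        **kw,
    )


@pytest.fixture
def two_sample_bundle():
    """One mRNA with tumor=[4,6], normal=[1,3]; one flat miRNA."""
    return make_bundle(
        mrna={"geneA": {"t1": 4.0, "t2": 6.0, "n1": 1.0, "n2": 3.0}},
        mirna={"mirX": {"t1": 5.0, "t2": 5.0, "n1": 5.0, "n2": 5.0}},
        phenotype={"t1": "tumor", "t2": "tumor", "n1": "normal", "n2": "normal"},
    )


# ---------------------------------------------------------------------------
# small random crosstalk fixtures (shared with the acceptance suite)


def make_risk_pathway(pid: str, mrnas, mirnas=(), mirna_edges=(), p: float = 0.01) -> RiskPathway:
    recon = ReconstructedPathway(
        base=PathwayGraph(id=pid, name=pid, mrna_nodes=set(mrnas)),
        mirna_nodes=set(mirnas),
        mirna_edges=set(mirna_edges),
        enrichment_p={mi: 0.01 for mi in mirnas},
    )
    return RiskPathway(pathway=recon, enrichment_p=p, overlap_features=set())


def random_crosstalk_fixture(rng: np.random.Generator):
    """Random small instance: <= 5 pathways, <= 8 features each, random
    edges, random differential p-values, 10-sample expression."""
    pool_m = [f"g{i}" for i in range(12)]
    pool_mi = [f"mi{i}" for i in range(4)]
    n_samples = 10

    ppi = {tuple(sorted((a, b))) for a in pool_m for b in pool_m if a < b and rng.random() < 0.25}
    targets = {(mi, g) for mi in pool_mi for g in pool_m if rng.random() < 0.25}
    network = InteractionNetwork(ppi_edges=set(ppi), mirna_target_edges=set(targets))

    n_pathways = int(rng.integers(2, 6))
    risk_pathways = []
    for i in range(n_pathways):
        mrnas = set(rng.choice(pool_m, size=int(rng.integers(2, 9)), replace=False).tolist())
        mirnas = set()
        edges = set()
        for mi in pool_mi:
            in_path = {t for (m, t) in targets if m == mi} & mrnas
            if in_path and rng.random() < 0.5:
                mirnas.add(mi)
                edges |= {(mi, t) for t in in_path}
        risk_pathways.append(make_risk_pathway(f"P{i}", mrnas, mirnas, edges))

    features = pool_m + pool_mi
    diff_p = {f: float(rng.uniform(1e-6, 1.0)) for f in features}
    expr = pd.DataFrame(
        rng.normal(size=(len(features), n_samples)),
        index=features,
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return risk_pathways, network, diff_p, expr, set(pool_mi)


def make_cascade_instance():
    """Minimal hand-built superadditivity case: miRNA 'mi' attached to PA
    via targets t1, t2 and wired into PB; only the union {t1} | {t2}
    orphans 'mi' and silences its cross-pathway contributions."""
    from crosspath.crosstalk import build_crosstalk_network
    from crosspath.datatypes import DrugTargetMap, DrugTargets

    pa = make_risk_pathway(
        "PA", {"t1", "t2"}, mirnas={"mi"}, mirna_edges={("mi", "t1"), ("mi", "t2")}
    )
    pb = make_risk_pathway("PB", {"q1", "q2"})
    network = InteractionNetwork(
        ppi_edges={("t1", "q1"), ("t2", "q2")},
        mirna_target_edges={("mi", "t1"), ("mi", "t2"), ("mi", "q1"), ("mi", "q2")},
    )
    rng = np.random.default_rng(5)
    expr = pd.DataFrame({f: rng.normal(size=12) for f in ("t1", "t2", "q1", "q2", "mi")}).T
    diff_p = {f: 0.01 for f in ("t1", "t2", "q1", "q2", "mi")}
    net = build_crosstalk_network([pa, pb], network, diff_p, expr, {"mi"})
    drugs = DrugTargetMap({"dA": DrugTargets({"t1"}), "dB": DrugTargets({"t2"})})
    return [pa, pb], net, drugs
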