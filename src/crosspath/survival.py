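"""Survival validation of a drug combination's target signature.

Tumor samples are split into two groups by K-means (k=2) on the z-scored
expression of the combination's targets; the groups are compared by the
two-group log-rank test. The group with the smaller median survival is
labelled high-risk (orientation is defined post hoc).
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from sklearn.cluster import KMeans

from .datatypes import ComboResult, DrugTargetMap, ExpressionBundle, SurvivalSplit, SurvivalTable

HIGH, LOW = "high_risk", "low_risk"


def stratify_kmeans(
    expr_targets: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
) -> np.ndarray:
    """K-means cluster labels for samples (rows) over target features
    (columns), after per-feature z-scoring. Deterministic given seed."""
    if expr_targets.shape[0] < 2:
        raise ValueError("need >= 2 samples to cluster")
    if expr_targets.shape[1] < 1:
        raise ValueError("need >= 1 target feature present in expression")
    x = expr_targets.to_numpy(dtype=float)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0, keepdims=True)) / sd
    if np.allclose(z, z[0]):
        raise ValueError("degenerate clustering: all samples identical")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(z)


def logrank_test(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> Tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its upper-tail p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    g0, g1 = groups == labels[0], groups == labels[1]
    if events.sum() == 0:
        warnings.warn("all subjects censored: log-rank statistic 0, p 1", stacklevel=2)
        return 0.0, 1.0
    res = _lifelines_logrank(times[g0], times[g1], event_observed_A=events[g0], event_observed_B=events[g1])
    return float(res.test_statistic), float(res.p_value)


def _median_survival(times: np.ndarray, events: np.ndarray) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    return float(kmf.median_survival_time_)


def evaluate_combo_survival(
    combo_targets: Set[str],
    bundle: ExpressionBundle,
    survival: SurvivalTable,
    seed: int = 0,
    n_init: int = 10,
) -> SurvivalSplit:
    """Split tumor samples by K-means on the combo target signature and test
    the survival difference by log-rank."""
    expr = bundle.combined_log2()
    present = sorted(combo_targets & set(expr.index))
    if not present:
        raise ValueError("no combination target present in the expression matrix")
    samples = [s for s in bundle.tumor_samples if s in set(survival.samples)]
    if len(samples) < 4:
        raise ValueError("need >= 4 tumor samples with survival records")
    mat = expr.loc[present, samples].T  # samples x targets
    labels = stratify_kmeans(mat, k=2, seed=seed, n_init=n_init)

    times = survival.data.loc[samples, "time"].to_numpy(dtype=float)
    events = survival.data.loc[samples, "event"].to_numpy(dtype=int)
    stat, p = logrank_test(times, events, labels)

    med = {lab: _median_survival(times[labels == lab], events[labels == lab]) for lab in (0, 1)}
    # high-risk group = smaller median survival (ties -> cluster 0)
    high_lab = 0 if med[0] <= med[1] else 1
    names = {high_lab: HIGH, 1 - high_lab: LOW}
    groups = pd.Series([names[l] for l in labels], index=samples, name="group")
    return SurvivalSplit(
        groups=groups,
        logrank_stat=stat,
        p_value=p,
        median_survival={names[l]: med[l] for l in (0, 1)},
    )


def km_curve_table(
    times: Sequence[float],
    events: Sequence[int],
    groups: pd.Series,
) -> pd.DataFrame:
    """Kaplan-Meier estimate per group as a tidy table
    (group, time, at_risk, survival)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    rows: List[dict] = []
    for lab in sorted(groups.unique()):
        mask = (groups == lab).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"]
        for t in surv.index:
            rows.append(
                {
                    "group": lab,
                    "time": float(t),
                    "at_risk": int(at_risk.get(t, 0)),
                    "survival": float(surv.loc[t]),
                }
            )
    return pd.DataFrame(rows)


def combo_target_features(
    combo: ComboResult,
    drug_map: DrugTargetMap,
    scope: str = "affected",
    risk_pathway_features: Optional[Dict[str, Set[str]]] = None,
) -> Set[str]:
    """Targets used for the survival split.

    scope="affected": targets appearing in the pathways of the combo's
    affected pathway pairs; scope="all": every target of either drug.
    """
    targets = drug_map[combo.drug1].all_targets | drug_map[combo.drug2].all_targets
    if scope == "all" or risk_pathway_features is None:
        return targets
    pathway_ids = {p["pathway_i"] for p in combo.affected_pathway_pairs} | {
        p["pathway_j"] for p in combo.affected_pathway_pairs
    }
    in_affected: Set[str] = set()
    for pid in pathway_ids:
        in_affected |= risk_pathway_features.get(pid, set())
    chosen = targets & in_affected
    return chosen if chosen else targets
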