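"""Tumor-vs-normal differential screen: Student t-test + fold change + BH FDR.

A feature is called differential when all three conditions hold
(FDR < 0.01, |log2FC| > 2, P < 0.05 by default). The t-test and the BH
correction are applied separately within each molecule class (mRNA, miRNA),
because the two classes are screened as separate datasets.
"""

from __future__ import annotations

import logging
from typing import Dict, Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionBundle

log = logging.getLogger(__name__)

#: added to both group means before the ratio so zero-expressed features
#: yield a finite fold change
PSEUDOCOUNT = 1e-9


def _ttest(tumor: np.ndarray, normal: np.ndarray, equal_var: bool) -> tuple[np.ndarray, np.ndarray]:
    t, p = stats.ttest_ind(tumor, normal, axis=1, equal_var=equal_var)
    # zero within-group variance in both groups with equal means -> 0/0; by
    # convention no evidence of difference
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        log.info("t-test: %d feature(s) with undefined statistic set to p=1", degenerate.sum())
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    return t, p


def _kind_table(
    mat: pd.DataFrame,
    tumor_cols,
    normal_cols,
    kind: str,
    is_log2: bool,
    equal_var: bool,
    test_scale: str,
    fc_on_log: bool,
) -> pd.DataFrame:
    linear = np.exp2(mat.to_numpy()) if is_log2 else mat.to_numpy()
    log2m = mat.to_numpy() if is_log2 else np.log2(linear + 1.0)

    tumor_idx = [mat.columns.get_loc(c) for c in tumor_cols]
    normal_idx = [mat.columns.get_loc(c) for c in normal_cols]

    test_mat = log2m if test_scale == "log2" else mat.to_numpy()
    t, p = _ttest(test_mat[:, tumor_idx], test_mat[:, normal_idx], equal_var)

    if fc_on_log:
        log2fc = log2m[:, tumor_idx].mean(axis=1) - log2m[:, normal_idx].mean(axis=1)
    else:
        mean_t = linear[:, tumor_idx].mean(axis=1)
        mean_n = linear[:, normal_idx].mean(axis=1)
        log2fc = np.log2((mean_t + PSEUDOCOUNT) / (mean_n + PSEUDOCOUNT))

    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "kind": kind,
            "log2fc": log2fc,
            "t_stat": t,
            "p_value": p,
            "fdr": fdr,
        },
        index=mat.index,
    )


def compute_differential(
    bundle: ExpressionBundle,
    fdr_threshold: float = 0.01,
    lfc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    welch: bool = False,
    test_scale: Literal["log2", "linear"] = "log2",
    fc_on_log: bool = False,
) -> pd.DataFrame:
    """One record per feature (both kinds) with t, p, BH FDR, log2FC and the
    conjunctive differential call.

    Parameters
    ----------
    test_scale : run the t-test on log2(x+1)-transformed values (default) or
        on the matrix values as stored. Fold change is always a ratio of
        linear-scale group means unless ``fc_on_log``.
    welch : use the unequal-variance t-test instead of the pooled Student t.
    """
    for thr, name in ((fdr_threshold, "fdr"), (lfc_threshold, "lfc"), (p_threshold, "p")):
        if thr < 0:
            raise ValueError(f"{name} threshold must be positive")
    tumor, normal = bundle.tumor_samples, bundle.normal_samples
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("need >= 2 samples in each phenotype group")

    parts = []
    for mat, kind in ((bundle.mrna, "mRNA"), (bundle.mirna, "miRNA")):
        if len(mat) == 0:
            continue
        parts.append(
            _kind_table(mat, tumor, normal, kind, bundle.is_log2, not welch, test_scale, fc_on_log)
        )
    table = pd.concat(parts, axis=0)
    table["is_differential"] = (
        (table["fdr"] < fdr_threshold)
        & (table["log2fc"].abs() > lfc_threshold)
        & (table["p_value"] < p_threshold)
    )
    return table


def differential_p_map(table: pd.DataFrame) -> Dict[str, float]:
    """feature id -> raw t-test p-value (used by the correlation-strength score)."""
    return dict(zip(table.index, table["p_value"]))


def differential_features(table: pd.DataFrame, kind: str | None = None) -> set:
    sel = table[table["is_differential"]]
    if kind is not None:
        sel = sel[sel["kind"] == kind]
    return set(sel.index)
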