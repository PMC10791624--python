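"""Weighted co-expression modules among differential features.

The differential mRNAs and miRNAs are clustered jointly: a soft-thresholded
correlation network is turned into a topological-overlap matrix (TOM),
average-linkage clustering of TOM dissimilarity is cut at a fixed height,
and modules are correlated with the tumor/normal phenotype through their
eigengene (first principal component of the standardized member submatrix).
Members of the phenotype-correlated module(s) are the risk mRNAs/miRNAs.

Notes on the static cut: within-module TOM dissimilarity is typically
0.4-0.8 even for strong modules, while cross-module merges happen near 1.0,
so the default ``cut_height`` is 0.9 (an absolute height on the dendrogram,
the ``cutreeStatic`` convention). Clusters below ``min_module_size`` go to
an unclustered grey pool that never contributes risk factors.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, List, Literal, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import CoexModule, RiskFactorSet

log = logging.getLogger(__name__)

GREY = "grey"


def _correlation(expr_sub: pd.DataFrame) -> np.ndarray:
    """Feature-feature Pearson correlation; constant features get 0 (warned)."""
    x = expr_sub.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{constant.sum()} constant feature(s): correlations set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(x)
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    return np.clip(cor, -1.0, 1.0)


def build_adjacency(expr_sub: pd.DataFrame, power: float = 6.0, signed: bool = False) -> np.ndarray:
    """Soft-threshold adjacency a_ij = |cor|^power (unsigned) or
    ((1+cor)/2)^power (signed); diagonal = 1."""
    if expr_sub.shape[1] < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    if power < 1:
        raise ValueError("soft power must be >= 1")
    cor = _correlation(expr_sub)
    adj = ((1.0 + cor) / 2.0) ** power if signed else np.abs(cor) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def scale_free_fit_r2(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log frequency-vs-connectivity regression (signed: a
    positive slope counts as no fit)."""
    k = adjacency.sum(axis=0) - 1.0
    if np.allclose(k.max(), k.min()):
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.digitize(k, edges[1:-1])
    mean_k, freq = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() > 0 and k[mask].mean() > 0:
            mean_k.append(k[mask].mean())
            freq.append(mask.mean())
    if len(mean_k) < 3:
        return 0.0
    lx, ly = np.log10(mean_k), np.log10(freq)
    slope, _, r, _, _ = stats.linregress(lx, ly)
    return float(r**2) if slope < 0 else 0.0


def pick_soft_power(
    expr_sub: pd.DataFrame,
    candidate_powers: Sequence[float] = tuple(range(1, 21)),
    target_r2: float = 0.8,
    signed: bool = False,
) -> float:
    """Smallest candidate power whose scale-free fit reaches target_r2;
    falls back to 6 (logged) when none qualifies."""
    if not candidate_powers:
        raise ValueError("candidate_powers must be non-empty")
    for power in candidate_powers:
        adj = build_adjacency(expr_sub, power=power, signed=signed)
        if scale_free_fit_r2(adj) >= target_r2:
            return float(power)
    log.warning("no candidate power reached scale-free R^2 >= %.2f; falling back to 6", target_r2)
    warnings.warn("scale-free criterion not met; using soft power 6", stacklevel=2)
    return 6.0


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (L_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)
    with L_ij = sum_{u != i,j} a_iu a_uj; TOM_ii = 1."""
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    # diagonal is 1 by construction; L must exclude u in {i, j}
    l_mat = a @ a - 2.0 * a  # subtracts a_ii*a_ij + a_ij*a_jj
    k = a.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l_mat + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    adjacency: np.ndarray,
    feature_ids: Sequence[str],
    min_module_size: int = 10,
    cut_height: float = 0.9,
) -> Tuple[List[CoexModule], Set[str]]:
    """Cluster TOM dissimilarity (average linkage, absolute cut) into modules.

    Returns (modules ordered by decreasing size, grey pool of unclustered
    feature ids). Clusters smaller than ``min_module_size`` go grey.
    """
    n = adjacency.shape[0]
    if len(feature_ids) != n:
        raise ValueError("feature_ids length must match adjacency")
    if n < min_module_size:
        return [], set(feature_ids)
    diss = 1.0 - tom_similarity(adjacency)
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="average")
    labels = fcluster(z, t=cut_height, criterion="distance")

    by_label: Dict[int, List[str]] = {}
    for fid, lab in zip(feature_ids, labels):
        by_label.setdefault(int(lab), []).append(fid)

    modules: List[CoexModule] = []
    grey: Set[str] = set()
    clusters = sorted(by_label.values(), key=lambda m: (-len(m), m[0]))
    for members in clusters:
        if len(members) >= min_module_size:
            modules.append(CoexModule(id=f"M{len(modules) + 1}", members=set(members)))
        else:
            grey.update(members)
    return modules, grey


def module_eigengene(expr_sub: pd.DataFrame, members: Set[str]) -> np.ndarray:
    """First principal component across the standardized member rows,
    sign-oriented to correlate positively with mean member expression."""
    sub = expr_sub.loc[sorted(members)].to_numpy(dtype=float)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    zscored = (sub - sub.mean(axis=1, keepdims=True)) / sd
    if zscored.shape[0] == 1:
        return zscored[0]
    # rows = features, columns = samples; eigengene lives in sample space
    _, _, vt = np.linalg.svd(zscored, full_matrices=False)
    eig = vt[0]
    mean_profile = zscored.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return eig


def module_trait(
    modules: List[CoexModule],
    expr_sub: pd.DataFrame,
    phenotype: pd.Series,
) -> List[CoexModule]:
    """Attach eigengene and eigengene-phenotype correlation (tumor=1)."""
    trait = (phenotype.loc[expr_sub.columns] == "tumor").astype(float).to_numpy()
    out = []
    for mod in modules:
        eig = module_eigengene(expr_sub, mod.members)
        if np.std(eig) == 0 or np.std(trait) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(eig, trait)
        out.append(CoexModule(mod.id, set(mod.members), eig, float(r), float(p)))
    return out


def extract_risk_factors(
    modules: List[CoexModule],
    mirna_ids: Set[str],
    alpha: float = 0.05,
    select: Literal["top", "all-significant"] = "top",
) -> RiskFactorSet:
    """Members of the cancer-correlated module(s), split by molecule kind.

    select="top": the single module with maximal |trait_r| among those with
    trait_p < alpha. select="all-significant": the union over all passing
    modules.
    """
    passing = [m for m in modules if m.trait_p is not None and m.trait_p < alpha]
    if not passing:
        warnings.warn("no module passes the phenotype-correlation threshold", stacklevel=2)
        return RiskFactorSet()
    if select == "top":
        chosen = [max(passing, key=lambda m: (abs(m.trait_r), m.id))]
    elif select == "all-significant":
        chosen = passing
    else:
        raise ValueError(f"unknown select mode {select!r}")
    members: Set[str] = set().union(*(m.members for m in chosen))
    return RiskFactorSet(
        risk_mrnas=members - mirna_ids,
        risk_mirnas=members & mirna_ids,
    )
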