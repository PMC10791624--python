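"""Risk-pathway crosstalk scoring.

For every unordered pair of risk pathways, all cross-pathway feature pairs
(a in pathway i, b in pathway j, a != b) that carry an interaction edge —
PPI for mRNA-mRNA, a miRNA->target edge for mixed pairs — contribute a
correlation strength

    CS(a, b) = -(ln P(a) + ln P(b) + ln P(a, b))

where P(a), P(b) are the raw differential t-test p-values and P(a, b) is
the two-sided p-value of the Pearson correlation between the two expression
profiles. Crosstalk(i, j) is the sum of CS over contributing pairs; the
network total is the sum over all pathway pairs. p-values are clamped to
[eps, 1] so CS is always finite and nonnegative.

A feature shared by both pathways never forms a self-pair but may still
pair with other members of the opposite pathway. miRNA-miRNA pairs are not
scored (no interaction source defines them).
"""

from __future__ import annotations

import logging
import math
import warnings
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CrosstalkNetwork,
    InteractingPair,
    InteractionNetwork,
    PathwayPairCrosstalk,
    RiskPathway,
)

log = logging.getLogger(__name__)

#: p-value clamp keeping ln finite; -ln(EPS) ~ 690.78
EPS = 1e-300


def correlation_strength(p_a: float, p_b: float, p_ab: float, eps: float = EPS) -> float:
    """CS = -(ln p_a + ln p_b + ln p_ab), inputs clamped to [eps, 1]."""
    for p in (p_a, p_b, p_ab):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    total = 0.0
    for p in (p_a, p_b, p_ab):
        total += math.log(min(max(p, eps), 1.0))
    return -total


def pearson_p(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Pearson r and its two-sided p from the t-distribution with n-2 df.

    Constant vectors yield (0, 1) by convention (warned).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant vector in correlation: r=0, p=1 by convention", stacklevel=2)
        return 0.0, 1.0
    r, p = stats.pearsonr(x, y)
    return float(r), float(min(max(p, 0.0), 1.0))


class _CorrelationCache:
    """Memoizes expression-correlation p-values across pathway pairs."""

    def __init__(self, expr: pd.DataFrame, samples: Optional[Sequence[str]] = None):
        self.expr = expr if samples is None else expr[list(samples)]
        self.index = set(expr.index)
        self._cache: Dict[Tuple[str, str], Tuple[float, float]] = {}

    def __contains__(self, feature: str) -> bool:
        return feature in self.index

    def get(self, a: str, b: str) -> Tuple[float, float]:
        key = (a, b) if a <= b else (b, a)
        hit = self._cache.get(key)
        if hit is None:
            hit = pearson_p(self.expr.loc[a].to_numpy(), self.expr.loc[b].to_numpy())
            self._cache[key] = hit
        return hit


def _pair_kind(a: str, b: str, mirna_ids: Set[str]) -> Optional[str]:
    a_mi, b_mi = a in mirna_ids, b in mirna_ids
    if not a_mi and not b_mi:
        return "mRNA-mRNA"
    if a_mi != b_mi:
        return "miRNA-mRNA"
    return None  # miRNA-miRNA: unscored


def _has_edge(a: str, b: str, kind: str, network: InteractionNetwork, mirna_ids: Set[str]) -> bool:
    if kind == "mRNA-mRNA":
        return network.has_ppi(a, b)
    mirna, mrna = (a, b) if a in mirna_ids else (b, a)
    return network.has_target(mirna, mrna)


def pathway_pair_crosstalk(
    path_i: RiskPathway,
    path_j: RiskPathway,
    network: InteractionNetwork,
    diff_p: Mapping[str, float],
    corr: _CorrelationCache,
    mirna_ids: Set[str],
) -> PathwayPairCrosstalk:
    """Score one unordered pathway pair; contributions sorted by (a, b)."""
    fi, fj = path_i.pathway.features, path_j.pathway.features
    seen: Set[Tuple[str, str]] = set()
    pairs: List[InteractingPair] = []
    n_skipped = 0
    for a in fi:
        for b in fj:
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            kind = _pair_kind(a, b, mirna_ids)
            if kind is None or not _has_edge(a, b, kind, network, mirna_ids):
                continue
            if a not in corr or b not in corr or a not in diff_p or b not in diff_p:
                n_skipped += 1
                continue
            r_ab, p_ab = corr.get(a, b)
            cs = correlation_strength(diff_p[a], diff_p[b], p_ab)
            pairs.append(
                InteractingPair(key[0], key[1], kind, diff_p[a], diff_p[b], p_ab, r_ab, cs)
            )
    if n_skipped:
        log.info(
            "crosstalk %s-%s: %d pair(s) skipped (feature missing from expression or p map)",
            path_i.id, path_j.id, n_skipped,
        )
    pairs.sort(key=lambda p: (p.a, p.b))
    return PathwayPairCrosstalk(
        pathway_i=path_i.id,
        pathway_j=path_j.id,
        score=float(sum(p.cs for p in pairs)),
        pairs=pairs,
        n_skipped=n_skipped,
    )


def build_crosstalk_network(
    risk_pathways: Sequence[RiskPathway],
    network: InteractionNetwork,
    diff_p: Mapping[str, float],
    expr: pd.DataFrame,
    mirna_ids: Set[str],
    samples: Optional[Sequence[str]] = None,
) -> CrosstalkNetwork:
    """Score all unordered pairs of risk pathways.

    ``expr`` is the features x samples matrix on the analysis (log2) scale;
    ``samples`` optionally restricts the correlation to a subset (e.g. tumor
    samples only). Pairs with zero score are retained with empty
    contribution lists.
    """
    if len(risk_pathways) < 2:
        warnings.warn("fewer than 2 risk pathways: empty crosstalk network", stacklevel=2)
        return CrosstalkNetwork()
    corr = _CorrelationCache(expr, samples)
    ordered = sorted(risk_pathways, key=lambda r: r.id)
    net = CrosstalkNetwork()
    for pi, pj in combinations(ordered, 2):
        entry = pathway_pair_crosstalk(pi, pj, network, diff_p, corr, mirna_ids)
        net.entries[(pi.id, pj.id)] = entry
    return net
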