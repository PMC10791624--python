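"""Independent reference implementations used to verify the package.

Everything here is deliberately naive (enumeration, step-up by hand,
triple loops) and shares no code with the implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations
from typing import Dict, Mapping, Sequence, Set, Tuple

import numpy as np
from scipy.stats import t as t_dist


def hypergeom_tail_enum(N: int, M: int, n: int, m: int) -> float:
    """P(X >= m) by exact rational enumeration of the PMF."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for k in range(m, min(M, n) + 1):
        total += Fraction(math.comb(M, k) * math.comb(N - M, n - k), denom)
    return float(total)


def bh_stepup(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule:
    q_(i) = min_{j >= i} min(1, p_(j) * n / j)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, min(1.0, p[idx] * n / rank))
        adjusted[idx] = running_min
    return adjusted


def pearson_p_closed_form(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """r and its two-sided p via t = r sqrt((n-2)/(1-r^2)) directly."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    denom = math.sqrt((xm**2).sum() * (ym**2).sum())
    if denom == 0:
        return 0.0, 1.0
    r = float((xm * ym).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t_stat = r * math.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * float(t_dist.sf(abs(t_stat), n - 2))
    return r, min(p, 1.0)


def brute_force_crosstalk(
    pathway_features: Mapping[str, Set[str]],
    ppi: Set[Tuple[str, str]],
    mirna_targets: Set[Tuple[str, str]],
    diff_p: Mapping[str, float],
    expr: Mapping[str, np.ndarray],
    mirna_ids: Set[str],
    eps: float = 1e-300,
) -> Dict[Tuple[str, str], float]:
    """Triple-loop crosstalk per unordered pathway pair, independent of the
    implementation under test."""
    ppi_norm = {tuple(sorted(e)) for e in ppi}
    scores: Dict[Tuple[str, str], float] = {}
    for pid_i, pid_j in combinations(sorted(pathway_features), 2):
        total = 0.0
        done = set()
        for a in sorted(pathway_features[pid_i]):
            for b in sorted(pathway_features[pid_j]):
                if a == b:
                    continue
                key = tuple(sorted((a, b)))
                if key in done:
                    continue
                done.add(key)
                a_mi, b_mi = a in mirna_ids, b in mirna_ids
                if a_mi and b_mi:
                    continue
                if not a_mi and not b_mi:
                    if key not in ppi_norm:
                        continue
                else:
                    mi, mr = (a, b) if a_mi else (b, a)
                    if (mi, mr) not in mirna_targets:
                        continue
                if a not in expr or b not in expr or a not in diff_p or b not in diff_p:
                    continue
                _, p_ab = pearson_p_closed_form(expr[a], expr[b])
                cs = 0.0
                for p in (diff_p[a], diff_p[b], p_ab):
                    cs -= math.log(min(max(p, eps), 1.0))
                total += cs
        scores[(pid_i, pid_j)] = total
    return scores


def logrank_by_hand(times, events, groups) -> Tuple[float, float]:
    """Two-group log-rank via the O - E / V tabulation at each event time."""
    from scipy.stats import chi2

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n - d) * n1 * (n - n1) / (n**2 * (n - 1))
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(chi2.sf(stat, 1))
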