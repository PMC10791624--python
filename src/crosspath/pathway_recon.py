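"""miRNA-augmented pathway reconstruction.

A miRNA is attached to a pathway when its target mRNAs are over-represented
among the pathway's mRNAs by the hypergeometric test; edges are added only
to the in-pathway targets. The printed over-representation tail is
P(X >= m) (``tail="ge"``); the strict tail P(X > m) is available as
``tail="gt"`` for compatibility with formulations that sum the PMF through
m inclusive.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Literal, Mapping, Set

from scipy.stats import hypergeom

from .datatypes import PathwayGraph, ReconstructedPathway

log = logging.getLogger(__name__)


def hypergeom_upper(N: int, M: int, n: int, m: int, tail: Literal["ge", "gt"] = "ge") -> float:
    """Upper-tail hypergeometric probability for over-representation.

    X counts the overlap when ``n`` items are drawn without replacement from
    a universe of ``N`` containing ``M`` marked items; returns P(X >= m)
    (or P(X > m) with ``tail="gt"``). Evaluated in log space by scipy.

    Parameters follow the enrichment convention: N background size, M
    category size, n query-set size, m observed overlap.
    """
    if not (0 <= m <= min(M, n) and 0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds: N={N}, M={M}, n={n}, m={m}")
    k = m - 1 if tail == "ge" else m
    p = float(hypergeom.sf(k, N, M, n))
    return min(max(p, 0.0), 1.0)


def attach_mirnas(
    pathways: Iterable[PathwayGraph],
    mirna_targets: Mapping[str, Set[str]],
    background_mrnas: Set[str],
    alpha: float = 0.05,
    tail: Literal["ge", "gt"] = "ge",
) -> List[ReconstructedPathway]:
    """Attach each miRNA to every pathway where its targets are enriched.

    The background universe is the mRNA universe (``background_mrnas``);
    a miRNA's query size n counts only its targets inside that universe.
    miRNAs with zero in-universe targets are skipped (logged). The result is
    independent of pathway and miRNA iteration order.
    """
    if not mirna_targets:
        raise ValueError("mirna_targets must be non-empty")
    n_background = len(background_mrnas)
    recon: List[ReconstructedPathway] = []
    for pw in pathways:
        pw_mrnas = pw.mrna_nodes & background_mrnas
        if len(pw.mrna_nodes) > n_background:
            raise ValueError(
                f"pathway {pw.id} larger than the background universe ({len(pw.mrna_nodes)} > {n_background})"
            )
        rp = ReconstructedPathway(base=pw)
        for mirna in sorted(mirna_targets):
            targets = mirna_targets[mirna] & background_mrnas
            if not targets:
                log.info("miRNA %s has no targets in the background universe; skipped", mirna)
                continue
            overlap = targets & pw_mrnas
            p = hypergeom_upper(n_background, len(pw_mrnas), len(targets), len(overlap), tail=tail)
            if p < alpha and overlap:
                rp.mirna_nodes.add(mirna)
                rp.mirna_edges.update((mirna, t) for t in overlap)
                rp.enrichment_p[mirna] = p
        recon.append(rp)
    return recon
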