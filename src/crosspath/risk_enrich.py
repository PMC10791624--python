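"""Risk-pathway identification.

A reconstructed pathway is a risk pathway for a cancer when the cancer's
risk mRNAs + miRNAs are over-represented among the pathway's features
(mRNA nodes plus attached miRNAs) by the cumulative hypergeometric test.
The background universe here counts mRNAs AND miRNAs, since both the
pathway feature set M and the risk set n mix the two kinds. Raw p-values
are thresholded (no multiple-testing correction) by default, with BH
available behind a flag.
"""

from __future__ import annotations

import warnings
from typing import Iterable, List, Literal, Set

from statsmodels.stats.multitest import multipletests

from .datatypes import ReconstructedPathway, RiskFactorSet, RiskPathway
from .pathway_recon import hypergeom_upper


def identify_risk_pathways(
    recon_pathways: Iterable[ReconstructedPathway],
    risk: RiskFactorSet,
    background_features: Set[str],
    alpha: float = 0.05,
    apply_bh: bool = False,
    tail: Literal["ge", "gt"] = "ge",
) -> List[RiskPathway]:
    """Pathways enriched for the risk factors, sorted ascending by p.

    ``background_features`` is the mRNA+miRNA expression universe; pathway
    features and risk factors are intersected with it before counting.
    """
    recon_pathways = list(recon_pathways)
    if not recon_pathways:
        raise ValueError("recon_pathways must be non-empty")
    n_background = len(background_features)
    risk_in_universe = risk.all_factors & background_features
    if not risk_in_universe:
        warnings.warn("empty risk-factor set: no risk pathways identified", stacklevel=2)
        return []

    candidates = []
    for rp in recon_pathways:
        features = rp.features & background_features
        overlap = features & risk_in_universe
        p = hypergeom_upper(
            n_background, len(features), len(risk_in_universe), len(overlap), tail=tail
        )
        candidates.append((rp, p, overlap))

    if apply_bh:
        _, adjusted, _, _ = multipletests([c[1] for c in candidates], method="fdr_bh")
        candidates = [(rp, float(q), ov) for (rp, _, ov), q in zip(candidates, adjusted)]

    # alpha >= 1 disables the filter entirely (p can be exactly 1.0)
    kept = [
        RiskPathway(pathway=rp, enrichment_p=p, overlap_features=ov)
        for rp, p, ov in candidates
        if p < alpha or alpha >= 1.0
    ]
    kept.sort(key=lambda r: (r.enrichment_p, r.id))
    return kept
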