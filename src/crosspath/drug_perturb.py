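"""Drug screening by crosstalk destruction.

A drug's destruction score is DS(d) = 1 - Crosstalk_d / Crosstalk_s: the
fraction of total risk-pathway crosstalk removed when the drug's targets
(mRNA and miRNA) are deleted from every risk pathway. Drug pairs are
screened on the union of their target sets and kept when the joint score is
at least the sum of the single scores (the superadditivity criterion).

Cascade removal: an attached pathway-miRNA whose in-pathway target mRNAs
have all been deleted is deleted too. Without the cascade, removal kills a
fixed set of nonnegative CS terms per target, so DS is provably subadditive
and the selection rule could only ever be met with equality; the cascade is
the mechanism by which a pair of drugs can jointly silence a miRNA that
neither silences alone, producing strictly superadditive destruction.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Dict, Iterable, List, Literal, Mapping, Sequence, Set, Tuple

from .datatypes import (
    ComboResult,
    CrosstalkNetwork,
    DrugScore,
    DrugTargetMap,
    ReconstructedPathway,
    RiskPathway,
)

log = logging.getLogger(__name__)


def remove_targets(
    risk_pathways: Sequence[RiskPathway],
    targets: Set[str],
    cascade: bool = True,
) -> List[ReconstructedPathway]:
    """Delete target features from every risk pathway; with ``cascade``,
    attached miRNAs left with no in-pathway target edge are deleted to
    fixpoint. Unknown ids are ignored. Returns reduced pathway copies."""
    reduced: List[ReconstructedPathway] = []
    for rp in risk_pathways:
        pw = rp.pathway
        mrnas = pw.mrna_nodes - targets
        mirnas = pw.mirna_nodes - targets
        edges = {(mi, t) for mi, t in pw.mirna_edges if mi in mirnas and t in mrnas}
        if cascade:
            while True:
                with_edges = {mi for mi, _ in edges}
                orphaned = mirnas - with_edges
                if not orphaned:
                    break
                mirnas -= orphaned
                edges = {(mi, t) for mi, t in edges if mi in mirnas}
        base = type(pw.base)(pw.base.id, pw.base.name, mrnas, None)
        reduced.append(
            ReconstructedPathway(
                base=base,
                mirna_nodes=mirnas,
                mirna_edges=edges,
                enrichment_p={mi: p for mi, p in pw.enrichment_p.items() if mi in mirnas},
            )
        )
    return reduced


def _reduced_feature_sets(reduced: Sequence[ReconstructedPathway]) -> Dict[str, Set[str]]:
    return {rp.id: rp.features for rp in reduced}


def crosstalk_after_removal(
    full: CrosstalkNetwork,
    reduced_features: Mapping[str, Set[str]],
) -> Tuple[float, Dict[Tuple[str, str], float]]:
    """Total and per-pair crosstalk after removal, by filtering the full
    network's contributions: a pair survives iff its endpoints still belong
    to opposite pathways of the pair (in either orientation). Removal never
    adds interacting pairs, so filtering is exact."""
    per_pair: Dict[Tuple[str, str], float] = {}
    for key, entry in full.entries.items():
        fi = reduced_features[entry.pathway_i]
        fj = reduced_features[entry.pathway_j]
        score = 0.0
        for pair in entry.pairs:
            if (pair.a in fi and pair.b in fj) or (pair.a in fj and pair.b in fi):
                score += pair.cs
        per_pair[key] = score
    return float(sum(per_pair.values())), per_pair


def destruction_score(
    crosstalk_full: CrosstalkNetwork,
    risk_pathways: Sequence[RiskPathway],
    targets: Set[str],
    cascade: bool = True,
    drug: str = "",
    ds_threshold: float = 0.01,
) -> DrugScore:
    """DS = 1 - crosstalk_after / crosstalk_before, clipped to [0, 1]."""
    before = crosstalk_full.total_crosstalk
    if before <= 0:
        raise ValueError("no crosstalk to destroy (total crosstalk is 0)")
    reduced = remove_targets(risk_pathways, targets, cascade=cascade)
    after, _ = crosstalk_after_removal(crosstalk_full, _reduced_feature_sets(reduced))
    ds = min(max(1.0 - after / before, 0.0), 1.0)
    removed: Set[str] = set()
    for rp, red in zip(risk_pathways, reduced):
        removed |= rp.pathway.features - red.features
    return DrugScore(drug=drug, ds=ds, removed_features=removed, passes_single=ds > ds_threshold)


def screen_single_drugs(
    drug_map: DrugTargetMap,
    crosstalk_full: CrosstalkNetwork,
    risk_pathways: Sequence[RiskPathway],
    cascade: bool = True,
    ds_threshold: float = 0.01,
) -> List[DrugScore]:
    """DS for every drug (mRNA + miRNA targets removed together), sorted
    descending by DS (ties broken by drug id)."""
    if not drug_map:
        raise ValueError("drug_map must be non-empty")
    scores = [
        destruction_score(
            crosstalk_full,
            risk_pathways,
            drug_map[drug].all_targets,
            cascade=cascade,
            drug=drug,
            ds_threshold=ds_threshold,
        )
        for drug in sorted(drug_map)
    ]
    scores.sort(key=lambda s: (-s.ds, s.drug))
    return scores


def optimize_combinations(
    passing_drugs: Sequence[DrugScore],
    drug_map: DrugTargetMap,
    crosstalk_full: CrosstalkNetwork,
    risk_pathways: Sequence[RiskPathway],
    criterion: Literal["ge", "gt"] = "ge",
    tol: float = 1e-9,
    cascade: bool = True,
) -> List[ComboResult]:
    """Score every unordered pair of passing drugs on the union of their
    target sets; keep pairs whose joint DS is >= (or strictly >) the sum of
    the single DS values. Results sorted descending by joint DS."""
    if len(passing_drugs) < 2:
        raise ValueError("need >= 2 passing drugs to form combinations")
    before = crosstalk_full.total_crosstalk
    per_pair_before = {key: entry.score for key, entry in crosstalk_full.entries.items()}
    single_ds = {s.drug: s.ds for s in passing_drugs}
    results: List[ComboResult] = []
    for s1, s2 in combinations(sorted(passing_drugs, key=lambda s: s.drug), 2):
        union = drug_map[s1.drug].all_targets | drug_map[s2.drug].all_targets
        reduced = remove_targets(risk_pathways, union, cascade=cascade)
        after, per_pair_after = crosstalk_after_removal(
            crosstalk_full, _reduced_feature_sets(reduced)
        )
        ds_combo = min(max(1.0 - after / before, 0.0), 1.0)
        margin = ds_combo - (single_ds[s1.drug] + single_ds[s2.drug])
        selected = margin >= -tol if criterion == "ge" else margin > tol
        affected = [
            {
                "pathway_i": key[0],
                "pathway_j": key[1],
                "crosstalk_before": per_pair_before[key],
                "crosstalk_after": per_pair_after[key],
            }
            for key in sorted(per_pair_after)
            if per_pair_after[key] != per_pair_before[key]
        ]
        results.append(
            ComboResult(
                drug1=s1.drug,
                drug2=s2.drug,
                ds1=single_ds[s1.drug],
                ds2=single_ds[s2.drug],
                ds_combo=ds_combo,
                synergy_margin=margin,
                selected=selected,
                affected_pathway_pairs=affected,
            )
        )
    results.sort(key=lambda c: (-c.ds_combo, c.drug1, c.drug2))
    return results
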