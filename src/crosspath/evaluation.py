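"""Recovery metrics for cohorts with planted ground truth."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Set

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .datatypes import ComboResult
from .diffexp import differential_features
from .simulate import GroundTruth


def differential_recall(diff_table: pd.DataFrame, truth: GroundTruth) -> float:
    """Fraction of planted differential features (both kinds) recovered."""
    planted = truth.differential_mrnas | truth.differential_mirnas
    if not planted:
        return float("nan")
    detected = differential_features(diff_table)
    return len(detected & planted) / len(planted)


def differential_fpr(diff_table: pd.DataFrame, truth: GroundTruth) -> float:
    """Fraction of non-planted features called differential."""
    planted = truth.differential_mrnas | truth.differential_mirnas
    null_features = set(diff_table.index) - planted
    if not null_features:
        return float("nan")
    detected = differential_features(diff_table)
    return len(detected & null_features) / len(null_features)


def module_ari(modules: Sequence, grey: Set[str], truth: GroundTruth) -> float:
    """Adjusted Rand index between detected and planted module labels over
    every clustered feature (grey pool and planted solo/background features
    each form one label)."""
    features = sorted(set().union(*(m.members for m in modules)) | grey) if modules or grey else []
    if not features:
        return float("nan")
    pred = {}
    for m in modules:
        for f in m.members:
            pred[f] = m.id
    labels_pred = [pred.get(f, "grey") for f in features]
    labels_true = [truth.modules.get(f, "background") for f in features]
    return float(adjusted_rand_score(labels_true, labels_pred))


def risk_pathway_recall(risk_pathways: Sequence, truth: GroundTruth) -> float:
    if not truth.risk_pathways:
        return float("nan")
    detected = {rp.id for rp in risk_pathways}
    return len(detected & set(truth.risk_pathways)) / len(truth.risk_pathways)


def combo_recovery(combos: Sequence[ComboResult], truth: GroundTruth) -> Dict[str, object]:
    """Whether each planted superadditive pair is selected, and whether the
    first one tops the joint-DS ranking of selected combinations."""
    def key(a: str, b: str):
        return tuple(sorted((a, b)))

    selected = [c for c in combos if c.selected]
    selected_keys = [key(c.drug1, c.drug2) for c in selected]
    planted = [key(*p) for p in truth.superadditive_pairs]
    out: Dict[str, object] = {
        "planted_selected": all(p in selected_keys for p in planted) if planted else None,
        "planted_top_ranked": bool(planted and selected_keys and selected_keys[0] == planted[0]),
        "n_selected": len(selected),
    }
    for c in combos:
        if planted and key(c.drug1, c.drug2) == planted[0]:
            out["planted_margin"] = c.synergy_margin
            out["planted_ds_combo"] = c.ds_combo
    return out
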