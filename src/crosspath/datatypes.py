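"""Shared domain types for the crosstalk pipeline.

Expression is carried as pandas DataFrames (features x samples) on linear
scale unless ``is_log2`` says otherwise; all identifiers are case-sensitive
opaque strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"


def ppi_edge(a: str, b: str) -> Tuple[str, str]:
    """Canonical (sorted) orientation-free PPI edge."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ExpressionBundle:
    """Matched mRNA and miRNA matrices with tumor/normal phenotype labels.

    Both matrices share identical, identically ordered sample columns.
    Values are linear-scale abundances (>= 0) unless ``is_log2`` is True.
    """

    mrna: pd.DataFrame
    mirna: pd.DataFrame
    phenotype: pd.Series  # index: samples, values in {tumor, normal}
    is_log2: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.mrna.columns) != list(self.mirna.columns):
            raise ValueError("mRNA and miRNA matrices must share identical sample columns")
        if list(self.phenotype.index) != list(self.mrna.columns):
            raise ValueError("phenotype index must match the sample columns")
        for name, mat in (("mRNA", self.mrna), ("miRNA", self.mirna)):
            if mat.index.has_duplicates:
                dup = mat.index[mat.index.duplicated()][0]
                raise ValueError(f"duplicate {name} feature id: {dup!r}")
            if not self.is_log2 and (mat.to_numpy() < 0).any():
                raise ValueError(f"negative abundance in {name} matrix")
        labels = set(self.phenotype.unique())
        if not labels <= {TUMOR, NORMAL}:
            raise ValueError(f"phenotype labels must be {{tumor, normal}}, got {labels}")
        counts = self.phenotype.value_counts()
        for lab in (TUMOR, NORMAL):
            if counts.get(lab, 0) < 2:
                raise ValueError(f"need >= 2 {lab!r} samples, got {counts.get(lab, 0)}")

    # -- convenience views -------------------------------------------------
    @property
    def samples(self) -> List[str]:
        return list(self.mrna.columns)

    @property
    def tumor_samples(self) -> List[str]:
        return list(self.phenotype.index[self.phenotype == TUMOR])

    @property
    def normal_samples(self) -> List[str]:
        return list(self.phenotype.index[self.phenotype == NORMAL])

    @property
    def mrna_ids(self) -> Set[str]:
        return set(self.mrna.index)

    @property
    def mirna_ids(self) -> Set[str]:
        return set(self.mirna.index)

    def feature_kind(self, feature: str) -> str:
        if feature in self.mrna.index:
            return "mRNA"
        if feature in self.mirna.index:
            return "miRNA"
        raise KeyError(feature)

    def combined(self) -> pd.DataFrame:
        """mRNA and miRNA rows stacked into one features x samples matrix."""
        return pd.concat([self.mrna, self.mirna], axis=0)

    def combined_log2(self) -> pd.DataFrame:
        """Combined matrix on log2 scale (log2(x + 1) if stored linear)."""
        mat = self.combined()
        if self.is_log2:
            return mat
        return np.log2(mat + 1.0)


@dataclass
class InteractionNetwork:
    """Undirected mRNA-mRNA (PPI) edges plus directed miRNA->mRNA target edges."""

    ppi_edges: Set[Tuple[str, str]] = field(default_factory=set)
    mirna_target_edges: Set[Tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.ppi_edges = {ppi_edge(a, b) for a, b in self.ppi_edges if a != b}
        self.mirna_target_edges = {(m, t) for m, t in self.mirna_target_edges if m != t}

    def has_ppi(self, a: str, b: str) -> bool:
        return ppi_edge(a, b) in self.ppi_edges

    def has_target(self, mirna: str, mrna: str) -> bool:
        return (mirna, mrna) in self.mirna_target_edges

    def targets_of(self, mirna: str) -> Set[str]:
        return {t for m, t in self.mirna_target_edges if m == mirna}


@dataclass
class PathwayGraph:
    """A pathway as an undirected graph over mRNA nodes (edges optional)."""

    id: str
    name: str
    mrna_nodes: Set[str]
    internal_edges: Optional[Set[Tuple[str, str]]] = None

    def __post_init__(self) -> None:
        self.mrna_nodes = set(self.mrna_nodes)
        if self.internal_edges is not None:
            self.internal_edges = {ppi_edge(a, b) for a, b in self.internal_edges if a != b}
            stray = {n for e in self.internal_edges for n in e} - self.mrna_nodes
            if stray:
                raise ValueError(
                    f"pathway {self.id}: internal edge endpoint(s) outside node set: {sorted(stray)[:3]}"
                )


@dataclass
class ReconstructedPathway:
    """Pathway augmented with miRNAs whose targets are over-represented in it."""

    base: PathwayGraph
    mirna_nodes: Set[str] = field(default_factory=set)
    mirna_edges: Set[Tuple[str, str]] = field(default_factory=set)  # (miRNA, target mRNA)
    enrichment_p: Dict[str, float] = field(default_factory=dict)  # per attached miRNA

    @property
    def id(self) -> str:
        return self.base.id

    @property
    def mrna_nodes(self) -> Set[str]:
        return self.base.mrna_nodes

    @property
    def features(self) -> Set[str]:
        return self.base.mrna_nodes | self.mirna_nodes

    def to_dict(self) -> dict:
        return {
            "id": self.base.id,
            "name": self.base.name,
            "mrna_nodes": sorted(self.base.mrna_nodes),
            "mirna_nodes": sorted(self.mirna_nodes),
            "mirna_edges": sorted(map(list, self.mirna_edges)),
            "enrichment_p": {k: self.enrichment_p[k] for k in sorted(self.enrichment_p)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReconstructedPathway":
        return cls(
            base=PathwayGraph(d["id"], d["name"], set(d["mrna_nodes"])),
            mirna_nodes=set(d["mirna_nodes"]),
            mirna_edges={tuple(e) for e in d["mirna_edges"]},
            enrichment_p=dict(d["enrichment_p"]),
        )


@dataclass
class RiskPathway:
    """A reconstructed pathway significantly enriched for a cancer's risk factors."""

    pathway: ReconstructedPathway
    enrichment_p: float
    overlap_features: Set[str]

    @property
    def id(self) -> str:
        return self.pathway.id

    def to_dict(self) -> dict:
        return {
            "pathway": self.pathway.to_dict(),
            "enrichment_p": self.enrichment_p,
            "overlap_features": sorted(self.overlap_features),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskPathway":
        return cls(
            pathway=ReconstructedPathway.from_dict(d["pathway"]),
            enrichment_p=d["enrichment_p"],
            overlap_features=set(d["overlap_features"]),
        )


@dataclass
class DrugTargets:
    mrna_targets: Set[str] = field(default_factory=set)
    mirna_targets: Set[str] = field(default_factory=set)

    @property
    def all_targets(self) -> Set[str]:
        return self.mrna_targets | self.mirna_targets


class DrugTargetMap(Dict[str, DrugTargets]):
    """drug id -> DrugTargets; every drug has >= 1 target of either kind."""

    def validate(self) -> None:
        for drug, t in self.items():
            if not t.all_targets:
                raise ValueError(f"drug {drug!r} has no targets")

    def to_dict(self) -> dict:
        return {
            d: {
                "mrna_targets": sorted(t.mrna_targets),
                "mirna_targets": sorted(t.mirna_targets),
            }
            for d, t in sorted(self.items())
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DrugTargetMap":
        out = cls()
        for drug, t in d.items():
            out[drug] = DrugTargets(set(t["mrna_targets"]), set(t["mirna_targets"]))
        return out


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (days) and event indicator (1 = death observed)."""

    data: pd.DataFrame  # index: sample, columns: time, event

    def __post_init__(self) -> None:
        if not {"time", "event"} <= set(self.data.columns):
            raise ValueError("survival table needs 'time' and 'event' columns")
        if (self.data["time"].to_numpy() < 0).any():
            raise ValueError("survival times must be >= 0")
        if not set(self.data["event"].unique()) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")

    @property
    def samples(self) -> List[str]:
        return list(self.data.index)


# -- co-expression ---------------------------------------------------------


@dataclass
class CoexModule:
    id: str
    members: Set[str]
    eigengene: Optional[np.ndarray] = None
    trait_r: Optional[float] = None
    trait_p: Optional[float] = None


@dataclass
class RiskFactorSet:
    risk_mrnas: Set[str] = field(default_factory=set)
    risk_mirnas: Set[str] = field(default_factory=set)

    @property
    def all_factors(self) -> Set[str]:
        return self.risk_mrnas | self.risk_mirnas

    def to_dict(self) -> dict:
        return {
            "risk_mrnas": sorted(self.risk_mrnas),
            "risk_mirnas": sorted(self.risk_mirnas),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskFactorSet":
        return cls(set(d["risk_mrnas"]), set(d["risk_mirnas"]))


# -- crosstalk -------------------------------------------------------------


@dataclass
class InteractingPair:
    """One interacting cross-pathway feature pair and its correlation strength."""

    a: str
    b: str
    kind: str  # "mRNA-mRNA" or "miRNA-mRNA"
    p_a: float
    p_b: float
    p_ab: float
    r_ab: float
    cs: float

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "kind": self.kind,
            "p_a": self.p_a,
            "p_b": self.p_b,
            "p_ab": self.p_ab,
            "r_ab": self.r_ab,
            "cs": self.cs,
        }


@dataclass
class PathwayPairCrosstalk:
    pathway_i: str
    pathway_j: str
    score: float
    pairs: List[InteractingPair] = field(default_factory=list)
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "pathway_i": self.pathway_i,
            "pathway_j": self.pathway_j,
            "score": self.score,
            "pairs": [p.to_dict() for p in self.pairs],
            "n_skipped": self.n_skipped,
        }


@dataclass
class CrosstalkNetwork:
    """Crosstalk scores for every unordered pair of risk pathways."""

    entries: Dict[Tuple[str, str], PathwayPairCrosstalk] = field(default_factory=dict)

    @property
    def total_crosstalk(self) -> float:
        return float(sum(e.score for e in self.entries.values()))

    def score(self, i: str, j: str) -> float:
        key = (i, j) if (i, j) in self.entries else (j, i)
        return self.entries[key].score

    def to_dict(self) -> dict:
        return {
            "total_crosstalk": self.total_crosstalk,
            "pairs": [self.entries[k].to_dict() for k in sorted(self.entries)],
        }


# -- drugs -----------------------------------------------------------------


@dataclass
class DrugScore:
    drug: str
    ds: float
    removed_features: Set[str]
    passes_single: bool

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "ds": self.ds,
            "removed_features": sorted(self.removed_features),
            "passes_single": self.passes_single,
        }


@dataclass
class ComboResult:
    drug1: str
    drug2: str
    ds1: float
    ds2: float
    ds_combo: float
    synergy_margin: float
    selected: bool
    affected_pathway_pairs: List[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "drug1": self.drug1,
            "drug2": self.drug2,
            "ds1": self.ds1,
            "ds2": self.ds2,
            "ds_combo": self.ds_combo,
            "synergy_margin": self.synergy_margin,
            "selected": self.selected,
            "affected_pathway_pairs": self.affected_pathway_pairs,
        }


# -- survival --------------------------------------------------------------


@dataclass
class SurvivalSplit:
    groups: pd.Series  # index sample, values in {high_risk, low_risk}
    logrank_stat: float
    p_value: float
    median_survival: Dict[str, float]

    def to_dict(self) -> dict:
        return {
            "groups": {s: self.groups[s] for s in sorted(self.groups.index)},
            "logrank_stat": self.logrank_stat,
            "p_value": self.p_value,
            "median_survival": self.median_survival,
        }
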