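"""End-to-end orchestration: one config, eight stages, deterministic outputs.

Stage order: differential screen -> co-expression risk factors -> pathway
reconstruction -> risk-pathway enrichment -> crosstalk network -> single-drug
screen -> combination screen -> survival validation of the top combination.
Rerunning with an identical config and inputs is byte-identical for every
deterministic stage (all randomness flows from the single root seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set

import pandas as pd
import yaml

from . import io as cio
from .coexpression import (
    build_adjacency,
    detect_modules,
    extract_risk_factors,
    module_trait,
    pick_soft_power,
)
from .crosstalk import build_crosstalk_network
from .datatypes import (
    CrosstalkNetwork,
    DrugTargetMap,
    ExpressionBundle,
    InteractionNetwork,
    PathwayGraph,
    RiskFactorSet,
    SurvivalTable,
)
from .diffexp import compute_differential, differential_features, differential_p_map
from .drug_perturb import optimize_combinations, screen_single_drugs
from .pathway_recon import attach_mirnas
from .risk_enrich import identify_risk_pathways
from .survival import combo_target_features, evaluate_combo_survival, km_curve_table

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All analysis thresholds in one place (defaults are the screening
    thresholds the method was published with)."""

    fdr_threshold: float = 0.01
    lfc_threshold: float = 2.0
    p_threshold: float = 0.05
    test_scale: str = "log2"
    fc_on_log: bool = False
    welch: bool = False
    soft_power: Optional[float] = 6.0  # None -> scale-free criterion
    signed: bool = False
    min_module_size: int = 10
    cut_height: float = 0.9
    module_alpha: float = 0.05
    module_select: str = "all-significant"
    recon_alpha: float = 0.05
    recon_tail: str = "ge"
    risk_alpha: float = 0.05
    risk_bh: bool = False
    correlation_samples: str = "all"  # or "tumor"
    ds_threshold: float = 0.01
    combo_criterion: str = "ge"
    combo_tol: float = 1e-9
    cascade: bool = True
    survival_scope: str = "affected"  # or "all"
    seed: int = 1

    def validate(self) -> None:
        for name in ("fdr_threshold", "p_threshold", "module_alpha", "recon_alpha", "risk_alpha", "ds_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if self.test_scale not in {"log2", "linear"}:
            raise ValueError("test_scale must be 'log2' or 'linear'")
        if self.module_select not in {"top", "all-significant"}:
            raise ValueError("module_select must be 'top' or 'all-significant'")
        if self.correlation_samples not in {"all", "tumor"}:
            raise ValueError("correlation_samples must be 'all' or 'tumor'")
        if self.combo_criterion not in {"ge", "gt"}:
            raise ValueError("combo_criterion must be 'ge' or 'gt'")
        if self.recon_tail not in {"ge", "gt"}:
            raise ValueError("recon_tail must be 'ge' or 'gt'")
        if self.survival_scope not in {"affected", "all"}:
            raise ValueError("survival_scope must be 'affected' or 'all'")


@dataclass
class PipelineConfig:
    """Input paths, output directory and analysis parameters."""

    expr_mrna: str
    expr_mirna: str
    phenotype: str
    ppi: str
    mirna_targets: str
    pathways_gmt: str
    drug_targets: str
    survival: Optional[str] = None
    outdir: str = "results"
    expression_is_log2: bool = False
    params: PipelineParams = field(default_factory=PipelineParams)

    def validate(self) -> None:
        self.params.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "params" in d and isinstance(d["params"], dict):
            d["params"] = PipelineParams(**d["params"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    diff_table: pd.DataFrame
    modules: list
    grey: Set[str]
    risk_factors: RiskFactorSet
    recon_pathways: list
    risk_pathways: list
    crosstalk: CrosstalkNetwork
    drug_scores: list
    combos: list
    survival_split: Optional[object]
    km_curves: Optional[pd.DataFrame]
    stage_counts: Dict[str, int]


def run_cohort(
    bundle: ExpressionBundle,
    network: InteractionNetwork,
    pathways: List[PathwayGraph],
    drug_map: DrugTargetMap,
    survival_table: Optional[SurvivalTable],
    params: Optional[PipelineParams] = None,
) -> PipelineResult:
    """Run every stage in memory and return all intermediate objects."""
    params = params or PipelineParams()
    params.validate()
    counts: Dict[str, int] = {}

    # 1. differential screen
    diff = compute_differential(
        bundle,
        fdr_threshold=params.fdr_threshold,
        lfc_threshold=params.lfc_threshold,
        p_threshold=params.p_threshold,
        welch=params.welch,
        test_scale=params.test_scale,  # type: ignore[arg-type]
        fc_on_log=params.fc_on_log,
    )
    diff_features = sorted(differential_features(diff))
    counts["features_tested"] = len(diff)
    counts["differential_features"] = len(diff_features)
    log.info("diffexp: %d/%d features differential", len(diff_features), len(diff))

    # 2. co-expression modules -> risk factors
    expr_log2 = bundle.combined_log2()
    modules: list = []
    grey: Set[str] = set(diff_features)
    risk = RiskFactorSet()
    if len(diff_features) >= params.min_module_size:
        expr_sub = expr_log2.loc[diff_features]
        power = params.soft_power
        if power is None:
            power = pick_soft_power(expr_sub, signed=params.signed)
        adjacency = build_adjacency(expr_sub, power=power, signed=params.signed)
        raw_modules, grey = detect_modules(
            adjacency, diff_features, min_module_size=params.min_module_size, cut_height=params.cut_height
        )
        modules = module_trait(raw_modules, expr_sub, bundle.phenotype)
        risk = extract_risk_factors(
            modules, bundle.mirna_ids, alpha=params.module_alpha, select=params.module_select  # type: ignore[arg-type]
        )
    counts["modules"] = len(modules)
    counts["risk_mrnas"] = len(risk.risk_mrnas)
    counts["risk_mirnas"] = len(risk.risk_mirnas)
    log.info("coexpression: %d modules, %d risk mRNAs, %d risk miRNAs",
             len(modules), len(risk.risk_mrnas), len(risk.risk_mirnas))

    # 3. pathway reconstruction (miRNA attachment)
    mirna_targets: Dict[str, Set[str]] = {}
    for mi, t in network.mirna_target_edges:
        mirna_targets.setdefault(mi, set()).add(t)
    recon = attach_mirnas(
        pathways, mirna_targets, bundle.mrna_ids, alpha=params.recon_alpha, tail=params.recon_tail  # type: ignore[arg-type]
    )
    counts["attached_mirnas"] = sum(len(r.mirna_nodes) for r in recon)
    log.info("pathway_recon: %d pathways, %d miRNA attachments", len(recon), counts["attached_mirnas"])

    # 4. risk pathways
    background = bundle.mrna_ids | bundle.mirna_ids
    risk_pw = identify_risk_pathways(
        recon, risk, background, alpha=params.risk_alpha, apply_bh=params.risk_bh,
        tail=params.recon_tail,  # type: ignore[arg-type]
    ) if risk.all_factors else []
    counts["risk_pathways"] = len(risk_pw)
    log.info("risk_enrich: %d risk pathways", len(risk_pw))

    # 5. crosstalk network
    samples = bundle.tumor_samples if params.correlation_samples == "tumor" else None
    crosstalk = build_crosstalk_network(
        risk_pw, network, differential_p_map(diff), expr_log2, bundle.mirna_ids, samples=samples
    ) if len(risk_pw) >= 2 else CrosstalkNetwork()
    counts["pathway_pairs"] = len(crosstalk.entries)
    log.info("crosstalk: %d pathway pairs, total %.3f", len(crosstalk.entries), crosstalk.total_crosstalk)

    # 6-7. drug screens
    drug_scores: list = []
    combos: list = []
    if crosstalk.total_crosstalk > 0 and drug_map:
        drug_scores = screen_single_drugs(
            drug_map, crosstalk, risk_pw, cascade=params.cascade, ds_threshold=params.ds_threshold
        )
        passing = [s for s in drug_scores if s.passes_single]
        if len(passing) >= 2:
            combos = optimize_combinations(
                passing, drug_map, crosstalk, risk_pw,
                criterion=params.combo_criterion,  # type: ignore[arg-type]
                tol=params.combo_tol, cascade=params.cascade,
            )
    counts["drugs_passing"] = sum(s.passes_single for s in drug_scores)
    counts["combos_selected"] = sum(c.selected for c in combos)
    log.info("drug_perturb: %d drugs passing, %d combos selected",
             counts["drugs_passing"], counts["combos_selected"])

    # 8. survival validation of the top selected combination
    split = None
    km = None
    selected = [c for c in combos if c.selected]
    if selected and survival_table is not None:
        top = selected[0]  # combos are sorted descending by joint DS
        features = {rp.id: rp.pathway.features for rp in risk_pw}
        targets = combo_target_features(top, drug_map, scope=params.survival_scope, risk_pathway_features=features)
        try:
            split = evaluate_combo_survival(targets, bundle, survival_table, seed=params.seed)
            samples_used = list(split.groups.index)
            km = km_curve_table(
                survival_table.data.loc[samples_used, "time"].to_numpy(),
                survival_table.data.loc[samples_used, "event"].to_numpy(),
                split.groups,
            )
        except ValueError as exc:
            log.warning("survival stage skipped: %s", exc)
    counts["survival_tested"] = int(split is not None)
    log.info("survival: %s", "log-rank p=%.4g" % split.p_value if split else "skipped")

    return PipelineResult(
        diff_table=diff,
        modules=modules,
        grey=grey,
        risk_factors=risk,
        recon_pathways=recon,
        risk_pathways=risk_pw,
        crosstalk=crosstalk,
        drug_scores=drug_scores,
        combos=combos,
        survival_split=split,
        km_curves=km,
        stage_counts=counts,
    )


STAGES = (
    "diffexp",
    "coexpression",
    "pathway_recon",
    "risk_enrich",
    "crosstalk",
    "drug_screen",
    "drug_combos",
    "survival",
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run the pipeline from files on disk and write every stage's output
    plus a manifest into ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bundle = cio.read_expression(
        config.expr_mrna, config.expr_mirna, config.phenotype, is_log2=config.expression_is_log2
    )
    network = InteractionNetwork(
        ppi_edges=cio.read_edges(config.ppi, "ppi"),
        mirna_target_edges=cio.read_edges(config.mirna_targets, "mirna_target"),
    )
    pathways = cio.read_gmt(config.pathways_gmt)
    drug_map = cio.read_drug_targets(config.drug_targets)
    survival_table = cio.read_survival(config.survival) if config.survival else None

    result = run_cohort(bundle, network, pathways, drug_map, survival_table, config.params)

    result.diff_table.to_csv(outdir / "diff.tsv", sep="\t", float_format=cio.FLOAT_FORMAT)
    cio.write_json(result.risk_factors, outdir / "risk_factors.json")
    cio.write_json(
        [
            {
                "id": m.id,
                "n_members": len(m.members),
                "members": sorted(m.members),
                "trait_r": m.trait_r,
                "trait_p": m.trait_p,
            }
            for m in result.modules
        ],
        outdir / "modules.json",
    )
    cio.write_json([r.to_dict() for r in result.recon_pathways], outdir / "recon.json")
    cio.write_json([r.to_dict() for r in result.risk_pathways], outdir / "risk_pathways.json")
    cio.write_json(result.crosstalk, outdir / "crosstalk.json")
    cio.write_json([s.to_dict() for s in result.drug_scores], outdir / "drugs.json")
    cio.write_json([c.to_dict() for c in result.combos], outdir / "combos.json")
    cio.write_json(
        result.survival_split.to_dict() if result.survival_split else None,
        outdir / "survival.json",
    )
    if result.km_curves is not None:
        result.km_curves.to_csv(outdir / "km_curves.tsv", sep="\t", index=False,
                                float_format=cio.FLOAT_FORMAT)

    # hash covers inputs and analysis parameters, not the output location
    hashed_cfg = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    config_json = json.dumps(hashed_cfg, sort_keys=True)
    inputs = {
        name: _sha256(Path(path))
        for name, path in (
            ("expr_mrna", config.expr_mrna),
            ("expr_mirna", config.expr_mirna),
            ("phenotype", config.phenotype),
            ("ppi", config.ppi),
            ("mirna_targets", config.mirna_targets),
            ("pathways_gmt", config.pathways_gmt),
            ("drug_targets", config.drug_targets),
        )
        if path
    }
    if config.survival:
        inputs["survival"] = _sha256(Path(config.survival))
    manifest = {
        "stages": list(STAGES),
        "stage_counts": result.stage_counts,
        "seed": config.params.seed,
        "parameter_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "input_hashes": inputs,
    }
    cio.write_json(manifest, outdir / "manifest.json")
    return result
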