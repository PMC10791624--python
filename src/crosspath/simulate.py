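"""Synthetic tumor/normal cohort with planted ground truth.

The generator emulates the statistical structure of the real inputs the
pipeline was designed for (TCGA-style expression, curated miRNA targets, a
PPI network, pathway membership, drug-target tables, survival follow-up)
without any download:

* log-normal expression: features live on log2 scale as
  ``mu + loading * module_factor + shift * tumor + noise`` and are
  exponentiated to linear scale;
* planted differential features (mean tumor/normal log2 ratio =
  ``effect_log2fc``), most of them organized into block-correlated
  co-expression modules via shared latent factors (pairwise correlation ~
  ``within_module_rho``); a small "solo" fraction is differential but
  unclustered (extra noise);
* module miRNAs load negatively on their module factor, so planted
  miRNA->target edges carry negative expression correlation;
* designated risk pathways draw most members from one module; bridge PPI
  edges connect designated risk-pathway pairs (the planted crosstalk);
* drugs whose targets hit the bridges, including one planted superadditive
  pair: the two drugs split the in-pathway targets of one pathway-attached
  miRNA, so only their union cascades the miRNA out of its home pathway and
  silences its cross-pathway edges; a second planted pair is exactly
  additive (disjoint modules, and background PPI edges are never placed
  between the two drugs' target sets);
* exponential survival whose log-rate increases with the mean z-scored
  expression of the planted combination signature.

Identical config + seed reproduces the cohort exactly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as cio
from .datatypes import (
    DrugTargetMap,
    DrugTargets,
    ExpressionBundle,
    InteractionNetwork,
    PathwayGraph,
    SurvivalTable,
    ppi_edge,
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort (defaults are the
    conditions every planted-truth check runs under)."""

    n_tumor: int = 40
    n_normal: int = 40
    n_mrna: int = 500
    n_mirna: int = 50
    n_modules: int = 4
    n_pathways: int = 20
    pathway_size: Tuple[int, int] = (15, 30)
    frac_differential: float = 0.3
    effect_log2fc: float = 3.0
    within_module_rho: float = 0.8
    noise_sd: float = 1.0
    n_drugs: int = 12
    planted_synergy_pairs: Tuple[str, ...] = ("cascade", "additive")
    seed: int = 1

    # secondary structure (documented in the methods note)
    n_risk_pathways: int = 8
    frac_solo_differential: float = 0.15
    mirna_targets_per_home: int = 8
    bridge_edges_per_pair: int = 12
    n_background_ppi: int = 600
    pathway_module_fraction: float = 0.75
    survival_beta: float = 1.0
    survival_median_days: float = 800.0
    censor_time_days: float = 3000.0

    def validate(self) -> None:
        for name in ("n_tumor", "n_normal", "n_mrna", "n_mirna", "n_modules", "n_pathways", "n_drugs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.frac_differential < 1.0):
            raise ValueError("frac_differential must be in [0, 1)")
        if not (abs(self.within_module_rho) < 1.0):
            raise ValueError("|within_module_rho| must be < 1")
        lo, hi = self.pathway_size
        if not (1 <= lo <= hi):
            raise ValueError("pathway_size must be a (low, high) range with 1 <= low <= high")
        if hi > self.n_mrna:
            raise ValueError(f"pathway sizes up to {hi} infeasible with n_mrna={self.n_mrna}")
        if self.n_risk_pathways > self.n_pathways:
            raise ValueError("n_risk_pathways cannot exceed n_pathways")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pathway_size"] = list(self.pathway_size)
        d["planted_synergy_pairs"] = list(self.planted_synergy_pairs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "pathway_size" in d:
            d["pathway_size"] = tuple(d["pathway_size"])
        if "planted_synergy_pairs" in d:
            d["planted_synergy_pairs"] = tuple(d["planted_synergy_pairs"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Labels for everything the generator planted."""

    differential_mrnas: Set[str] = field(default_factory=set)
    differential_mirnas: Set[str] = field(default_factory=set)
    modules: Dict[str, str] = field(default_factory=dict)  # feature -> module id / "solo"
    risk_pathways: List[str] = field(default_factory=list)
    bridge_pairs: List[Tuple[str, str]] = field(default_factory=list)
    planted_negative_edges: List[Tuple[str, str]] = field(default_factory=list)
    superadditive_pairs: List[Tuple[str, str]] = field(default_factory=list)
    additive_pairs: List[Tuple[str, str]] = field(default_factory=list)
    strong_drug: Optional[str] = None
    cascade_mirna: Optional[str] = None
    combo_signature: List[str] = field(default_factory=list)
    latent_risk: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "differential_mrnas": sorted(self.differential_mrnas),
            "differential_mirnas": sorted(self.differential_mirnas),
            "modules": {k: self.modules[k] for k in sorted(self.modules)},
            "risk_pathways": list(self.risk_pathways),
            "bridge_pairs": [list(p) for p in self.bridge_pairs],
            "planted_negative_edges": [list(e) for e in self.planted_negative_edges],
            "superadditive_pairs": [list(p) for p in self.superadditive_pairs],
            "additive_pairs": [list(p) for p in self.additive_pairs],
            "strong_drug": self.strong_drug,
            "cascade_mirna": self.cascade_mirna,
            "combo_signature": list(self.combo_signature),
            "latent_risk": {k: self.latent_risk[k] for k in sorted(self.latent_risk)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            differential_mrnas=set(d["differential_mrnas"]),
            differential_mirnas=set(d["differential_mirnas"]),
            modules=dict(d["modules"]),
            risk_pathways=list(d["risk_pathways"]),
            bridge_pairs=[tuple(p) for p in d["bridge_pairs"]],
            planted_negative_edges=[tuple(e) for e in d["planted_negative_edges"]],
            superadditive_pairs=[tuple(p) for p in d["superadditive_pairs"]],
            additive_pairs=[tuple(p) for p in d["additive_pairs"]],
            strong_drug=d["strong_drug"],
            cascade_mirna=d["cascade_mirna"],
            combo_signature=list(d["combo_signature"]),
            latent_risk=dict(d["latent_risk"]),
        )


def _partition(items: List[str], n_parts: int) -> List[List[str]]:
    parts: List[List[str]] = [[] for _ in range(n_parts)]
    for i, item in enumerate(items):
        parts[i % n_parts].append(item)
    return parts


def _sample(rng: np.random.Generator, pool: Sequence[str], k: int) -> List[str]:
    pool = sorted(pool)
    k = min(k, len(pool))
    if k == 0:
        return []
    return sorted(rng.choice(pool, size=k, replace=False).tolist())


def generate_cohort(
    config: SyntheticConfig,
) -> Tuple[ExpressionBundle, InteractionNetwork, List[PathwayGraph], DrugTargetMap, SurvivalTable, GroundTruth]:
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    # ----- samples and feature ids ---------------------------------------
    normals = [f"N{i + 1:03d}" for i in range(config.n_normal)]
    tumors = [f"T{i + 1:03d}" for i in range(config.n_tumor)]
    samples = normals + tumors
    tumor_ind = np.array([0.0] * len(normals) + [1.0] * len(tumors))
    mrna_ids = [f"G{i + 1:04d}" for i in range(config.n_mrna)]
    mirna_ids = [f"mir-{i + 1:03d}" for i in range(config.n_mirna)]

    # ----- planted differential features and modules ----------------------
    n_diff_m = round(config.frac_differential * config.n_mrna)
    n_diff_mi = round(config.frac_differential * config.n_mirna)
    diff_m = _sample(rng, mrna_ids, n_diff_m)
    diff_mi = _sample(rng, mirna_ids, n_diff_mi)
    truth.differential_mrnas = set(diff_m)
    truth.differential_mirnas = set(diff_mi)

    n_solo = round(config.frac_solo_differential * n_diff_m)
    shuffled = list(diff_m)
    rng.shuffle(shuffled)
    solo_m = sorted(shuffled[:n_solo])
    module_m_parts = _partition(sorted(shuffled[n_solo:]), config.n_modules) if n_diff_m else []
    module_mi_parts = _partition(diff_mi, config.n_modules) if n_diff_mi else []
    n_modules_eff = len(module_m_parts)

    deltas = [config.effect_log2fc * (1 if k % 2 == 0 else -1) for k in range(config.n_modules)]
    for k, part in enumerate(module_m_parts):
        for f in part:
            truth.modules[f] = f"module{k}"
    for k, part in enumerate(module_mi_parts):
        for f in part:
            truth.modules[f] = f"module{k}"
    for f in solo_m:
        truth.modules[f] = "solo"

    # latent factor scale chosen so total within-module correlation
    # (phenotype shift + shared factor vs. unit noise) hits within_module_rho
    p_t = config.n_tumor / (config.n_tumor + config.n_normal)
    shift_var = config.effect_log2fc**2 * p_t * (1 - p_t) if n_diff_m else 0.0
    rho = abs(config.within_module_rho)
    s_f2 = max(rho / (1.0 - rho) * config.noise_sd**2 - shift_var, 0.04)
    factors = rng.normal(size=(config.n_modules, len(samples))) * math.sqrt(s_f2)

    # ----- expression matrices (log2 scale, then exponentiated) ----------
    member_module_m = {f: k for k, part in enumerate(module_m_parts) for f in part}
    member_module_mi = {f: k for k, part in enumerate(module_mi_parts) for f in part}
    solo_set = set(solo_m)

    def build_matrix(ids: List[str], is_mirna: bool) -> pd.DataFrame:
        lo, hi = (4.0, 10.0) if is_mirna else (6.0, 12.0)
        mu = rng.uniform(lo, hi, size=len(ids))
        x = np.empty((len(ids), len(samples)))
        for i, fid in enumerate(ids):
            loading, shift, sd = 0.0, 0.0, config.noise_sd
            module = member_module_mi.get(fid) if is_mirna else member_module_m.get(fid)
            if module is not None:
                loading = -1.0 if is_mirna else 1.0
                shift = loading * deltas[module]
            elif fid in solo_set:
                shift = deltas[0] * (1 if rng.random() < 0.5 else -1)
                sd = 2.0 * config.noise_sd
            row = mu[i] + sd * rng.normal(size=len(samples)) + shift * tumor_ind
            if module is not None:
                row = row + loading * factors[module]
            x[i] = row
        return pd.DataFrame(np.exp2(x), index=ids, columns=samples)

    mrna_mat = build_matrix(mrna_ids, is_mirna=False)
    mirna_mat = build_matrix(mirna_ids, is_mirna=True)
    phenotype = pd.Series(
        ["normal"] * len(normals) + ["tumor"] * len(tumors), index=samples, name="phenotype"
    )
    bundle = ExpressionBundle(mrna=mrna_mat, mirna=mirna_mat, phenotype=phenotype)

    # ----- pathways --------------------------------------------------------
    lo, hi = config.pathway_size
    nondiff_m = sorted(set(mrna_ids) - set(diff_m))
    pathways: List[PathwayGraph] = []
    pathway_members: Dict[str, Set[str]] = {}
    risk_ids: List[str] = []
    risk_module: Dict[str, int] = {}
    n_risk = config.n_risk_pathways if n_modules_eff else 0
    for p in range(config.n_pathways):
        pid = f"PATH{p + 1:02d}"
        size = int(rng.integers(lo, hi + 1))
        if p < n_risk:
            k = p % n_modules_eff
            from_module = _sample(rng, module_m_parts[k], round(config.pathway_module_fraction * size))
            rest = _sample(rng, nondiff_m, size - len(from_module))
            members = set(from_module) | set(rest)
            risk_ids.append(pid)
            risk_module[pid] = k
        else:
            members = set(_sample(rng, nondiff_m + solo_m, size))
        pathways.append(PathwayGraph(id=pid, name=f"synthetic pathway {p + 1}", mrna_nodes=members))
        pathway_members[pid] = members
    truth.risk_pathways = list(risk_ids)

    # bridge pairs: pathway i paired with pathway i + n_risk//2 (same module
    # by construction when n_modules divides n_risk//2, hence strongly
    # correlated cross-pathway members)
    half = len(risk_ids) // 2
    bridges = [(risk_ids[i], risk_ids[i + half]) for i in range(half)]
    truth.bridge_pairs = list(bridges)

    # ----- miRNA target edges ---------------------------------------------
    mirna_targets: Dict[str, Set[str]] = {m: set() for m in mirna_ids}
    home_of: Dict[str, str] = {}
    for k, part in enumerate(module_mi_parts):
        homes = [pid for pid in risk_ids if risk_module[pid] == k]
        for idx, mi in enumerate(part):
            if not homes:
                continue
            home = homes[idx % len(homes)]
            home_of[mi] = home
            in_home = _sample(
                rng,
                pathway_members[home] & set(module_m_parts[k]),
                config.mirna_targets_per_home,
            )
            mirna_targets[mi].update(in_home)
            truth.planted_negative_edges.extend((mi, t) for t in in_home)
            decoy = _sample(rng, nondiff_m, 1)
            mirna_targets[mi].update(decoy)
    # non-differential miRNAs: a few random targets (attachment decoys)
    for mi in mirna_ids:
        if mi not in truth.differential_mirnas:
            mirna_targets[mi].update(_sample(rng, mrna_ids, int(rng.integers(3, 7))))

    # ----- cascade construction -------------------------------------------
    cascade_mirna: Optional[str] = None
    cascade_T: List[str] = []
    q_edges: List[str] = []
    if bridges and "cascade" in config.planted_synergy_pairs:
        home_pid, partner_pid = bridges[0]
        k = risk_module[home_pid]
        candidates = [
            mi for mi in module_mi_parts[k] if home_of.get(mi) == home_pid
            and len(mirna_targets[mi] & pathway_members[home_pid]) >= 4
        ]
        if candidates:
            cascade_mirna = candidates[0]
            cascade_T = sorted(mirna_targets[cascade_mirna] & pathway_members[home_pid])
            # cross-pathway edges that only the joint removal can silence:
            # targets inside other risk pathways but outside the home pathway,
            # preferring members of modules with the same shift sign (those
            # correlate negatively with the miRNA, like its true targets)
            sign_k = 1 if deltas[k] >= 0 else -1
            taken: Set[str] = set(cascade_T)
            for pz in [partner_pid] + [p for p in risk_ids if p not in (home_pid, partner_pid)]:
                avail = sorted((pathway_members[pz] - pathway_members[home_pid]) - taken)
                same_sign = [
                    a for a in avail
                    if a in member_module_m
                    and (1 if deltas[member_module_m[a]] >= 0 else -1) == sign_k
                ]
                other = [a for a in avail if a not in member_module_m]
                picks = (same_sign + other)[: 12 if pz == partner_pid else 6]
                q_edges.extend(picks)
                taken.update(picks)
                if len(q_edges) >= 28:
                    break
            mirna_targets[cascade_mirna].update(q_edges)
            truth.planted_negative_edges.extend(
                (cascade_mirna, q)
                for q in q_edges
                if q in member_module_m
                and (1 if deltas[member_module_m[q]] >= 0 else -1) == sign_k
            )
            truth.cascade_mirna = cascade_mirna
    truth.combo_signature = list(cascade_T)

    # ----- PPI network ------------------------------------------------------
    ppi: Set[Tuple[str, str]] = set()
    bridge_endpoints: Dict[Tuple[str, str], List[Tuple[str, str]]] = {}
    for pair_idx, (pa, pb) in enumerate(bridges):
        diff_a = sorted(pathway_members[pa] & set(diff_m))
        diff_b = sorted(pathway_members[pb] & set(diff_m))
        if not diff_a or not diff_b:
            continue
        edges_here: List[Tuple[str, str]] = []
        # the cascade pair's bridge covers each in-pathway miRNA target once,
        # so each half of the planted drug pair has direct crosstalk to lose;
        # partners never come from the miRNA's target set itself, keeping the
        # two halves' destroyed contributions disjoint (margin = cascade only)
        if pair_idx == 0 and cascade_T:
            diff_b = [b for b in diff_b if b not in set(cascade_T)]
            if not diff_b:
                continue
            for t in cascade_T:
                partner = _sample(rng, [b for b in diff_b if b != t], 1)
                if partner:
                    edges_here.append((t, partner[0]))
        while len(edges_here) < config.bridge_edges_per_pair:
            a = diff_a[int(rng.integers(len(diff_a)))]
            b = diff_b[int(rng.integers(len(diff_b)))]
            if a != b:
                edges_here.append((a, b))
        bridge_endpoints[(pa, pb)] = edges_here
        ppi.update(ppi_edge(a, b) for a, b in edges_here)

    # ----- drugs ------------------------------------------------------------
    drug_map = DrugTargetMap()
    drug_ids = [f"DRUG{i + 1:02d}" for i in range(config.n_drugs)]
    module_mi_all = [mi for part in module_mi_parts for mi in part]

    def bridge_targets(pair_idx: int, n: int) -> List[str]:
        if pair_idx >= len(bridges):
            return []
        edges = bridge_endpoints.get(bridges[pair_idx], [])
        endpoints = sorted({e for edge in edges for e in edge})
        return _sample(rng, endpoints, n)

    planted: Dict[str, DrugTargets] = {}
    if cascade_mirna and len(cascade_T) >= 2 and config.n_drugs >= 2:
        split = len(cascade_T) // 2
        planted[drug_ids[0]] = DrugTargets(mrna_targets=set(cascade_T[:split]))
        planted[drug_ids[1]] = DrugTargets(mrna_targets=set(cascade_T[split:]))
        truth.superadditive_pairs.append((drug_ids[0], drug_ids[1]))
    if "additive" in config.planted_synergy_pairs and len(bridges) >= 3 and config.n_drugs >= 4:
        planted[drug_ids[2]] = DrugTargets(mrna_targets=set(bridge_targets(1, 3)))
        planted[drug_ids[3]] = DrugTargets(mrna_targets=set(bridge_targets(2, 3)))
        if planted[drug_ids[2]].all_targets and planted[drug_ids[3]].all_targets:
            truth.additive_pairs.append((drug_ids[2], drug_ids[3]))
    if len(bridges) >= 4 and config.n_drugs >= 5:
        strong = set(bridge_targets(3, 10))
        k_strong = risk_module[bridges[3][0]]
        strong_mi = _sample(rng, [m for m in module_mi_parts[k_strong] if m != cascade_mirna], 1)
        planted[drug_ids[4]] = DrugTargets(mrna_targets=strong, mirna_targets=set(strong_mi))
        truth.strong_drug = drug_ids[4]

    all_endpoints = sorted({e for edges in bridge_endpoints.values() for edge in edges for e in edge})
    module_m_all = [m for part in module_m_parts for m in part]
    filler_pool = sorted(set(all_endpoints) | set(module_m_all)) or mrna_ids
    for did in drug_ids:
        if did in planted:
            drug_map[did] = planted[did]
            continue
        drug_map[did] = DrugTargets(
            mrna_targets=set(_sample(rng, filler_pool, int(rng.integers(2, 5))))
        )
    drug_map.validate()

    # ----- background PPI ---------------------------------------------------
    # never between the two planted-additive drugs' target sets (keeps that
    # pair exactly additive) nor between the two halves of the cascade
    # miRNA's targets (keeps the planted pair's margin purely the cascade)
    add_a = planted.get(drug_ids[2], DrugTargets()).mrna_targets if config.n_drugs >= 4 else set()
    add_b = planted.get(drug_ids[3], DrugTargets()).mrna_targets if config.n_drugs >= 4 else set()
    casc_a = planted.get(drug_ids[0], DrugTargets()).mrna_targets if cascade_T else set()
    casc_b = planted.get(drug_ids[1], DrugTargets()).mrna_targets if cascade_T else set()
    attempts = 0

    def _crosses(a: str, b: str, s1: Set[str], s2: Set[str]) -> bool:
        return (a in s1 and b in s2) or (a in s2 and b in s1)

    while len(ppi) < config.n_background_ppi and attempts < 20 * config.n_background_ppi:
        attempts += 1
        a = mrna_ids[int(rng.integers(config.n_mrna))]
        b = mrna_ids[int(rng.integers(config.n_mrna))]
        if a == b:
            continue
        if _crosses(a, b, add_a, add_b) or _crosses(a, b, casc_a, casc_b):
            continue
        ppi.add(ppi_edge(a, b))
    network = InteractionNetwork(
        ppi_edges=ppi,
        mirna_target_edges={(mi, t) for mi, ts in mirna_targets.items() for t in ts},
    )

    # ----- survival ---------------------------------------------------------
    signature = cascade_T
    if signature:
        sub = np.log2(mrna_mat.loc[signature, tumors].to_numpy() + 1.0)
        z = (sub - sub.mean(axis=1, keepdims=True)) / np.where(
            sub.std(axis=1, keepdims=True) == 0, 1.0, sub.std(axis=1, keepdims=True)
        )
        risk_score = z.mean(axis=0)
    else:
        risk_score = np.zeros(len(tumors))
    base_rate = math.log(2) / config.survival_median_days
    rates = base_rate * np.exp(config.survival_beta * risk_score)
    raw_times = rng.exponential(1.0 / rates)
    event = (raw_times <= config.censor_time_days).astype(int)
    times = np.minimum(raw_times, config.censor_time_days)
    survival = SurvivalTable(
        pd.DataFrame({"time": times, "event": event}, index=pd.Index(tumors, name="sample"))
    )
    truth.latent_risk = {s: float(r) for s, r in zip(tumors, risk_score)}

    return bundle, network, pathways, drug_map, survival, truth


def write_cohort(
    bundle: ExpressionBundle,
    network: InteractionNetwork,
    pathways: List[PathwayGraph],
    drug_map: DrugTargetMap,
    survival: SurvivalTable,
    truth: GroundTruth,
    outdir,
) -> Dict[str, Path]:
    """Emit the cohort in every on-disk format the pipeline reads, plus the
    ground-truth labels as JSON. Returns the path of each file written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna": outdir / "mrna_expression.tsv",
        "mirna": outdir / "mirna_expression.tsv",
        "phenotype": outdir / "phenotype.tsv",
        "ppi": outdir / "ppi_edges.tsv",
        "mirna_targets": outdir / "mirna_targets.tsv",
        "pathways": outdir / "pathways.gmt",
        "drug_targets": outdir / "drug_targets.tsv",
        "survival": outdir / "survival.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    cio.write_expression(bundle, paths["mrna"], paths["mirna"], paths["phenotype"])
    cio.write_edges(network.ppi_edges, paths["ppi"])
    cio.write_edges(network.mirna_target_edges, paths["mirna_targets"])
    cio.write_gmt(pathways, paths["pathways"])
    cio.write_drug_targets(drug_map, paths["drug_targets"])
    cio.write_survival(survival, paths["survival"])
    cio.write_json(truth.to_dict(), paths["ground_truth"])
    return paths
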