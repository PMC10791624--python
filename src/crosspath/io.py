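"""Readers and writers for every on-disk format the pipeline touches.

Formats: expression TSV (features in rows, header row of sample ids),
phenotype TSV (sample -> tumor/normal), GMT pathway membership, 2-column
edge TSVs (PPI, miRNA->target), 3-column drug-target TSV, survival TSV, and
JSON for all result objects. Networks can also be exported to GraphML.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    DrugTargetMap,
    DrugTargets,
    ExpressionBundle,
    InteractionNetwork,
    PathwayGraph,
    SurvivalTable,
    ppi_edge,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

FLOAT_FORMAT = "%.17g"  # round-trips IEEE doubles exactly


class FormatError(ValueError):
    """Raised when an on-disk file violates its declared format."""


# -- expression ------------------------------------------------------------


def _read_matrix(path: PathLike, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{what} file {path}: duplicate feature id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = df.index[coerced.isna().argmax()]
            raise FormatError(f"{what} file {path}: non-numeric cell at row {row!r}, column {col!r}")
        df[col] = coerced
    if df.isna().any().any():
        raise FormatError(f"{what} file {path}: missing value present")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_phenotype(path: PathLike) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"phenotype file {path}: need sample and label columns")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="phenotype")
    return ser


def read_expression(
    path_mrna: PathLike,
    path_mirna: PathLike,
    path_phenotype: PathLike,
    is_log2: bool = False,
) -> ExpressionBundle:
    """Load matched mRNA/miRNA matrices; the working cohort is the sorted
    intersection of the two matrices' samples and the phenotype file."""
    mrna = _read_matrix(path_mrna, "mRNA expression")
    mirna = _read_matrix(path_mirna, "miRNA expression")
    pheno = read_phenotype(path_phenotype)

    common = sorted(set(mrna.columns) & set(mirna.columns) & set(pheno.index))
    if not common:
        offending = (sorted(mrna.columns) or ["<empty>"])[0]
        raise FormatError(
            f"no common samples between expression matrices and phenotype (first mRNA sample: {offending!r})"
        )
    return ExpressionBundle(
        mrna=mrna[common],
        mirna=mirna[common],
        phenotype=pheno[common],
        is_log2=is_log2,
    )


def write_expression(bundle: ExpressionBundle, path_mrna: PathLike, path_mirna: PathLike, path_phenotype: PathLike) -> None:
    bundle.mrna.to_csv(path_mrna, sep="\t", float_format=FLOAT_FORMAT)
    bundle.mirna.to_csv(path_mirna, sep="\t", float_format=FLOAT_FORMAT)
    pd.DataFrame({"sample": bundle.phenotype.index, "phenotype": bundle.phenotype.values}).to_csv(
        path_phenotype, sep="\t", index=False
    )


# -- pathways (GMT) --------------------------------------------------------


def read_gmt(path: PathLike, edges_path: Optional[PathLike] = None) -> List[PathwayGraph]:
    """Read standard GMT (name TAB description TAB member ids...).

    ``edges_path`` optionally supplies internal edges as a 3-column TSV
    (pathway_id, node_a, node_b).
    """
    edges_by_pathway: Dict[str, Set[Tuple[str, str]]] = {}
    if edges_path is not None:
        edf = pd.read_csv(edges_path, sep="\t", header=None, dtype=str)
        for _, row in edf.iterrows():
            edges_by_pathway.setdefault(row[0], set()).add(ppi_edge(row[1], row[2]))

    pathways: List[PathwayGraph] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT {path}:{lineno}: expected >= 3 tab-separated fields")
            pid, name = fields[0], fields[1]
            members = {f for f in fields[2:] if f}
            pathways.append(
                PathwayGraph(id=pid, name=name, mrna_nodes=members, internal_edges=edges_by_pathway.get(pid))
            )
    return pathways


def write_gmt(pathways: Iterable[PathwayGraph], path: PathLike, edges_path: Optional[PathLike] = None) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.id, p.name] + sorted(p.mrna_nodes)) + "\n")
    if edges_path is not None:
        with open(edges_path, "w") as fh:
            for p in pathways:
                for a, b in sorted(p.internal_edges or ()):
                    fh.write(f"{p.id}\t{a}\t{b}\n")


# -- edge lists ------------------------------------------------------------


def read_edges(path: PathLike, kind: str) -> Set[Tuple[str, str]]:
    """Read a 2-column TSV edge list.

    kind="ppi": unordered, deduplicated, self-loops skipped with a warning.
    kind="mirna_target": directed (miRNA, mRNA) pairs.
    """
    if kind not in {"ppi", "mirna_target"}:
        raise ValueError(f"unknown edge kind {kind!r}")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"edge file {path}: need two id columns")
    edges: Set[Tuple[str, str]] = set()
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if a == b:
            log.warning("edge file %s: skipping self-loop (%s, %s)", path, a, b)
            warnings.warn(f"self-loop ({a}, {b}) skipped", stacklevel=2)
            continue
        edges.add(ppi_edge(a, b) if kind == "ppi" else (a, b))
    return edges


def write_edges(edges: Iterable[Tuple[str, str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")


def read_drug_targets(path: PathLike) -> DrugTargetMap:
    """3-column TSV: drug id, target id, target kind (mRNA|miRNA)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"drug-target file {path}: need drug, target, kind columns")
    dmap = DrugTargetMap()
    for drug, target, kind in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
        entry = dmap.setdefault(drug, DrugTargets())
        if kind == "mRNA":
            entry.mrna_targets.add(target)
        elif kind == "miRNA":
            entry.mirna_targets.add(target)
        else:
            raise FormatError(f"drug-target file {path}: unknown target kind {kind!r}")
    dmap.validate()
    return dmap


def write_drug_targets(dmap: DrugTargetMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        for drug in sorted(dmap):
            for t in sorted(dmap[drug].mrna_targets):
                fh.write(f"{drug}\t{t}\tmRNA\n")
            for t in sorted(dmap[drug].mirna_targets):
                fh.write(f"{drug}\t{t}\tmiRNA\n")


# -- survival --------------------------------------------------------------


def read_survival(path: PathLike) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    df.columns = ["sample", "time", "event"][: df.shape[1]]
    df = df.set_index("sample")
    df["time"] = pd.to_numeric(df["time"])
    df["event"] = pd.to_numeric(df["event"]).astype(int)
    return SurvivalTable(df)


def write_survival(table: SurvivalTable, path: PathLike) -> None:
    out = table.data.reset_index()
    out.columns = ["sample", "time", "event"]
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# -- JSON / GraphML --------------------------------------------------------


def write_json(obj, path: PathLike) -> None:
    """Deterministic JSON (sorted keys) for result objects with to_dict()."""
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: PathLike):
    with open(path) as fh:
        return json.load(fh)


def network_to_graphml(network: InteractionNetwork, path: PathLike) -> None:
    g = nx.Graph()
    for a, b in sorted(network.ppi_edges):
        g.add_edge(a, b, kind="ppi")
    for m, t in sorted(network.mirna_target_edges):
        g.add_edge(m, t, kind="mirna_target")
    nx.write_graphml(g, path)


def crosstalk_to_graphml(crosstalk, path: PathLike) -> None:
    g = nx.Graph()
    for (i, j), entry in sorted(crosstalk.entries.items()):
        g.add_edge(i, j, crosstalk=float(entry.score), n_pairs=len(entry.pairs))
    nx.write_graphml(g, path)
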