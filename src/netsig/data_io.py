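"""Readers and writers for every external format the pipeline touches.

Formats: expression matrices (TSV, genes x samples), TF->target edge lists
(TSV), signed pathway graphs (a SIF dialect: ``source<TAB>relation<TAB>target``
with relation in {activation, inhibition}), drug-target catalogs (TSV),
synergy screens (CSV) and merged core networks (GraphML plus a flat TSV edge
list).

Gene and sample orderings are canonicalized (sorted) on load so that input
file ordering can never leak into downstream results.  Identifiers are
opaque case-sensitive strings; no symbol mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

SIF_RELATIONS = {"activation": 1, "inhibition": -1}
_SIGN_TO_RELATION = {1: "activation", -1: "inhibition"}

NODE_ROLES = ("start", "transduction", "tf", "drug")


class DataFormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A dense genes x samples expression matrix with a role label.

    ``values[i, j]`` is the expression of ``genes[i]`` in ``samples[j]`` on
    the working (linear) scale.  Gene and sample ids are unique and sorted.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    role: str = "control"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise DataFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise DataFormatError("duplicate gene ids")
        if len(set(self.samples)) != len(self.samples):
            raise DataFormatError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise DataFormatError("expression matrix contains missing or non-finite values")
        self._canonicalize()

    def _canonicalize(self) -> None:
        gene_order = np.argsort(self.genes)
        sample_order = np.argsort(self.samples)
        self.genes = [self.genes[i] for i in gene_order]
        self.samples = [self.samples[j] for j in sample_order]
        self.values = self.values[np.ix_(gene_order, sample_order)]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def row(self, gene: str) -> np.ndarray:
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.values[i]


def read_expression_matrix(path: str | Path, scale: str = "linear", role: str = "control") -> ExpressionMatrix:
    """Load a genes x samples TSV.

    The header row holds sample ids; the first column holds gene ids.
    ``scale='log2'`` exponentiates values (2**x) so the in-memory matrix is
    always on the linear scale the doubled-variable p-value operates on.
    Duplicate gene rows, duplicate sample columns and missing or non-numeric
    cells are hard errors: silent imputation would corrupt the null model.
    """
    if scale not in ("linear", "log2"):
        raise ValueError(f"scale must be 'linear' or 'log2', got {scale!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise DataFormatError(f"{path}: duplicated gene rows: {', '.join(map(str, dupes))}")
    if df.columns.duplicated().any():
        dupes = sorted(df.columns[df.columns.duplicated()].unique())
        raise DataFormatError(f"{path}: duplicated sample columns: {', '.join(map(str, dupes))}")
    vals = df.apply(pd.to_numeric, errors="coerce")
    bad = vals.isna().values
    if bad.any():
        gi, sj = np.argwhere(bad)[0]
        cell = df.iloc[gi, sj]
        kind = "missing value" if pd.isna(cell) else f"non-numeric cell {cell!r}"
        raise DataFormatError(
            f"{path}: {kind} at gene {df.index[gi]!r}, sample {df.columns[sj]!r}"
        )
    values = vals.values
    if scale == "log2":
        values = np.exp2(values)
    return ExpressionMatrix(list(vals.index), list(vals.columns), values, role=role)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(Path(path), sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Regulatory network
# ---------------------------------------------------------------------------


@dataclass
class RegulatoryNetwork:
    """A bipartite TF -> target-gene network (unique directed edges)."""

    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.edges)) != len(self.edges):
            raise DataFormatError("duplicate TF->target edges")
        self.edges = sorted(self.edges)
        self._targets_by_tf: dict[str, frozenset[str]] = {}
        for tf, target in self.edges:
            self._targets_by_tf.setdefault(tf, set()).add(target)  # type: ignore[arg-type]
        self._targets_by_tf = {tf: frozenset(t) for tf, t in self._targets_by_tf.items()}

    @property
    def tfs(self) -> list[str]:
        return sorted(self._targets_by_tf)

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.edges}

    def targets_of(self, tf: str) -> frozenset[str]:
        try:
            return self._targets_by_tf[tf]
        except KeyError:
            raise KeyError(f"unknown TF {tf!r}") from None

    def counts(self) -> dict[str, int]:
        return {
            "tfs": len(self._targets_by_tf),
            "targets": len(self.targets),
            "interactions": len(self.edges),
        }


def read_regulatory_network(path: str | Path) -> RegulatoryNetwork:
    """Load a two-column TSV (tf, target) with a header row."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: expected columns (tf, target)")
    if df.iloc[:, :2].isna().any().any():
        raise DataFormatError(f"{path}: dangling fields in edge list")
    edges = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return RegulatoryNetwork(edges)


def write_regulatory_network(network: RegulatoryNetwork, path: str | Path) -> None:
    pd.DataFrame(network.edges, columns=["tf", "target"]).to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pathway graphs (SIF dialect)
# ---------------------------------------------------------------------------


@dataclass
class PathwayGraph:
    """A directed signed gene graph (sign +1 activation, -1 inhibition)."""

    pathway_id: str
    name: str
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_edge(self, source: str, target: str, sign: int) -> None:
        if sign not in (1, -1):
            raise DataFormatError(f"edge sign must be +1 or -1, got {sign}")
        if not source or not target:
            raise DataFormatError("node names must be nonempty")
        self.graph.add_edge(source, target, sign=sign)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges_with_signs(self) -> list[tuple[str, str, int]]:
        return sorted((u, v, d["sign"]) for u, v, d in self.graph.edges(data=True))


def read_pathway_sif(path: str | Path, pathway_id: str | None = None, name: str | None = None) -> PathwayGraph:
    """Parse the extended-SIF dialect: ``source<TAB>relation<TAB>target``."""
    path = Path(path)
    pid = pathway_id if pathway_id is not None else path.stem
    pw = PathwayGraph(pid, name if name is not None else pid)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise DataFormatError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
            source, relation, target = parts
            if relation not in SIF_RELATIONS:
                raise DataFormatError(
                    f"{path}:{lineno}: unknown relation {relation!r}; "
                    f"accepted relations: {', '.join(sorted(SIF_RELATIONS))}"
                )
            pw.add_edge(source, target, SIF_RELATIONS[relation])
    return pw


def write_pathway_sif(pathway: PathwayGraph, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for u, v, sign in pathway.edges_with_signs():
            fh.write(f"{u}\t{_SIGN_TO_RELATION[sign]}\t{v}\n")


def read_pathway_dir(directory: str | Path) -> list[PathwayGraph]:
    return [read_pathway_sif(p) for p in sorted(Path(directory).glob("*.sif"))]


# ---------------------------------------------------------------------------
# Drug catalogs and synergy screens
# ---------------------------------------------------------------------------


@dataclass
class DrugTargetCatalog:
    """Unique (drug, target-gene) records."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.records)) != len(self.records):
            raise DataFormatError("duplicate (drug, target) pairs in catalog")
        self.records = sorted(self.records)

    @property
    def drugs(self) -> list[str]:
        return sorted({d for d, _ in self.records})

    def targets_of(self, drug: str) -> set[str]:
        return {t for d, t in self.records if d == drug}


def read_drug_catalog(path: str | Path) -> DrugTargetCatalog:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: expected columns (drug, target)")
    if df.iloc[:, :2].isna().any().any():
        raise DataFormatError(f"{path}: dangling fields in drug catalog")
    return DrugTargetCatalog(list(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip())))


def write_drug_catalog(catalog: DrugTargetCatalog, path: str | Path) -> None:
    pd.DataFrame(catalog.records, columns=["drug", "target"]).to_csv(Path(path), sep="\t", index=False)


@dataclass(frozen=True, order=True)
class SynergyRecord:
    """One combination-screen measurement; drug order is normalized on load."""

    drug1: str
    drug2: str
    cell_line: str
    score: float

    @classmethod
    def normalized(cls, drug1: str, drug2: str, cell_line: str, score: float) -> "SynergyRecord":
        a, b = sorted((drug1.strip(), drug2.strip()))
        return cls(a, b, cell_line.strip(), float(score))

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug1, self.drug2)


def read_synergy_table(path: str | Path) -> list[SynergyRecord]:
    """Load a CSV with columns drug1, drug2, cell_line, score (extra columns ignored)."""
    df = pd.read_csv(Path(path))
    cols = {c.lower().replace(" ", "_"): c for c in df.columns}
    required = ["drug1", "drug2", "cell_line", "score"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    records = []
    for _, row in df.iterrows():
        try:
            score = float(row[cols["score"]])
        except (TypeError, ValueError):
            raise DataFormatError(f"{path}: non-numeric score {row[cols['score']]!r}") from None
        records.append(
            SynergyRecord.normalized(
                str(row[cols["drug1"]]), str(row[cols["drug2"]]), str(row[cols["cell_line"]]), score
            )
        )
    return records


def write_synergy_table(records: Sequence[SynergyRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.drug1, r.drug2, r.cell_line, r.score) for r in records],
        columns=["drug1", "drug2", "cell_line", "score"],
    ).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Core-network export (GraphML + flat TSV)
# ---------------------------------------------------------------------------


def write_core_network(
    graph: nx.DiGraph,
    path: str | Path,
    edge_list_path: str | Path | None = None,
) -> None:
    """Serialize a merged core signaling network.

    Nodes carry a ``role`` attribute in {start, transduction, tf, drug};
    edges carry ``sign`` and a provenance string.  GraphML is the primary
    format; a flat TSV edge list is written alongside when requested.
    """
    path = Path(path)
    out = nx.DiGraph()
    for node, data in graph.nodes(data=True):
        role = data.get("role", "transduction")
        if role not in NODE_ROLES:
            raise DataFormatError(f"node {node!r}: unknown role {role!r}")
        out.add_node(node, role=role)
    for u, v, data in graph.edges(data=True):
        attrs = {"sign": int(data.get("sign", 1))}
        prov = data.get("provenance")
        if prov is not None:
            attrs["provenance"] = ";".join(f"{p}:{c}" for p, c in prov) if not isinstance(prov, str) else prov
        out.add_edge(u, v, **attrs)
    nx.write_graphml(out, path)
    if edge_list_path is not None:
        rows = [
            (u, v, d.get("sign", 1), d.get("provenance", ""))
            for u, v, d in sorted(out.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "sign", "provenance"]).to_csv(
            Path(edge_list_path), sep="\t", index=False
        )


def read_core_network(path: str | Path) -> nx.DiGraph:
    graph = nx.read_graphml(Path(path))
    out = nx.DiGraph()
    for node, data in graph.nodes(data=True):
        out.add_node(node, role=data.get("role", "transduction"))
    for u, v, data in graph.edges(data=True):
        out.add_edge(u, v, sign=int(data.get("sign", 1)), provenance=data.get("provenance", ""))
    return out
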