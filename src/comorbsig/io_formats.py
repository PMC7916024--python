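"""Readers and writers for the external formats the pipeline touches.

Every other module operates on the in-memory domain types defined here:
expression matrices with case/control labels, GMT gene-set collections,
undirected interaction edge lists, and TF->target regulon tables.  All files
are UTF-8, tab-delimited, with a header row, so writer/reader pairs
round-trip bit-stably.

Gene identifiers are opaque, case-sensitive strings; no symbol aliasing is
attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("comorbsig")

CASE = "case"
CONTROL = "control"

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "RegulonTable",
    "EdgeList",
    "FormatError",
    "ValidationError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_regulon_tsv",
    "write_regulon_tsv",
    "write_results_tsv",
    "load_reference_common_degs",
]


class FormatError(ValueError):
    """A file does not conform to the documented layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """One cohort's genes x samples expression matrix with group labels.

    ``values`` holds raw-scale intensities on load and log-scale intensities
    after normalization; the container itself is scale-agnostic.
    """

    dataset_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        G, S = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (G, S):
            raise ValidationError(
                f"{self.dataset_id}: matrix shape {self.values.shape} does not "
                f"match {G} genes x {S} samples"
            )
        if G < 2:
            raise ValidationError(f"{self.dataset_id}: need at least 2 genes")
        if len(set(self.gene_ids)) != G:
            raise ValidationError(f"{self.dataset_id}: duplicate gene ids")
        if len(set(self.sample_ids)) != S:
            raise ValidationError(f"{self.dataset_id}: duplicate sample ids")
        if any(g not in (CASE, CONTROL) for g in self.group):
            raise ValidationError(
                f"{self.dataset_id}: group labels must be '{CASE}' or '{CONTROL}'"
            )
        if len(self.group) != S:
            raise ValidationError(f"{self.dataset_id}: one group label per sample required")
        if self.n_case < 2 or self.n_control < 2:
            raise ValidationError(
                f"{self.dataset_id}: need >=2 case and >=2 control samples "
                f"(got {self.n_case} case, {self.n_control} control)"
            )

    @property
    def n_case(self) -> int:
        return sum(g == CASE for g in self.group)

    @property
    def n_control(self) -> int:
        return sum(g == CONTROL for g in self.group)

    def case_matrix(self) -> np.ndarray:
        mask = np.array([g == CASE for g in self.group])
        return self.values[:, mask]

    def control_matrix(self) -> np.ndarray:
        mask = np.array([g == CONTROL for g in self.group])
        return self.values[:, mask]

    def with_values(self, values: np.ndarray) -> "ExpressionDataset":
        return ExpressionDataset(
            self.dataset_id, list(self.gene_ids), list(self.sample_ids),
            np.asarray(values, dtype=float), list(self.group),
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionDataset(
            self.dataset_id, list(gene_ids), list(self.sample_ids),
            self.values[rows, :], list(self.group),
        )


@dataclass
class GeneSetCollection:
    """term_id -> (term_name, member gene set), with a source tag."""

    sets: dict[str, tuple[str, frozenset[str]]]
    source: str = ""

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {term_id!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, term_id: str) -> frozenset[str]:
        return self.sets[term_id][1]

    def name(self, term_id: str) -> str:
        return self.sets[term_id][0]

    def term_ids(self) -> list[str]:
        return list(self.sets)


@dataclass(frozen=True)
class RegulonRow:
    tf: str
    target: str
    mode: str  # activation | repression | unknown


_REGULON_MODES = {
    "activation": "activation",
    "repression": "repression",
    "unknown": "unknown",
}


@dataclass
class RegulonTable:
    """TRRUST-style TF -> target rows with an interaction mode."""

    rows: list[RegulonRow]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        deduped = []
        for row in self.rows:
            key = (row.tf, row.target)
            if key in seen:
                continue
            seen.add(key)
            deduped.append(row)
        self.rows = deduped

    def to_gene_sets(self) -> GeneSetCollection:
        """Collapse to TF -> target-set terms (modes ignored for membership)."""
        targets: dict[str, set[str]] = {}
        for row in self.rows:
            targets.setdefault(row.tf, set()).add(row.target)
        return GeneSetCollection(
            {tf: (tf, frozenset(members)) for tf, members in targets.items()},
            source="regulons",
        )


@dataclass
class EdgeList:
    """Undirected edges with optional nonnegative weights.

    Self-loops are dropped; duplicate undirected pairs are merged keeping the
    maximum weight.  Node pairs are stored in canonical (min, max) order.
    """

    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        merged: dict[tuple[str, str], float] = {}
        for a, b, *rest in self.edges:
            w = float(rest[0]) if rest else 1.0
            if w < 0:
                raise ValidationError(f"negative edge weight on {a}-{b}")
            if a == b:
                logger.warning("dropping self-loop %s-%s", a, b)
                continue
            key = (a, b) if a <= b else (b, a)
            merged[key] = max(merged.get(key, 0.0), w)
        self.edges = [(a, b, w) for (a, b), w in sorted(merged.items())]

    def nodes(self) -> set[str]:
        return {n for a, b, _ in self.edges for n in (a, b)}

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    # keep the duplicate row with the highest mean intensity
    if df.index.is_unique:
        return df
    means = df.mean(axis=1)
    order = np.argsort(-means.to_numpy(), kind="stable")
    kept = df.iloc[order]
    kept = kept[~kept.index.duplicated(keep="first")]
    # restore original first-occurrence order of gene ids
    first_order = df.index.drop_duplicates()
    return kept.loc[first_order]


def read_expression_tsv(
    path: str | Path,
    labels: str | Path | Mapping[str, str] | None = None,
    dataset_id: str | None = None,
) -> ExpressionDataset:
    """Read a genes x samples TSV into an :class:`ExpressionDataset`.

    The first column holds gene ids and the header row holds sample ids.
    Group labels come either from an embedded second header row whose first
    field is ``group``, or from ``labels``: a two-column sidecar TSV
    (sample_id, group) or an in-memory mapping.

    Duplicate gene ids are collapsed by keeping the row with the highest mean.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: header must contain gene-id column plus samples")
        pos = fh.tell()
        second = fh.readline().rstrip("\n").split("\t")
        embedded = second and second[0] == "group"
        if embedded:
            if len(second) != len(header):
                raise FormatError(f"{path}: group row has {len(second)} fields, expected {len(header)}")
            group_by_sample = dict(zip(header[1:], second[1:]))
        else:
            fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", header=None, index_col=0, names=header)
    df.index = df.index.astype(str)
    if not embedded:
        if labels is None:
            raise FormatError(f"{path}: no embedded group row and no label sidecar given")
        if isinstance(labels, (str, Path)):
            lab = pd.read_csv(labels, sep="\t", dtype=str)
            if lab.shape[1] < 2:
                raise FormatError(f"{labels}: sidecar needs sample_id and group columns")
            group_by_sample = dict(zip(lab.iloc[:, 0], lab.iloc[:, 1]))
        else:
            group_by_sample = dict(labels)
    missing = [s for s in df.columns if s not in group_by_sample]
    if missing:
        raise ValidationError(f"{path}: samples without group label: {missing}")
    df = _collapse_duplicate_genes(df)
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem,
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        values=df.to_numpy(dtype=float),
        group=[group_by_sample[s] for s in df.columns],
    )


def write_expression_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write an expression matrix with an embedded ``group`` label row."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(dataset.sample_ids) + "\n")
        fh.write("group\t" + "\t".join(dataset.group) + "\n")
        for gene, row in zip(dataset.gene_ids, dataset.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, source: str = "") -> GeneSetCollection:
    """Read a GMT file: per line, term id, description, then member genes."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            term_id, desc, *genes = fields
            genes = [g for g in genes if g]
            if term_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            if not genes:
                logger.warning("%s:%d: dropping empty gene set %s", path, lineno, term_id)
                continue
            sets[term_id] = (desc, frozenset(genes))
    return GeneSetCollection(sets, source=source or str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id, (desc, members) in collection.sets.items():
            fh.write("\t".join([term_id, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Edge lists and regulons
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> EdgeList:
    """Read an undirected edge list TSV: node_a, node_b[, weight]."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: edge list needs node_a and node_b columns")
    edges = []
    for row in df.itertuples(index=False):
        w = float(row[2]) if df.shape[1] >= 3 and not pd.isna(row[2]) else 1.0
        edges.append((str(row[0]), str(row[1]), w))
    return EdgeList(edges)


def write_edge_list(edge_list: EdgeList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b, w in edge_list.edges:
            fh.write(f"{a}\t{b}\t{repr(w)}\n")


def read_regulon_tsv(path: str | Path) -> RegulonTable:
    """Read a TRRUST-style regulon TSV: tf, target, mode."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: regulon table needs tf, target, mode columns")
    rows = []
    for tf, target, mode in df.iloc[:, :3].itertuples(index=False):
        key = str(mode).strip().lower()
        if key not in _REGULON_MODES:
            raise ValidationError(f"{path}: unknown regulon mode {mode!r} for {tf}->{target}")
        rows.append(RegulonRow(str(tf), str(target), _REGULON_MODES[key]))
    return RegulonTable(rows)


def write_regulon_tsv(table: RegulonTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tf\ttarget\tmode\n")
        for row in table.rows:
            fh.write(f"{row.tf}\t{row.target}\t{row.mode}\n")


def write_results_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write an analysis result table as a UTF-8 TSV with header."""
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged reference data
# ---------------------------------------------------------------------------

def load_reference_common_degs() -> pd.DataFrame:
    """The reported 28-gene concordant signature shared by the SCZ and T2DM
    PBMC cohorts (7 up-, 21 down-regulated), used for reproduction runs.

    Columns: gene_id, description, regulation ("up"/"down").
    """
    with resources.files("comorbsig.data").joinpath("concordant_degs.tsv").open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)
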