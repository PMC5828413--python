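"""Readers and writers for the file formats the pipeline touches.

Expression compendia travel as tab-separated tables (genes in rows,
experiments in columns, header row of experiment IDs).  Gene sets use the
GMT format (set name, description, then member gene IDs, tab-separated,
one set per line).  Disease gene lists are plain text, one ID per line.
Screen reports, network edge lists and enrichment tables are written as
deterministic TSV so identical inputs yield byte-identical files.

Gene identifiers are opaque strings throughout (compendia mix Entrez
numerals and symbols); matching is exact string equality.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "na", "nan", "null", "none"}


@dataclass
class ExpressionMatrix:
    """A genes x experiments numeric table.

    Rows are genes, columns experiments; values are expression on whatever
    scale the source uses (unitless).  Missing values are stored as NaN and
    must be removed (``drop_missing_genes``) before correlation analysis.
    """

    gene_ids: list[str]
    experiment_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.experiment_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.experiment_ids)} experiments"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene ID: {dup!r}")
        dup = _first_duplicate(self.experiment_ids)
        if dup is not None:
            raise ValueError(f"duplicate experiment ID: {dup!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def submatrix(self, genes: Sequence[str]) -> np.ndarray:
        """Rows for ``genes`` in the given order (genes x experiments)."""
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return self.values[[idx[g] for g in genes], :]

    def drop_missing_genes(self) -> "ExpressionMatrix":
        """Remove every gene with at least one missing value (logged)."""
        keep = ~np.isnan(self.values).any(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d genes with missing values", n_drop)
        return ExpressionMatrix(
            [g for g, k in zip(self.gene_ids, keep) if k],
            list(self.experiment_ids),
            self.values[keep, :],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.experiment_ids)


@dataclass
class PathwayCollection:
    """Ordered named gene sets (KEGG-style pathways)."""

    entries: list[tuple[str, str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        dup = _first_duplicate([pid for pid, _, _ in self.entries])
        if dup is not None:
            raise ValueError(f"duplicate pathway ID: {dup!r}")
        for pid, _, members in self.entries:
            if not members:
                raise ValueError(f"pathway {pid!r} has no members")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def pathway_ids(self) -> list[str]:
        return [pid for pid, _, _ in self.entries]

    def members(self, pathway_id: str) -> list[str]:
        for pid, _, genes in self.entries:
            if pid == pathway_id:
                return list(genes)
        raise KeyError(pathway_id)

    def all_genes(self) -> list[str]:
        """Union of member genes, in first-appearance order."""
        seen: dict[str, None] = {}
        for _, _, genes in self.entries:
            for g in genes:
                seen.setdefault(g)
        return list(seen)


@dataclass
class GeneList:
    """An ordered, unique, non-empty list of gene identifiers."""

    gene_ids: list[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("gene list is empty")
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicate gene ID: {dup!r}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# readers


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression table.

    First row: a label cell then experiment IDs.  Each following row:
    gene ID then one numeric value per experiment.  Empty or NA cells become
    NaN (missing); genes carrying missing values are dropped later, at
    analysis time, not here.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        experiment_ids = [c.strip() for c in header[1:]]
        if not experiment_ids:
            raise ValueError(f"{path}: header has no experiment IDs")
        n_cols = len(experiment_ids)
        gene_ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != n_cols + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_cols + 1} fields, got {len(row)}"
                )
            gene = row[0].strip()
            if gene in seen:
                raise ValueError(f"{path}: duplicate gene ID {gene!r} (line {lineno})")
            seen.add(gene)
            vals = []
            for j, cell in enumerate(row[1:]):
                text = cell.strip()
                if text.lower() in _MISSING_TOKENS:
                    vals.append(math.nan)
                    continue
                try:
                    vals.append(float(text))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {text!r} at line {lineno}, "
                        f"column {experiment_ids[j]!r}"
                    ) from None
            gene_ids.append(gene)
            rows.append(vals)
        values = np.array(rows, dtype=float) if rows else np.empty((0, n_cols))
    return ExpressionMatrix(gene_ids, experiment_ids, values)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write the TSV form ``read_expression_matrix`` reads (17 sig. digits)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("gene_id\t" + "\t".join(expr.experiment_ids) + "\n")
        for gene, row in zip(expr.gene_ids, expr.values):
            cells = ["" if math.isnan(v) else format(v, ".17g") for v in row]
            fh.write(gene + "\t" + "\t".join(cells) + "\n")


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read gene sets in GMT format, preserving file order.

    Duplicate genes within one set are collapsed with a logged warning;
    a duplicate set name or a line with fewer than three fields is an error.
    """
    path = Path(path)
    entries: list[tuple[str, str, list[str]]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs name, description and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            name, desc = fields[0].strip(), fields[1].strip()
            genes: list[str] = []
            seen: set[str] = set()
            for g in (f.strip() for f in fields[2:]):
                if not g:
                    continue
                if g in seen:
                    logger.warning(
                        "%s: line %d: duplicate gene %r in set %r collapsed",
                        path, lineno, g, name,
                    )
                    continue
                seen.add(g)
                genes.append(g)
            entries.append((name, desc, genes))
    return PathwayCollection(entries)


def write_gmt(pathways: PathwayCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for pid, desc, genes in pathways:
            fh.write("\t".join([pid, desc, *genes]) + "\n")


def read_gene_list(path: str | Path) -> GeneList:
    """Read one gene ID per line; '#' comments and blank lines are ignored.

    Repeated IDs are collapsed with a warning; zero IDs is an error.
    """
    path = Path(path)
    ids: list[str] = []
    seen: set[str] = set()
    with path.open() as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            if token in seen:
                logger.warning("%s: duplicate gene %r ignored", path, token)
                continue
            seen.add(token)
            ids.append(token)
    if not ids:
        raise ValueError(f"{path}: no gene IDs found")
    return GeneList(ids)


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    Path(path).write_text("".join(g + "\n" for g in genes))


# ---------------------------------------------------------------------------
# report writers

SCREEN_COLUMNS = [
    "pathway", "n_genes", "r", "p_value", "q_value",
    "S_a", "S_b", "representative_genes", "passed",
]


def _fmt_real(x: float) -> str:
    return "nan" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.4f}"


def _fmt_p(x: float) -> str:
    return "nan" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.4e}"


def write_screen_table(records, path: str | Path) -> None:
    """Write screen records as TSV (reals to 4 decimals, p/q scientific)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("\t".join(SCREEN_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join([
                    rec.pathway_id,
                    str(rec.n_genes_used),
                    _fmt_real(rec.r),
                    _fmt_p(rec.p_value),
                    _fmt_p(rec.q_value),
                    _fmt_real(rec.S_a),
                    _fmt_real(rec.S_b),
                    ",".join(rec.representative_genes),
                    str(bool(rec.passed)),
                ]) + "\n"
            )


def read_screen_table(path: str | Path) -> pd.DataFrame:
    """Parse a screen TSV back into a DataFrame (round-trip convenience)."""
    return pd.read_csv(path, sep="\t", dtype={"pathway": str, "representative_genes": str})


def write_edge_list(network, path: str | Path) -> None:
    """Edge TSV: source, target, r, source_class, target_class.

    Rows sorted lexicographically by source then target so identical
    networks serialize byte-identically.
    """
    path = Path(path)
    rows = sorted(network.iter_edges(), key=lambda e: (e[0], e[1]))
    with path.open("w", newline="") as fh:
        fh.write("source\ttarget\tr\tsource_class\ttarget_class\n")
        for src, tgt, r, src_cls, tgt_cls in rows:
            fh.write(f"{src}\t{tgt}\t{format(r, '.17g')}\t{src_cls}\t{tgt_cls}\n")


def write_enrichment_table(rows, path: str | Path) -> None:
    """Enrichment TSV: term, count, pop, p_value, q_value, genes."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("term\tcount\tpop\tp_value\tq_value\tgenes\n")
        for row in rows:
            fh.write(
                f"{row.pathway_id}\t{row.hit_count}\t{row.pathway_size}\t"
                f"{_fmt_p(row.p_value)}\t{_fmt_p(row.q_value)}\t{','.join(row.hit_genes)}\n"
            )
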