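"""Reading, validation and alignment of expression, IER and covariate tables.

Three on-disk formats are supported:

* expression — TSV with a gene-id first column and one column per sample, or
  GCT 1.2 (``#1.2`` header line, dimensions line, ``Name``/``Description``
  columns);
* intron excision ratios — LeafCutter-style TSV whose first column holds
  ``chrom:start:end:cluster`` intron identifiers and whose cells are either
  ratios in [0, 1] or ``count/total`` fractions (``0/0`` meaning missing),
  plus a two-column intron-to-gene map;
* covariates — TSV with samples as rows; an intercept column is added on
  load and rank-deficient covariates are pruned with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLUSTER_SUM_TOL = 1e-6
MIN_SHARED_SAMPLES = 10


class TableValidationError(ValueError):
    """A table violates a structural invariant (duplicates, range, rank)."""


class TableParseError(ValueError):
    """A file could not be parsed into the expected layout."""


class NoEligibleGenesError(ValueError):
    """Gene selection produced an empty set."""


@dataclass
class ExpressionTable:
    """Gene x sample matrix of (normalized) total-expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise TableValidationError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dups = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise TableValidationError(f"duplicated gene id(s): {dups[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableValidationError("duplicated sample id(s)")
        if not np.all(np.isfinite(self.values)):
            raise TableValidationError("non-finite expression values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class IERTable:
    """Intron x sample excision ratios with an intron-to-gene map.

    Missing values (e.g. LeafCutter ``0/0`` clusters) are NaN until
    :func:`center_and_align` imputes them.
    """

    intron_ids: list[str]
    gene_map: dict[str, str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0) | (self.values > 1)
        if np.any(bad & np.isfinite(self.values)):
            raise TableValidationError("IER values outside [0, 1]")
        missing = [i for i in self.intron_ids if i not in self.gene_map]
        if missing:
            raise TableValidationError(
                f"{len(missing)} intron(s) missing from gene map")

    @property
    def clusters(self) -> list[str]:
        return [parse_intron_id(i)[3] for i in self.intron_ids]

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in self.intron_ids:
            seen.setdefault(self.gene_map[i], None)
        return list(seen)

    def gene_block(self, gene_id: str) -> np.ndarray:
        """Intron x sample block of all introns mapped to ``gene_id``."""
        idx = [j for j, i in enumerate(self.intron_ids)
               if self.gene_map[i] == gene_id]
        if not idx:
            raise KeyError(f"no introns mapped to gene {gene_id!r}")
        return self.values[idx]

    def intron_count(self, gene_id: str) -> int:
        return sum(1 for i in self.intron_ids if self.gene_map[i] == gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.intron_ids,
                            columns=self.sample_ids)


@dataclass
class CovariateTable:
    """Sample x covariate matrix; first column is always the intercept."""

    sample_ids: list[str]
    covariate_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise TableValidationError("non-finite covariate values")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise TableValidationError("covariate matrix is rank deficient")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.covariate_names)


def parse_intron_id(intron_id: str) -> tuple[str, int, int, str]:
    """Split ``chrom:start:end:cluster`` into its components."""
    parts = intron_id.split(":")
    if len(parts) != 4:
        raise TableParseError(
            f"intron id {intron_id!r} is not chrom:start:end:cluster")
    chrom, start, end, cluster = parts
    try:
        return chrom, int(start), int(end), cluster
    except ValueError as exc:
        raise TableParseError(f"non-integer coordinates in {intron_id!r}") from exc


def load_expression(path, dialect: str = "tsv") -> ExpressionTable:
    """Read a gene x sample expression table (``tsv`` or ``gct`` dialect)."""
    if dialect not in ("tsv", "gct"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise TableParseError(
                f"{path}: line 1: expected GCT version header '#1.2', "
                f"got {version!r}")
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if df.columns[0].lower() == "description":
            df = df.drop(columns=df.columns[0])
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise TableParseError(f"{path}: line 1: no sample columns found")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise TableParseError(f"{path}: non-numeric expression value: {exc}") from exc
    return ExpressionTable(gene_ids=[str(g) for g in df.index],
                           sample_ids=[str(s) for s in df.columns],
                           values=values)


def _parse_ratio(cell, path, line_no: int) -> float:
    """A cell is a float ratio or a ``count/total`` fraction; 0/0 -> NaN."""
    if isinstance(cell, float):
        return cell
    text = str(cell).strip()
    if text in ("", "NA", "nan"):
        return math.nan
    if "/" in text:
        num_s, den_s = text.split("/", 1)
        try:
            num, den = float(num_s), float(den_s)
        except ValueError as exc:
            raise TableParseError(
                f"{path}: line {line_no}: bad fraction {text!r}") from exc
        if den == 0:
            return math.nan
        return num / den
    try:
        return float(text)
    except ValueError as exc:
        raise TableParseError(
            f"{path}: line {line_no}: bad ratio {text!r}") from exc


def load_gene_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TableParseError(f"{path}: gene map needs 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_ier(path, gene_map_path) -> IERTable:
    """Read a LeafCutter-style IER table and its intron-to-gene map.

    Introns absent from the gene map are dropped with a warning; completed
    clusters whose per-sample ratios do not sum to 1 within ``1e-6`` are
    rejected rather than renormalized (they indicate an upstream
    quantification problem).
    """
    gene_map = load_gene_map(gene_map_path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    intron_ids = [str(i) for i in df.index]
    values = np.empty(df.shape, dtype=float)
    for r, (_, row) in enumerate(df.iterrows()):
        for c, cell in enumerate(row):
            values[r, c] = _parse_ratio(cell, path, r + 2)

    with np.errstate(invalid="ignore"):
        bad = ((values < 0) | (values > 1)) & np.isfinite(values)
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise TableValidationError(
            f"{path}: ratio {values[r, c]} outside [0, 1] for intron "
            f"{intron_ids[r]}")

    keep = [j for j, i in enumerate(intron_ids) if i in gene_map]
    n_dropped = len(intron_ids) - len(keep)
    if n_dropped:
        logger.warning("%s: dropped %d intron(s) absent from gene map",
                       path, n_dropped)
    intron_ids = [intron_ids[j] for j in keep]
    values = values[keep]

    table = IERTable(intron_ids=intron_ids,
                     gene_map={i: gene_map[i] for i in intron_ids},
                     sample_ids=[str(s) for s in df.columns],
                     values=values)
    _check_cluster_sums(table, path)
    return table


def _check_cluster_sums(table: IERTable, origin) -> None:
    clusters = np.asarray(table.clusters)
    for clu in dict.fromkeys(table.clusters):
        block = table.values[clusters == clu]
        complete = np.all(np.isfinite(block), axis=0)
        if not np.any(complete):
            continue
        sums = block[:, complete].sum(axis=0)
        off = np.abs(sums - 1.0) > CLUSTER_SUM_TOL
        if np.any(off):
            raise TableValidationError(
                f"{origin}: cluster {clu!r}: complete per-sample ratio sums "
                f"deviate from 1 by up to {np.abs(sums - 1).max():.3g}")


def select_genes(expr: ExpressionTable, ier: IERTable,
                 min_introns: int = 2) -> list[str]:
    """Genes present in the expression table with >= ``min_introns`` introns.

    Intron count is the working surrogate for the number of isoforms: a gene
    needs at least two quantified introns for its splicing composition to
    vary, mirroring the restriction of the analysis to multi-isoform genes.
    """
    mapped = set(ier.gene_map.values())
    genes = [g for g in expr.gene_ids
             if g in mapped and ier.intron_count(g) >= min_introns]
    if not genes:
        raise NoEligibleGenesError(
            f"no eligible genes with >= {min_introns} introns")
    return genes


def center_and_align(expr: ExpressionTable, ier: IERTable,
                     cov: CovariateTable
                     ) -> tuple[ExpressionTable, IERTable, CovariateTable]:
    """Restrict all tables to shared samples, in one canonical order.

    Expression rows are mean-centered; missing IERs are imputed by the
    intron's mean over observed samples (neutral after the kernel's
    standardization step).  The canonical order is the sorted sample-id
    intersection, so the output is invariant to input column order.
    """
    shared = sorted(set(expr.sample_ids) & set(ier.sample_ids)
                    & set(cov.sample_ids))
    if len(shared) < MIN_SHARED_SAMPLES:
        raise TableValidationError(
            f"only {len(shared)} shared sample(s); "
            f"need >= {MIN_SHARED_SAMPLES}")

    e_idx = [expr.sample_ids.index(s) for s in shared]
    e_vals = expr.values[:, e_idx]
    e_vals = e_vals - e_vals.mean(axis=1, keepdims=True)
    expr_out = ExpressionTable(expr.gene_ids, shared, e_vals)

    i_idx = [ier.sample_ids.index(s) for s in shared]
    i_vals = ier.values[:, i_idx].copy()
    n_imputed = 0
    for r in range(i_vals.shape[0]):
        row = i_vals[r]
        miss = ~np.isfinite(row)
        if np.any(miss):
            if np.all(miss):
                raise TableValidationError(
                    f"intron {ier.intron_ids[r]} has no observed values "
                    "among shared samples")
            row[miss] = row[~miss].mean()
            n_imputed += int(miss.sum())
    if n_imputed:
        logger.info("imputed %d missing IER value(s) by intron means",
                    n_imputed)
    ier_out = IERTable(ier.intron_ids, dict(ier.gene_map), shared, i_vals)

    c_idx = [cov.sample_ids.index(s) for s in shared]
    cov_out = CovariateTable(shared, list(cov.covariate_names),
                             cov.values[c_idx])
    return expr_out, ier_out, cov_out


def load_covariates(path) -> CovariateTable:
    """Read a sample x covariate TSV, add an intercept, prune to full rank."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    names = ["intercept"] + [str(c) for c in df.columns]
    values = np.column_stack([np.ones(len(df)), values])

    # greedy QR-based pruning of linearly dependent columns
    kept: list[int] = []
    for j in range(values.shape[1]):
        cand = values[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            logger.warning("%s: pruning rank-deficient covariate %r",
                           path, names[j])
    return CovariateTable(sample_ids=[str(s) for s in df.index],
                          covariate_names=[names[j] for j in kept],
                          values=values[:, kept])


def write_expression(table: ExpressionTable, path) -> None:
    table.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


def write_ier(table: IERTable, path, gene_map_path=None) -> None:
    table.to_frame().rename_axis("intron_id").to_csv(path, sep="\t")
    if gene_map_path is not None:
        pd.DataFrame({"intron_id": list(table.gene_map),
                      "gene_id": list(table.gene_map.values())}
                     ).to_csv(gene_map_path, sep="\t", index=False)


def write_covariates(table: CovariateTable, path) -> None:
    # the intercept is re-added on load
    df = table.to_frame().rename_axis("sample_id")
    if "intercept" in df.columns:
        df = df.drop(columns="intercept")
    df.to_csv(path, sep="\t")
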