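"""Genome-scan bookkeeping: pair enumeration and multiple-testing control.

A scan over g analysis-ready genes tests every ordered (predictor,
response) pair — g(g-1) directed tests per p-value family.  Results are
kept in a "pair table": a DataFrame with one row per directed pair and one
column per test.  On top of it sit the standard corrections: Bonferroni,
Benjamini-Hochberg, BH stratified by response gene (each response gene's
predictors form one stratum, matching the many-predictors-per-response
scan geometry), and Storey's estimate of the null proportion pi0.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: fixed serialization column order for pair tables
PAIR_TABLE_COLUMNS = [
    "predictor_gene", "response_gene",
    "p_interaction", "p_joint", "p_correlation",
    "rho_hat", "rho_star", "flags",
]

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


def count_pairs(n_genes: int) -> int:
    """Number of ordered gene pairs, n(n-1)."""
    if n_genes < 2:
        raise ValueError(f"need at least 2 genes, got {n_genes}")
    return n_genes * (n_genes - 1)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise p-value cutoff alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level q.

    Returns ``(reject, p_adjusted)`` aligned with the input; missing
    p-values are never rejected and get NaN adjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    reject = np.zeros(p.shape, dtype=bool)
    p_adj = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return reject, p_adj
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values outside [0, 1]")
    rej, adj, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
    reject[ok] = rej
    p_adj[ok] = adj
    return reject, p_adj


def stratified_fdr(table: pd.DataFrame, q: float = 0.05,
                   stratum_key: str = "response_gene",
                   p_col: str = "p_interaction") -> pd.Series:
    """BH at level q independently within each stratum of the pair table.

    The default stratifies by response gene, so each response gene's set of
    candidate predictors is corrected on its own.
    """
    if p_col not in table.columns:
        raise KeyError(f"no column {p_col!r} in pair table")
    if stratum_key not in table.columns:
        raise KeyError(f"no stratum column {stratum_key!r} in pair table")
    reject = pd.Series(False, index=table.index)
    for _, idx in table.groupby(stratum_key, sort=False).groups.items():
        rej, _ = bh_fdr(table.loc[idx, p_col].to_numpy(), q=q)
        reject.loc[idx] = rej
    return reject


def storey_pi0(p_values, lambda_grid=DEFAULT_LAMBDA_GRID) -> float:
    """Storey's null-proportion estimate, averaged over the lambda grid.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` estimates the null
    proportion from the right of the p-value histogram, where alternatives
    are rare; the lambda-average variant is used for determinism, clipped
    to [0, 1].  ``1 - pi0`` is the estimated non-null proportion.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if p.size < 100:
        warnings.warn(f"pi0 estimate from only {p.size} p-values is "
                      "unstable", stacklevel=2)
    lam = np.asarray(lambda_grid, dtype=float)
    est = np.array([(p > lo).mean() / (1.0 - lo) for lo in lam])
    return float(np.clip(est.mean(), 0.0, 1.0))


def make_pair_table(records) -> pd.DataFrame:
    """Build a pair table with the canonical column order from records."""
    df = pd.DataFrame.from_records(records)
    for col in PAIR_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[PAIR_TABLE_COLUMNS + [c for c in df.columns
                                  if c not in PAIR_TABLE_COLUMNS]]
    if (df["predictor_gene"] == df["response_gene"]).any():
        raise ValueError("pair table contains self-pairs")
    return df


def write_pair_table(table: pd.DataFrame, path) -> None:
    """Serialize as TSV (gzip-transparent via the file extension)."""
    table.to_csv(path, sep="\t", index=False)


def read_pair_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PAIR_TABLE_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"pair table at {path} lacks columns {missing}")
    return df
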