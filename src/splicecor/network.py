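"""Directed co-expression networks from per-pair test significance.

An edge predictor -> response is drawn when the chosen test (interaction,
joint, or correlation) is significant for that directed pair at a
stratified FDR level.  A gene's outdegree counts how many other genes it
significantly predicts; genes with outdegree >= 5 are called hubs.
Pathway-level summaries (size-adjusted mean outdegree), multi-tissue
sharing profiles, and a tumor-versus-normal differential-correlation test
round out the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .fdr import stratified_fdr

logger = logging.getLogger(__name__)

TEST_LABELS = ("interaction", "joint", "correlation")


def _p_column(test_label: str) -> str:
    if test_label not in TEST_LABELS:
        raise ValueError(f"unknown test label {test_label!r}; "
                         f"expected one of {TEST_LABELS}")
    return f"p_{test_label}"


def build_network(pair_table: pd.DataFrame, test_label: str = "interaction",
                  q: float = 0.05,
                  stratum_key: str = "response_gene") -> nx.DiGraph:
    """Directed network of pairs significant at a stratified FDR level q.

    Nodes are all genes appearing in the pair table; each edge carries the
    raw p-value and the test label it came from.
    """
    p_col = _p_column(test_label)
    if p_col not in pair_table.columns:
        raise KeyError(f"pair table has no column {p_col!r}")
    g = nx.DiGraph(test_label=test_label, q=q)
    genes = sorted(set(pair_table["predictor_gene"])
                   | set(pair_table["response_gene"]))
    g.add_nodes_from(genes)
    sig = stratified_fdr(pair_table, q=q, stratum_key=stratum_key,
                         p_col=p_col)
    for _, row in pair_table[sig].iterrows():
        if row["predictor_gene"] == row["response_gene"]:
            continue
        g.add_edge(row["predictor_gene"], row["response_gene"],
                   p=float(row[p_col]), test=test_label)
    return g


def detect_hubs(network: nx.DiGraph, min_outdegree: int = 5) -> list[str]:
    """Genes with outdegree >= min_outdegree, by descending outdegree.

    Ties are broken lexicographically for deterministic output.
    """
    deg = dict(network.out_degree())
    hubs = [g for g, d in deg.items() if d >= min_outdegree]
    return sorted(hubs, key=lambda g: (-deg[g], g))


def size_adjusted_outdegree(network: nx.DiGraph, pathway_genes) -> float:
    """Mean outdegree per pathway gene: sum of outdegrees / pathway size."""
    pathway_genes = list(pathway_genes)
    if not pathway_genes:
        raise ValueError("empty pathway")
    deg = dict(network.out_degree())
    return sum(deg.get(g, 0) for g in pathway_genes) / len(pathway_genes)


@dataclass
class TissueSharingProfile:
    """How significance of gene pairs and hub activity spread over tissues."""

    pair_sharing: pd.Series          # (predictor, response) -> tissue count
    outdegree: pd.DataFrame          # gene x tissue outdegrees
    n_tissues: int

    def sharing_histogram(self) -> pd.Series:
        """Count of significant pairs by number of tissues shared."""
        shared = self.pair_sharing[self.pair_sharing > 0]
        return shared.value_counts().sort_index()

    def hub_sharing(self, min_outdegree: int = 5) -> pd.Series:
        """Per gene: number of tissues in which it is a hub."""
        return (self.outdegree >= min_outdegree).sum(axis=1)


def tissue_sharing(per_tissue_tables: dict[str, pd.DataFrame],
                   test_label: str = "interaction",
                   q: float = 0.05,
                   stratum_key: str = "response_gene") -> TissueSharingProfile:
    """Cross-tissue sharing of significant pairs and per-tissue outdegrees.

    All tissue tables must contain the same directed pair keys.
    """
    if len(per_tissue_tables) < 2:
        raise ValueError("need at least 2 tissue tables")
    keysets = {
        t: set(zip(tab["predictor_gene"], tab["response_gene"]))
        for t, tab in per_tissue_tables.items()
    }
    ref_name, ref = next(iter(keysets.items()))
    for t, ks in keysets.items():
        if ks != ref:
            diff = sorted(ks ^ ref)[:10]
            raise ValueError(
                f"pair keys of tissue {t!r} differ from {ref_name!r}; "
                f"e.g. {diff}")

    pairs = sorted(ref)
    sharing = pd.Series(0, index=pd.MultiIndex.from_tuples(
        pairs, names=["predictor_gene", "response_gene"]))
    genes = sorted({g for pr in pairs for g in pr})
    outdeg = pd.DataFrame(0, index=genes,
                          columns=sorted(per_tissue_tables))
    for tissue, tab in per_tissue_tables.items():
        net = build_network(tab, test_label=test_label, q=q,
                            stratum_key=stratum_key)
        for a, b in net.edges():
            sharing.loc[(a, b)] += 1
        for g, d in net.out_degree():
            outdeg.loc[g, tissue] = d
    return TissueSharingProfile(pair_sharing=sharing, outdegree=outdeg,
                                n_tissues=len(per_tissue_tables))


@dataclass
class DifferentialCorrelationResult:
    p_value: float
    coef: float        # difference in x-slope between the two groups
    stat: float
    method: str


def differential_correlation(y, x, Z, group_labels,
                             method: str = "interaction"
                             ) -> DifferentialCorrelationResult:
    """Test whether the x -> y slope differs between two sample groups.

    Default is a Wald test of the ``x * group`` coefficient in the stacked
    linear model ``y ~ x + group + x:group + Z`` — covariate adjustment is
    applied exactly as in the per-group correlation analyses.  A Fisher-z
    contrast of the per-group partial correlations is available as
    ``method="fisher_z"``.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    g = np.asarray(group_labels)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {levels.size}")
    ind = (g == levels[1]).astype(float)
    for lev in levels:
        mask = g == lev
        if mask.sum() < 10:
            raise ValueError(f"group {lev!r} has fewer than 10 samples")
        if np.std(x[mask]) == 0:
            raise ValueError(f"group {lev!r} has zero variance in x")

    if method == "fisher_z":
        zs, ns = [], []
        for lev in levels:
            m = g == lev
            q_, _ = np.linalg.qr(Z[m])
            rx = x[m] - q_ @ (q_.T @ x[m])
            ry = y[m] - q_ @ (q_.T @ y[m])
            r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
            zs.append(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)))
            ns.append(m.sum() - Z.shape[1])
        stat = (zs[1] - zs[0]) / np.sqrt(1.0 / (ns[0] - 1) + 1.0 / (ns[1] - 1))
        return DifferentialCorrelationResult(
            p_value=float(2 * norm.sf(abs(stat))), coef=float(zs[1] - zs[0]),
            stat=float(stat), method="fisher_z")

    if method != "interaction":
        raise ValueError(f"unknown method {method!r}")
    M = np.column_stack([x * ind, x, ind, Z])
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    r = y - M @ coef
    dof = y.size - M.shape[1]
    sigma2 = float(r @ r) / dof
    gram_inv = np.linalg.inv(M.T @ M)
    se = np.sqrt(sigma2 * gram_inv[0, 0])
    stat = float(coef[0]) / se if se > 0 else 0.0
    return DifferentialCorrelationResult(
        p_value=float(2 * norm.sf(abs(stat))), coef=float(coef[0]),
        stat=stat, method="interaction")


def write_edge_list(network: nx.DiGraph, path) -> None:
    """Edge-list TSV: predictor, response, test label, p, q threshold."""
    rows = [
        {"predictor_gene": a, "response_gene": b,
         "test_label": d.get("test", network.graph.get("test_label", "")),
         "p": d.get("p", np.nan), "q_threshold": network.graph.get("q", np.nan)}
        for a, b, d in network.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["predictor_gene", "response_gene",
                                "test_label", "p", "q_threshold"]
                 ).to_csv(path, sep="\t", index=False)


def write_graphml(network: nx.DiGraph, path) -> None:
    nx.write_graphml(network, path)


def read_gmt(path) -> dict[str, list[str]]:
    """Read pathway gene sets in GMT format (name, description, genes...)."""
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = parts[2:]
    return pathways
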