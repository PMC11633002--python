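import networkx as nx
import numpy as np
import pandas as pd
import pytest

from splicecor.fdr import make_pair_table
from splicecor.network import (build_network, detect_hubs,
                               differential_correlation, read_gmt,
                               size_adjusted_outdegree, tissue_sharing,
                               write_edge_list, write_graphml)


def pair_table(rows):
    return make_pair_table([
        dict(predictor_gene=a, response_gene=b, p_interaction=p,
             p_joint=p, p_correlation=p, rho_hat=np.nan, rho_star=np.nan,
             flags="")
        for a, b, p in rows
    ])


@pytest.fixture
def five_gene_table():
    """Known p-value layout: gA drives gB and gC; everything else null."""
    genes = ["gA", "gB", "gC", "gD", "gE"]
    rows = []
    for a in genes:
        for b in genes:
            if a == b:
                continue
            p = 1e-6 if (a, b) in {("gA", "gB"), ("gA", "gC")} else 0.8
            rows.append((a, b, p))
    return pair_table(rows)


class TestBuildNetwork:
    def test_expected_edges_from_fixture(self, five_gene_table):
        net = build_network(five_gene_table, "interaction", q=0.05)
        assert sorted(net.edges()) == [("gA", "gB"), ("gA", "gC")]
        assert net.number_of_nodes() == 5

    def test_no_significant_rows_empty_edges(self):
        tab = pair_table([("gA", "gB", 0.9), ("gB", "gA", 0.7)])
        net = build_network(tab, "interaction", q=0.05)
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 2

    def test_outdegree_sum_equals_edge_count(self, five_gene_table):
        net = build_network(five_gene_table, "interaction", q=0.05)
        assert sum(d for _, d in net.out_degree()) == net.number_of_edges()

    def test_missing_column_rejected(self, five_gene_table):
        with pytest.raises(ValueError):
            build_network(five_gene_table, "wald", q=0.05)

    def test_reproducible_from_serialized_table(self, five_gene_table,
                                                tmp_path):
        from splicecor.fdr import read_pair_table, write_pair_table
        path = tmp_path / "pairs.tsv"
        write_pair_table(five_gene_table, path)
        net1 = build_network(five_gene_table, "interaction", q=0.05)
        net2 = build_network(read_pair_table(path), "interaction", q=0.05)
        assert sorted(net1.edges()) == sorted(net2.edges())


class TestDetectHubs:
    def _star(self, center, n_leaves):
        g = nx.DiGraph()
        for i in range(n_leaves):
            g.add_edge(center, f"leaf{i}")
        return g

    def test_star_center_is_only_hub(self):
        hubs = detect_hubs(self._star("hub", 6))
        assert hubs == ["hub"]

    def test_threshold_boundary_excludes_outdegree_four(self):
        g = nx.DiGraph()
        for c in "abcd":
            for i in range(4):
                g.add_edge(c, f"{c}{i}")
        assert detect_hubs(g) == []

    def test_twelve_target_hub_reported_with_ties_sorted(self):
        g = self._star("gBig", 12)
        for i in range(5):
            g.add_edge("gSmallB", f"t{i}")
            g.add_edge("gSmallA", f"t{i}")
        hubs = detect_hubs(g)
        assert hubs == ["gBig", "gSmallA", "gSmallB"]
        assert g.out_degree("gBig") == 12

    def test_invariant_under_relabeling(self):
        g = self._star("hub", 7)
        mapping = {n: f"x_{n}" for n in g.nodes()}
        hubs = detect_hubs(nx.relabel_nodes(g, mapping))
        assert hubs == ["x_hub"]


class TestSizeAdjustedOutdegree:
    def test_simple_ratio(self):
        g = nx.DiGraph()
        genes = [f"g{i}" for i in range(10)]
        k = 0
        for a in genes:
            for b in genes[:2]:
                if a != b and k < 20:
                    g.add_edge(a, b)
                    k += 1
        # top the count up to exactly 20 edges inside the pathway
        extra = [("g0", "g5"), ("g1", "g5"), ("g2", "g5")]
        for a, b in extra:
            if g.number_of_edges() < 20:
                g.add_edge(a, b)
        assert g.number_of_edges() == 20
        assert size_adjusted_outdegree(g, genes) == pytest.approx(2.0)

    def test_empty_edge_set_zero(self):
        g = nx.DiGraph()
        g.add_nodes_from(["a", "b"])
        assert size_adjusted_outdegree(g, ["a", "b"]) == 0.0

    def test_equal_density_pathways_equal_adjusted_mean(self):
        g = nx.DiGraph()
        small = [f"s{i}" for i in range(4)]
        large = [f"l{i}" for i in range(8)]
        for nodes in (small, large):   # each gene hits its next neighbour
            for i, a in enumerate(nodes):
                g.add_edge(a, nodes[(i + 1) % len(nodes)])
        assert size_adjusted_outdegree(g, small) == \
            size_adjusted_outdegree(g, large) == pytest.approx(1.0)

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            size_adjusted_outdegree(nx.DiGraph(), [])


class TestTissueSharing:
    def _tables(self, sig_by_tissue):
        genes = ["gA", "gB", "gC"]
        tables = {}
        for tissue, sig in sig_by_tissue.items():
            rows = [(a, b, 1e-6 if (a, b) in sig else 0.9)
                    for a in genes for b in genes if a != b]
            tables[tissue] = pair_table(rows)
        return tables

    def test_single_tissue_significance_counts_one(self):
        tables = self._tables({
            "t1": {("gA", "gB")}, "t2": set(), "t3": set()})
        prof = tissue_sharing(tables)
        assert prof.pair_sharing.loc[("gA", "gB")] == 1
        assert prof.sharing_histogram().to_dict() == {1: 1}

    def test_identical_tissues_share_everything(self):
        sig = {("gA", "gB"), ("gC", "gA")}
        tables = self._tables({"t1": sig, "t2": sig, "t3": sig})
        prof = tissue_sharing(tables)
        shared = prof.pair_sharing[prof.pair_sharing > 0]
        assert (shared == 3).all()

    def test_outdegree_matrix(self):
        tables = self._tables({
            "t1": {("gA", "gB"), ("gA", "gC")}, "t2": {("gA", "gB")}})
        prof = tissue_sharing(tables)
        assert prof.outdegree.loc["gA", "t1"] == 2
        assert prof.outdegree.loc["gA", "t2"] == 1
        assert prof.outdegree.loc["gB"].sum() == 0

    def test_key_mismatch_rejected(self):
        tables = self._tables({"t1": set(), "t2": set()})
        tables["t2"] = tables["t2"].iloc[:-1]
        with pytest.raises(ValueError, match="pair keys"):
            tissue_sharing(tables)


class TestDifferentialCorrelation:
    def _groups(self, rng, n_per=60, slope0=1.0, slope1=1.0, sigma=0.5):
        x = rng.standard_normal(2 * n_per)
        g = np.repeat([0, 1], n_per)
        Z = np.column_stack([np.ones(2 * n_per),
                             rng.standard_normal(2 * n_per)])
        slopes = np.where(g == 0, slope0, slope1)
        y = slopes * x + Z @ np.array([0.2, 0.4]) \
            + sigma * rng.standard_normal(2 * n_per)
        return y, x, Z, g

    def test_null_calibration(self):
        rng = np.random.default_rng(21)
        hits = 0
        reps = 1000
        for _ in range(reps):
            y, x, Z, g = self._groups(rng, n_per=40)
            if differential_correlation(y, x, Z, g).p_value < 0.05:
                hits += 1
        assert 0.03 <= hits / reps <= 0.07

    def test_power_for_opposite_slopes(self):
        rng = np.random.default_rng(22)
        hits = 0
        for _ in range(50):
            y, x, Z, g = self._groups(rng, n_per=100, slope0=1.0,
                                      slope1=-1.0, sigma=0.5)
            if differential_correlation(y, x, Z, g).p_value < 1e-6:
                hits += 1
        assert hits >= 48

    def test_identical_groups_zero_interaction(self):
        rng = np.random.default_rng(23)
        n = 50
        x0 = rng.standard_normal(n)
        y0 = 0.8 * x0 + rng.standard_normal(n)
        Z0 = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = np.concatenate([y0, y0])
        x = np.concatenate([x0, x0])
        Z = np.vstack([Z0, Z0])
        g = np.repeat([0, 1], n)
        res = differential_correlation(y, x, Z, g)
        assert res.coef == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_group_rejected(self):
        rng = np.random.default_rng(24)
        y, x, Z, g = self._groups(rng, n_per=20)
        x[g == 1] = 0.0
        with pytest.raises(ValueError, match="zero variance"):
            differential_correlation(y, x, Z, g)

    def test_fisher_z_agrees_qualitatively(self):
        rng = np.random.default_rng(25)
        y, x, Z, g = self._groups(rng, n_per=100, slope0=1.0, slope1=-1.0)
        p_int = differential_correlation(y, x, Z, g).p_value
        p_fz = differential_correlation(y, x, Z, g,
                                        method="fisher_z").p_value
        assert p_int < 1e-6 and p_fz < 1e-6


def test_serialization_roundtrips(tmp_path, five_gene_table=None):
    tab = pair_table([("gA", "gB", 1e-6), ("gB", "gA", 0.9)])
    net = build_network(tab, "interaction", q=0.05)
    write_edge_list(net, tmp_path / "edges.tsv")
    edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
    assert edges.loc[0, "predictor_gene"] == "gA"
    write_graphml(net, tmp_path / "net.graphml")
    back = nx.read_graphml(tmp_path / "net.graphml")
    assert sorted(back.edges()) == sorted(net.edges())
    gmt = tmp_path / "p.gmt"
    gmt.write_text("pathA\tdesc\tgA\tgB\npathB\tdesc\tgC\n")
    assert read_gmt(gmt) == {"pathA": ["gA", "gB"], "pathB": ["gC"]}


class TestMultiTissueSharingContrast:
    def test_interaction_sharing_smaller_than_correlation_sharing(self):
        """Tissue-specific splicing modulation vs stable co-expression:
        significant interaction pairs concentrate in single tissues while
        significant correlation pairs are shared across tissues."""
        import splicecor as sc
        cfg = sc.SimulationConfig(n_samples=200, seed=55, sigma_Int2=0.9,
                                  beta1=0.8)
        cohorts = sc.simulate_multitissue(cfg, n_tissues=3,
                                          tissue_specific_fraction=0.7,
                                          n_genes=10, signal_fraction=0.12)
        tables = {}
        for tissue, cohort in cohorts.items():
            expr = sc.ExpressionTable(list(cohort.expression.index),
                                      list(cohort.expression.columns),
                                      cohort.expression.to_numpy())
            ier = sc.IERTable(list(cohort.ier.index),
                              dict(zip(cohort.gene_map.intron_id,
                                       cohort.gene_map.gene_id)),
                              list(cohort.ier.columns),
                              cohort.ier.to_numpy())
            cov = sc.CovariateTable(
                list(cohort.covariates.index),
                ["intercept"] + list(cohort.covariates.columns),
                np.column_stack([np.ones(len(cohort.covariates)),
                                 cohort.covariates.to_numpy()]))
            expr, ier, cov = sc.center_and_align(expr, ier, cov)
            tables[tissue] = sc.scan_pairs(
                expr, ier, cov, tests=("interaction", "correlation"),
                compute_rho=False)
        prof_int = tissue_sharing(tables, test_label="interaction", q=0.05)
        prof_corr = tissue_sharing(tables, test_label="correlation", q=0.05)
        share_int = prof_int.pair_sharing[prof_int.pair_sharing > 0]
        share_corr = prof_corr.pair_sharing[prof_corr.pair_sharing > 0]
        assert len(share_int) > 0 and len(share_corr) > 0
        assert share_int.mean() < share_corr.mean()
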