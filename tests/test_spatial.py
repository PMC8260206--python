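"""Ductal distances, classical MDS, gradients, territories."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import glandphylo as gp
from glandphylo.ductal import DuctalGraph
from glandphylo.spatial import multiclonality_vs_distance


def chain_graph(lengths):
    nodes = [{"id": "n0", "kind": "urethral_origin", "position": (0, 0, 0)}]
    edges = []
    x = 0.0
    for i, L in enumerate(lengths, start=1):
        x += L
        kind = "acinus" if i == len(lengths) else "duct"
        nodes.append({"id": f"n{i}", "kind": kind, "position": (x, 0, 0)})
        edges.append({"parent": f"n{i-1}", "child": f"n{i}", "length": L})
    return DuctalGraph.from_records(nodes, edges)


class TestPathDistance:
    def test_root_distance_zero(self):
        g = chain_graph([100.0, 250.0])
        assert gp.path_distance(g, g.root) == 0.0

    def test_chain_sums_edges(self):
        g = chain_graph([100.0, 250.0])
        assert gp.path_distance(g, "n2") == 350.0

    def test_unknown_node_errors(self):
        with pytest.raises(KeyError):
            gp.path_distance(chain_graph([100.0]), "nope")

    def test_matches_dijkstra_on_random_trees(self):
        for seed in range(5):
            g = gp.generate_ductal_tree(gp.SimulationConfig(seed=seed))
            und = g.undirected()
            oracle = nx.single_source_dijkstra_path_length(
                und, g.root, weight="length"
            )
            for node in g.nodes:
                assert gp.path_distance(g, node) == pytest.approx(oracle[node])

    def test_monotone_along_root_to_leaf(self):
        g = gp.generate_ductal_tree(gp.SimulationConfig(seed=3))
        dists = gp.all_path_distances(g)
        for node in g.nodes:
            p = g.parent(node)
            if p is not None:
                assert dists[node] > dists[p]


class TestMDS:
    def test_planar_points_embedded_exactly(self, rng):
        pts = np.column_stack(
            [rng.normal(size=20), rng.normal(size=20), np.zeros(20)]
        )
        emb, eigval = gp.mds_2d(pts)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(emb), pdist(pts), atol=1e-9)

    def test_collinear_points_fit_one_axis(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3.5, 3.5, 3.5]])
        emb, _ = gp.mds_2d(pts)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(emb), pdist(pts), atol=1e-9)
        assert np.allclose(emb[:, 1], 0, atol=1e-6)

    def test_matches_direct_eigensolver(self, rng):
        pts = rng.normal(size=(15, 3))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
        emb, eigval = gp.mds_2d(D)
        # independent spectral oracle
        n = len(D)
        J = np.eye(n) - 1 / n
        B = -0.5 * J @ D**2 @ J
        w, v = np.linalg.eigh(B)
        idx = np.argsort(w)[::-1][:2]
        oracle = v[:, idx] * np.sqrt(w[idx])
        for k in range(2):
            col = oracle[:, k]
            if col[np.argmax(np.abs(col))] < 0:
                oracle[:, k] = -col
        np.testing.assert_allclose(emb, oracle, atol=1e-8)

    def test_eigenvalues_sorted_descending(self, rng):
        emb, eigval = gp.mds_2d(rng.normal(size=(10, 3)))
        assert (np.diff(eigval) <= 1e-9).all()

    def test_truncation_never_stretches_distances(self, rng):
        from scipy.spatial.distance import pdist

        pts = rng.normal(size=(12, 3))
        emb, _ = gp.mds_2d(pts)
        assert (pdist(emb) <= pdist(pts) + 1e-8).all()

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            gp.mds_2d(np.zeros((2, 3)))

    def test_non_euclidean_input_warns(self):
        # perfect matching of huge distances among otherwise-close
        # points grossly violates the triangle inequality
        n = 8
        D = np.full((n, n), 0.1)
        np.fill_diagonal(D, 0)
        for i in range(0, n, 2):
            D[i, i + 1] = D[i + 1, i] = 10.0
        with pytest.warns(UserWarning):
            gp.mds_2d(D)


class TestGradientRegression:
    def test_exact_line_recovered(self, rng):
        x = rng.uniform(0, 3000, size=40)
        fit = gp.gradient_regression(0.06 * x + 700, x)
        assert fit.slope == pytest.approx(0.06)
        assert fit.r_squared == pytest.approx(1.0)

    def test_permuted_response_covers_zero(self, rng):
        x = rng.uniform(0, 3000, size=60)
        y = 0.06 * x + rng.normal(0, 30, size=60)
        fit = gp.gradient_regression(rng.permutation(y), x)
        assert fit.slope_ci[0] <= 0 <= fit.slope_ci[1]

    def test_nominal_coverage_of_true_slope(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 3000, size=30)
            y = 0.06 * x + rng.normal(0, 60, size=30)
            fit = gp.gradient_regression(y, x)
            hits += fit.slope_ci[0] <= 0.06 <= fit.slope_ci[1]
        assert hits >= 33  # ~95% nominal with binomial slack

    def test_zero_x_variance_errors(self):
        with pytest.raises(ValueError):
            gp.gradient_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_outlier_exclusion_refit(self):
        x = np.array([0, 10, 20, 30, 40.0])
        y = 0.06 * x + 100
        y[-1] = 5000.0
        fit = gp.gradient_regression(y, x, exclude_y_above=2000)
        assert fit.n == 4
        assert fit.slope == pytest.approx(0.06)


class TestCloneTerritory:
    @staticmethod
    def _setup():
        g = chain_graph([100.0] * 5)  # n0..n5
        samples = [f"S{i}" for i in range(5)]
        nodes = pd.Series([f"n{i+1}" for i in range(5)], index=samples)
        return g, nodes

    def test_all_zero_is_empty(self):
        g, nodes = self._setup()
        t = gp.clone_territory(g, pd.Series(0.0, index=nodes.index), nodes)
        assert t.positive_samples == [] and t.components == [] and t.span_um == 0

    def test_single_positive_sample(self):
        g, nodes = self._setup()
        cc = pd.Series([0.0, 0.5, 0.0, 0.0, 0.0], index=nodes.index)
        t = gp.clone_territory(g, cc, nodes)
        assert t.positive_samples == ["S1"]
        assert t.n_components == 1 and t.span_um == 0.0

    def test_interrupted_path_splits_components(self):
        """Positives at chain positions 1,2,5 with negatives between
        them form two territory components."""
        g, nodes = self._setup()
        cc = pd.Series([0.5, 0.5, 0.0, 0.0, 0.5], index=nodes.index)
        t = gp.clone_territory(g, cc, nodes)
        assert sorted(map(sorted, t.components)) == [["S0", "S1"], ["S4"]]
        assert t.span_um == pytest.approx(400.0)

    def test_unsampled_nodes_do_not_interrupt(self):
        g = chain_graph([100.0] * 4)
        samples = ["A", "B"]
        nodes = pd.Series(["n1", "n4"], index=samples)
        cc = pd.Series([0.4, 0.4], index=samples)
        t = gp.clone_territory(g, cc, nodes)
        assert t.n_components == 1

    def test_invariant_under_sample_relabelling(self):
        g, nodes = self._setup()
        cc = pd.Series([0.5, 0.0, 0.5, 0.5, 0.0], index=nodes.index)
        t1 = gp.clone_territory(g, cc, nodes)
        ren = {s: f"X{i}" for i, s in enumerate(nodes.index)}
        t2 = gp.clone_territory(
            g, cc.rename(index=ren), nodes.rename(index=ren)
        )
        remapped = sorted(
            sorted(ren[s] for s in comp) for comp in t1.components
        )
        assert remapped == sorted(sorted(c) for c in t2.components)


class TestMulticlonalFraction:
    def test_paper_counts_give_27_percent(self):
        """47 multiclonal out of 177 microdissections is 27%."""
        cc = pd.DataFrame(0.0, index=["e1", "e2"], columns=range(177))
        cc.iloc[0, :] = 0.5
        cc.iloc[1, :47] = 0.2
        res = gp.multiclonal_fraction(cc)
        assert (res.numerator, res.denominator, res.percent) == (47, 177, 27)

    def test_all_monoclonal_zero(self):
        cc = pd.DataFrame([[0.9, 0.8], [0.05, 0.0]], index=["e1", "e2"])
        assert gp.multiclonal_fraction(cc).percent == 0

    def test_matches_bruteforce_on_toy_matrix(self, rng):
        cc = pd.DataFrame(rng.uniform(0, 0.4, size=(3, 4)))
        res = gp.multiclonal_fraction(cc)
        brute = sum(
            sum(cc.iloc[i, j] > 0.10 for i in range(3)) >= 2 for j in range(4)
        )
        assert res.numerator == brute

    def test_no_samples_errors(self):
        with pytest.raises(ValueError):
            gp.multiclonal_fraction(pd.DataFrame(index=["e1"]))

    def test_multiclonality_distance_regression_runs(self, rng):
        out = multiclonality_vs_distance(
            rng.integers(0, 2, size=30), rng.uniform(0, 2000, size=30)
        )
        assert "p_value" in out


class TestAdultCloneSpan:
    def test_driver_expansion_flagged_across_13_microdissections(self):
        """With a driver expansion simulated, exactly one adult clone
        spans >= 13 microdissections and is flagged; without it, adult
        clones stay within 5."""
        cfg = gp.SimulationConfig(
            seed=9, n_terminal_acini=20, n_microdissections=100,
            driver_expansion_flag=True,
        )
        sim = gp.simulate_gland(cfg)
        tr = sim.truth
        nodes = sim.samples.set_index("sample_id")["duct_node"]
        epochs = dict(zip(tr.clone_table["clone_id"], tr.clone_table["epoch"]))
        territories = {
            c: gp.clone_territory(sim.graph, tr.cc.loc[c], nodes, cluster_id=c)
            for c in tr.cc.index
            if epochs.get(c) == "adult"
        }
        spans = gp.adult_clone_span(epochs, territories)
        flagged = spans[spans["flagged_expansion"]]
        driver = sim.genealogy.driver_clone
        assert driver in set(flagged["cluster_id"])
        assert (
            spans.set_index("cluster_id").loc[driver, "n_samples"] >= 13
        )

    def test_default_simulation_adult_clones_spatially_confined(self, small_gland):
        tr = small_gland.truth
        nodes = small_gland.samples.set_index("sample_id")["duct_node"]
        epochs = dict(zip(tr.clone_table["clone_id"], tr.clone_table["epoch"]))
        territories = {
            c: gp.clone_territory(small_gland.graph, tr.cc.loc[c], nodes, cluster_id=c)
            for c in tr.cc.index
            if epochs.get(c) == "adult"
        }
        spans = gp.adult_clone_span(epochs, territories)
        assert not spans["flagged_expansion"].any()

    def test_empty_adult_set(self):
        df = gp.adult_clone_span({}, {})
        assert df.empty

    def test_flags_only_wide_clones(self):
        terr = {
            "small": gp.CloneTerritory("small", ["S1", "S2"], [{"S1", "S2"}], 150.0),
            "wide": gp.CloneTerritory(
                "wide", [f"S{i}" for i in range(13)], [set(f"S{i}" for i in range(13))], 2500.0
            ),
        }
        epochs = {"small": "adult", "wide": "adult", "emb": "embryonic"}
        df = gp.adult_clone_span(epochs, terr).set_index("cluster_id")
        assert not df.loc["small", "flagged_expansion"]
        assert df.loc["wide", "flagged_expansion"]
        assert "emb" not in df.index
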