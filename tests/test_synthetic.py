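"""Generative model: topology, founders, genealogy, mutations, reads."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import glandphylo as gp
from glandphylo.simulate import (
    InvalidConfigError,
    InvalidGenealogyError,
    ZYGOTE,
    sample_branch_mutation_counts,
)


class TestDuctalTree:
    def test_single_acinus_is_a_path(self):
        cfg = gp.SimulationConfig(seed=3, n_terminal_acini=1)
        g = gp.generate_ductal_tree(cfg)
        assert len(g.acini) == 1
        for node in g.nodes:
            assert len(g.children(node)) <= 1
        g.validate()

    def test_same_seed_identical_graphs(self):
        cfg = gp.SimulationConfig(seed=11)
        assert gp.generate_ductal_tree(cfg) == gp.generate_ductal_tree(cfg)

    def test_leaf_count_and_path_lengths_over_seeds(self):
        cfg = gp.SimulationConfig(n_terminal_acini=30)
        depths = []
        for seed in range(25):
            g = gp.generate_ductal_tree(cfg, seed=seed)
            assert len(g.acini) == 30
            dists = gp.all_path_distances(g)
            depths.append(np.mean([dists[a] for a in g.acini]))
        # each root-acinus path has ~log2(30)+trunk segments of mean
        # exp(mu + sigma^2/2) um; generous envelope around that
        seg = np.exp(cfg.segment_length_mu + cfg.segment_length_sigma**2 / 2)
        assert 4 * seg < np.mean(depths) < 25 * seg

    def test_invalid_acinus_count(self):
        with pytest.raises(InvalidConfigError):
            gp.generate_ductal_tree(gp.SimulationConfig(n_terminal_acini=0))


class TestFounders:
    @pytest.fixture()
    def graph(self):
        return gp.generate_ductal_tree(gp.SimulationConfig(seed=5))

    def test_single_founder_owns_everything(self, graph):
        fa = gp.seed_embryonic_founders(graph, 1, seed=0)
        for node in graph.nodes:
            assert fa.shares[node] == [("F0", 1.0)]

    def test_every_node_covered_and_shares_sum_to_one(self, graph):
        fa = gp.seed_embryonic_founders(graph, 7, seed=1)
        for node in graph.nodes:
            fr = fa.shares[node]
            assert len(fr) >= 1
            assert sum(f for _, f in fr) == pytest.approx(1.0)

    def test_territories_are_contiguous(self, graph):
        import networkx as nx

        fa = gp.seed_embryonic_founders(graph, 6, seed=2)
        und = graph.undirected()
        for f in fa.founders:
            sub = und.subgraph(fa.territory(f))
            assert nx.number_connected_components(sub) <= 3

    def test_multiclonal_fraction_near_target_over_seeds(self):
        """Pooled over seeds, the realised fraction of nodes with a
        >10% second founder sits within 10 points of the 27% target."""
        fracs = []
        for seed in range(10):
            g = gp.generate_ductal_tree(gp.SimulationConfig(seed=seed))
            fa = gp.seed_embryonic_founders(g, 7, seed=seed)
            mixed = sum(len(fa.shares[n]) > 1 for n in g.nodes)
            fracs.append(mixed / len(g.nodes))
        assert abs(100 * np.mean(fracs) - 27) <= 10

    def test_too_many_founders_rejected(self, graph):
        with pytest.raises(InvalidConfigError):
            gp.seed_embryonic_founders(graph, len(graph.nodes) + 1, seed=0)


class TestGenealogy:
    def test_founder_splits_inside_embryonic_window(self, small_gland):
        gen = small_gland.genealogy
        for f in small_gland.founders.founders:
            assert 0 < gen.clones[f].founding_time < 20

    def test_pubertal_foundings_in_molecular_range(self, small_gland):
        for c in small_gland.genealogy.clones.values():
            if c.epoch == "pubertal":
                assert 300 <= c.founding_time <= 500

    def test_no_adult_coalescence_without_driver(self, small_gland):
        """Internal truth-tree nodes all pre-date adulthood when no
        driver expansion is simulated."""
        tree = small_gland.truth.true_tree()
        gen = small_gland.genealogy
        for c in tree.clusters:
            if len(tree.children(c)) >= 2:
                assert gen.clones[c].founding_time <= 500

    def test_cc_monotone_along_lineages(self, small_gland):
        gen = small_gland.genealogy
        for cid, clone in gen.clones.items():
            if clone.parent in (None, ZYGOTE):
                continue
            for node, fr in gen.cell_fraction[cid].items():
                assert fr <= gen.cell_fraction[clone.parent].get(node, 0) + 1e-9

    def test_sibling_shares_respect_pigeonhole(self, small_gland):
        """Per sample, children of one clone cannot jointly exceed it."""
        gen = small_gland.genealogy
        cc = small_gland.truth.cc
        for cid in gen.clones:
            kids = gen.children(cid)
            kids = [k for k in kids if k in cc.index]
            if len(kids) < 2 or cid == ZYGOTE:
                continue
            total = cc.loc[kids].sum(axis=0)
            parent_cc = cc.loc[cid] if cid in cc.index else 1.0
            assert (total <= parent_cc + 1e-6).all()

    def test_driver_run_spans_required_territory(self):
        cfg = gp.SimulationConfig(
            seed=9, n_terminal_acini=20, n_microdissections=100,
            driver_expansion_flag=True,
        )
        sim = gp.simulate_gland(cfg)
        gen = sim.genealogy
        assert gen.driver_clone is not None
        terr = gen.clones[gen.driver_clone].territory
        acini = [n for n in terr if sim.graph.kind(n) == "acinus"]
        assert len(acini) >= 4
        assert len(terr) >= 13
        # the driver is an adult clone with adult subclones beneath it
        assert gen.clones[gen.driver_clone].founding_time > 500
        assert len(gen.children(gen.driver_clone)) >= 2


class TestMutationAccumulation:
    def test_zero_duration_zero_mutations(self):
        assert sample_branch_mutation_counts(16.4, 0.0, seed=0) == 0

    def test_negative_duration_rejected(self):
        with pytest.raises(InvalidGenealogyError):
            sample_branch_mutation_counts(16.4, -1.0, seed=0)

    def test_poisson_mean_at_paper_rate(self):
        """1,000 branches of 10 years at 16.4 mutations/year average
        ~164 mutations."""
        counts = sample_branch_mutation_counts(
            16.4, np.full(1000, 10.0), seed=42
        )
        se = np.sqrt(164 / 1000)
        assert abs(counts.mean() - 164) < 4 * se

    def test_every_mutation_on_exactly_one_branch(self, small_gland):
        muts = small_gland.truth.mutations
        assert muts["mutation_id"].is_unique
        assert muts["clone_id"].isin(small_gland.genealogy.clones).all()

    def test_age59_burden_in_expected_range(self, default_gland):
        """A 59-year-old donor accumulates ~1,000-1,500 mutations per
        dominant lineage."""
        assert 1000 <= default_gland.truth.true_burden.mean() <= 1500


class TestTelomeres:
    def test_zero_noise_is_exactly_affine(self):
        cfg = gp.SimulationConfig(telomere_noise_sd=0.0)
        burden = pd.Series([500.0, 1000.0, 1500.0], index=list("abc"))
        tel = gp.simulate_telomeres(burden, cfg)
        np.testing.assert_allclose(
            tel.to_numpy(), cfg.telomere_baseline - 0.32 * burden.to_numpy()
        )

    def test_ols_recovers_attrition_slope(self):
        """95% CIs of the telomere-on-burden regression cover the
        generative -0.32 bp/mutation slope at near-nominal rate."""
        cfg = gp.SimulationConfig(seed=0)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            burden = pd.Series(rng.uniform(800, 2000, size=150))
            tel = gp.simulate_telomeres(burden, cfg, seed=seed + 100)
            fit = gp.gradient_regression(tel.to_numpy(), burden.to_numpy())
            hits += fit.slope_ci[0] <= -0.32 <= fit.slope_ci[1]
        assert hits >= 8

    def test_zero_slope_ci_covers_zero(self):
        cfg = gp.SimulationConfig(seed=0, telomere_slope=0.0)
        rng = np.random.default_rng(3)
        burden = pd.Series(rng.uniform(800, 2000, size=150))
        tel = gp.simulate_telomeres(burden, cfg, seed=4)
        fit = gp.gradient_regression(tel.to_numpy(), burden.to_numpy())
        assert fit.slope_ci[0] <= 0 <= fit.slope_ci[1]


class TestMicrodissections:
    def test_fully_clonal_deep_sample_has_vaf_half(self):
        """cc = 1 at depth 10,000 pins the observed VAF at 0.5."""
        cfg = gp.SimulationConfig(
            seed=13, n_terminal_acini=1, n_microdissections=1,
            depth_mean=10000, depth_sample_sd=0.0,
            n_embryonic_founders=1, pubertal_per_founder=0,
            minor_adult_per_node=0, adult_share=(1.0, 1.0),
        )
        sim = gp.simulate_gland(cfg)
        vm = sim.vaf_matrix
        truth = sim.truth
        aid = sim.genealogy.adult_of[sim.samples["duct_node"].iloc[0]]
        stems = truth.mutations.query("clone_id == @aid and kind == 'stem'")
        vafs = vm.vaf().loc[
            [m for m in stems["mutation_id"] if m in vm.alt.index]
        ]
        assert abs(vafs.to_numpy().mean() - 0.5) < 0.01

    def test_median_vaf_band_for_most_samples(self, default_gland):
        """Median observed VAF per microdissection mostly falls in the
        0.15-0.3 polyclonal band."""
        vm = default_gland.vaf_matrix
        alt, dep = vm.alt.to_numpy(), vm.depth.to_numpy()
        med = []
        for j in range(vm.n_samples):
            rep = alt[:, j] >= 4
            med.append(np.median(alt[rep, j] / dep[rep, j]))
        assert sum(0.15 <= m <= 0.3 for m in med) >= 0.6 * len(med)

    def test_detection_censoring_matches_closed_form(self):
        """With cc = 0.1 at ~30x the per-mutation detection fraction
        matches the depth-mixed binomial tail P(alt >= 4)."""
        cfg = gp.SimulationConfig(
            seed=21, n_terminal_acini=1, n_microdissections=1,
            depth_mean=30.0, depth_sample_sd=0.0,
            n_embryonic_founders=1, pubertal_per_founder=0,
            minor_adult_per_node=0, adult_share=(0.1, 0.1),
            burden_dispersion_sd=0.0, donor_age=90.0,
        )
        sim = gp.simulate_gland(cfg)
        truth = sim.truth
        aid = sim.genealogy.adult_of[sim.samples["duct_node"].iloc[0]]
        stems = truth.mutations[
            (truth.mutations["clone_id"] == aid)
            & (truth.mutations["kind"] == "stem")
        ]
        frac = stems["detected"].mean()
        # alt ~ Binom(Poisson(30), 0.05) == Poisson(1.5)
        expected = stats.poisson.sf(3, 30 * 0.05)
        n = len(stems)
        assert abs(frac - expected) < 4 * np.sqrt(expected * (1 - expected) / n)

    def test_truth_retains_censored_mutations(self, small_gland):
        muts = small_gland.truth.mutations
        assert (~muts["detected"]).any()
        assert set(small_gland.vaf_matrix.mutations) == set(
            muts[muts["detected"]]["mutation_id"]
        ) & set(muts["mutation_id"])

    def test_fixed_seed_bit_identical_outputs(self):
        cfg = gp.SimulationConfig(seed=17, n_terminal_acini=5, n_microdissections=6)
        a = gp.simulate_gland(cfg)
        b = gp.simulate_gland(cfg)
        assert a.vaf_matrix.checksum() == b.vaf_matrix.checksum()
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.truth.clone_table, b.truth.clone_table)

    def test_expected_observed_burden_is_true_times_sensitivity(self):
        """Over replicate simulations, E[b_r] tracks the per-mutation
        detection probabilities summed over the sample's mutations."""
        cfg = gp.SimulationConfig(
            seed=0, n_terminal_acini=1, n_microdissections=1,
            n_embryonic_founders=1, pubertal_per_founder=0,
            minor_adult_per_node=0, adult_share=(0.6, 0.6),
            burden_dispersion_sd=0.0, depth_sample_sd=0.0,
        )
        obs, exp = [], []
        for seed in range(10):
            sim = gp.simulate_gland(
                gp.SimulationConfig(**{**cfg.__dict__, "seed": seed})
            )
            vm = sim.vaf_matrix
            s_id = vm.samples[0]
            b_r = int((vm.alt[s_id] >= 4).sum())
            cc = sim.truth.cc[s_id]
            muts = sim.truth.mutations
            vaf = 0.5 * cc.loc[muts["clone_id"]].to_numpy() * muts["vaf_scale"].to_numpy()
            # depth is Poisson(30), so alt is Poisson(30 * vaf)
            exp.append(float(stats.poisson.sf(3, 30 * vaf).sum()))
            obs.append(b_r)
        ratio = np.sum(obs) / np.sum(exp)
        assert 0.97 <= ratio <= 1.03


class TestClockCohort:
    def test_generative_moments(self):
        tab = gp.simulate_clock_cohort(seed=0, samples_per_donor=200)
        resid = tab["b_c"] - (133 + 16.4 * tab["age"])
        assert abs(resid.std() - np.sqrt(550**2 + 150**2)) < 40

    def test_deterministic_for_seed(self):
        pd.testing.assert_frame_equal(
            gp.simulate_clock_cohort(seed=4), gp.simulate_clock_cohort(seed=4)
        )
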