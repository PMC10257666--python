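import numpy as np
import pytest

from pulsegcn.correction import theoretical_gene_abundance
from pulsegcn.model import GroupAssignment, HeterogeneousPEModel
from pulsegcn.simulate import (SC1Design, SC2Design, SimConfig,
                               default_model, simulate_gcn, simulate_sc1,
                               simulate_sc2, simulate_tree)


class TestTreeGenerator:
    def test_deterministic_under_seed(self):
        a = simulate_tree(30, 0.4, seed=5).to_newick()
        b = simulate_tree(30, 0.4, seed=5).to_newick()
        assert a == b

    def test_bifurcating_node_count(self):
        t = simulate_tree(500, 0.4, seed=1)
        assert t.n_tips == 500
        assert t.n_nodes == 2 * 500 - 1
        assert all(len(c) in (0, 2) for c in t.children)

    def test_depth_scaling_and_positive_lengths(self):
        t = simulate_tree(100, 0.4, seed=2)
        assert np.mean(t.depths()[t.tip_ids]) == pytest.approx(0.4, rel=1e-6)
        nonroot = np.arange(t.n_nodes) != t.root
        assert (t.lengths[nonroot] > 0).all()

    def test_total_length_grows_with_size(self):
        totals = {n: np.mean([simulate_tree(n, 0.4, seed=s).lengths.sum()
                              for s in range(5)]) for n in (20, 100, 300)}
        assert totals[20] < totals[100] < totals[300]

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(2)


class TestGCNGenerator:
    def test_no_jumps_no_noise_everyone_at_root(self):
        t = simulate_tree(40, 0.4, seed=3)
        m = HeterogeneousPEModel(1.0, 0.0, 1e-300, 0.0, 0.0,
                                 GroupAssignment.uniform(t))
        traits = simulate_gcn(t, m, root_value=4, seed=0)
        assert set(traits.values()) == {4}

    def test_clamped_at_one(self):
        t = simulate_tree(200, 0.4, seed=4)
        m = default_model(t, SimConfig(n_tips=200, root_value=1.0, seed=4))
        traits = simulate_gcn(t, m, root_value=1.0, seed=1)
        assert min(traits.values()) >= 1

    def test_deterministic_under_seed(self):
        t = simulate_tree(40, 0.4, seed=5)
        m = default_model(t, SimConfig(n_tips=40, seed=5))
        assert simulate_gcn(t, m, seed=9) == simulate_gcn(t, m, seed=9)

    def test_compound_poisson_variance_identity(self):
        """Across replicate simulations the tip deviation variance matches
        lambda*sigma2_jump*(root-to-tip length) within 10%."""
        from pulsegcn.tree import parse_tree

        t = parse_tree("(A:0.5,B:0.5);")
        m = HeterogeneousPEModel(1.0, 10.0, 10.0, 0.0, 0.0,
                                 GroupAssignment.uniform(t))
        devs = []
        for s in range(1000):
            vals = simulate_gcn(t, m, root_value=50.0, seed=s, discretize=False)
            devs.append(vals["A"] - 50.0)
        target = 10.0 * 1.0 * 0.5
        assert abs(np.var(devs) - target) / target < 0.1


class TestSC1:
    def test_expected_gene_fraction_matches_closed_form(self, reference300):
        tree, _, _, traits = reference300
        community, truth, refs = simulate_sc1(
            tree, traits, SC1Design(n_otus=100, depth=200_000, seed=3))
        p = truth["S1"].values
        gcn = np.array([traits[o] for o in community.otus])
        expected = theoretical_gene_abundance(p, gcn)
        observed = community.counts["S1"].values / community.counts["S1"].sum()
        # multinomial error at this depth
        assert np.max(np.abs(observed - expected)) < 5 * np.sqrt(
            expected.max() / 200_000)

    def test_equal_gcns_reads_converge_to_cells(self, reference300):
        tree = reference300[0]
        traits = {lab: 3 for lab in tree.tip_labels}
        community, truth, _ = simulate_sc1(
            tree, traits, SC1Design(n_otus=50, depth=2_000_000, seed=4))
        observed = community.counts["S1"] / community.counts["S1"].sum()
        assert np.allclose(observed.values, truth["S1"].values, atol=2e-3)

    def test_reference_sets_respect_thresholds(self, reference300):
        tree, _, _, traits = reference300
        community, _, refs = simulate_sc1(tree, traits,
                                          SC1Design(n_otus=60, seed=5))
        tips, D = tree.tip_distance_matrix()
        pos = {tree.labels[t]: k for k, t in enumerate(tips)}
        crow = [pos[o] for o in community.otus]
        for thr in (0.046, 0.215):
            for ref in refs[thr][:10]:
                assert D[pos[ref], crow].min() >= thr

    def test_seeded_run_reproducible(self, reference300):
        tree, _, _, traits = reference300
        a, ta, _ = simulate_sc1(tree, traits, SC1Design(n_otus=30, seed=6))
        b, tb, _ = simulate_sc1(tree, traits, SC1Design(n_otus=30, seed=6))
        assert a.counts.equals(b.counts) and ta.equals(tb)

    def test_zero_depth_rejected(self, reference300):
        tree, _, _, traits = reference300
        with pytest.raises(ValueError):
            simulate_sc1(tree, traits, SC1Design(depth=0))


class TestSC2:
    def test_default_design_gives_20_signature_otus(self):
        assert SC2Design().n_signature == 20

    def test_zero_signature_rejected(self, reference300):
        tree, _, _, traits = reference300
        with pytest.raises(ValueError):
            simulate_sc2(tree, traits,
                         SC2Design(n_otus=100, signature_fraction=0.001))

    def test_zero_turnover_shares_otu_set_within_environment(self, reference300):
        tree, _, _, traits = reference300
        out = simulate_sc2(tree, traits,
                           SC2Design(n_otus=100, n_samples=4, turnover_rate=0.0,
                                     signature_fraction=0.05, seed=7))
        counts = out["gene_counts"].counts
        a_samples = [s for s, e in out["labels"].items() if e == "A"]
        support = [set(counts.index[counts[s] > 0]) for s in a_samples]
        # all samples drawn from the same member set (multinomial zeros aside)
        members = set(counts.index[(counts[a_samples] > 0).any(axis=1)])
        for s in support:
            assert s <= members

    def test_turnover_replaces_fraction_of_core(self, reference300):
        tree, _, _, traits = reference300
        out = simulate_sc2(tree, traits,
                           SC2Design(n_otus=150, n_samples=3, turnover_rate=0.2,
                                     signature_fraction=0.04, seed=8))
        cell = out["true_cell_abundance"]
        a_samples = [s for s, e in out["labels"].items() if e == "A"]
        sets = [set(cell.index[cell[s] > 0]) for s in a_samples]
        core_size = 150 - 2 * 6
        for x, y in zip(sets, sets[1:]):
            overlap = len(x & y)
            assert overlap < len(x)  # turnover really replaces members

    def test_realised_enrichment_close_to_design(self, reference300):
        """Mean signature-OTU enrichment across seeds within 15% of the
        configured fold."""
        tree, _, _, traits = reference300
        folds = []
        for seed in range(6):
            d = SC2Design(n_otus=150, n_samples=6, signature_fraction=0.04,
                          enrichment_fold=4.0, seed=seed)
            out = simulate_sc2(tree, traits, d)
            cell = out["true_cell_abundance"]
            labels = out["labels"]
            for env, other in (("A", "B"), ("B", "A")):
                sig = out["signatures"][env]
                home = [s for s, e in labels.items() if e == env]
                away = [s for s, e in labels.items() if e == other]
                ratio = cell.loc[sig, home].mean(axis=1) / \
                    cell.loc[sig, away].mean(axis=1)
                folds.append(ratio.mean())
        assert abs(np.mean(folds) - 4.0) / 4.0 < 0.15
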