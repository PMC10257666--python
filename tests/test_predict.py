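import json

import numpy as np
import pytest
from scipy.stats import norm, poisson

from pulsegcn.model import GroupAssignment, HeterogeneousPEModel
from pulsegcn.predict import (AncestralReconstructor, Placement, IntegerPMF,
                              adjusted_nsti, predict_holdout, predict_tip,
                              read_jplace, rescale_reference)
from pulsegcn.tree import nstd, parse_tree


def uniform_model(tree, lam=1.0, s2j=1.0, eps=0.0):
    uni = GroupAssignment.uniform(tree)
    return HeterogeneousPEModel(s2j, lam, lam, eps, eps, uni)


@pytest.fixture
def pair_tree():
    return parse_tree("(A:1,B:1);")


class TestPredictTip:
    def test_single_neighbor_zero_everything_is_certain(self, pair_tree):
        m = uniform_model(pair_tree, lam=1e-12)
        res = predict_tip(Placement("q", pair_tree.tip_id("A"), 0.0, 0.0),
                          pair_tree, {"A": 4.0}, m)
        assert res.point_estimate == 4
        assert res.confidence == pytest.approx(1.0, abs=1e-9)

    def test_regular_group_confidence_cap_85(self, pair_tree):
        """With the fitted time-independent sd 0.3473 a query identical to a
        reference has confidence ~85%: the cap of the regularly-evolving
        group."""
        m = uniform_model(pair_tree, lam=1e-12, eps=0.3473 ** 2)
        res = predict_tip(Placement("q", pair_tree.tip_id("A"), 0.0, 0.0),
                          pair_tree, {"A": 4.0}, m)
        assert res.confidence == pytest.approx(2 * norm.cdf(0.5 / 0.3473) - 1,
                                               abs=1e-6)

    def test_confidence_matches_truncated_sum_oracle(self, pair_tree):
        m = uniform_model(pair_tree, lam=0.1, s2j=4.0)
        res = predict_tip(Placement("q", pair_tree.tip_id("A"), 0.0, 1.0),
                          pair_tree, {"A": 4.0}, m)
        expect = np.exp(-0.1) + sum(
            poisson.pmf(n, 0.1) * (norm.cdf(0.5 / np.sqrt(4 * n))
                                   - norm.cdf(-0.5 / np.sqrt(4 * n)))
            for n in range(1, 80))
        assert res.confidence == pytest.approx(expect, rel=1e-8)

    def test_pmf_sums_to_one(self, reference300):
        tree, _, model, traits = reference300
        queries = sorted(tree.tip_labels)[:15]
        for p in predict_holdout(tree, traits, model, queries):
            assert sum(p.pmf.values()) == pytest.approx(1.0, abs=1e-9)
            assert p.point_estimate >= 1
            assert p.confidence == pytest.approx(p.pmf.get(p.point_estimate, 0.0))
            assert p.reliable == (p.confidence >= 0.95)

    def test_confidence_decreases_with_pendant_length(self, pair_tree):
        m = uniform_model(pair_tree, lam=2.0, s2j=1.0)
        confs = []
        for pend in (0.0, 0.2, 0.5, 1.0, 2.0):
            r = predict_tip(Placement("q", pair_tree.tip_id("A"), 0.0, pend),
                            pair_tree, {"A": 4.0}, m)
            confs.append(r.confidence)
        assert all(a >= b - 1e-12 for a, b in zip(confs, confs[1:]))

    def test_slow_confidence_geq_regular_at_equal_distance(self, pair_tree):
        node = pair_tree.tip_id("A")
        slow = uniform_model(pair_tree, lam=20 / 145, s2j=0.75, eps=0.0)
        reg = uniform_model(pair_tree, lam=20.0, s2j=0.75, eps=0.3473 ** 2)
        for pend in (0.01, 0.05, 0.2, 0.5):
            c_slow = predict_tip(Placement("q", node, 0.0, pend), pair_tree,
                                 {"A": 4.0}, slow).confidence
            c_reg = predict_tip(Placement("q", node, 0.0, pend), pair_tree,
                                {"A": 4.0}, reg).confidence
            assert c_slow >= c_reg

    def test_empty_reference_errors(self, pair_tree):
        m = uniform_model(pair_tree)
        with pytest.raises(ValueError):
            predict_tip(Placement("q", pair_tree.tip_id("A"), 0.0, 0.0),
                        pair_tree, {}, m)


class TestRescalingAndNSTD:
    def test_slow_branches_rescaled_by_frequency_ratio(self):
        tree = parse_tree("((A:0.1,B:0.1):0.1,C:0.1);")
        reg = np.ones(tree.n_nodes, dtype=bool)
        reg[tree.tip_id("A")] = False
        m = HeterogeneousPEModel(1.0, 20 / 145, 20.0, 0.0, 0.0,
                                 GroupAssignment(tree, reg))
        out = rescale_reference(tree, m)
        assert out.lengths[tree.tip_id("A")] == pytest.approx(0.1 / 145)
        assert out.lengths[tree.tip_id("B")] == pytest.approx(0.1)

    def test_all_regular_rescaling_is_identity(self, basic_tree):
        m = uniform_model(basic_tree)
        out = rescale_reference(basic_tree, m)
        assert np.allclose(out.lengths, basic_tree.lengths)

    def test_rescaling_requires_positive_regular_rate(self, basic_tree):
        m = uniform_model(basic_tree)
        m.lambda_regular = 0.0
        with pytest.raises(ValueError):
            rescale_reference(basic_tree, m)

    def test_adjusted_nstd_scales_with_slow_branches(self):
        tree = parse_tree("((A:0.29,B:0.29):0.001,C:0.3);")
        reg = np.ones(tree.n_nodes, dtype=bool)
        for lab in ("A", "B"):
            reg[tree.tip_id(lab)] = False
        m = HeterogeneousPEModel(1.0, 20 / 145, 20.0, 0.0, 0.0,
                                 GroupAssignment(tree, reg))
        out = rescale_reference(tree, m)
        assert nstd(out, "A", ["B"]) == pytest.approx(2 * 0.29 / 145)

    def test_adjusted_nsti_is_weighted_mean(self):
        assert adjusted_nsti({"x": 1}, {"x": 0.2}) == pytest.approx(0.2)
        assert adjusted_nsti({"x": 3, "y": 1}, {"x": 0.1, "y": 0.3}) == \
            pytest.approx(0.15)
        assert adjusted_nsti({"x": 2, "y": 2}, {"x": 0.0, "y": 0.2}) == \
            pytest.approx(0.1)

    def test_adjusted_nsti_zero_reads_errors(self):
        with pytest.raises(ValueError):
            adjusted_nsti({"x": 0}, {"x": 0.1})


class TestHoldout:
    def test_masking_matches_pruned_placement(self):
        """Masking a sister tip moves the attachment to the junction with the
        first informative lineage, pendant accumulating the path."""
        tree = parse_tree("((A:0.01,B:0.01):0.1,(C:0.05,D:0.05):0.06);")
        m = uniform_model(tree, lam=5.0, s2j=1.0)
        traits = {"A": 4.0, "B": 4.0, "C": 6.0, "D": 6.0}
        rec = AncestralReconstructor(tree, traits, m, masked={"A", "B"})
        mean, var, pend, pois = rec.holdout_attachment(tree.tip_id("A"))
        assert pend == pytest.approx(0.11)
        assert pois == pytest.approx(5.0 * 0.11)
        assert mean == pytest.approx(6.0)

    def test_nstds_attached(self, reference300):
        tree, _, model, traits = reference300
        queries = sorted(tree.tip_labels)[:5]
        out = predict_holdout(tree, traits, model, queries)
        refs = [t for t in tree.tip_labels if t not in set(queries)]
        for p in out:
            assert p.raw_nstd == pytest.approx(nstd(tree, p.query, refs), abs=1e-9)
            assert p.adjusted_nstd <= p.raw_nstd + 1e-12

    def test_all_masked_errors(self, reference300):
        tree, _, model, traits = reference300
        with pytest.raises(ValueError):
            predict_holdout(tree, traits, model, sorted(tree.tip_labels)[:1],
                            masked_tips=set(tree.tip_labels))


class TestJplace:
    JPLACE = {
        "version": 3,
        "tree": "((A:2{0},B:2{1}):1{2},C:3{3});",
        "fields": ["edge_num", "likelihood", "like_weight_ratio",
                   "distal_length", "pendant_length"],
        "placements": [
            {"p": [[0, -100.0, 0.2, 0.5, 0.1], [3, -99.0, 0.8, 1.0, 0.2]],
             "n": ["q1"]},
        ],
    }

    def test_best_placement_by_weight_ratio(self):
        tree, placements = read_jplace(json.dumps(self.JPLACE))
        assert len(placements) == 1
        p = placements[0]
        assert tree.labels[p.edge_node] == "C"  # edge 3, higher weight ratio
        assert p.distal_position == 1.0 and p.pendant_length == 0.2

    def test_tree_edges_mapped(self):
        tree, placements = read_jplace(json.dumps(self.JPLACE))
        assert sorted(tree.tip_labels) == ["A", "B", "C"]
        assert tree.patristic_distance("A", "C") == pytest.approx(6.0)

    def test_placement_prediction_end_to_end(self):
        tree, placements = read_jplace(json.dumps(self.JPLACE))
        m = uniform_model(tree, lam=1.0, s2j=1.0, eps=0.05)
        res = predict_tip(placements[0], tree, {"A": 3.0, "B": 5.0, "C": 4.0}, m)
        assert res.point_estimate >= 1
        assert 0 < res.confidence <= 1


class TestIntegerPMF:
    def test_validates_normalisation(self):
        with pytest.raises(ValueError):
            IntegerPMF({1: 0.5, 2: 0.4})

    def test_json_round_trip_and_mode(self):
        pmf = IntegerPMF({1: 0.25, 2: 0.5, 3: 0.25})
        again = IntegerPMF.from_json(pmf.to_json())
        assert again == pmf
        assert pmf.mode == 2
        assert pmf.mean() == pytest.approx(2.0)
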