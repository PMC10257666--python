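import numpy as np
import pandas as pd
import pytest

from pulsegcn.evaluate import (DistanceMatrix, cross_validate, distance_matrix,
                               pcoa, permanova, shift_reduction)
from pulsegcn.predict import IntegerPMF, PredictionResult


def make_prediction(query, point, confidence, true_value=None):
    pmf = {point: confidence}
    rest = 1.0 - confidence
    if rest > 0:
        pmf[point + 1] = rest
    return PredictionResult(
        query=query, point_estimate=point, continuous_mean=float(point),
        continuous_variance=0.1, pmf=IntegerPMF(pmf), confidence=confidence,
        reliable=confidence >= 0.95, group="regular", adjusted_nstd=0.01,
        raw_nstd=0.01)


class TestCrossValidation:
    def test_oracle_predictor_scores_perfectly(self, reference300):
        tree, _, model, traits = reference300

        def oracle(queries, mask):
            return [make_prediction(q, int(traits[q]), 1.0) for q in queries]

        cv = cross_validate(tree, traits, model, thresholds=(0.0, 0.01),
                            repeats=5, seed=0, predictor=oracle)
        assert (cv.summary["precision"] == 1.0).all()
        assert (cv.summary["recall"] == 1.0).all()
        assert (cv.summary["r2"] == 1.0).all()

    def test_constant_predictor_r2_nonpositive(self, reference300):
        tree, _, model, traits = reference300
        mode = int(pd.Series(list(traits.values())).mode()[0])

        def constant(queries, mask):
            return [make_prediction(q, mode, 1.0) for q in queries]

        cv = cross_validate(tree, traits, model, thresholds=(0.0,),
                            repeats=8, seed=0, predictor=constant)
        assert cv.summary["r2"].iloc[0] <= 0.05
        # precision equals overall accuracy when everything is 'reliable'
        assert cv.summary["precision"].iloc[0] == \
            pytest.approx(cv.summary["accuracy"].iloc[0])

    def test_summary_matches_naive_recomputation(self, reference300):
        """Precision/recall/R^2 re-derived from the stored per-prediction
        records equal the summary values."""
        tree, _, model, traits = reference300
        cv = cross_validate(tree, traits, model, thresholds=(0.0, 0.046),
                            repeats=4, seed=1)
        for _, row in cv.summary.iterrows():
            rec = cv.records[cv.records["bin"] == row["bin"]]
            per_rep = []
            for _, g in rec.groupby("repeat"):
                correct = (g["point"] == g["true"]).to_numpy()
                reliable = g["reliable"].to_numpy(dtype=bool)
                prec = correct[reliable].mean() if reliable.any() else np.nan
                per_rep.append(prec)
            assert row["precision"] == pytest.approx(np.nanmean(per_rep))

    def test_non_overlapping_test_sets_within_bin(self, reference300):
        tree, _, model, traits = reference300
        cv = cross_validate(tree, traits, model, thresholds=(0.0,),
                            repeats=10, seed=2)
        rec = cv.records
        queries = rec[rec["bin"] == 0].groupby("repeat")["query"].apply(set)
        seen = set()
        for s in queries:
            assert not (s & seen)
            seen |= s

    def test_impossible_threshold_skips_bin(self, reference300):
        tree, _, model, traits = reference300
        with pytest.warns(UserWarning, match="skipped"):
            cv = cross_validate(tree, traits, model, thresholds=(50.0,),
                                repeats=2, seed=0)
        assert cv.summary.empty


class TestDistances:
    def _tab(self):
        return pd.DataFrame({"s1": [5, 5, 0], "s2": [5, 5, 0], "s3": [0, 0, 10]},
                            index=["X", "Y", "Z"], dtype=float)

    def test_identical_samples_distance_zero(self):
        tab = self._tab()
        for metric in ("bray_curtis", "aitchison"):
            dm = distance_matrix(tab, metric)
            assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_bray_curtis_is_one(self):
        dm = distance_matrix(self._tab(), "bray_curtis")
        assert dm.data[0, 2] == pytest.approx(1.0)

    def test_weighted_unifrac_two_tip_star_oracle(self):
        """Hand computation on (X:1,Y:1): samples (1,0) vs (0,1) move all
        mass across both unit branches; normalised weighted UniFrac = 1."""
        from pulsegcn.tree import parse_tree

        tree = parse_tree("(X:1,Y:1);")
        tab = pd.DataFrame({"a": [1, 0], "b": [0, 1]}, index=["X", "Y"],
                           dtype=float)
        dm = distance_matrix(tab, "weighted_unifrac", tree=tree)
        assert dm.data[0, 1] == pytest.approx(1.0)

    def test_weighted_unifrac_requires_tree(self):
        with pytest.raises(ValueError):
            distance_matrix(self._tab(), "weighted_unifrac")

    def test_aitchison_perturbation_invariance(self):
        """Multiplying all samples componentwise by a fixed composition
        leaves Aitchison distances unchanged (after closure)."""
        rng = np.random.default_rng(3)
        tab = pd.DataFrame(rng.uniform(0.5, 3.0, size=(6, 4)),
                           index=[f"o{i}" for i in range(6)],
                           columns=list("abcd"))
        g = rng.uniform(0.5, 2.0, size=6)
        pert = tab.mul(g, axis=0)
        d0 = distance_matrix(tab, "aitchison").data
        d1 = distance_matrix(pert, "aitchison").data
        assert np.allclose(d0, d1, atol=1e-10)

    def test_zero_total_sample_errors(self):
        tab = self._tab()
        tab["s4"] = 0.0
        with pytest.raises(ValueError):
            distance_matrix(tab, "bray_curtis")

    def test_symmetry_and_zero_diagonal_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"], "x")


class TestPCoA:
    def test_euclidean_distances_recovered(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(X))
        dm = DistanceMatrix(D, [f"s{i}" for i in range(6)], "euclidean")
        coords, eig, neg = pcoa(dm)
        D2 = squareform(pdist(coords.values))
        assert np.allclose(D, D2, atol=1e-8)
        assert len(neg) == 0 or np.all(neg > -1e-8)

    def test_duplicated_sample_coincident(self):
        D = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        dm = DistanceMatrix(D, ["a", "b", "c"], "x")
        coords, _, _ = pcoa(dm)
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-8)

    def test_eigenvalue_sum_equals_gower_trace(self):
        rng = np.random.default_rng(5)
        tab = pd.DataFrame(rng.integers(1, 50, size=(8, 6)).astype(float),
                           index=[f"o{i}" for i in range(8)],
                           columns=[f"s{i}" for i in range(6)])
        dm = distance_matrix(tab, "bray_curtis")
        coords, eig, neg = pcoa(dm)
        D2 = dm.data ** 2
        J = np.eye(6) - np.ones((6, 6)) / 6
        gower = -0.5 * J @ D2 @ J
        assert eig.sum() + neg.sum() == pytest.approx(np.trace(gower), abs=1e-8)

    def test_too_few_samples_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ["a", "b"], "x")
        with pytest.raises(ValueError):
            pcoa(dm)


class TestPermanova:
    def _clustered(self, sep, seed=0, n=6):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(2 * n, 3))
        X[n:] += sep
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(2 * n)]
        labels = {s: ("A" if i < n else "B") for i, s in enumerate(ids)}
        return DistanceMatrix(squareform(pdist(X)), ids, "euclidean"), labels

    def test_strong_separation_gives_minimal_p(self):
        dm, labels = self._clustered(sep=50.0)
        res = permanova(dm, labels, n_permutations=999, seed=0)
        # random permutations can reproduce the original partition (ties in
        # F), so the attainable minimum is (1 + #ties)/1000
        assert res.p_value <= 5 / 1000
        assert res.pve > 0.9

    def test_duplicate_samples_distinct_labels_pve_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 3))
        XX = np.vstack([X, X])
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(10)]
        labels = {s: ("A" if i < 5 else "B") for i, s in enumerate(ids)}
        dm = DistanceMatrix(squareform(pdist(XX)), ids, "euclidean")
        res = permanova(dm, labels, n_permutations=99, seed=0)
        assert res.pve < 0.05

    def test_single_group_rejected(self):
        dm, labels = self._clustered(sep=1.0)
        with pytest.raises(ValueError):
            permanova(dm, {s: "A" for s in dm.ids})

    def test_pseudo_f_matches_skbio(self):
        """Independent cross-check of the statistic against scikit-bio."""
        from skbio import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        dm, labels = self._clustered(sep=1.0, seed=2)
        mine = permanova(dm, labels, n_permutations=99, seed=0)
        theirs = sk_permanova(SkDM(dm.data, ids=dm.ids),
                              pd.Series(labels, name="group"), permutations=99)
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"],
                                              rel=1e-9)


class TestShiftReduction:
    def _tables(self, seed=0):
        rng = np.random.default_rng(seed)
        true = pd.DataFrame(rng.uniform(0.5, 2.0, size=(8, 5)),
                            index=[f"o{i}" for i in range(8)],
                            columns=[f"s{i}" for i in range(5)])
        gene = true * rng.uniform(0.5, 2.0, size=(8, 1))
        return true / true.sum(), gene / gene.sum()

    def test_corrected_equals_true_full_reduction(self):
        true, gene = self._tables()
        _, red = shift_reduction(true, gene, true.copy(), "bray_curtis")
        assert red == pytest.approx(1.0, abs=1e-9)

    def test_corrected_equals_gene_no_reduction(self):
        true, gene = self._tables()
        _, red = shift_reduction(true, gene, gene.copy(), "bray_curtis")
        assert red == pytest.approx(0.0, abs=1e-9)

    def test_shape_mismatch_errors(self):
        true, gene = self._tables()
        with pytest.raises(ValueError):
            shift_reduction(true, gene, gene.iloc[:, :-1], "bray_curtis")
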