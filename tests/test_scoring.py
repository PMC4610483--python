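import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from spiralkin import scoring
from spiralkin.scoring import (
    ConfusionMatrix2x2,
    assemble_learning_set,
    confusion_metrics,
    cross_validated_evaluation,
    fit_pca,
    mean_pairwise_icc,
    pairwise_rater_agreement,
    pc_rating_correlations,
)

B, D = scoring.BRADYKINESIA, scoring.DYSKINESIA


class TestPCA:
    def test_isotropic_features_share_variance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((500, 6))
        model = fit_pca(X, n_components=6)
        assert np.all(np.abs(model.explained_variance_fraction - 1 / 6) < 0.05)

    def test_rank_two_structure(self):
        rng = np.random.default_rng(2)
        s1, s2 = rng.standard_normal((2, 300))
        X = np.column_stack([s1, s1, s1, s1, s2, s2, s2, s2])
        X = X + rng.normal(0, 1e-3, X.shape)
        model = fit_pca(X, n_components=8)
        assert model.explained_variance_fraction[:2].sum() > 0.99

    def test_explained_fractions_conserve_variance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 5)) @ rng.standard_normal((5, 5))
        model = fit_pca(X, n_components=5)
        assert model.explained_variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(model.explained_variance_fraction) <= 1e-12).all()

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 6))
        model = fit_pca(X, n_components=6)
        Z = (X - model.feature_means) / model.feature_sds
        scores = model.transform(X)
        np.testing.assert_allclose(scores @ model.loadings.T, Z, atol=1e-8)

    def test_loadings_orthonormal_and_sign_convention(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 7))
        model = fit_pca(X, n_components=4)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-10)
        for j in range(4):
            col = model.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_zero_variance_feature_dropped(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(
            {"a": rng.standard_normal(50), "b": np.ones(50), "c": rng.standard_normal(50)}
        )
        model = fit_pca(X, n_components=2)
        assert model.feature_names == ["a", "c"]

    def test_too_many_components_errors(self):
        with pytest.raises(ValueError):
            fit_pca(np.random.default_rng(0).standard_normal((20, 3)), n_components=4)


def _ratings_frame(cases, raters, labels_by_rater, impairment=7.0):
    rows = []
    for case in cases:
        for rater in raters:
            rows.append(
                {
                    "case_id": case,
                    "rater_id": rater,
                    "impairment": impairment,
                    "symptom": labels_by_rater[rater](case),
                }
            )
    return pd.DataFrame(rows)


class TestLearningSet:
    def _scores(self, cases):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            rng.standard_normal((len(cases), 4)),
            index=pd.Index(cases, name="case_id"),
            columns=["PC1", "PC2", "PC3", "PC4"],
        )

    def test_unanimous_ratings_are_seed_independent(self):
        cases = [f"c{i}" for i in range(20)]
        ratings = _ratings_frame(
            cases, ["r1", "r2", "r3"],
            {r: (lambda c: B if c < "c5" else D) for r in ["r1", "r2", "r3"]},
        )
        scores = self._scores(cases)
        a = assemble_learning_set(ratings, scores, seed=1)
        b = assemble_learning_set(ratings, scores, seed=999)
        pd.testing.assert_series_equal(a["label"], b["label"])

    def test_zero_threshold_retains_all_cases(self):
        cases = [f"c{i}" for i in range(30)]
        ratings = _ratings_frame(
            cases, ["r1"], {"r1": lambda c: B}, impairment=1.0
        )
        scores = self._scores(cases)
        assert len(assemble_learning_set(ratings, scores, impairment_threshold=0)) == 30
        assert len(assemble_learning_set(ratings, scores, impairment_threshold=5)) == 0

    def test_ineligible_symptoms_excluded(self):
        cases = ["c1", "c2"]
        ratings = _ratings_frame(
            cases, ["r1"], {"r1": lambda c: "tremor" if c == "c1" else B}
        )
        out = assemble_learning_set(ratings, self._scores(cases), seed=0)
        assert list(out["case_id"]) == ["c2"]

    def test_rater_sampling_is_uniform(self):
        cases = [f"c{i:04d}" for i in range(1000)]
        raters = ["r1", "r2", "r3", "r4"]
        # fixed disagreement pattern: every rater is eligible on every case
        labellers = {
            "r1": lambda c: B,
            "r2": lambda c: D,
            "r3": lambda c: B,
            "r4": lambda c: D,
        }
        ratings = _ratings_frame(cases, raters, labellers)
        scores = self._scores(cases)
        counts = {r: 0 for r in raters}
        n_seeds = 40
        for seed in range(1, n_seeds + 1):
            out = assemble_learning_set(ratings, scores, seed=seed)
            for r, c in out["rater_id"].value_counts().items():
                counts[r] += c
        total = sum(counts.values())
        assert total == 1000 * n_seeds
        for r in raters:
            assert counts[r] / total == pytest.approx(0.25, abs=0.04)


def _gaussian_examples(n, delta, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [rng.normal(0.0, 1.0, (half, 4)), rng.normal(delta, 1.0, (half, 4))]
    )
    y = np.array([B] * half + [D] * half)
    df = pd.DataFrame(X, columns=["PC1", "PC2", "PC3", "PC4"])
    df["label"] = y
    return df


class TestCrossValidation:
    @pytest.mark.parametrize("method", scoring.CLASSIFIERS)
    def test_separable_clouds_classified(self, method):
        examples = _gaussian_examples(200, delta=6.0, seed=1)
        rep = cross_validated_evaluation(examples, method=method, folds=10, seed=0)
        assert rep.accuracy_pct >= 95.0
        assert rep.auc >= 0.99

    def test_permuted_labels_are_chance_level(self):
        examples = _gaussian_examples(500, delta=6.0, seed=2)
        rng = np.random.default_rng(3)
        examples["label"] = rng.permutation(examples["label"].to_numpy())
        rep = cross_validated_evaluation(examples, method="LR", folds=10, seed=0)
        assert 40.0 <= rep.accuracy_pct <= 60.0
        assert abs(rep.weighted_kappa) <= 0.15

    def test_deterministic_given_seed(self):
        examples = _gaussian_examples(100, delta=2.0, seed=4)
        a = cross_validated_evaluation(examples, method="MLP", folds=10, seed=5)
        b = cross_validated_evaluation(examples, method="MLP", folds=10, seed=5)
        assert a.to_dict() == b.to_dict()

    def test_small_class_errors(self):
        examples = _gaussian_examples(16, delta=2.0, seed=5)
        with pytest.raises(ValueError, match="folds"):
            cross_validated_evaluation(examples, method="LR", folds=10, seed=0)


class TestConfusionMetrics:
    def test_published_style_worked_example(self):
        # rater rows (bradykinesia 28+8, dyskinesia 9+64); classifier columns
        cm = ConfusionMatrix2x2(tp=28, fn=8, fp=9, tn=64)
        m = confusion_metrics(cm)
        assert round(m["accuracy_pct"]) == 84
        assert m["sensitivity_pct"] == pytest.approx(75.7, abs=0.05)
        assert m["specificity_pct"] == pytest.approx(88.9, abs=0.05)
        assert round(m["weighted_kappa"], 2) == 0.65

    def test_perfect_agreement(self):
        m = confusion_metrics(ConfusionMatrix2x2(tp=50, fn=0, fp=0, tn=50))
        assert m["accuracy_pct"] == 100.0
        assert m["weighted_kappa"] == 1.0

    def test_kappa_matches_sklearn_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.choice([B, D], 60)
            b = rng.choice([B, D], 60)
            cm = ConfusionMatrix2x2(
                tp=int(((a == B) & (b == B)).sum()),
                fn=int(((a == B) & (b == D)).sum()),
                fp=int(((a == D) & (b == B)).sum()),
                tn=int(((a == D) & (b == D)).sum()),
            )
            m = confusion_metrics(cm)
            if math.isnan(m["weighted_kappa"]):
                continue
            assert m["weighted_kappa"] == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-10
            )
            assert -1.0 <= m["weighted_kappa"] <= 1.0


class TestRaterAgreement:
    def test_identical_raters(self):
        labels = np.array([B, D, B, D, D])
        out = pairwise_rater_agreement(labels, labels)
        assert out["weighted_kappa"] == pytest.approx(1.0)
        assert out["percent_agreement"] == 100.0
        assert out["fp_rate"] == 0.0
        assert out["fn_rate"] == 0.0

    def test_independent_raters_near_zero_kappa(self):
        rng = np.random.default_rng(11)
        a = rng.choice([B, D], 500)
        b = rng.choice([B, D], 500)
        out = pairwise_rater_agreement(a, b)
        assert abs(out["weighted_kappa"]) < 0.1

    def test_anticorrelated_raters_negative_kappa(self):
        a = np.array([B, D] * 20)
        b = np.array([D, B] * 20)
        assert pairwise_rater_agreement(a, b)["weighted_kappa"] < 0

    def test_no_shared_cases_errors(self):
        with pytest.raises(ValueError):
            pairwise_rater_agreement([B], [B])


class TestMeanPairwiseICC:
    def test_identical_vectors(self):
        v = np.arange(10.0)
        assert mean_pairwise_icc([v, v, v, v]) == pytest.approx(1.0)

    def test_noise_attenuation(self):
        # v, v+n1, v+n2 with sd(n) = sd(v): clean-noisy pairs correlate
        # at 1/sqrt(2), the noisy-noisy pair at 1/2
        rng = np.random.default_rng(12)
        v = rng.standard_normal(200)
        n1, n2 = rng.standard_normal((2, 200))
        expected = (2 / math.sqrt(2) + 0.5) / 3
        got = mean_pairwise_icc([v, v + n1, v + n2])
        assert got == pytest.approx(expected, abs=0.1)

    def test_two_vectors_equal_pearson(self):
        rng = np.random.default_rng(13)
        a, b = rng.standard_normal((2, 50))
        assert mean_pairwise_icc([a, b]) == pytest.approx(np.corrcoef(a, b)[0, 1])

    def test_zero_variance_vector_excluded(self):
        rng = np.random.default_rng(14)
        a, b = rng.standard_normal((2, 50))
        flat = np.zeros(50)
        assert mean_pairwise_icc([a, b, flat]) == pytest.approx(
            np.corrcoef(a, b)[0, 1]
        )


class TestPCRatingCorrelations:
    def _frames(self, n=300, seed=15):
        rng = np.random.default_rng(seed)
        cases = pd.Index([f"c{i}" for i in range(n)], name="case_id")
        pcs = pd.DataFrame(
            rng.standard_normal((n, 4)), index=cases,
            columns=["PC1", "PC2", "PC3", "PC4"],
        )
        ratings = pd.DataFrame(
            rng.standard_normal((n, 4)), index=cases,
            columns=["impairment", "speed", "irregularity", "hesitation"],
        )
        return pcs, ratings

    def test_monotone_transform_gives_unit_correlation(self):
        pcs, ratings = self._frames()
        ratings["speed"] = np.exp(-pcs["PC1"])  # decreasing monotone
        out = pc_rating_correlations(pcs, ratings)
        assert out.loc["speed", "PC1"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        pcs, ratings = self._frames()
        out = pc_rating_correlations(pcs, ratings)
        assert (out.to_numpy() < 0.15).all()

    def test_entries_bounded(self):
        pcs, ratings = self._frames(n=50, seed=16)
        out = pc_rating_correlations(pcs, ratings)
        vals = out.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_too_few_cases_errors(self):
        pcs, ratings = self._frames(n=3, seed=17)
        with pytest.raises(ValueError):
            pc_rating_correlations(pcs, ratings)
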