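import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoresp.scoring import (
    EvaluationReport,
    auc,
    auc_difference_table,
    classify,
    composite_score,
    evaluate,
    fit_model,
    pearson_correlation,
    roc_curve,
    round_half_up,
    weight_search,
    youden_threshold,
    zscale,
)
from thermoresp.synthetic import sample_feature_table

# ---------------------------------------------------------------- oracles


def roc_oracle(scores, labels):
    """Enumerate every cut point under the >=-threshold rule."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    thresholds = sorted(set(scores), reverse=True)
    thresholds = [max(scores) + 1.0] + thresholds
    pts = []
    for t in thresholds:
        pred = scores >= t
        tpr = (pred & labels).sum() / labels.sum()
        fpr = (pred & ~labels).sum() / (~labels).sum()
        pts.append((fpr, tpr, t))
    return pts


def auc_pairwise_oracle(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def youden_oracle(scores, labels):
    best_j, best_t = -np.inf, None
    for fpr, tpr, t in roc_oracle(scores, labels):
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t, best_j


# ---------------------------------------------------------------- zscale


class TestZscale:
    def test_at_mean_is_zero(self):
        z, mu, sigma = zscale([10.0, 20.0, 30.0])
        assert mu == 20.0
        assert z[1] == 0.0

    def test_one_sigma_above(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        z, mu, sigma = zscale(values)
        assert np.isclose(z[-1], (4.0 - 2.5) / values.std(ddof=0))

    def test_ddof_switch(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        z, _, sigma = zscale(values, ddof=1)
        assert np.isclose(sigma, values.std(ddof=1))

    def test_constant_column_error_names_feature(self):
        with pytest.raises(ValueError, match="'trv'"):
            zscale([5.0, 5.0, 5.0], name="trv")

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=3,
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_output_standardized(self, values):
        values = np.asarray(values)
        if values.std() < 1e-9:
            return
        z, _, _ = zscale(values)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=0) - 1.0) < 1e-9


# ---------------------------------------------------------------- composite


class TestCompositeScore:
    def test_zero_z_any_weights(self):
        assert composite_score([0, 0, 0, 0], [48, 3, 46, 33]) == 0.0

    def test_unit_z_selected_weights_is_130(self):
        # arithmetic with the published weight vector
        assert composite_score([1, 1, 1, 1], [48, 3, 46, 33]) == 130.0

    def test_subset_drops_term_exactly(self):
        full = composite_score([1.0, 2.0, 3.0, 4.0], [48, 3, 46, 33])
        without_ade = composite_score([1.0, 3.0, 4.0], [48, 46, 33])
        assert full - without_ade == 2.0 * 3

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="align"):
            composite_score([1, 2, 3], [1, 2])


# ---------------------------------------------------------------- roc / auc


class TestRocCurve:
    def test_perfect_separation_hits_corner(self):
        fpr, tpr, _ = roc_curve([1, 2, 10, 11], [0, 0, 1, 1])
        assert any(f == 0 and t == 1 for f, t in zip(fpr, tpr))

    def test_all_ties_trivial_points(self):
        fpr, tpr, _ = roc_curve([5, 5, 5, 5], [0, 1, 0, 1])
        assert set(zip(fpr, tpr)) == {(0.0, 0.0), (1.0, 1.0)}

    def test_monotone_curve(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=12)
        labels = rng.integers(0, 2, 12)
        labels[0], labels[1] = 0, 1
        fpr, tpr, _ = roc_curve(scores, labels)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=8), 1)  # provoke ties
        labels = rng.integers(0, 2, 8)
        labels[:2] = [0, 1]
        got = list(zip(*roc_curve(scores, labels)))
        assert got == pytest.approx(roc_oracle(scores, labels))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1, 2, 3], [1, 1, 1])


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 10, 11], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert auc([3, 3, 3, 3], [0, 1, 0, 1]) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=12), 1)
        labels = np.array([0] * 6 + [1] * 6)
        assert auc(scores, labels) == pytest.approx(auc_pairwise_oracle(scores, labels))

    def test_equals_trapezoid_area(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=12)
        labels = np.array([0] * 6 + [1] * 6)
        fpr, tpr, _ = roc_curve(scores, labels)
        assert auc(scores, labels) == pytest.approx(np.trapezoid(tpr, fpr))

    @pytest.mark.parametrize("transform", [np.exp, lambda s: 3 * s + 7, np.arctan])
    def test_invariant_under_monotone_transform(self, transform):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=12)
        labels = np.array([0, 1] * 6)
        assert auc(scores, labels) == pytest.approx(auc(transform(scores), labels))


class TestYoudenThreshold:
    def test_separable_case_perfect(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [0, 0, 1, 1]
        thr, j = youden_threshold(scores, labels)
        assert j == 1.0
        assert np.array_equal(classify(scores, thr), np.array(labels, bool))

    def test_all_ties_zero(self):
        _, j = youden_threshold([2, 2, 2, 2], [0, 1, 0, 1])
        assert j == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=10), 1)
        labels = rng.integers(0, 2, 10)
        labels[:2] = [0, 1]
        _, j = youden_threshold(scores, labels)
        _, j_oracle = youden_oracle(scores, labels)
        assert j == pytest.approx(j_oracle)

    def test_published_sens_spec_imply_youden(self):
        # sensitivity 0.95 and specificity 0.75 give J = 0.70
        report = EvaluationReport(tp=19, fn=1, tn=15, fp=5)
        assert report.youden == pytest.approx(0.70)


class TestClassify:
    def test_boundary_inclusive(self):
        assert classify([5.0], 5.0)[0]

    def test_below_threshold_negative(self):
        assert not classify([5.0 - 1e-9], 5.0)[0]

    def test_raising_trv_never_unflips_positive(self):
        df = sample_feature_table(6, rng_seed=3)
        y = df["label"].astype(bool).to_numpy()
        model, _ = fit_model(df, y, {"trv": 48, "ade_s": 3, "adi_s": 46, "trr": 33})
        pred = model.predict(df)
        bumped = df.copy()
        bumped["trv"] = bumped["trv"] + 1e6
        pred_b = model.predict(bumped)
        assert np.all(pred_b[pred])  # positives stay positive


# ---------------------------------------------------------------- evaluate


class TestEvaluate:
    def test_printed_confusion_counts(self):
        report = EvaluationReport(tp=19, fn=1, tn=15, fp=5)
        assert report.precision_pos == pytest.approx(19 / 24)
        assert report.recall_pos == pytest.approx(19 / 20)
        assert report.accuracy == pytest.approx(34 / 40)
        assert report.precision_neg == pytest.approx(15 / 16)
        assert report.recall_neg == pytest.approx(15 / 20)

    def test_perfect_predictions(self):
        y = [0, 0, 1, 1]
        report = evaluate(y, y)
        d = report.to_dict()
        for key in ("precision_pos", "recall_pos", "f1_pos", "accuracy", "specificity"):
            assert d[key] == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_random_counts_match_formulae(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 2, 30).astype(bool)
        y_true[:2] = [0, 1]
        y_pred = rng.integers(0, 2, 30).astype(bool)
        r = evaluate(y_true, y_pred)
        tp = int((y_true & y_pred).sum())
        fp = int((~y_true & y_pred).sum())
        fn = int((y_true & ~y_pred).sum())
        tn = int((~y_true & ~y_pred).sum())
        assert (r.tp, r.fp, r.fn, r.tn) == (tp, fp, fn, tn)
        assert r.precision_pos == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
        assert r.f1_neg == pytest.approx(
            2 * tn / (2 * tn + fn + fp) if tn else 0.0
        )
        assert r.tp + r.fn == y_true.sum()
        assert r.tn + r.fp == (~y_true).sum()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            evaluate([0, 1], [0, 1, 1])

    def test_round_half_up(self):
        assert round_half_up(0.005) == 0.01
        assert round_half_up(0.835) == 0.84
        assert round_half_up(19 / 24) == 0.79


# ---------------------------------------------------------------- search


class TestWeightSearch:
    def _separable_cohort(self):
        df = sample_feature_table(6, rng_seed=0)
        df.loc[df.label == 1, "trv"] = np.linspace(2e6, 3e6, 6)
        df.loc[df.label == 0, "trv"] = np.linspace(1e5, 2e5, 6)
        return df, df["label"].astype(bool).to_numpy()

    def test_separable_trv_perfect_accuracy(self):
        df, y = self._separable_cohort()
        for seed in (0, 1, 2):
            model, _ = weight_search(df, y, n_iter=20, rng_seed=seed)
            assert model.accuracy == 1.0

    def test_same_seed_same_weights(self):
        df, y = self._separable_cohort()
        m1, log1 = weight_search(df, y, n_iter=50, rng_seed=7)
        m2, log2 = weight_search(df, y, n_iter=50, rng_seed=7)
        assert m1.weights == m2.weights
        assert m1.threshold == m2.threshold
        assert log1.equals(log2)

    def test_default_cohort_beats_youden_criterion(self):
        # moderately-spread two-group simulation from the published means
        for seed in (1, 2, 3):
            df = sample_feature_table(20, rng_seed=seed)
            y = df["label"].astype(bool).to_numpy()
            model, _ = weight_search(df, y, n_iter=300, rng_seed=seed)
            assert model.youden > 0.70
            assert not model.below_criteria

    def test_single_iteration_reduces_to_one_candidate(self):
        df, y = self._separable_cohort()
        model, log = weight_search(df, y, n_iter=1, rng_seed=5)
        assert len(log) == 1
        drawn = {f: float(log.iloc[0][f"w_{f}"]) for f in model.feature_subset}
        assert model.weights == drawn
        refit, _ = fit_model(df, y, drawn)
        assert refit.threshold == model.threshold

    def test_no_candidate_flags_below_criteria(self):
        # labels orthogonal to every feature: Youden cannot exceed 0.70
        df = pd.DataFrame(
            {
                "trv": [1.0, 2.0, 1.0, 2.0, 1.0, 2.0],
                "ade_s": [1.0, 2.0, 1.0, 2.0, 1.0, 2.0],
                "adi_s": [1.0, 2.0, 1.0, 2.0, 1.0, 2.0],
                "trr": [1.0, 2.0, 1.0, 2.0, 1.0, 2.0],
            }
        )
        y = np.array([0, 0, 1, 1, 0, 1], bool)
        model, _ = weight_search(df, y, n_iter=10, rng_seed=0)
        assert model.below_criteria

    def test_search_log_columns(self):
        df, y = self._separable_cohort()
        _, log = weight_search(df, y, n_iter=5, rng_seed=0)
        assert {"iteration", "w_trv", "youden", "accuracy", "recall_pos"} <= set(log.columns)

    def test_weights_inside_range(self):
        df, y = self._separable_cohort()
        model, log = weight_search(df, y, n_iter=30, rng_seed=3)
        for f in model.feature_subset:
            assert 1 <= model.weights[f] <= 50
            assert log[f"w_{f}"].between(1, 50).all()

    def test_dominant_trv_gets_top_weight_more_than_chance(self):
        hits = 0
        for seed in range(10):
            df = sample_feature_table(15, rng_seed=seed + 100)
            # amplify the TRV effect so it dominates separation
            df.loc[df.label == 1, "trv"] += 5e5
            y = df["label"].astype(bool).to_numpy()
            model, _ = weight_search(df, y, n_iter=100, rng_seed=seed)
            top = max(model.weights, key=model.weights.get)
            hits += top == "trv"
        assert hits >= 4  # chance level is 1/4 over 10 runs

    def test_three_factor_subset(self):
        df, y = self._separable_cohort()
        subset = ["trv", "adi_s", "trr"]
        model, _ = weight_search(df, y, n_iter=20, rng_seed=0, feature_subset=subset)
        assert model.feature_subset == subset
        assert set(model.weights) == set(subset)


# ---------------------------------------------------------------- misc


class TestAucDifferenceTable:
    def test_feature_equal_to_composite_zero_difference(self):
        df = pd.DataFrame({"trv": [1.0, 2.0, 3.0, 4.0]})
        labels = [0, 0, 1, 1]
        table = auc_difference_table(
            df, labels, df["trv"], {"trv": 0.05}, feature_subset=["trv"]
        )
        assert table.observed_difference[0] == 0.0
        assert not table.mcid_met[0]

    def test_differences_are_exact_subtractions(self):
        df = sample_feature_table(8, rng_seed=2)
        y = df["label"].astype(bool).to_numpy()
        scores = df["trv"] + df["trr"]
        table = auc_difference_table(
            df, y, scores, {f: 0.1 for f in ("trv", "ade_s", "adi_s", "trr")}
        )
        for _, row in table.iterrows():
            assert row.observed_difference == row.composite_auc - row.feature_auc
            assert row.feature_auc == pytest.approx(auc(df[row.feature], y))

    def test_half_point_difference(self):
        # composite separates perfectly (AUC 1.0), feature is all ties (0.5)
        df = pd.DataFrame({"trv": [5.0, 5.0, 5.0, 5.0]})
        labels = [0, 0, 1, 1]
        table = auc_difference_table(
            df, labels, [1.0, 2.0, 3.0, 4.0], {"trv": 0.1}, feature_subset=["trv"]
        )
        assert table.observed_difference[0] == 0.5
        assert table.mcid_met[0]


class TestPearsonCorrelation:
    def test_feature_equals_label(self):
        assert pearson_correlation([0, 1, 0, 1], [0, 1, 0, 1]) == pytest.approx(1.0)

    def test_feature_negated_label(self):
        assert pearson_correlation([1, 0, 1, 0], [0, 1, 0, 1]) == pytest.approx(-1.0)

    def test_toy_table_matches_formula(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        r = pearson_correlation(x, y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        assert r == pytest.approx(cov / (x.std() * y.std()))

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([2, 2, 2, 2], [0, 1, 0, 1])
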