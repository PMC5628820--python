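"""Design encoding, penalized paths, Boruta, forest tuning and evaluation."""

import numpy as np
import pandas as pd
import pytest

import phenostrat as ps
from phenostrat.supervised import (
    ALPHA_GRID,
    NTREE_GRID,
    OrdinalScheme,
    _pick,
    _refit,
    lambda_max,
)

from conftest import make_matrix


def toy_cohort(n_per_class=20, n_noise=9, seed=0, signal=1.0):
    """Three classes, one (near-)deterministic feature among noise."""
    rng = np.random.default_rng(seed)
    classes = ["K", "P", "V"]
    y, key = [], []
    for c in classes:
        y += [c] * n_per_class
        for _ in range(n_per_class):
            if rng.random() < signal:
                key.append({"K": "a", "P": "b", "V": "c"}[c])
            else:
                key.append(rng.choice(["a", "b", "c"]))
    cols = {"key": key}
    for j in range(n_noise):
        cols[f"noise{j}"] = list(rng.choice(["a", "b", "c"], size=len(y)))
    return make_matrix(cols, labels=y)


class TestEncodeDesign:
    def test_three_level_feature_gets_two_columns(self):
        m = make_matrix({"f": ["a", "b", "c", "a"]})
        design = ps.encode_design(m)
        assert len(design.column_ids) == 2
        assert all(design.parent[c] == "f" for c in design.column_ids)

    def test_reference_is_modal_level(self):
        m = make_matrix({"f": ["b", "b", "b", "a"]})
        design = ps.encode_design(m)
        assert design.scheme["f"][0] == "b"
        assert design.column_ids == ["f=a"]

    def test_row_sums_within_feature_are_zero_or_one(self, small_clean):
        design = ps.encode_design(small_clean)
        for f in small_clean.feature_ids:
            cols = [i for i, c in enumerate(design.column_ids) if design.parent[c] == f]
            sums = design.X[:, cols].sum(axis=1)
            assert set(np.unique(sums)) <= {0.0, 1.0}

    def test_parents_partition_columns_into_features(self, small_clean):
        design = ps.encode_design(small_clean)
        assert set(design.parent.values()) == set(small_clean.feature_ids)

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ps.encode_design(make_matrix({"f": ["a", "a", "a"]}))

    def test_transform_errors_on_absent_feature(self):
        design = ps.encode_design(make_matrix({"f": ["a", "b"], "g": ["x", "y"]}))
        with pytest.raises(ValueError, match="'g'"):
            design.transform(make_matrix({"f": ["a", "b"]}))

    def test_unseen_level_encodes_as_reference(self):
        design = ps.encode_design(make_matrix({"f": ["a", "a", "b"]}))
        X = design.transform(make_matrix({"f": ["z"]}))
        assert np.all(X == 0.0)


class TestSplit:
    def test_study_shaped_split_realizes_7_4_5(self):
        m = ps.generate_extreme(ps.default_spec(seed=1))
        train, test = ps.split_train_test(m, 0.9, seed=1)
        assert test.n_samples == 16 and train.n_samples == 131
        assert test.labels.value_counts().to_dict() == {
            "Vata": 7, "Kapha": 5, "Pitta": 4}

    def test_union_disjoint(self, small_clean):
        train, test = ps.split_train_test(small_clean, 0.9, seed=3)
        assert set(train.sample_ids).isdisjoint(test.sample_ids)
        assert sorted(train.sample_ids + test.sample_ids) == sorted(small_clean.sample_ids)

    def test_fraction_one_gives_empty_test(self, small_clean):
        train, test = ps.split_train_test(small_clean, 1.0, seed=0)
        assert test.n_samples == 0 and train.n_samples == small_clean.n_samples

    def test_tiny_class_rejected(self):
        m = make_matrix({"f": ["a", "b", "a"]}, labels=["x", "x", "y"])
        with pytest.raises(ValueError):
            ps.split_train_test(m, 0.9, seed=0)


class TestLasso:
    def test_informative_feature_found_and_holdout_perfect(self):
        m = toy_cohort(n_per_class=22, seed=1)
        train, test = ps.split_train_test(m, 0.9, seed=1)
        model = ps.fit_lasso(train, seed=1)
        assert "key" in model.selected_features
        assert ps.evaluate(model, test).overall_accuracy == 1.0

    def test_all_coefficients_zero_at_lambda_max(self):
        m = toy_cohort(seed=2)
        design = ps.encode_design(m)
        y = m.labels.to_numpy()
        lam = lambda_max(design.X, y, alpha=1.0)
        lr = _refit(design.X, y, lam, 1.0)
        assert np.max(np.abs(lr.coef_)) < 1e-6

    def test_permuted_labels_give_chance_error_and_few_features(self):
        # 180 samples so the min-over-path CV error's selection optimism
        # stays within the 0.1 band around the 2/3 chance rate
        rng = np.random.default_rng(4)
        m = toy_cohort(n_per_class=60, n_noise=14, seed=4)
        m.labels = pd.Series(rng.permutation(m.labels.to_numpy()), index=m.data.index)
        model = ps.fit_lasso(m, seed=4)
        cv_err = min(e for _, _, e in model.cv_error_path)
        assert cv_err == pytest.approx(2 / 3, abs=0.1)
        assert len(model.selected_features) <= 5

    def test_nonzero_count_monotone_along_path(self):
        m = toy_cohort(n_per_class=15, seed=5, signal=0.9)
        design = ps.encode_design(m)
        y = m.labels.to_numpy()
        lams = lambda_max(design.X, y, 1.0) * np.logspace(0, -3, 8)
        nnz = [int((np.abs(_refit(design.X, y, lam, 1.0).coef_).max(axis=0) > 1e-8).sum())
               for lam in lams]
        assert all(b >= a - 1 for a, b in zip(nnz, nnz[1:]))  # tolerance 1
        assert nnz[0] == 0 and nnz[-1] > 0


class TestElasticNet:
    def test_alpha_grid_has_eleven_values(self):
        assert len(ALPHA_GRID) == 11
        assert ALPHA_GRID[0] == 0.0 and ALPHA_GRID[-1] == 1.0

    def test_alpha_one_reproduces_lasso(self):
        m = toy_cohort(n_per_class=15, seed=6)
        lasso = ps.fit_lasso(m, seed=6)
        enet = ps.fit_enet(m, seed=6)
        if enet.alpha == 1.0 and enet.lambda_star == pytest.approx(lasso.lambda_star):
            assert np.allclose(enet.coef, lasso.coef, atol=1e-8)
        design = ps.encode_design(m)
        y = m.labels.to_numpy()
        a = _refit(design.X, y, lasso.lambda_star, 1.0)
        assert np.allclose(a.coef_, lasso.coef, atol=1e-8)

    def test_grouping_keeps_correlated_duplicates_together(self):
        m = toy_cohort(n_per_class=25, n_noise=5, seed=7, signal=0.95)
        m.data["key_copy"] = m.data["key"]
        design = ps.encode_design(m)
        y = m.labels.to_numpy()
        lam = lambda_max(design.X, y, 0.5) * 0.05
        lr = _refit(design.X, y, lam, 0.5)
        cols = {c: i for i, c in enumerate(design.column_ids)}
        _, other_levels = design.scheme["key"]  # non-reference levels
        for level in other_levels:
            c1 = lr.coef_[:, cols[f"key={level}"]]
            c2 = lr.coef_[:, cols[f"key_copy={level}"]]
            big = np.abs(c1) > 1e-4
            assert big.any()
            assert np.all(np.sign(c1[big]) == np.sign(c2[big]))
            assert np.all(np.abs(c2[big]) > 1e-6)


class TestBoruta:
    def test_planted_confirmed_noise_rejected(self):
        spec = ps.CohortSpec(n_per_class=(25, 25, 25), n_features=24, n_informative=6,
                             n_blocks=4, signal_strength=0.9, block_coupling=0.0,
                             missing_rate=0.0, seed=8)
        m = ps.generate_extreme(spec)
        res = ps.boruta(m, max_runs=40, seed=8, n_trees=200)
        informative = set(spec.feature_ids[:6])
        assert informative <= set(res.confirmed)
        noise = set(spec.feature_ids[6:])
        assert len(noise & set(res.rejected)) >= 0.95 * len(noise)

    def test_permuted_labels_confirm_nothing(self):
        # n=150: large enough that in-sample chance associations (which
        # Boruta genuinely detects) stay below the shadow bar, and enough
        # runs for the binomial test to reject instead of leaving leftovers
        # to the coarser tentative-resolution rule
        spec = ps.CohortSpec(n_per_class=(50, 50, 50), n_features=12, n_informative=6,
                             n_blocks=3, signal_strength=0.9, block_coupling=0.0,
                             missing_rate=0.0, seed=9)
        confirmed_runs = 0
        for rep in range(10):
            m = ps.generate_extreme(spec)
            rng = np.random.default_rng(rep)
            m.labels = pd.Series(rng.permutation(m.labels.to_numpy()), index=m.data.index)
            res = ps.boruta(m, max_runs=30, seed=rep, n_trees=100)
            confirmed_runs += bool(res.confirmed)
        assert confirmed_runs <= 1

    def test_minimum_run_count_enforced(self, small_clean):
        with pytest.raises(ValueError):
            ps.boruta(small_clean, max_runs=6)

    def test_hit_counts_cover_all_features(self, small_clean):
        sub = small_clean.select_features(small_clean.feature_ids[:10])
        res = ps.boruta(sub, max_runs=10, seed=1, n_trees=50)
        assert set(res.hit_counts) == set(sub.feature_ids)
        assert set(res.confirmed) | set(res.rejected) | set(res.tentative) \
            == set(sub.feature_ids)


class TestForestTuning:
    def test_default_ntree_grid_has_twenty_candidates(self):
        assert len(NTREE_GRID) == 20
        assert NTREE_GRID[0] == 500 and NTREE_GRID[-1] == 10_000

    def test_selection_rule_least_median_then_sd_then_size(self):
        grid = (500, 1000, 1500)
        assert _pick(grid, [0.2, 0.1, 0.1], [0.05, 0.02, 0.01]) == 1500
        assert _pick(grid, [0.1, 0.1, 0.2], [0.02, 0.02, 0.0]) == 500
        assert _pick(grid, [0.3, 0.1, 0.2], [0.1, 0.5, 0.0]) == 1000

    def test_reproducible_and_accurate_on_strong_signal(self):
        m = toy_cohort(n_per_class=20, n_noise=4, seed=10)
        kw = dict(ntree_grid=(50, 100), mtry_grid=(1, 2), n_repeats=2)
        f1 = ps.tune_forest(m, m.feature_ids, seed=10, **kw)
        f2 = ps.tune_forest(m, m.feature_ids, seed=10, **kw)
        assert (f1.ntree_star, f1.mtry_star) == (f2.ntree_star, f2.mtry_star)
        assert f1.oob_error <= 0.05
        assert ps.evaluate(f1, m).overall_accuracy == 1.0

    def test_empty_feature_list_rejected(self, small_clean):
        with pytest.raises(ValueError):
            ps.tune_forest(small_clean, [], seed=0)


class TestPrediction:
    def test_probabilities_sum_to_one(self, small_clean):
        m = toy_cohort(seed=11)
        model = ps.fit_lasso(m, seed=11)
        proba = ps.predict_proba(model, m)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert proba.to_numpy().min() >= 0

    def test_zero_coefficients_give_identical_rows(self):
        m = toy_cohort(seed=12)
        design = ps.encode_design(m)
        y = m.labels.to_numpy()
        lam = lambda_max(design.X, y, 1.0)
        lr = _refit(design.X, y, lam, 1.0)
        model = ps.PenalizedModel("lasso", 1.0, lam, list(lr.classes_), lr.coef_,
                                  lr.intercept_, design, [], [], 10)
        proba = model.predict_proba(m).to_numpy()
        assert np.allclose(proba, proba[0], atol=1e-6)

    def test_unanimous_forest_votes_are_one_hot(self):
        m = toy_cohort(n_per_class=15, n_noise=0, seed=13)
        f = ps.tune_forest(m, ["key"], seed=13, ntree_grid=(60,), mtry_grid=(1,),
                           n_repeats=2)
        proba = f.predict_proba(m).to_numpy()
        assert set(np.unique(proba)) <= {0.0, 1.0}


class TestEvaluate:
    def test_perfect_prediction_scores_100(self):
        m = toy_cohort(seed=14)
        model = ps.fit_lasso(m, seed=14)
        rep = ps.evaluate(model, m)
        assert rep.overall_accuracy == 1.0
        assert all(v == 1.0 for v in rep.sensitivity.values())
        assert all(v == 1.0 for v in rep.specificity.values())

    def test_sensitivity_arithmetic(self):
        class Stub:
            def predict_proba(self, m):
                probs = []
                for s in m.sample_ids:
                    cls = truth[s] if s not in flipped else "P"
                    probs.append([1.0 if c == cls else 0.0 for c in ("K", "P", "V")])
                return pd.DataFrame(probs, index=m.sample_ids, columns=["K", "P", "V"])

        samples = [f"s{i}" for i in range(29 + 10)]
        truth = {s: ("K" if i < 29 else "V") for i, s in enumerate(samples)}
        flipped = {"s0", "s1"}  # two Kapha samples misread as Pitta
        m = make_matrix({"f": ["a"] * 39}, labels=[truth[s] for s in samples],
                        samples=samples)
        rep = ps.evaluate(Stub(), m)
        assert rep.sensitivity["K"] == pytest.approx(27 / 29)
        assert round(100 * rep.sensitivity["K"], 1) == 93.1

    def test_confusion_rows_sum_to_truth_counts(self, small_clean):
        model = ps.fit_lasso(*[ps.split_train_test(small_clean, 0.9, 5)[0]], seed=5)
        rep = ps.evaluate(model, small_clean)
        assert rep.confusion.sum(axis=1).to_dict() == \
            small_clean.labels.value_counts().sort_index().to_dict()
        assert rep.overall_accuracy == pytest.approx(
            np.trace(rep.confusion.to_numpy()) / small_clean.n_samples)


class TestHarmonize:
    def test_identity_when_feature_sets_match(self, small_clean):
        a, b, shared = ps.harmonize_features(small_clean, small_clean)
        assert shared == small_clean.feature_ids and a == small_clean

    def test_restriction_to_intersection(self, small_model, small_spec):
        a = small_model.generate_extreme()
        b = small_model.generate_second_cohort(30, (5, 5, 5))
        a2, b2, shared = ps.harmonize_features(a, b)
        assert len(shared) == 30 and a2.feature_ids == b2.feature_ids

    def test_disjoint_rejected(self):
        a = make_matrix({"f": ["a", "b"]})
        b = make_matrix({"g": ["a", "b"]})
        with pytest.raises(ValueError):
            ps.harmonize_features(a, b)


class TestCrossCohort:
    def test_same_cohort_matches_in_cohort_evaluation(self, small_clean):
        rep, model = ps.cross_cohort_validate(small_clean, small_clean, "lasso", seed=2)
        direct = ps.evaluate(model, small_clean)
        assert rep.confusion.equals(direct.confusion)
        assert rep.overall_accuracy == direct.overall_accuracy
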