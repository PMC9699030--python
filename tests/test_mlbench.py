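"""Preprocessing, stratified split, benchmark and permutation importance."""

import numpy as np
import pandas as pd
import pytest

from cisdose import (
    benchmark,
    permutation_importance,
    preprocess,
    stratified_split,
)


def make_cohort_frame(n=80, seed=0, signal="cmax"):
    """Covariates + exposure with benefit driven by the chosen feature."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "age": rng.normal(58, 11, n),
        "sex": rng.choice(["M", "F"], n),
        "cmax_mean": 2.9 * np.exp(rng.normal(0, 0.3, n)),
        "auc_mean": rng.normal(42, 14, n),
        "cmin_mean": np.abs(rng.normal(0.2, 0.15, n)),
    })
    if signal == "cmax":
        p = (1 / (1 + np.exp(-3 * (df.cmax_mean - 2.1)))
             * (1 - 1 / (1 + np.exp(-3 * (df.cmax_mean - 4.1)))))
        df["clinical_benefit"] = rng.random(n) < p
    elif signal == "none":
        df["clinical_benefit"] = rng.random(n) < 0.6
    elif signal == "separable":
        df["clinical_benefit"] = df.cmax_mean > df.cmax_mean.median()
    return df


class TestPreprocess:
    def test_minmax_to_unit_interval(self):
        df = pd.DataFrame({"x": [1.0, 3.0, 5.0],
                           "clinical_benefit": [True, False, True]})
        ft = preprocess(df)
        np.testing.assert_allclose(ft.X["x"], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        df = pd.DataFrame({"x": [7.0, 7.0, 7.0],
                           "clinical_benefit": [True, False, True]})
        ft = preprocess(df)
        np.testing.assert_array_equal(ft.X["x"], [0.0, 0.0, 0.0])

    def test_one_hot_rows_sum_to_one(self):
        df = make_cohort_frame(30)
        ft = preprocess(df)
        sex_cols = [c for c in ft.X.columns if c.startswith("sex_")]
        assert len(sex_cols) == 2
        np.testing.assert_array_equal(ft.X[sex_cols].sum(axis=1), 1.0)

    def test_scaling_learned_on_fit_partition_only(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0],
                           "clinical_benefit": [True, False, True, False]})
        ft = preprocess(df, fit_index=[0, 1, 2])
        np.testing.assert_allclose(ft.X["x"], [0.0, 0.5, 1.0, 5.0])
        assert ft.scaling["x"] == (0.0, 2.0)

    def test_missing_response_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0],
                           "clinical_benefit": [True, None]})
        with pytest.raises(ValueError):
            preprocess(df)

    def test_non_numeric_value_named(self):
        df = pd.DataFrame({"x": [1.0, "oops", 3.0],
                           "y": [1.0, 2.0, 3.0],
                           "clinical_benefit": [True, False, True]})
        df["x"] = df["x"].astype(object)
        with pytest.raises(ValueError, match="x"):
            preprocess(df)


class TestStratifiedSplit:
    def test_prevalence_preserved_at_study_size(self):
        """80 patients with 65 responders -> 56-row train with 45-46."""
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=80)})
        df["clinical_benefit"] = np.array([True] * 65 + [False] * 15)
        ft = preprocess(df)
        idx_train, idx_test = stratified_split(ft, 0.7, seed=3)
        assert len(idx_train) == 56 and len(idx_test) == 24
        assert int(ft.y[idx_train].sum()) in (45, 46)

    def test_reproducible_and_partitioning(self):
        df = make_cohort_frame(60, seed=2)
        ft = preprocess(df)
        a = stratified_split(ft, 0.7, seed=9)
        b = stratified_split(ft, 0.7, seed=9)
        assert list(a[0]) == list(b[0]) and list(a[1]) == list(b[1])
        assert set(a[0]).isdisjoint(a[1])
        assert set(a[0]) | set(a[1]) == set(ft.X.index)

    def test_tiny_class_rejected(self):
        df = pd.DataFrame({"x": np.arange(10.0),
                           "clinical_benefit": [True] * 9 + [False]})
        with pytest.raises(ValueError):
            stratified_split(preprocess(df), 0.7, seed=0)


class TestBenchmark:
    def test_separable_data_reaches_perfect_accuracy(self):
        df = make_cohort_frame(80, seed=4, signal="separable")
        ft = preprocess(df)
        itr, ite = stratified_split(ft, 0.7, seed=0)
        scores, _ = benchmark(ft.X.loc[itr], ft.y[itr],
                              ft.X.loc[ite], ft.y[ite],
                              search_budget=3, seed=0,
                              families=("decision_tree", "glm"))
        assert scores["accuracy"].max() == 1.0

    def test_pure_noise_accuracy_near_prevalence(self):
        df = make_cohort_frame(120, seed=5, signal="none")
        ft = preprocess(df)
        itr, ite = stratified_split(ft, 0.7, seed=0)
        scores, _ = benchmark(ft.X.loc[itr], ft.y[itr],
                              ft.X.loc[ite], ft.y[ite],
                              search_budget=3, seed=0, families=("glm",))
        prev = max(ft.y[ite].mean(), 1 - ft.y[ite].mean())
        n_test = len(ite)
        # binomial 3-sigma band around the majority-class rate
        slack = 3 * np.sqrt(prev * (1 - prev) / n_test)
        assert scores["accuracy"].iloc[0] >= prev - slack - 0.05
        assert scores["accuracy"].iloc[0] <= prev + slack + 0.05

    def test_scores_bounded_and_best_marked(self):
        df = make_cohort_frame(60, seed=6)
        ft = preprocess(df)
        itr, ite = stratified_split(ft, 0.7, seed=0)
        scores, fitted = benchmark(ft.X.loc[itr], ft.y[itr],
                                   ft.X.loc[ite], ft.y[ite],
                                   search_budget=2, seed=0,
                                   families=("naive_bayes", "decision_tree",
                                             "glm"))
        for col in ("accuracy", "recall", "precision"):
            assert scores[col].between(0, 1).all()
        assert scores["best"].sum() == 1
        best_row = scores.loc[scores.best].iloc[0]
        assert best_row["accuracy"] == scores["accuracy"].max()
        assert set(fitted) == {"naive_bayes", "decision_tree", "glm"}


class TestPermutationImportance:
    @pytest.fixture()
    def fitted(self):
        df = make_cohort_frame(100, seed=7)
        df["noise"] = np.random.default_rng(8).normal(size=100)
        ft = preprocess(df)
        itr, ite = stratified_split(ft, 0.7, seed=0)
        scores, models = benchmark(ft.X.loc[itr], ft.y[itr],
                                   ft.X.loc[ite], ft.y[ite],
                                   search_budget=4, seed=0,
                                   families=("glm",))
        return models["glm"], ft.X.loc[ite], ft.y[ite]

    def test_noise_feature_has_near_zero_drop(self, fitted):
        model, X, y = fitted
        imp = permutation_importance(model, X, y, seed=0)
        noise_drop = imp.set_index("feature").loc["noise", "mean_drop"]
        assert abs(noise_drop) <= 0.05

    def test_model_untouched_by_permutation(self, fitted):
        model, X, y = fitted
        before = model.predict(X.values).copy()
        permutation_importance(model, X, y, seed=0)
        np.testing.assert_array_equal(model.predict(X.values), before)

    def test_label_copy_feature_dominates(self):
        """A feature equal to the label drops accuracy to ~prevalence."""
        rng = np.random.default_rng(9)
        n = 200
        y = rng.random(n) < 0.6
        df = pd.DataFrame({"copy": y.astype(float),
                           "junk": rng.normal(size=n),
                           "clinical_benefit": y})
        ft = preprocess(df)
        itr, ite = stratified_split(ft, 0.7, seed=0)
        scores, models = benchmark(ft.X.loc[itr], ft.y[itr],
                                   ft.X.loc[ite], ft.y[ite],
                                   search_budget=3, seed=0,
                                   families=("decision_tree",))
        model = models["decision_tree"]
        imp = permutation_importance(model, ft.X.loc[ite], ft.y[ite],
                                     repeats=10, seed=0)
        drop = imp.set_index("feature").loc["copy", "mean_drop"]
        prev = max(ft.y[ite].mean(), 1 - ft.y[ite].mean())
        baseline = scores["accuracy"].iloc[0]
        # permuted predictions agree with truth about half the time on the
        # shuffled entries; expectation is baseline - (p^2 + (1-p)^2)
        expected = baseline - (prev ** 2 + (1 - prev) ** 2)
        assert drop == pytest.approx(expected, abs=0.1)

    def test_cmax_ranks_first_when_it_drives_outcome(self):
        """Benefit is high inside a Cmax band, so a tree model leans on it."""
        hits = 0
        for seed in range(5):
            df = make_cohort_frame(150, seed=20 + seed, signal="cmax")
            ft = preprocess(df)
            itr, ite = stratified_split(ft, 0.7, seed=seed)
            _, models = benchmark(ft.X.loc[itr], ft.y[itr],
                                  ft.X.loc[ite], ft.y[ite],
                                  search_budget=4, seed=seed,
                                  families=("random_forest",))
            imp = permutation_importance(models["random_forest"],
                                         ft.X.loc[ite], ft.y[ite], seed=seed)
            hits += imp.iloc[0]["feature"] == "cmax_mean"
        assert hits >= 4

    def test_single_row_rejected(self, fitted):
        model, X, y = fitted
        with pytest.raises(ValueError):
            permutation_importance(model, X.iloc[:1], y.iloc[:1])
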