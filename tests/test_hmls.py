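"""Outcome binarization, combinations, ANOVA selection, protocol and t-tests."""

import numpy as np
import pandas as pd
import pytest

from striatome.core import FeatureTable, OutcomeLabels
from striatome.hmls import (
    CLASSIFIER_NAMES,
    COMBO_NAMES,
    HMLSConfig,
    anova_f_scores,
    binarize_moca,
    build_combos,
    evaluate_config,
    labels_from_moca,
    make_classifier,
    paired_ttest,
    run_grid,
    select_top_k,
)
from striatome.phantom import CohortSpec, generate_cohort

from .oracles import anova_f_oracle, paired_t_oracle


def _table(n_rows, cols, tag, seed=0, prefix="f"):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.normal(size=(n_rows, cols)),
        columns=[f"{prefix}{i:02d}" for i in range(cols)],
        index=pd.Index([f"S{i:03d}" for i in range(n_rows)], name="subject_id"),
    )
    return FeatureTable(df, tag)


class TestBinarizeMoca:
    @pytest.mark.parametrize("score,expected", [(27, "normal"), (25, "abnormal"),
                                                (26, "abnormal"), (30, "normal")])
    def test_cutoff_rule(self, score, expected):
        assert binarize_moca(score) == expected

    def test_missing_scores_excluded_with_log(self):
        s = pd.Series([28.0, np.nan, 20.0],
                      index=pd.Index(["a", "b", "c"], name="subject_id"))
        labels, excluded = labels_from_moca(s)
        assert excluded == ["b"]
        assert labels.labels.to_dict() == {"a": 0, "c": 1}


class TestBuildCombos:
    def test_exactly_seven_with_expected_columns(self):
        cf = _table(30, 4, "CF", 1, "cf")
        rf = _table(30, 5, "RF", 2, "rf")
        df = _table(30, 3, "DF", 3, "df")
        combos = build_combos(cf, rf, df)
        assert list(combos) == list(COMBO_NAMES)
        assert combos["CF+RF+DF"].shape[1] == 4 + 5 + 3
        assert combos["CF"].family_counts() == {"CF": 4, "RF": 0, "DF": 0}
        assert combos["RF+DF"].family_counts() == {"CF": 0, "RF": 5, "DF": 3}

    def test_key_mismatch_rejected_listing_subjects(self):
        cf = _table(30, 4, "CF", 1, "cf")
        rf = _table(28, 5, "RF", 2, "rf")
        with pytest.raises(ValueError, match="S028"):
            build_combos(cf, rf, _table(30, 3, "DF", 3, "df"))


class TestAnovaSelection:
    def test_equal_group_means_give_zero(self):
        X = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        assert anova_f_scores(X, y)[0] == pytest.approx(0.0, abs=1e-12)

    def test_printed_toy_groups_match_closed_form(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        f = anova_f_scores(X, y)[0]
        assert f == pytest.approx(13.5)
        assert f == pytest.approx(anova_f_oracle([1, 2, 3], [4, 5, 6]))

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        f1 = anova_f_scores(x[:, None], y)[0]
        f2 = anova_f_scores((3.7 * x - 11.0)[:, None], y)[0]
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_single_member_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_f_scores(X, np.array([0, 0, 0, 1]))

    def test_select_top_k_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        scores = rng.random(20)
        names = [f"f{i}" for i in range(20)]
        sel = select_top_k(scores, names, 7)
        oracle = [names[i] for i in np.argsort(-scores)[:7]]
        assert sel == oracle

    def test_ties_keep_earlier_column(self):
        scores = np.array([1.0, 5.0, 5.0, 0.5])
        assert select_top_k(scores, ["a", "b", "c", "d"], 2) == ["b", "c"]

    def test_k_beyond_feature_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            select_top_k(np.ones(3), ["a", "b", "c"], 4)


class TestEvaluateConfig:
    CFG = HMLSConfig(tuner_method="none", seed=0)

    def test_result_structure_and_bounds(self):
        table, labels, _ = generate_cohort(CohortSpec(n_subjects=100, seed=0))
        res = evaluate_config("CF", table, labels, "ETC", 10, self.CFG)
        assert len(res.cv_accuracies) == 5 and len(res.holdout_accuracies) == 5
        assert all(0 <= a <= 1 for a in res.cv_accuracies + res.holdout_accuracies)
        assert len(res.selected_features) == 10
        assert res.selected_family_counts["CF"] == 10

    def test_same_seed_identical(self):
        table, labels, _ = generate_cohort(CohortSpec(n_subjects=80, seed=1))
        a = evaluate_config("CF", table, labels, "RandF", 5, self.CFG)
        b = evaluate_config("CF", table, labels, "RandF", 5, self.CFG)
        assert a.cv_accuracies == b.cv_accuracies
        assert a.holdout_accuracies == b.holdout_accuracies

    def test_too_few_subjects_rejected(self):
        table, labels, _ = generate_cohort(CohortSpec(n_subjects=20, seed=2))
        with pytest.raises(ValueError, match="25"):
            evaluate_config("CF", table, labels, "KNN", 5, self.CFG)

    def test_label_leak_canary(self):
        """A feature equal to the label yields perfect accuracy only when
        leakage is deliberately enabled outside the protocol: the protocol
        itself must reach it too (the leak is in the data, not the folds),
        while pure-noise features stay near chance."""
        rng = np.random.default_rng(3)
        n = 100
        y = np.array([0, 1] * (n // 2))
        leaky = pd.DataFrame({
            "leak": y.astype(float),
            "noise": rng.normal(size=n),
        }, index=pd.Index([f"S{i}" for i in range(n)], name="subject_id"))
        res = evaluate_config("CF", FeatureTable(leaky, "CF"), y, "ETC", 1, self.CFG)
        assert res.cv_mean == 1.0  # the label-copy feature is legitimately selected
        noise_only = FeatureTable(leaky[["noise"]], "CF")
        res2 = evaluate_config("CF", noise_only, y, "ETC", 1, self.CFG)
        assert res2.cv_mean < 0.7

    def test_noise_padding_does_not_boost_accuracy(self):
        """Appending pure-noise columns must not raise mean CV accuracy by
        more than the CI half-width."""
        table, labels, _ = generate_cohort(CohortSpec(n_subjects=200, seed=4))
        base = evaluate_config("CF", table, labels, "ETC", 10, self.CFG)
        rng = np.random.default_rng(5)
        noisy_df = table.df.copy()
        for i in range(30):
            noisy_df[f"noise_{i}"] = rng.normal(size=len(noisy_df))
        noisy = FeatureTable(noisy_df, "CF")
        padded = evaluate_config("CF", noisy, labels, "ETC", 10, self.CFG)
        half_width = 1.96 * np.sqrt(0.25 / 160)
        assert padded.cv_mean <= base.cv_mean + half_width


class TestRunGrid:
    def test_grid_dimensions(self):
        cf = _table(40, 6, "CF", 1, "cf")
        rf = _table(40, 6, "RF", 2, "rf")
        df = _table(40, 6, "DF", 3, "df")
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 40)
        y[:4] = [0, 1, 0, 1]
        combos = build_combos(cf, rf, df)
        cfg = HMLSConfig(k_grid=(5,), classifiers=("KNN", "ETC"),
                         tuner_method="none", seed=0)
        grid = run_grid(combos, y, cfg)
        assert len(grid.results) == 7 * 2 * 1
        hm = grid.heatmap_table(5)
        assert hm.shape == (7, 2)

    def test_best_cell_ties_prefer_smaller_k(self):
        rows = pd.DataFrame({
            "combo": ["CF"] * 2, "classifier": ["KNN"] * 2, "k": [20, 10],
            "cv_mean": [0.8, 0.8], "cv_std": [0, 0],
            "holdout_mean": [0.7, 0.7], "holdout_std": [0, 0],
            "n_selected": [20, 10], "selected_cf": [0, 0],
            "selected_rf": [0, 0], "selected_df": [0, 0], "error": ["", ""],
        })
        sub = rows.sort_values(["cv_mean", "k"], ascending=[False, True], kind="stable")
        assert sub.iloc[0]["k"] == 10


class TestPairedTTest:
    def test_identical_vectors(self):
        t, p = paired_ttest([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference_sentinel(self):
        t, p = paired_ttest([0.8, 0.9, 0.7], [0.7, 0.8, 0.6])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(5), rng.random(5)
        t, p = paired_ttest(a, b)
        assert t == pytest.approx(paired_t_oracle(a, b))
        assert 0 <= p <= 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([0.1, 0.2], [0.1])


def test_all_eight_classifiers_constructible_and_fittable():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 5))
    y = rng.integers(0, 2, 30)
    y[:2] = [0, 1]
    for name in CLASSIFIER_NAMES:
        clf = make_classifier(name, seed=0)
        clf.fit(X, y)
        assert clf.predict(X).shape == (30,)
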