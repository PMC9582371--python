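"""Trial categorization, SC/NSC classification, and behavioral statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from selfcontrol_fmri import behavior


def make_profile(health, taste, gv):
    n = len(health)
    return pd.DataFrame({
        "stimulus_id": [f"stim{i:03d}" for i in range(n)],
        "health": np.asarray(health, dtype=float),
        "taste": np.asarray(taste, dtype=float),
        "gv": np.asarray(gv, dtype=float),
    })


class TestCategorization:
    @pytest.mark.parametrize(
        "h,t,gv,requires,success",
        [
            (-2, 2, -1, True, True),    # declined liked-unhealthy
            (-1, 1, 2, True, False),    # accepted liked-unhealthy
            (-2, 0, -2, False, False),  # taste-neutral: no conflict
            (2, -1, 1, True, True),     # chose disliked-healthy
            (2, -1, 0, True, False),    # neutral decision counts as failure
            (1, 2, 2, False, False),    # liked-healthy: no conflict
        ],
    )
    def test_definitional_cases(self, h, t, gv, requires, success):
        prof = make_profile([h], [t], [gv])
        cats = behavior.categorize_trials(prof)
        assert bool(cats["requires_self_control"][0]) is requires
        assert bool(cats["self_control_success"][0]) is success

    def test_missing_rating_excludes_from_conflict(self):
        prof = make_profile([np.nan], [2], [-1])
        cats = behavior.categorize_trials(prof)
        assert not cats["requires_self_control"][0]

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(ValueError, match="-2"):
            behavior.categorize_trials(make_profile([3], [0], [0]))


def boundary_profile():
    """Exactly half of the self-control trials succeed (rate = 0.5)."""
    # four liked-unhealthy conflicts: two declined, two accepted; filler
    # stimuli vary both ratings so the choice regressions are defined.
    return make_profile(
        health=[-1, -1, -1, -1, 2, 1, 0, -2],
        taste=[1, 1, 2, 2, 1, 0, 0, -2],
        gv=[-1, 1, -2, 2, 2, -1, 0, -2],
    )


class TestClassification:
    def test_boundary_rate_half(self):
        prof = boundary_profile()
        one = behavior.classify_participant(prof, "one_criterion")
        assert one.criterion1_rate == 0.5
        assert one.label == "SC"
        three = behavior.classify_participant(prof, "three_criteria")
        assert three.criterion1_rate == 0.5
        assert three.label != "SC"  # criterion 1 requires strictly > 0.5

    def test_always_yes_to_liked_unhealthy_is_nsc(self):
        prof = make_profile(
            health=[-1, -1, -2, 1, 2, 0],
            taste=[1, 2, 1, 1, -1, 0],
            gv=[2, 2, 1, 2, -1, 0],
        )
        res = behavior.classify_participant(prof, "one_criterion")
        assert res.criterion1_rate == 0.0
        assert res.label == "NSC"

    def test_no_required_trials_unclassified(self):
        prof = make_profile([1, 2, 0, 1], [1, 2, 0, 2], [1, 2, 0, 1])
        res = behavior.classify_participant(prof, "three_criteria")
        assert res.label == "unclassified"
        assert "self-control" in res.diagnostics

    def test_missing_decisions_excluded_from_rate(self):
        prof = make_profile(
            health=[-1, -1, -1, 2, 1, -2],
            taste=[1, 1, 1, 1, 0, -1],
            gv=[-1, np.nan, 1, 2, 1, -1],
        )
        res = behavior.classify_participant(prof, "one_criterion")
        assert res.n_required == 2
        assert res.criterion1_rate == 0.5

    def test_classification_invariant_to_stimulus_order(self):
        prof = boundary_profile()
        rng = np.random.default_rng(0)
        shuffled = prof.sample(frac=1, random_state=3).reset_index(drop=True)
        for mode in ("one_criterion", "three_criteria"):
            a = behavior.classify_participant(prof, mode)
            b = behavior.classify_participant(shuffled, mode)
            assert a.label == b.label
            assert a.criterion1_rate == b.criterion1_rate


class TestChoiceRegressions:
    def test_gv_equals_health(self):
        rng = np.random.default_rng(0)
        h = rng.integers(-2, 3, 30).astype(float)
        t = rng.integers(-2, 3, 30).astype(float)
        b_h, b_t, r2_h, r2_t = behavior.choice_regressions(
            make_profile(h, t, h))
        assert b_h == pytest.approx(1.0, abs=1e-10)
        assert b_t == pytest.approx(0.0, abs=1e-10)
        assert r2_h == pytest.approx(1.0, abs=1e-10)

    def test_gv_equals_taste_r2_is_squared_correlation(self):
        rng = np.random.default_rng(1)
        h = rng.integers(-2, 3, 40).astype(float)
        t = rng.integers(-2, 3, 40).astype(float)
        _, _, r2_h, r2_t = behavior.choice_regressions(make_profile(h, t, t))
        assert r2_t == pytest.approx(1.0, abs=1e-10)
        assert r2_h == pytest.approx(np.corrcoef(h, t)[0, 1] ** 2, abs=1e-10)

    def test_matches_normal_equation_oracle(self):
        """OLS implementation equals the closed-form normal equations on
        random instances."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(5, 40)
            h = rng.standard_normal(n)
            t = rng.standard_normal(n)
            gv = rng.standard_normal(n)
            prof = pd.DataFrame({
                "stimulus_id": [f"s{i}" for i in range(n)],
                "health": np.clip(h, -2, 2), "taste": np.clip(t, -2, 2),
                "gv": np.clip(gv, -2, 2)})
            b_h, b_t, r2_h, r2_t = behavior.choice_regressions(prof)
            X = np.column_stack([np.ones(n), prof["health"], prof["taste"]])
            y = prof["gv"].to_numpy()
            oracle = np.linalg.solve(X.T @ X, X.T @ y)
            assert b_h == pytest.approx(oracle[1], abs=1e-10)
            assert b_t == pytest.approx(oracle[2], abs=1e-10)

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError, match="taste"):
            behavior.choice_regressions(
                make_profile([1, -1, 2, 0], [1, 1, 1, 1], [1, -1, 2, 0]))


class TestGroupTable:
    def _profiles(self, rng, n, shift=0.0):
        out = []
        for _ in range(n):
            h = rng.integers(-2, 3, 20).astype(float)
            t = rng.integers(-2, 3, 20).astype(float)
            gv = np.clip(np.round(0.5 * t + shift
                                  + rng.normal(0, 1, 20)), -2, 2)
            out.append(make_profile(h, t, gv))
        return out

    def test_identical_groups_t_zero(self):
        rng = np.random.default_rng(0)
        profs = self._profiles(rng, 4)
        tables = behavior.group_choice_table(profs + profs,
                                             ["SC"] * 4 + ["NSC"] * 4)
        props = tables["proportions"]
        assert np.allclose(props["t"], 0.0)
        assert np.allclose(props["p"], 1.0)

    def test_identical_mean_ratings_r_one(self):
        rng = np.random.default_rng(1)
        profs = self._profiles(rng, 4)
        tables = behavior.group_choice_table(profs + profs,
                                             ["SC"] * 4 + ["NSC"] * 4)
        assert np.allclose(tables["correlations"]["r"], 1.0)

    def test_pooled_df(self):
        rng = np.random.default_rng(2)
        profs = self._profiles(rng, 5) + self._profiles(rng, 7)
        props = behavior.group_choice_table(
            profs, ["SC"] * 5 + ["NSC"] * 7)["proportions"]
        # pooled-variance df: contributing subjects minus two
        assert (props["df"] == props["n_sc"] + props["n_nsc"] - 2).all()

    def test_empty_group_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="non-empty"):
            behavior.group_choice_table(self._profiles(rng, 3), ["SC"] * 3)

    def test_type_one_error_on_permuted_labels(self):
        """With labels permuted at random the category test rejects at
        roughly the nominal rate."""
        rng = np.random.default_rng(4)
        profs = self._profiles(rng, 24)
        props = np.array([behavior._yes_proportion(p, 1, -1) for p in profs])
        props = props[~np.isnan(props)]
        assert len(props) >= 20
        rejections = 0
        n_perm = 1000
        half = len(props) // 2
        for _ in range(n_perm):
            perm = rng.permutation(len(props))
            a, b = props[perm[:half]], props[perm[half:]]
            _, p = stats.ttest_ind(a, b, equal_var=True)
            rejections += int(p < 0.05)
        rate = rejections / n_perm
        assert 0.02 <= rate <= 0.09


class TestRobustRegression:
    def test_clean_data_matches_ols(self):
        """With residuals far below the Huber threshold no observation is
        downweighted and the robust fit reduces to OLS."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(60)
        y = 1.5 * x + 0.3 + rng.uniform(-1e-5, 1e-5, 60)
        res = behavior.robust_regression(x, y)
        X = np.column_stack([np.ones(60), x])
        ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.loc["const", "coef"] == pytest.approx(ols[0], abs=1e-6)
        assert res.loc["x", "coef"] == pytest.approx(ols[1], abs=1e-6)

    def test_outlier_resistance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        y = 2.0 * x + rng.normal(0, 0.1, 40)
        clean_slope = np.polyfit(x, y, 1)[0]
        y_bad = y.copy()
        y_bad[0] += 50.0
        contaminated_slope = np.polyfit(x, y_bad, 1)[0]
        robust_slope = behavior.robust_regression(x, y_bad).loc["x", "coef"]
        assert (abs(robust_slope - clean_slope)
                < abs(contaminated_slope - clean_slope))

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            behavior.robust_regression(np.ones(10), np.arange(10.0))

    def test_covariate_included(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(50)
        z = rng.standard_normal(50)
        y = x + 0.5 * z + rng.normal(0, 0.05, 50)
        res = behavior.robust_regression(x, y, covariates=z)
        assert res.loc["cov0", "coef"] == pytest.approx(0.5, abs=0.05)
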