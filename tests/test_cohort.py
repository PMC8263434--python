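import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lapmotion import (
    RobustZScaler,
    SignificanceGatedPCA,
    assemble_metric_table,
    kruskal_wallis,
    mann_whitney_pairwise,
    robust_z_normalize,
    select_and_project,
)
from lapmotion.cohort import NIQR_FACTOR, metric_table_to_wide
from lapmotion.errors import (
    ConstantMetricError,
    InsufficientInputError,
    IntegrityError,
    TrackValidationError,
)


def rec(p, metric, value, task="task1", instrument="scissors"):
    return dict(participant_id=p, task=task, instrument=instrument, metric=metric, value=value)


class TestAssembleTable:
    def test_cardinality(self):
        rows = [rec(p, m, 1.0) for p in ("P1", "P2") for m in "abcde"]
        assert len(assemble_metric_table(rows)) == 10

    def test_undefined_metric_is_null_not_zero(self):
        t = assemble_metric_table([rec("P1", "open_close", None), rec("P1", "path", 2.0)])
        assert t.loc[t.metric == "open_close", "value"].isna().all()

    def test_duplicate_key_rejected(self):
        with pytest.raises(IntegrityError):
            assemble_metric_table([rec("P1", "path", 1.0), rec("P1", "path", 2.0)])

    def test_pivot_round_trip(self, rng):
        rows = [rec(f"P{i}", m, rng.normal()) for i in range(5) for m in "abc"]
        table = assemble_metric_table(rows)
        wide = metric_table_to_wide(table)
        back = (
            wide.stack()
            .rename("value")
            .reset_index()
        )
        back[["instrument", "metric"]] = back["column"].str.split(":", expand=True)
        merged = table.merge(back, on=["participant_id", "instrument", "metric"])
        np.testing.assert_allclose(merged["value_x"], merged["value_y"])
        assert len(merged) == len(table)


class TestKruskalWallis:
    def test_identical_groups_no_effect(self):
        h, p = kruskal_wallis([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_hand_computed_rank_oracle(self):
        """{1,2,3},{4,5,6},{7,8,9}: mean ranks 2/5/8 give H = 7.2 exactly."""
        from scipy.stats import chi2

        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, no ties
        expected = 12.0 / (9 * 10) * 3 * ((2 - 5) ** 2 + 0 + (8 - 5) ** 2)
        assert h == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(chi2.sf(expected, df=2), rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(TrackValidationError):
            kruskal_wallis([1, 2], [], [3, 4])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(size=n) for n in (6, 7, 5)]
        h1, p1 = kruskal_wallis(*groups)
        h2, p2 = kruskal_wallis(*[np.exp(g) + 3 for g in groups])
        assert h1 == pytest.approx(h2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestMannWhitney:
    def test_identical_samples(self):
        _, p = mann_whitney_pairwise([1.0, 2.0, 3.5, 4.0], [1.5, 2.5, 3.0, 4.5])
        assert p > 0.5

    def test_exact_enumeration_small_sample(self):
        """U=0 for fully separated 3v3; exact two-sided p = 2/20 = 0.1."""
        u, p = mann_whitney_pairwise([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1, rel=1e-12)

    def test_exact_p_matches_brute_enumeration(self, rng):
        """Oracle: enumerate all C(8,4) labelings of the pooled sample."""
        a, b = rng.normal(size=4), rng.normal(0.8, size=4)
        _, p = mann_whitney_pairwise(a, b)
        pooled = np.concatenate([a, b])
        ranks = pd.Series(pooled).rank().to_numpy()

        def ustat(idx):
            r = ranks[list(idx)].sum()
            return r - 4 * 5 / 2

        obs = min(ustat(range(4)), 4 * 4 - ustat(range(4)))
        count = 0
        total = 0
        for idx in itertools.combinations(range(8), 4):
            u = ustat(idx)
            total += 1
            if min(u, 16 - u) <= obs:
                count += 1
        assert p == pytest.approx(count / total, rel=1e-9)

    def test_normal_approximation_close_to_exact_n8(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(10):
            a, b = rng.normal(size=8), rng.normal(0.5, size=8)
            pe = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            pa = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            assert abs(pe - pa) < 0.02


class TestRobustZ:
    def test_median_maps_to_zero(self):
        z, params = robust_z_normalize([3.0, 5.0, 9.0, 11.0, 20.0])
        assert z[2] == 0.0
        assert params.median == 9.0

    def test_niqr_definition(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, params = robust_z_normalize(x)
        q1, q3 = np.percentile(x, [25, 75])
        assert params.niqr == pytest.approx((q3 - q1) * NIQR_FACTOR)

    def test_unit_sd_under_normality(self, rng):
        z, _ = robust_z_normalize(rng.normal(size=10_000))
        assert abs(z.std() - 1.0) < 0.05

    def test_outlier_robustness(self, rng):
        x = rng.normal(10, 2, size=40)
        z0, _ = robust_z_normalize(x)
        x_out = np.r_[x, x.mean() * 100]
        z1, _ = robust_z_normalize(x_out)
        rel = np.abs(z1[:-1] - z0) / np.maximum(np.abs(z0), 0.1)
        assert np.max(rel) < 0.10

    def test_constant_metric_rejected(self):
        with pytest.raises(ConstantMetricError):
            robust_z_normalize([2.0, 2.0, 2.0, 2.0, 2.0])

    def test_too_few_values_rejected(self):
        with pytest.raises(TrackValidationError):
            robust_z_normalize([1.0, 2.0, 3.0])


class TestRobustZScaler:
    def test_sklearn_contract(self, rng):
        from sklearn.base import clone

        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        sc = RobustZScaler().fit(X)
        clone(sc)  # get_params/set_params round trip
        Z = sc.transform(X)
        np.testing.assert_allclose(np.median(Z, axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(sc.inverse_transform(Z), X.to_numpy(), rtol=1e-12)

    def test_params_reusable_on_new_data(self, rng):
        X = pd.DataFrame(rng.normal(5, 2, size=(50, 2)), columns=["m1", "m2"])
        sc = RobustZScaler().fit(X)
        new = pd.DataFrame({"m1": [5.0], "m2": [5.0]})
        z = sc.transform(new)
        expected = (5.0 - sc.center_) / sc.scale_
        np.testing.assert_allclose(z[0], expected)


def _cohort_frame(rng, effects, n=(18, 12, 15)):
    """Metric matrix with group-ordered shifts given per metric."""
    labels = np.repeat(["novice", "intermediate", "expert"], n)
    cols = {}
    for name, effect in effects.items():
        base = rng.normal(size=labels.size)
        shift = {"novice": 0.0, "intermediate": effect / 2, "expert": effect}
        cols[name] = base + np.array([shift[g] for g in labels])
    X = pd.DataFrame(cols, index=[f"P{i}" for i in range(labels.size)])
    return X, pd.Series(labels, index=X.index)


class TestSelectAndProject:
    def test_threshold_selects_significant_metrics(self, rng):
        X, y = _cohort_frame(rng, {"a": 3.0, "b": 0.0, "c": 2.5, "d": 0.0})
        res = select_and_project(X, y)
        assert set(res.selected_metrics) == {"a", "c"}
        assert set(res.pairwise_p.index) == {"a", "c"}
        assert set(res.pairwise_p.columns) == {"N-E", "I-E", "N-I"}

    def test_exclusions_removed_from_pca_not_tests(self, rng):
        X, y = _cohort_frame(rng, {"a": 3.0, "b": 2.5, "c": 2.8})
        res = select_and_project(X, y, exclusions=("b",))
        assert "b" not in res.selected_metrics
        assert "b" in res.kw_p.index and res.kw_p["b"] < 0.05

    def test_rank_one_data_single_component(self, rng):
        X, y = _cohort_frame(rng, {"a": 3.0})
        X["b"] = 2.0 * X["a"] + 1.0  # exactly collinear
        res = select_and_project(X, y)
        assert res.var_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal_and_reconstruction(self, rng):
        X, y = _cohort_frame(rng, {m: e for m, e in zip("abcde", [3, 2.5, 2.8, 3.2, 2.6])})
        res = select_and_project(X, y)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)
        Z = RobustZScaler().fit(X[res.selected_metrics]).transform(X[res.selected_metrics])
        np.testing.assert_allclose(res.scores.to_numpy() @ L.T, Z, atol=1e-9)
        assert abs(res.var_explained.sum() - 1.0) < 1e-9
        assert np.all(np.diff(res.var_explained) <= 1e-12)

    def test_expert_mean_pc1_nonnegative_and_group_ordered(self, rng):
        X, y = _cohort_frame(rng, {m: 3.0 for m in "abcd"})
        res = select_and_project(X, y)
        means = res.scores["PC1"].groupby(y).mean()
        assert means["expert"] >= 0
        assert means["novice"] < means["intermediate"] < means["expert"]

    def test_insufficient_metrics_rejected(self, rng):
        X, y = _cohort_frame(rng, {"a": 0.0, "b": 0.0})
        with pytest.raises(InsufficientInputError):
            select_and_project(X, y)

    def test_estimator_transform_matches_fit_scores(self, rng):
        X, y = _cohort_frame(rng, {m: 2.5 for m in "abc"})
        est = SignificanceGatedPCA().fit(X, y)
        s1 = est.transform(X)
        s2 = select_and_project(X, y).scores.to_numpy()
        np.testing.assert_allclose(s1, s2, atol=1e-12)
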