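"""Explained variance, condition enumeration and exhaustive discovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from actisleep.features import FeatureId
from actisleep.subgroups import (
    Condition,
    SubgroupSearch,
    UndefinedQualityError,
    discover_best,
    enumerate_conditions,
    explained_variance,
    normalized_target_mean,
    rank_subgroups,
)
from tests.conftest import make_case_table

FID = FeatureId("steps", "mean", 1)


class TestExplainedVariance:
    def test_equal_group_means_zero(self):
        y = np.array([1.0, 3.0, 1.0, 3.0])
        assert explained_variance(y, [True, True, False, False]) == 0.0

    def test_perfect_separation_one(self):
        y = np.array([5.0, 5.0, 9.0, 9.0])
        assert explained_variance(y, [True, True, False, False]) == 1.0

    def test_hand_computed(self):
        # y = (1,2,3,4), subgroup = last two: SS_total = 5, SS_within = 1
        y = np.array([1.0, 2.0, 3.0, 4.0])
        ev = explained_variance(y, [False, False, True, True])
        assert ev == pytest.approx(0.8, abs=1e-14)

    def test_constant_target_undefined(self):
        with pytest.raises(UndefinedQualityError):
            explained_variance([2.0, 2.0, 2.0], [True, False, False])

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            explained_variance([1.0, 2.0], [True, True])

    @given(st.integers(0, 60))
    def test_equals_squared_point_biserial(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 40)
        y = rng.normal(size=n)
        m = np.zeros(n, bool)
        m[: rng.integers(1, n)] = True
        rng.shuffle(m)
        if m.all() or not m.any():
            m[0] = not m[0]
        ev = explained_variance(y, m)
        r = np.corrcoef(m.astype(float), y)[0, 1]
        assert ev == pytest.approx(r**2, abs=1e-10)

    @given(st.integers(0, 40))
    def test_affine_and_complement_invariance(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=20)
        m = rng.random(20) < 0.4
        if m.all() or not m.any():
            m[0] = not m[0]
        ev = explained_variance(y, m)
        assert explained_variance(3.5 * y + 11, m) == pytest.approx(ev, abs=1e-12)
        assert explained_variance(y, ~m) == pytest.approx(ev, abs=1e-12)


class TestEnumerateConditions:
    def test_ten_distinct_values_counts(self):
        vals = np.arange(10.0)
        conds = enumerate_conditions(vals, FID, (0.10, 0.90))
        le = [c for c in conds if c.operator == "<="]
        ge = [c for c in conds if c.operator == ">="]
        assert sorted(int(c.covers(vals).sum()) for c in le) == list(range(1, 10))
        assert sorted(int(c.covers(vals).sum()) for c in ge) == list(range(1, 10))
        # memberships all distinct
        keys = {frozenset(np.flatnonzero(c.covers(vals))) for c in conds}
        assert len(keys) == len(conds) == 18

    def test_constant_feature_empty(self):
        assert enumerate_conditions(np.full(20, 7.0), FID) == []

    def test_random_vector_fractions_within_bounds(self):
        rng = np.random.default_rng(3)
        vals = np.round(rng.normal(size=50), 1)
        for c in enumerate_conditions(vals, FID, (0.10, 0.90)):
            frac = c.covers(vals).mean()
            assert 0.10 <= frac <= 0.90


def _brute_force_best(df, feature_names, y, bounds=(0.10, 0.90)):
    """Independent exhaustive search with the package's tie-break rule."""
    best = None
    n = len(y)
    for name in feature_names:
        vals = df[name].to_numpy(float)
        for t in np.unique(vals):
            for op in ("<=", ">="):
                m = vals <= t if op == "<=" else vals >= t
                k = int(m.sum())
                if not bounds[0] <= k / n <= bounds[1]:
                    continue
                mu, mu1, mu2 = y.mean(), y[m].mean(), y[~m].mean()
                ss_tot = ((y - mu) ** 2).sum()
                ss_w = ((y[m] - mu1) ** 2).sum() + ((y[~m] - mu2) ** 2).sum()
                q = 1 - ss_w / ss_tot
                key = (-q, k, 0 if op == "<=" else 1, abs(t), name)
                if best is None or key < best[0]:
                    best = (key, name, op, float(t), q)
    return best


class TestDiscoverBest:
    def test_matches_brute_force(self):
        for seed in range(5):
            table = make_case_table(60, seed=seed)
            y = table.df["light_sleep_s"].to_numpy(float)
            res = discover_best(table, "light_sleep")
            _, name, op, t, q = _brute_force_best(table.df, table.feature_names, y)
            assert res.condition.feature.name == name
            assert res.condition.operator == op
            assert res.condition.threshold == t
            assert res.quality == pytest.approx(q, abs=1e-12)

    def test_null_best_ev_vanishes_at_large_n(self):
        table = make_case_table(10_000, seed=9)
        res = discover_best(table, "light_sleep")
        assert res.quality < 0.01

    def test_case_order_invariance(self):
        table = make_case_table(80, seed=1)
        shuffled = make_case_table(80, seed=1)
        shuffled.df = shuffled.df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = discover_best(table, "deep_sleep")
        b = discover_best(shuffled, "deep_sleep")
        assert a.condition == b.condition and a.quality == b.quality

    def test_relaxing_bounds_never_decreases_best_ev(self):
        for seed in range(4):
            table = make_case_table(70, seed=seed)
            tight = discover_best(table, "light_sleep", (0.10, 0.90))
            loose = discover_best(table, "light_sleep", (0.05, 0.95))
            assert loose.quality >= tight.quality - 1e-15

    def test_pluggable_quality_callable(self):
        table = make_case_table(40, seed=2)

        def smd(y, m):  # |standardized mean difference|
            return abs(y[m].mean() - y[~m].mean()) / y.std(ddof=1)

        res = discover_best(table, "light_sleep", quality=smd)
        assert res is not None and res.quality > 0

    def test_small_scope_rejected(self):
        with pytest.raises(ValueError, match="10 cases"):
            discover_best(make_case_table(8, seed=0), "light_sleep")

    def test_kernel_ev_matches_definitional(self):
        table = make_case_table(50, seed=6)
        res = discover_best(table, "light_sleep")
        vals = table.df[res.condition.feature.name].to_numpy(float)
        y = table.df["light_sleep_s"].to_numpy(float)
        assert res.quality == pytest.approx(
            explained_variance(y, res.condition.covers(vals)), abs=1e-12
        )


class TestNormalizedTargetMean:
    def test_equal_means_unity(self):
        y = np.array([6.0, 6.0, 6.0, 6.0])
        assert normalized_target_mean(y, [True, False, True, False]) == 1.0

    def test_eight_over_six(self):
        y = np.array([8.0, 8.0, 6.0, 4.0])
        ratio = normalized_target_mean(y, [True, True, False, False])
        assert ratio == pytest.approx(8 / 6.5)

    def test_matches_direct_recomputation(self):
        table = make_case_table(60, seed=12)
        res = discover_best(table, "deep_sleep")
        vals = table.df[res.condition.feature.name].to_numpy(float)
        y = table.df["deep_sleep_s"].to_numpy(float)
        m = res.condition.covers(vals)
        assert res.normalized_target_mean == pytest.approx(
            y[m].mean() / y.mean(), abs=1e-12
        )

    def test_standardized_target_suppressed(self):
        y = np.array([-1.0, 1.0, -0.5, 0.5])
        with pytest.raises(ValueError):
            normalized_target_mean(y, [True, False, True, False])


class TestRankSubgroups:
    def test_ranked_descending_with_sizes(self):
        table = make_case_table(50, seed=3)
        ranked = rank_subgroups(table, "light_sleep", top_k=20)
        assert (ranked["quality"].diff().dropna() <= 1e-15).all()
        assert ((ranked["size_frac"] >= 0.10) & (ranked["size_frac"] <= 0.90)).all()

    def test_binned_search_approximates_full(self):
        # threshold thinning never beats, and stays close to, the exact best
        table = make_case_table(500, seed=4)
        exact = discover_best(table, "light_sleep")
        binned = discover_best(table, "light_sleep", bins=20)
        assert binned.quality <= exact.quality + 1e-15
        assert binned.quality >= 0.5 * exact.quality
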