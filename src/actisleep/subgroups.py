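"""Single-condition subgroup discovery on a numeric sleep target.

The search considers every condition of the form ``feature <= t`` or
``feature >= t`` where ``t`` is an observed value of one of the lagged
activity descriptors, keeps those covering between 10% and 90% of the
cases, and scores each induced subgroup/complement split with the
*explained variance*

    EV = 1 - SS_within / SS_total = SS_between / SS_total,

the fraction of target variance explained by splitting the cases into the
subgroup and its complement.  The search is exhaustive (with 28 features
and at most 2n observed thresholds each it is exact and cheap at the case
counts involved); the best subgroup is returned with deterministic
tie-breaking.

Implementation note: for a fixed feature the memberships of ``<=`` conditions
are prefixes of the value-sorted case order, so all admissible splits of all
features are scored from per-feature sort orders and cumulative sums.  The
sort orders depend only on the features, letting permutation-based
significance tests (see :mod:`actisleep.dfd`) re-score thousands of permuted
targets without re-sorting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import CaseTable, FeatureId, target_column


class UndefinedQualityError(ValueError):
    """The target has zero total variance; subgroup quality is undefined."""


@dataclass(frozen=True)
class Condition:
    """A single threshold condition on one feature, e.g. steps_min_3d <= 3351."""

    feature: FeatureId
    operator: str  # '<=' or '>='
    threshold: float

    def __post_init__(self) -> None:
        if self.operator not in ("<=", ">="):
            raise ValueError(f"operator must be '<=' or '>=': {self.operator!r}")

    def covers(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.operator == "<=":
            return values <= self.threshold
        return values >= self.threshold

    def __str__(self) -> str:
        return f"{self.feature.name} {self.operator} {self.threshold:g}"


@dataclass(frozen=True)
class SubgroupResult:
    """Best (or one ranked) subgroup for a target within one scope."""

    condition: Condition
    target: str
    size_frac: float
    quality: float
    normalized_target_mean: float | None  # subgroup mean / overall mean
    target_mean_diff: float  # subgroup mean - overall mean (target units)
    n_cases: int  # cases covered by the condition
    n_total: int


def explained_variance(target_values, membership) -> float:
    """Fraction of target variance explained by a subgroup/complement split.

    ``EV = 1 - SS_within / SS_total`` with ``SS_within`` the sum of squared
    deviations of each case from its own group mean and ``SS_total`` the sum
    of squared deviations from the grand mean.  Both groups must be
    non-empty; a constant target raises :class:`UndefinedQualityError`.
    """
    y = np.asarray(target_values, dtype=float)
    m = np.asarray(membership, dtype=bool)
    if y.shape != m.shape or y.ndim != 1:
        raise ValueError("target and membership must be 1-D of equal length")
    if not m.any() or m.all():
        raise ValueError("both subgroup and complement must be non-empty")
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0.0:
        raise UndefinedQualityError("zero total variance: quality undefined")
    ss_within = float(((y[m] - y[m].mean()) ** 2).sum()) + float(
        ((y[~m] - y[~m].mean()) ** 2).sum()
    )
    return float(np.clip(1.0 - ss_within / ss_total, 0.0, 1.0))


def normalized_target_mean(target_values, membership) -> float:
    """Subgroup mean divided by the overall mean of the target.

    Values above 1 indicate a subgroup with an above-average target.  Only
    meaningful for positive overall means (raw, unstandardized targets);
    raises ``ValueError`` otherwise — callers should then report the
    absolute mean difference instead.
    """
    y = np.asarray(target_values, dtype=float)
    m = np.asarray(membership, dtype=bool)
    overall = y.mean()
    if not _ratio_meaningful(y):
        raise ValueError("overall mean <= 0 (or ~0): ratio not meaningful")
    return float(y[m].mean() / overall)


def _ratio_meaningful(y: np.ndarray) -> bool:
    """A mean ratio only makes sense when the overall mean is genuinely
    positive — not the near-zero mean of a standardized column."""
    overall = y.mean()
    return overall > 1e-9 * float(np.abs(y).mean() + 1e-300)


def enumerate_conditions(
    values,
    feature: FeatureId,
    size_bounds: tuple[float, float] = (0.10, 0.90),
) -> list[Condition]:
    """Admissible threshold conditions on one feature.

    For every distinct observed value ``t`` both ``<= t`` and ``>= t`` are
    candidates; those whose covered fraction falls outside ``size_bounds``
    are discarded, and conditions inducing the same membership set are
    deduplicated (first occurrence kept).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    lo, hi = size_bounds
    seen: set[frozenset[int]] = set()
    out: list[Condition] = []
    for t in np.unique(x):
        for op in ("<=", ">="):
            cond = Condition(feature, op, float(t))
            member = cond.covers(x)
            frac = member.sum() / n
            if not lo <= frac <= hi:
                continue
            key = frozenset(np.flatnonzero(member).tolist())
            if key in seen:
                continue
            seen.add(key)
            out.append(cond)
    return out


def _operator_rank(op: str) -> int:
    return 0 if op == "<=" else 1


class SubgroupSearch:
    """Pre-indexed exhaustive search over all admissible single conditions.

    Built once from the feature matrix; :meth:`best_quality` then scores any
    target vector (e.g. a permuted one) against every admissible condition
    in a handful of vectorized passes.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        size_bounds: tuple[float, float] = (0.10, 0.90),
        bins: int | None = None,
    ) -> None:
        """``bins`` thins candidate thresholds per feature to roughly that
        many equal-frequency split points (exactness traded for speed at
        large n); ``None`` keeps every observed threshold."""
        lo, hi = size_bounds
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("size bounds must satisfy 0 < lo < hi < 1")
        if bins is not None and bins < 2:
            raise ValueError("bins must be >= 2")
        self.size_bounds = (float(lo), float(hi))
        self.feature_ids = [FeatureId.from_name(c) for c in X.columns]
        arr = X.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("feature matrix must not contain missing values")
        self.n = n = arr.shape[0]
        if n < 2:
            raise ValueError("need at least 2 cases")
        # column-wise stable sort; memberships of '<= t' are prefixes
        self.orders = np.argsort(arr, axis=0, kind="stable").T  # (F, n)
        self.sorted_vals = np.take_along_axis(arr.T, self.orders, axis=1)
        # split after position k (prefix size k), k = 1..n-1: a real threshold
        # only where the sorted value changes (dedup by induced membership)
        boundary = self.sorted_vals[:, :-1] != self.sorted_vals[:, 1:]  # (F, n-1)
        if bins is not None and bins < n:
            # equal-frequency thinning: keep only split points nearest the
            # quantile grid (still only at genuine value changes)
            grid = np.unique(np.round(np.arange(1, bins) * n / bins).astype(int))
            keep = np.zeros(n - 1, dtype=bool)
            keep[np.clip(grid - 1, 0, n - 2)] = True
            boundary = boundary & keep
        k = np.arange(1, n)
        frac = k / n
        self.le_ok = boundary & (lo <= frac) & (frac <= hi)
        self.ge_ok = boundary & (lo <= 1 - frac) & (1 - frac <= hi)
        self.any_ok = self.le_ok | self.ge_ok
        self._k = k

    def split_quality(self, y: np.ndarray) -> tuple[np.ndarray, float]:
        """EV at every split point for every feature.

        Returns ``(ev, ss_total)`` where ``ev`` has shape (F, n-1); entries
        at inadmissible splits are NaN.  ``ss_total = 0`` yields all-NaN.
        """
        y = np.asarray(y, dtype=float)
        n = self.n
        y0 = y - y.mean()  # centering: SS_between = c_k^2 (1/k + 1/(n-k))
        ss_total = float((y0**2).sum())
        ev = np.full_like(self.le_ok, np.nan, dtype=float)
        if ss_total == 0.0:
            return ev, ss_total
        ys = y0[self.orders]  # (F, n)
        csum = np.cumsum(ys, axis=1)[:, :-1]  # prefix sums, k = 1..n-1
        k = self._k
        between = csum**2 * (1.0 / k + 1.0 / (n - k))
        np.divide(between, ss_total, out=ev, where=self.any_ok)
        np.clip(ev, 0.0, 1.0, out=ev)
        ev[~self.any_ok] = np.nan
        return ev, ss_total

    def best_quality(self, y: np.ndarray) -> float:
        """Maximum EV over all admissible conditions (0.0 if none)."""
        ev, _ = self.split_quality(y)
        if np.isnan(ev).all():
            return 0.0
        return float(np.nanmax(ev))

    def _candidates(self, ev: np.ndarray) -> pd.DataFrame:
        """All admissible (feature, operator, threshold) candidates with EV."""
        recs = []
        n = self.n
        for f, fid in enumerate(self.feature_ids):
            for kk in np.flatnonzero(self.le_ok[f]):
                recs.append(
                    (
                        fid.name,
                        "<=",
                        self.sorted_vals[f, kk],
                        int(kk + 1),
                        ev[f, kk],
                    )
                )
            for kk in np.flatnonzero(self.ge_ok[f]):
                recs.append(
                    (
                        fid.name,
                        ">=",
                        self.sorted_vals[f, kk + 1],
                        int(n - kk - 1),
                        ev[f, kk],
                    )
                )
        return pd.DataFrame(
            recs, columns=["feature", "operator", "threshold", "n_cases", "quality"]
        )

    def rank(self, y: np.ndarray, top_k: int | None = None) -> pd.DataFrame:
        """Candidates ordered by descending EV with deterministic tie-breaks.

        A subgroup and its complement always tie on EV (they induce the same
        split); ties are broken by *smaller* subgroup first — the side whose
        mean deviates more from the overall mean, the side a reader of the
        ranked list cares about — then ``<=`` before ``>=``, then smaller
        ``|threshold|``, then feature name.
        """
        ev, ss_total = self.split_quality(y)
        if ss_total == 0.0:
            raise UndefinedQualityError("zero total variance: quality undefined")
        cand = self._candidates(ev)
        if cand.empty:
            return cand
        cand["_op"] = cand["operator"].map(_operator_rank)
        cand["_abs_t"] = cand["threshold"].abs()
        cand = cand.sort_values(
            ["quality", "n_cases", "_op", "_abs_t", "feature"],
            ascending=[False, True, True, True, True],
            kind="stable",
        ).drop(columns=["_op", "_abs_t"])
        cand["size_frac"] = cand["n_cases"] / self.n
        if top_k is not None:
            cand = cand.head(top_k)
        return cand.reset_index(drop=True)


def _result_from_row(
    row: pd.Series, X: pd.DataFrame, y: np.ndarray, target: str
) -> SubgroupResult:
    cond = Condition(
        FeatureId.from_name(row["feature"]), row["operator"], float(row["threshold"])
    )
    member = cond.covers(X[row["feature"]].to_numpy(dtype=float))
    overall = float(y.mean())
    diff = float(y[member].mean() - overall)
    ratio = normalized_target_mean(y, member) if _ratio_meaningful(y) else None
    return SubgroupResult(
        condition=cond,
        target=target,
        size_frac=float(member.sum() / len(y)),
        quality=float(row["quality"]),
        normalized_target_mean=ratio,
        target_mean_diff=diff,
        n_cases=int(member.sum()),
        n_total=int(len(y)),
    )


def discover_best(
    case_table: CaseTable,
    target: str,
    size_bounds: tuple[float, float] = (0.10, 0.90),
    quality: str | Callable = "explained_variance",
    search: SubgroupSearch | None = None,
    bins: int | None = None,
) -> SubgroupResult | None:
    """Best single-condition subgroup for ``target`` in one scope.

    Evaluates EV for every admissible condition over all features and
    returns the maximum-EV subgroup (deterministic tie-breaks; see
    :meth:`SubgroupSearch.rank`), or ``None`` when no admissible condition
    exists.  ``quality`` may be a callable ``(target_values, membership) ->
    float`` for alternate quality measures (slower, non-indexed path).
    """
    df = case_table.df
    feat_cols = case_table.feature_names
    if len(df) < 10:
        raise ValueError("scope must have at least 10 cases")
    X = df[feat_cols]
    y = df[target_column(target)].to_numpy(dtype=float)
    if callable(quality):
        return _discover_best_generic(X, y, target, size_bounds, quality)
    if quality != "explained_variance":
        raise ValueError(f"unknown quality {quality!r}")
    if search is None:
        search = SubgroupSearch(X, size_bounds, bins=bins)
    ranked = search.rank(y, top_k=1)
    if ranked.empty:
        return None
    return _result_from_row(ranked.iloc[0], X, y, target)


def rank_subgroups(
    case_table: CaseTable,
    target: str,
    size_bounds: tuple[float, float] = (0.10, 0.90),
    top_k: int | None = 10,
    bins: int | None = None,
) -> pd.DataFrame:
    """Ranked list of admissible subgroups by descending EV (Table-style)."""
    df = case_table.df
    X = df[case_table.feature_names]
    y = df[target_column(target)].to_numpy(dtype=float)
    search = SubgroupSearch(X, size_bounds, bins=bins)
    ranked = search.rank(y, top_k=top_k)
    if ranked.empty:
        return ranked
    overall = float(y.mean())
    meaningful = _ratio_meaningful(y)
    norm = []
    for _, row in ranked.iterrows():
        member = Condition(
            FeatureId.from_name(row["feature"]),
            row["operator"],
            float(row["threshold"]),
        ).covers(X[row["feature"]].to_numpy(dtype=float))
        norm.append(float(y[member].mean() / overall) if meaningful else np.nan)
    ranked = ranked.copy()
    ranked["normalized_target_mean"] = norm
    ranked.insert(0, "target", target)
    return ranked


def _discover_best_generic(
    X: pd.DataFrame,
    y: np.ndarray,
    target: str,
    size_bounds: tuple[float, float],
    quality_fn: Callable,
) -> SubgroupResult | None:
    """Exhaustive loop path for pluggable quality measures."""
    best: tuple | None = None
    for col in X.columns:
        fid = FeatureId.from_name(col)
        vals = X[col].to_numpy(dtype=float)
        for cond in enumerate_conditions(vals, fid, size_bounds):
            member = cond.covers(vals)
            q = float(quality_fn(y, member))
            key = (
                -q,
                int(member.sum()),
                _operator_rank(cond.operator),
                abs(cond.threshold),
                cond.feature.name,
            )
            if best is None or key < best[0]:
                best = (key, cond, q, member)
    if best is None:
        return None
    _, cond, q, member = best
    row = pd.Series(
        {
            "feature": cond.feature.name,
            "operator": cond.operator,
            "threshold": cond.threshold,
            "quality": q,
        }
    )
    return _result_from_row(row, X, y, target)
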