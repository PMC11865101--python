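"""Lagged activity features and the case table.

One *case* is an analyzable participant-day: the light and deep sleep
durations recorded on day ``d`` together with 28 aggregate descriptors of
physical activity on the three preceding calendar days.  The descriptors
are the mean, minimum and maximum of four daily quantities (step count and
the durations of light, moderate and intense activity) over windows of one,
two and three days ending on day ``d - 1``; over a one-day window the three
aggregates coincide, so only the mean is kept, giving
4 quantities x (1 + 3 + 3) = 28 distinct features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four daily physical-activity quantities, in canonical order.
QUANTITIES = ("steps", "light_activity", "moderate_activity", "intense_activity")

#: Aggregate functions applied over a lag window, in canonical order.
AGGREGATES = ("mean", "min", "max")

#: Lag windows (days before the sleep day) considered.
WINDOWS = (1, 2, 3)

#: Raw-record column name for each quantity.
QUANTITY_COLUMNS = {
    "steps": "steps",
    "light_activity": "light_activity_s",
    "moderate_activity": "moderate_activity_s",
    "intense_activity": "intense_activity_s",
}

TARGET_COLUMNS = ("light_sleep_s", "deep_sleep_s")
TARGETS = ("light_sleep", "deep_sleep")


@dataclass(frozen=True, order=True)
class FeatureId:
    """Identifier of one lagged aggregate descriptor.

    ``quantity`` is one of :data:`QUANTITIES`, ``aggregate`` one of
    :data:`AGGREGATES` and ``window`` the number of prior days aggregated.
    A one-day window only admits ``aggregate='mean'`` (its canonical form:
    min and max over a single value equal the mean).
    """

    quantity: str
    aggregate: str
    window: int

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.aggregate not in AGGREGATES:
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        if self.window not in WINDOWS:
            raise ValueError(f"window must be one of {WINDOWS}, got {self.window}")
        if self.window == 1 and self.aggregate != "mean":
            raise ValueError(
                "a 1-day window admits only aggregate='mean' (canonical form)"
            )

    @property
    def name(self) -> str:
        """Canonical column name, e.g. ``steps_min_3d``."""
        return f"{self.quantity}_{self.aggregate}_{self.window}d"

    @classmethod
    def from_name(cls, name: str) -> "FeatureId":
        parts = name.rsplit("_", 2)
        if len(parts) != 3 or not parts[2].endswith("d"):
            raise ValueError(f"not a feature column name: {name!r}")
        return cls(parts[0], parts[1], int(parts[2][:-1]))

    @property
    def is_duration(self) -> bool:
        return self.quantity != "steps"


def feature_universe(windows: tuple[int, ...] = WINDOWS) -> list[FeatureId]:
    """All distinct feature identifiers, in canonical order.

    For the default windows {1, 2, 3} this is exactly 28 features.
    """
    out: list[FeatureId] = []
    for quantity in QUANTITIES:
        for window in sorted(windows):
            aggs = ("mean",) if window == 1 else AGGREGATES
            for agg in aggs:
                out.append(FeatureId(quantity, agg, window))
    return out


FEATURE_UNIVERSE = feature_universe()
FEATURE_NAMES = [f.name for f in FEATURE_UNIVERSE]


def lagged_aggregate(values: np.ndarray, aggregate: str, window: int) -> np.ndarray:
    """Aggregate of ``values`` over the ``window`` days before each day.

    ``values`` must be one value per *consecutive* calendar day.  Entry ``d``
    of the result aggregates days ``d-1 ... d-window``; entries with an
    incomplete window (the first ``window`` days, or any window containing a
    NaN) are NaN.
    """
    values = np.asarray(values, dtype=float)
    s = pd.Series(values).shift(1).rolling(window, min_periods=window)
    if aggregate == "mean":
        agg = s.mean()
    elif aggregate == "min":
        agg = s.min()
    elif aggregate == "max":
        agg = s.max()
    else:  # pragma: no cover - guarded by FeatureId
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return agg.to_numpy()


@dataclass
class CaseTable:
    """Ordered collection of cases, one row per analyzable participant-day.

    ``df`` has columns ``participant_id``, ``date``, the feature columns
    (canonical names), and the two targets ``light_sleep_s``/``deep_sleep_s``.
    ``provenance`` records how the table was produced (source file or
    generator config/seed, standardization, dropped columns).
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c in set(FEATURE_NAMES)]

    @property
    def n_cases(self) -> int:
        return len(self.df)

    def participant_counts(self) -> pd.Series:
        return self.df.groupby("participant_id", sort=True).size()

    def for_participant(self, participant_id: str) -> "CaseTable":
        sub = self.df[self.df["participant_id"] == participant_id].reset_index(drop=True)
        return CaseTable(sub, {**self.provenance, "scope": participant_id})


def target_column(target: str) -> str:
    """Map a target name ('light_sleep' or 'deep_sleep') to its column."""
    if target in TARGETS:
        return f"{target}_s"
    if target in TARGET_COLUMNS:
        return target
    raise ValueError(f"unknown target {target!r}")


def build_cases(records: pd.DataFrame, windows: tuple[int, ...] = WINDOWS) -> CaseTable:
    """Build the case table from daily records.

    A case is emitted for day ``d`` of a participant iff (a) both sleep
    targets are present on day ``d`` and (b) all four activity quantities
    are present on every one of the ``max(windows)`` preceding *calendar*
    days (a missing row counts as a fully missing day).  Every emitted case
    therefore carries all features for the requested windows with no
    missing values.
    """
    windows = tuple(sorted(windows))
    max_w = max(windows)
    features = feature_universe(windows)
    rows: list[pd.DataFrame] = []
    for pid, grp in records.groupby("participant_id", sort=True):
        grp = grp.sort_values("date")
        dates = pd.DatetimeIndex(pd.to_datetime(grp["date"]))
        full = pd.date_range(dates.min(), dates.max(), freq="D")
        daily = grp.set_index(dates).reindex(full)

        activity = np.column_stack(
            [daily[QUANTITY_COLUMNS[q]].to_numpy(dtype=float) for q in QUANTITIES]
        )
        sleep_ok = (
            daily["light_sleep_s"].notna() & daily["deep_sleep_s"].notna()
        ).to_numpy()
        act_day_ok = ~np.isnan(activity).any(axis=1)
        # all max_w prior days fully observed for activity
        prior_ok = (
            pd.Series(act_day_ok)
            .rolling(max_w, min_periods=max_w)
            .min()
            .shift(1)
            .to_numpy()
        )
        valid = sleep_ok & (prior_ok == 1.0)
        if not valid.any():
            continue

        cols: dict[str, np.ndarray] = {}
        for fid in features:
            q_vals = daily[QUANTITY_COLUMNS[fid.quantity]].to_numpy(dtype=float)
            cols[fid.name] = lagged_aggregate(q_vals, fid.aggregate, fid.window)
        out = pd.DataFrame(cols, index=full)
        out.insert(0, "participant_id", pid)
        out.insert(1, "date", full)
        out["light_sleep_s"] = daily["light_sleep_s"].to_numpy(dtype=float)
        out["deep_sleep_s"] = daily["deep_sleep_s"].to_numpy(dtype=float)
        rows.append(out.loc[valid])

    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        cols = ["participant_id", "date"] + [f.name for f in features] + list(
            TARGET_COLUMNS
        )
        df = pd.DataFrame(columns=cols)
    df = df.sort_values(["participant_id", "date"], kind="stable").reset_index(drop=True)
    return CaseTable(df, {"windows": list(windows)})


def eligibility_filter(
    case_table: CaseTable, min_days: int = 30
) -> tuple[CaseTable, list[str]]:
    """Keep participants with strictly more than ``min_days`` cases.

    Returns the filtered table and the list of excluded participant ids.
    The strict inequality implements the "> 30 days of data" inclusion rule.
    """
    counts = case_table.participant_counts()
    included = counts[counts > min_days].index
    excluded = sorted(set(counts.index) - set(included))
    df = case_table.df[case_table.df["participant_id"].isin(included)].reset_index(
        drop=True
    )
    prov = {**case_table.provenance, "min_days": min_days, "excluded": excluded}
    return CaseTable(df, prov), excluded


def standardize_per_participant(case_table: CaseTable) -> CaseTable:
    """Z-standardize every feature and target column within each participant.

    Each value becomes ``(value - participant mean) / participant SD`` with
    the sample (n-1) SD, so pooling across participants no longer reflects
    between-person differences in average activity or sleep.  A column that
    is constant within *any* participant has zero SD there; such columns are
    dropped from the pooled table for all participants (a constant carries
    no rank or subgroup information) and recorded in
    ``provenance['dropped_columns']`` with a warning.

    Every participant must contribute at least 2 cases.
    """
    df = case_table.df
    value_cols = case_table.feature_names + [
        c for c in TARGET_COLUMNS if c in df.columns
    ]
    counts = case_table.participant_counts()
    if (counts < 2).any():
        bad = list(counts[counts < 2].index)
        raise ValueError(f"participants with < 2 cases cannot be standardized: {bad}")

    grouped = df.groupby("participant_id")[value_cols]
    means = grouped.transform("mean")
    sds = grouped.transform("std")  # ddof=1

    dropped = [c for c in value_cols if (sds[c] == 0).any() or sds[c].isna().any()]
    if dropped:
        warnings.warn(
            "columns constant within at least one participant excluded from the "
            f"pooled table: {dropped}",
            stacklevel=2,
        )
        logger.warning("standardize: dropping zero-variance columns %s", dropped)

    kept = [c for c in value_cols if c not in dropped]
    out = df[["participant_id", "date"]].copy()
    for c in kept:
        out[c] = (df[c] - means[c]) / sds[c]
    prov = {
        **case_table.provenance,
        "standardized": "per-participant",
        "dropped_columns": dropped,
    }
    return CaseTable(out, prov)
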