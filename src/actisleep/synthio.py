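"""Daily-record CSV schema and synthetic cohort generation.

The on-disk format is one CSV row per participant-day::

    participant_id,date,steps,light_activity_s,moderate_activity_s,intense_activity_s,light_sleep_s,deep_sleep_s

with ISO dates, durations in seconds, and empty cells for missing
measurements.  The generator emulates a wearable-tracker cohort:
participants differ widely in habitual activity (median daily steps
spanning roughly 1 000-10 000), sleep about 7-8 h/day split into light and
deep components, and individual days may lack any measurement.  Optional
*planted effects* shift a sleep target on days selected by a threshold on
one lagged activity descriptor, providing ground truth for recovery tests
of the discovery method.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd
import yaml

from .features import FeatureId, QUANTITY_COLUMNS, lagged_aggregate, target_column

SCHEMA_COLUMNS = [
    "participant_id",
    "date",
    "steps",
    "light_activity_s",
    "moderate_activity_s",
    "intense_activity_s",
    "light_sleep_s",
    "deep_sleep_s",
]
MEASUREMENT_COLUMNS = SCHEMA_COLUMNS[2:]
SECONDS_PER_DAY = 86_400


class SchemaError(ValueError):
    """The input violates the daily-record schema (columns, key uniqueness)."""


class RecordValidationError(ValueError):
    """A record value violates an invariant (sign, range)."""


class ConfigurationError(ValueError):
    """A cohort configuration is internally inconsistent."""


def validate_daily_records(df: pd.DataFrame) -> None:
    """Check the DailyRecord invariants, raising on the first violation."""
    missing_cols = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing schema columns: {missing_cols}")
    dup = df.duplicated(subset=["participant_id", "date"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        key = (first["participant_id"], pd.Timestamp(first["date"]).date().isoformat())
        raise SchemaError(f"duplicate (participant_id, date) key: {key}")
    for col in MEASUREMENT_COLUMNS:
        vals = df[col]
        neg = vals < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise RecordValidationError(
                f"negative value in column {col!r} at data row {row}: {vals.iloc[row]}"
            )
    for col in MEASUREMENT_COLUMNS[1:]:  # durations only
        too_big = df[col] >= SECONDS_PER_DAY
        if too_big.any():
            row = int(np.flatnonzero(too_big.to_numpy())[0])
            raise RecordValidationError(
                f"duration >= 86400 s in column {col!r} at data row {row}"
            )


def read_daily_records(source: str | Path | IO[str]) -> pd.DataFrame:
    """Read and validate a daily-record CSV.

    Missing cells become NaN; rows are returned sorted by
    (participant_id, date).  Raises :class:`SchemaError` for column or
    key-uniqueness problems and :class:`RecordValidationError` for value
    violations, naming the offending row.
    """
    df = pd.read_csv(source, dtype={"participant_id": str})
    validate_daily_records(df)
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    df = df[SCHEMA_COLUMNS]
    return df.sort_values(["participant_id", "date"], kind="stable").reset_index(
        drop=True
    )


def write_daily_records(records: pd.DataFrame, dest: str | Path | IO[str]) -> None:
    """Write records as schema CSV; ``read(write(x)) == x`` field for field.

    Columns whose present values are all whole numbers are written without a
    decimal point; missing cells are written empty.
    """
    out = records[SCHEMA_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    for col in MEASUREMENT_COLUMNS:
        vals = pd.to_numeric(out[col])
        if ((vals.dropna() % 1) == 0).all():
            out[col] = vals.astype("Int64")
        else:
            out[col] = vals
    out.to_csv(dest, index=False)


@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth lagged activity -> sleep effect inserted by the generator.

    On days where the lagged descriptor ``feature`` satisfies
    ``operator threshold`` (threshold = the ``quantile`` of the descriptor's
    per-participant empirical marginal), the target mean is shifted by
    ``shift`` times that participant's configured target SD.  The implied
    subgroup fraction (quantile for ``<=``, 1 - quantile for ``>=``) must lie
    strictly inside (0.10, 0.90) so the planted subgroup is admissible for
    the discovery search.
    """

    target: str  # 'light_sleep' or 'deep_sleep'
    feature: FeatureId
    operator: str  # '<=' or '>='
    quantile: float
    shift: float
    participants: tuple[str, ...] | None = None  # None = all

    def __post_init__(self) -> None:
        target_column(self.target)  # validates
        if self.operator not in ("<=", ">="):
            raise ConfigurationError(f"operator must be '<=' or '>=': {self.operator!r}")
        frac = self.quantile if self.operator == "<=" else 1.0 - self.quantile
        if not 0.10 < frac < 0.90:
            raise ConfigurationError(
                f"planted subgroup fraction {frac:.3f} outside (0.10, 0.90)"
            )

    @property
    def subgroup_fraction(self) -> float:
        return self.quantile if self.operator == "<=" else 1.0 - self.quantile


def _as_range(value) -> tuple[float, float]:
    if np.isscalar(value):
        return (float(value), float(value))
    lo, hi = value
    if hi < lo:
        raise ConfigurationError(f"range upper bound below lower: {value}")
    return (float(lo), float(hi))


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic wearable cohort.

    Per-participant baselines are drawn once per participant from the
    configured between-person ranges, then daily values are drawn around
    those baselines: steps log-normally (right-skewed counts), activity
    durations from gamma distributions (right-skewed, nonnegative), sleep
    durations normally, truncated at 0 and capped below 24 h.  Ranges may be
    degenerate (lo == hi) to pin a baseline exactly.  Identical config and
    seed reproduce the identical dataset.
    """

    n_participants: int = 18
    days_per_participant: int | tuple[int, int] = (32, 173)
    # between-person baseline ranges
    steps_median_range: tuple[float, float] = (1_000.0, 10_000.0)
    steps_log_sd: float = 0.5
    light_activity_mean_range: tuple[float, float] = (7_200.0, 16_200.0)
    light_activity_shape: float = 4.0
    moderate_activity_mean_range: tuple[float, float] = (600.0, 2_700.0)
    moderate_activity_shape: float = 2.0
    intense_activity_mean_range: tuple[float, float] = (600.0, 3_000.0)
    intense_activity_shape: float = 2.0
    light_sleep_mean_range: tuple[float, float] = (11_000.0, 16_000.0)
    light_sleep_sd: float = 2_700.0
    deep_sleep_mean_range: tuple[float, float] = (11_500.0, 15_500.0)
    deep_sleep_sd: float = 2_400.0
    missing_prob: float = 0.05
    seed: int = 0
    start_date: str = "2021-01-01"
    planted_effects: tuple[PlantedEffect, ...] = ()

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ConfigurationError("missing_prob must lie in [0, 1]")
        for name in (
            "steps_log_sd",
            "light_activity_shape",
            "moderate_activity_shape",
            "intense_activity_shape",
            "light_sleep_sd",
            "deep_sleep_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    def target_sd(self, target: str) -> float:
        return self.light_sleep_sd if target == "light_sleep" else self.deep_sleep_sd


def load_cohort_config(source: str | Path | IO[str]) -> CohortConfig:
    """Load a CohortConfig from a flat JSON or YAML document."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        doc = yaml.safe_load(Path(source).read_text())
    return cohort_config_from_dict(doc)


def cohort_config_from_dict(doc: dict) -> CohortConfig:
    doc = dict(doc)
    effects = []
    for e in doc.pop("planted_effects", []) or []:
        e = dict(e)
        feat = e.pop("feature")
        if isinstance(feat, str):
            feat = FeatureId.from_name(feat)
        participants = e.pop("participants", None)
        if participants is not None:
            participants = tuple(participants)
        effects.append(PlantedEffect(feature=feat, participants=participants, **e))
    known = {f.name for f in fields(CohortConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key, val in list(doc.items()):
        if isinstance(val, list) and len(val) == 2:
            doc[key] = tuple(val)
    return CohortConfig(planted_effects=tuple(effects), **doc)


def _truncated_normal(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    """Normal draws re-sampled into [0, 86400) (resampling, not clipping)."""
    out = rng.normal(mean, sd, size)
    bad = (out < 0) | (out >= SECONDS_PER_DAY)
    while bad.any():
        out[bad] = rng.normal(
            np.broadcast_to(mean, out.shape)[bad] if np.ndim(mean) else mean,
            sd,
            bad.sum(),
        )
        bad = (out < 0) | (out >= SECONDS_PER_DAY)
    return out


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a synthetic cohort of daily records.

    Each participant gets consecutive calendar days.  Planted effects are
    applied after the activity series is simulated: the planted descriptor
    is computed from the complete activity record, its per-participant
    empirical quantile becomes the threshold, and qualifying days have the
    target mean shifted by ``shift`` x the participant's configured target
    SD.  Missing cells are then inserted independently per measurement field
    per day (MCAR).  The same config and seed yield the identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.start_date)
    frames: list[pd.DataFrame] = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        if np.isscalar(config.days_per_participant):
            n_days = int(config.days_per_participant)
        else:
            lo, hi = config.days_per_participant
            n_days = int(rng.integers(int(lo), int(hi) + 1))
        if n_days == 0:
            continue

        # per-participant baselines
        lo, hi = _as_range(config.steps_median_range)
        steps_median = np.exp(rng.uniform(np.log(lo), np.log(hi))) if lo > 0 else lo
        means = {}
        for q in (
            "light_activity",
            "moderate_activity",
            "intense_activity",
            "light_sleep",
            "deep_sleep",
        ):
            lo_m, hi_m = _as_range(getattr(config, f"{q}_mean_range"))
            means[q] = rng.uniform(lo_m, hi_m)

        steps = np.round(
            np.exp(rng.normal(np.log(steps_median), config.steps_log_sd, n_days))
        )
        daily = {
            "steps": steps,
            "light_activity_s": np.round(
                np.minimum(
                    rng.gamma(
                        config.light_activity_shape,
                        means["light_activity"] / config.light_activity_shape,
                        n_days,
                    ),
                    SECONDS_PER_DAY - 1,
                )
            ),
            "moderate_activity_s": np.round(
                np.minimum(
                    rng.gamma(
                        config.moderate_activity_shape,
                        means["moderate_activity"] / config.moderate_activity_shape,
                        n_days,
                    ),
                    SECONDS_PER_DAY - 1,
                )
            ),
            "intense_activity_s": np.round(
                np.minimum(
                    rng.gamma(
                        config.intense_activity_shape,
                        means["intense_activity"] / config.intense_activity_shape,
                        n_days,
                    ),
                    SECONDS_PER_DAY - 1,
                )
            ),
            "light_sleep_s": np.round(
                _truncated_normal(
                    rng, means["light_sleep"], config.light_sleep_sd, n_days
                )
            ),
            "deep_sleep_s": np.round(
                _truncated_normal(rng, means["deep_sleep"], config.deep_sleep_sd, n_days)
            ),
        }

        for effect in config.planted_effects:
            if effect.participants is not None and pid not in effect.participants:
                continue
            descriptor = lagged_aggregate(
                daily[QUANTITY_COLUMNS[effect.feature.quantity]],
                effect.feature.aggregate,
                effect.feature.window,
            )
            defined = ~np.isnan(descriptor)
            if not defined.any():
                continue
            threshold = float(np.nanquantile(descriptor, effect.quantile))
            if effect.operator == "<=":
                member = defined & (descriptor <= threshold)
            else:
                member = defined & (descriptor >= threshold)
            frac = member.sum() / defined.sum()
            if not 0.10 < frac < 0.90:
                raise ConfigurationError(
                    f"planted effect on {effect.feature.name} realizes subgroup "
                    f"fraction {frac:.3f} outside (0.10, 0.90) for {pid}"
                )
            col = target_column(effect.target)
            shift = effect.shift * config.target_sd(effect.target)
            daily[col] = np.clip(
                daily[col] + shift * member, 0, SECONDS_PER_DAY - 1
            )

        df = pd.DataFrame(daily)
        df.insert(0, "participant_id", pid)
        df.insert(1, "date", pd.date_range(start, periods=n_days, freq="D"))
        if config.missing_prob > 0:
            mask = rng.random((n_days, len(MEASUREMENT_COLUMNS))) < config.missing_prob
            for j, col in enumerate(MEASUREMENT_COLUMNS):
                df.loc[mask[:, j], col] = np.nan
        frames.append(df)

    if not frames:
        return pd.DataFrame(columns=SCHEMA_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out[SCHEMA_COLUMNS]
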