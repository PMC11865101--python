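"""Daily-record schema I/O and the synthetic cohort generator."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from actisleep.features import FeatureId, build_cases
from actisleep.correlate import spearman_r_matrix
from actisleep.synthio import (
    CohortConfig,
    ConfigurationError,
    PlantedEffect,
    RecordValidationError,
    SchemaError,
    SCHEMA_COLUMNS,
    cohort_config_from_dict,
    generate_cohort,
    read_daily_records,
    write_daily_records,
)

HEADER = ",".join(SCHEMA_COLUMNS)


def _csv(*rows: str) -> io.StringIO:
    return io.StringIO("\n".join([HEADER, *rows]) + "\n")


class TestReadDailyRecords:
    def test_count_preserved(self):
        rows = [
            f"P0{p},2021-03-0{d},1000,3600,600,300,13000,12000"
            for p in (1, 2)
            for d in (1, 2, 3)
        ]
        df = read_daily_records(_csv(*rows))
        assert len(df) == 6
        assert list(df.columns) == SCHEMA_COLUMNS

    def test_duplicate_key_names_offender(self):
        rows = [
            "P01,2021-03-01,1000,3600,600,300,13000,12000",
            "P01,2021-03-01,2000,3600,600,300,13000,12000",
        ]
        with pytest.raises(SchemaError, match="P01.*2021-03-01"):
            read_daily_records(_csv(*rows))

    def test_negative_duration_rejected_with_row(self):
        rows = [
            "P01,2021-03-01,1000,3600,600,300,13000,12000",
            "P01,2021-03-02,1000,3600,600,300,-5,12000",
        ]
        with pytest.raises(RecordValidationError, match="light_sleep_s.*row 1"):
            read_daily_records(_csv(*rows))

    def test_duration_above_day_rejected(self):
        rows = ["P01,2021-03-01,1000,90000,600,300,13000,12000"]
        with pytest.raises(RecordValidationError, match="86400"):
            read_daily_records(_csv(*rows))

    def test_missing_cells_become_nan_and_rows_sorted(self):
        rows = [
            "P02,2021-03-01,1000,3600,600,300,13000,12000",
            "P01,2021-03-02,,3600,600,300,13000,",
            "P01,2021-03-01,1000,3600,600,300,13000,12000",
        ]
        df = read_daily_records(_csv(*rows))
        assert list(df["participant_id"]) == ["P01", "P01", "P02"]
        assert math.isnan(df.loc[1, "steps"])
        assert math.isnan(df.loc[1, "deep_sleep_s"])


class TestWriteDailyRecords:
    def test_empty_collection_header_only(self):
        buf = io.StringIO()
        write_daily_records(pd.DataFrame(columns=SCHEMA_COLUMNS), buf)
        assert buf.getvalue().strip() == HEADER

    def test_missing_cell_round_trips(self):
        df = read_daily_records(
            _csv("P01,2021-03-01,1000,3600,600,300,13000,")
        )
        buf = io.StringIO()
        write_daily_records(df, buf)
        again = read_daily_records(io.StringIO(buf.getvalue()))
        pd.testing.assert_frame_equal(df, again)

    def test_round_trip_and_byte_stability_random_cohort(self):
        cfg = CohortConfig(
            n_participants=10, days_per_participant=100, seed=42, missing_prob=0.1
        )
        records = generate_cohort(cfg)
        assert len(records) == 1000
        b1, b2 = io.StringIO(), io.StringIO()
        write_daily_records(records, b1)
        write_daily_records(records, b2)
        assert b1.getvalue() == b2.getvalue()
        again = read_daily_records(io.StringIO(b1.getvalue()))
        pd.testing.assert_frame_equal(
            records.reset_index(drop=True), again, check_dtype=False
        )


class TestGenerateCohort:
    def test_zero_participants_empty(self):
        assert generate_cohort(CohortConfig(n_participants=0)).empty

    def test_same_seed_identical(self):
        cfg = CohortConfig(n_participants=4, days_per_participant=(32, 90), seed=7)
        pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(cfg))

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(n_participants=2, days_per_participant=30, seed=1))
        b = generate_cohort(CohortConfig(n_participants=2, days_per_participant=30, seed=2))
        assert not a.equals(b)

    def test_steps_mean_within_clt_bound(self):
        # degenerate ranges pin the participant baseline exactly
        median, log_sd, n = 4000.0, 0.5, 10_000
        cfg = CohortConfig(
            n_participants=1,
            days_per_participant=n,
            steps_median_range=(median, median),
            steps_log_sd=log_sd,
            missing_prob=0.0,
            seed=3,
        )
        steps = generate_cohort(cfg)["steps"].to_numpy()
        mean = median * math.exp(log_sd**2 / 2)
        sd = mean * math.sqrt(math.exp(log_sd**2) - 1)
        assert abs(steps.mean() - mean) < 3 * sd / math.sqrt(n)

    def test_missingness_rate(self):
        cfg = CohortConfig(
            n_participants=2, days_per_participant=2000, missing_prob=0.2, seed=9
        )
        rec = generate_cohort(cfg)
        frac = rec[SCHEMA_COLUMNS[2:]].isna().to_numpy().mean()
        assert abs(frac - 0.2) < 0.02

    def test_invariants_of_generated_values(self):
        rec = generate_cohort(
            CohortConfig(n_participants=5, days_per_participant=60, seed=17)
        )
        vals = rec[SCHEMA_COLUMNS[2:]]
        assert (vals.min(numeric_only=True) >= 0).all()
        assert (vals[SCHEMA_COLUMNS[3:]].max() < 86_400).all()
        assert not rec.duplicated(["participant_id", "date"]).any()


class TestPlantedEffects:
    def test_quantile_outside_band_rejected(self):
        with pytest.raises(ConfigurationError, match="0.10, 0.90"):
            PlantedEffect("light_sleep", FeatureId("steps", "mean", 1), "<=", 0.05, 1.0)
        with pytest.raises(ConfigurationError):
            PlantedEffect("deep_sleep", FeatureId("steps", "mean", 1), ">=", 0.05, 1.0)

    def test_realized_shift_converges(self):
        # planted 1-SD shift: subgroup-vs-complement target mean difference
        # approaches shift * SD at large n
        fid = FeatureId("steps", "min", 3)
        shift, q = 1.0, 0.4
        cfg = CohortConfig(
            n_participants=1,
            days_per_participant=10_000,
            missing_prob=0.0,
            seed=21,
            planted_effects=(PlantedEffect("light_sleep", fid, "<=", q, shift),),
        )
        table = build_cases(generate_cohort(cfg))
        x = table.df[fid.name].to_numpy()
        y = table.df["light_sleep_s"].to_numpy()
        thr = np.quantile(x, q)
        member = x <= thr
        diff = y[member].mean() - y[~member].mean()
        assert abs(diff - shift * cfg.light_sleep_sd) / (shift * cfg.light_sleep_sd) < 0.05

    def test_no_shift_targets_independent_of_descriptors(self):
        # over replicate null cohorts the mean Spearman r of every
        # descriptor with the target stays within Monte-Carlo error of 0
        reps, rs = 200, []
        for s in range(reps):
            cfg = CohortConfig(
                n_participants=1, days_per_participant=43, missing_prob=0.0, seed=s
            )
            table = build_cases(generate_cohort(cfg))
            X = table.df[table.feature_names].to_numpy()
            y = table.df["light_sleep_s"].to_numpy()
            rs.append(spearman_r_matrix(X, y))
        rs = np.array(rs)  # (reps, 28)
        n_cases = 40
        se = 1 / math.sqrt((n_cases - 1) * reps)
        assert (np.abs(rs.mean(axis=0)) < 4 * se).all()


class TestConfigDocument:
    def test_from_dict_with_planted_effect(self):
        cfg = cohort_config_from_dict(
            {
                "n_participants": 2,
                "days_per_participant": [40, 60],
                "planted_effects": [
                    {
                        "target": "deep_sleep",
                        "feature": "steps_min_3d",
                        "operator": "<=",
                        "quantile": 0.3,
                        "shift": 0.8,
                    }
                ],
            }
        )
        assert cfg.days_per_participant == (40, 60)
        assert cfg.planted_effects[0].feature == FeatureId("steps", "min", 3)

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            cohort_config_from_dict({"n_participnts": 3})
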