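"""End-to-end study pipeline and report rendering.

Runs the full analysis replica from a single config: ingest or generate
daily records, build the lagged case table, apply the >30-day inclusion
filter, screen Spearman correlations with Holm control, discover the best
subgroup per scope and target, and validate it with the Distribution of
False Discoveries — on the individual level (each participant separately)
and on the group level (pooled per-participant-standardized cases).
Reports are written as deterministic JSON/CSV given fixed seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlate import GROUP_SCOPE, run_correlation_screen
from .dfd import DfdResult, dfd_test
from .features import (
    CaseTable,
    TARGETS,
    build_cases,
    eligibility_filter,
    standardize_per_participant,
)
from .subgroups import Condition
from .synthio import CohortConfig, generate_cohort, read_daily_records

logger = logging.getLogger(__name__)

_QUANTITY_PHRASES = {
    "steps": "number of steps",
    "light_activity": "duration of light physical activities",
    "moderate_activity": "duration of moderate physical activities",
    "intense_activity": "duration of intense physical activities",
}
_AGGREGATE_WORDS = {"mean": "average", "min": "minimum", "max": "maximum"}


def _format_duration(seconds: float) -> str:
    """Durations print in minutes up to 2 h, then as 'H h and M min'."""
    minutes = int(round(seconds / 60.0))
    if minutes <= 120:
        return f"{minutes} min"
    h, m = divmod(minutes, 60)
    return f"{h} h and {m} min"


def render_condition_text(condition: Condition, standardized: bool = False) -> str:
    """Human-readable description of a threshold condition.

    Raw thresholds are printed as whole steps or as minutes (h + min above
    two hours); standardized (group-level) thresholds are printed in
    within-person SD units.  The rendering is injective over the feature
    universe: every feature yields a distinct phrase.
    """
    fid = condition.feature
    phrase = _QUANTITY_PHRASES[fid.quantity]
    if fid.window == 1:
        desc = f"{phrase} previous day"
    else:
        desc = f"{_AGGREGATE_WORDS[fid.aggregate]} {phrase} in prior {fid.window} days"
    if standardized:
        value = f"{condition.threshold:.2f} SD"
    elif fid.is_duration:
        value = _format_duration(condition.threshold)
    else:
        value = f"{int(round(condition.threshold))}"
    return f"{desc} {condition.operator.replace('<=', '≤').replace('>=', '≥')} {value}"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end study run."""

    source: CohortConfig | str | Path
    min_days: int = 30
    windows: tuple[int, ...] = (1, 2, 3)
    alpha: float = 0.05
    size_bounds: tuple[float, float] = (0.10, 0.90)
    n_permutations: int = 1000
    seed_permutation: int = 0
    modes: tuple[str, ...] = ("individual", "group")
    group_permute_within: bool = True
    holm_family: str = "per-scope"

    def __post_init__(self) -> None:
        lo, hi = self.size_bounds
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("size bounds must satisfy 0 < lo < hi < 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for m in self.modes:
            if m not in ("individual", "group"):
                raise ValueError(f"unknown mode {m!r}")


@dataclass
class StudyReport:
    """Everything the study computed, plus provenance."""

    headline_correlations: pd.DataFrame  # Table-2 shape (significant only)
    correlations: pd.DataFrame  # all tests, both modes
    significant_subgroups: pd.DataFrame  # Table-3/4 shape (DFD-gated)
    dfd_results: list[DfdResult]
    counts: dict
    provenance: dict
    log_lines: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "counts": self.counts,
            "headline_correlations": _df_records(self.headline_correlations),
            "significant_subgroups": _df_records(self.significant_subgroups),
            "dfd": [
                {
                    "scope": r.scope,
                    "target": r.target,
                    "observed_quality": round(r.observed_quality, 10),
                    "p_value": round(r.p_value, 10),
                    "significant": bool(r.significant),
                    "n_permutations": int(r.n_permutations),
                    "seed": int(r.seed),
                    "condition": str(r.best_subgroup.condition)
                    if r.best_subgroup
                    else None,
                }
                for r in self.dfd_results
            ],
            "provenance": self.provenance,
        }


def _df_records(df: pd.DataFrame) -> list[dict]:
    recs = df.to_dict("records")
    out = []
    for rec in recs:
        clean = {}
        for k, v in rec.items():
            if isinstance(v, (np.floating, float)):
                clean[k] = round(float(v), 10) if v == v else None
            elif isinstance(v, (np.integer,)):
                clean[k] = int(v)
            elif isinstance(v, (np.bool_, bool)):
                clean[k] = bool(v)
            else:
                clean[k] = v
        out.append(clean)
    return out


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _subgroup_row(scope: str, res: DfdResult, standardized: bool) -> dict:
    sg = res.best_subgroup
    return {
        "scope": scope,
        "target": res.target,
        "condition": render_condition_text(sg.condition, standardized=standardized),
        "feature": sg.condition.feature.name,
        "operator": sg.condition.operator,
        "threshold": sg.condition.threshold,
        "size_pct": round(100.0 * sg.size_frac, 1),
        "n_cases": sg.n_cases,
        "quality": sg.quality,
        "normalized_target_mean": sg.normalized_target_mean,
        "target_mean_diff": sg.target_mean_diff,
        "dfd_p": res.p_value,
    }


def run_study(config: RunConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Execute the full pipeline and (optionally) write the report bundle.

    Output files (when ``out_dir`` is given): ``report.json`` (deterministic
    given seeds — no timestamps), ``correlations.csv``, ``subgroups.csv``,
    ``dfd.json`` (including full null-quality vectors for resumability) and
    ``log.txt``.  A run with zero included participants still produces a
    report with an explicit inclusion summary and empty findings.
    """
    log: list[str] = []

    if isinstance(config.source, CohortConfig):
        records = generate_cohort(config.source)
        source_prov = {"generator": _jsonable(config.source)}
    else:
        records = read_daily_records(config.source)
        source_prov = {"file": str(config.source)}
    n_total = records["participant_id"].nunique() if len(records) else 0
    log.append(f"ingest: {n_total} participants, {len(records)} daily records")

    cases = build_cases(records, config.windows)
    log.append(f"features: {cases.n_cases} cases, {len(cases.feature_names)} features")

    included, excluded = eligibility_filter(cases, config.min_days)
    n_included = included.df["participant_id"].nunique() if included.n_cases else 0
    log.append(
        f"inclusion: {n_included} participants with > {config.min_days} cases "
        f"included, {len(excluded)} excluded"
    )

    corr_frames: list[pd.DataFrame] = []
    dfd_results: list[DfdResult] = []
    subgroup_rows: list[dict] = []
    pooled: CaseTable | None = None

    # deterministic permutation seeds, one per (scope, target) test
    seed_pool = iter(
        int(s % (2**31))
        for s in np.random.SeedSequence(config.seed_permutation).generate_state(4096)
    )

    if "individual" in config.modes and n_included > 0:
        corr_ind = run_correlation_screen(
            included, "individual", config.alpha, config.holm_family
        )
        corr_ind.insert(0, "mode", "individual")
        corr_frames.append(corr_ind)
        log.append(
            f"correlate[individual]: {len(corr_ind)} tests across "
            f"{n_included} participants"
        )
        for pid in sorted(included.df["participant_id"].unique()):
            table = included.for_participant(pid)
            for target in TARGETS:
                res = dfd_test(
                    table,
                    target,
                    n_permutations=config.n_permutations,
                    seed=next(seed_pool),
                    alpha=config.alpha,
                    size_bounds=config.size_bounds,
                    scope=pid,
                )
                dfd_results.append(res)
                if res.significant:
                    subgroup_rows.append(_subgroup_row(pid, res, standardized=False))
        log.append(
            f"dfd[individual]: {2 * n_included} tests x "
            f"{config.n_permutations} permutations"
        )

    if "group" in config.modes and n_included > 0:
        pooled = standardize_per_participant(included)
        log.append(
            f"standardize: {len(pooled.feature_names)} feature columns retained, "
            f"{len(pooled.provenance.get('dropped_columns', []))} dropped"
        )
        corr_grp = run_correlation_screen(
            pooled, "group", config.alpha, config.holm_family
        )
        corr_grp.insert(0, "mode", "group")
        corr_frames.append(corr_grp)
        for target in TARGETS:
            res = dfd_test(
                pooled,
                target,
                n_permutations=config.n_permutations,
                seed=next(seed_pool),
                alpha=config.alpha,
                size_bounds=config.size_bounds,
                within_participant=config.group_permute_within,
                scope=GROUP_SCOPE,
            )
            dfd_results.append(res)
            if res.significant:
                subgroup_rows.append(
                    _subgroup_row(GROUP_SCOPE, res, standardized=True)
                )
        log.append(
            f"dfd[group]: pooled n = {pooled.n_cases}, "
            f"{config.n_permutations} permutations "
            f"({'within' if config.group_permute_within else 'global'} permutation)"
        )

    correlations = (
        pd.concat(corr_frames, ignore_index=True)
        if corr_frames
        else pd.DataFrame(
            columns=[
                "mode",
                "scope",
                "target",
                "feature",
                "n",
                "r",
                "p",
                "strength",
                "holm_reject",
                "headline",
            ]
        )
    )
    headline = correlations[correlations.get("headline", False) == True]  # noqa: E712
    sub_cols = [
        "scope",
        "target",
        "condition",
        "feature",
        "operator",
        "threshold",
        "size_pct",
        "n_cases",
        "quality",
        "normalized_target_mean",
        "target_mean_diff",
        "dfd_p",
    ]
    subgroups_df = pd.DataFrame(subgroup_rows, columns=sub_cols)

    # gatekeeping invariant: nothing reported outside the size bounds or
    # without DFD significance
    lo, hi = config.size_bounds
    assert (subgroups_df["dfd_p"] < config.alpha).all()
    assert ((subgroups_df["size_pct"] / 100 >= lo) & (subgroups_df["size_pct"] / 100 <= hi)).all()

    sig_participants = set(headline["scope"]) | set(subgroups_df["scope"])
    sig_participants.discard(GROUP_SCOPE)
    counts = {
        "participants_total": int(n_total),
        "participants_included": int(n_included),
        "participants_excluded": [str(e) for e in excluded],
        "participants_with_significant_finding": sorted(sig_participants),
        "n_cases_included": int(included.n_cases),
        "n_correlation_tests": int(len(correlations)),
        "n_dfd_tests": int(len(dfd_results)),
    }
    provenance = {
        "source": source_prov,
        "run_config": {
            k: _jsonable(v)
            for k, v in dataclasses.asdict(config).items()
            if k != "source"
        },
        "version": __version__,
    }

    report = StudyReport(
        headline_correlations=headline.reset_index(drop=True),
        correlations=correlations,
        significant_subgroups=subgroups_df,
        dfd_results=dfd_results,
        counts=counts,
        provenance=provenance,
        log_lines=log,
    )
    if out_dir is not None:
        write_report(report, out_dir)
        # persist intermediates so each stage is independently re-runnable
        _write_case_csv(included, Path(out_dir) / "cases.csv")
        if pooled is not None:
            _write_case_csv(pooled, Path(out_dir) / "cases_standardized.csv")
    return report


def _write_case_csv(table: CaseTable, path: Path) -> None:
    df = table.df.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report.to_json_dict(), sort_keys=True, indent=2) + "\n"
    )
    report.correlations.to_csv(out / "correlations.csv", index=False)
    report.significant_subgroups.to_csv(out / "subgroups.csv", index=False)
    dfd_doc = [
        {
            "scope": r.scope,
            "target": r.target,
            "observed_quality": round(r.observed_quality, 10),
            "p_value": round(r.p_value, 10),
            "significant": bool(r.significant),
            "n_permutations": int(r.n_permutations),
            "seed": int(r.seed),
            "null_qualities": [round(float(q), 6) for q in r.null_qualities],
        }
        for r in report.dfd_results
    ]
    (out / "dfd.json").write_text(json.dumps(dfd_doc, sort_keys=True, indent=2) + "\n")
    (out / "log.txt").write_text("\n".join(report.log_lines) + "\n")
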