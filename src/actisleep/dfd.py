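"""Distribution of False Discoveries: permutation significance for subgroups.

Exhaustively searching 28 descriptors for the best-scoring subgroup is a
massive multiple comparison; even pure noise yields a subgroup with a
respectable explained variance.  The Distribution of False Discoveries
(DFD) quantifies this: repeatedly swap-randomize the target column
(destroying any real descriptor-target association while keeping both
marginals and the descriptors' joint distribution intact), re-run the full
discovery, and collect the best quality of each permuted dataset.  The
observed best quality is then located in this null distribution; its
add-one permutation p-value is

    p = (1 + #{null >= observed}) / (1 + n_permutations),

strictly positive and exact for exchangeable targets.  A finding is
declared significant when p < alpha (strictly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import CaseTable, target_column
from .subgroups import SubgroupSearch, SubgroupResult, discover_best

logger = logging.getLogger(__name__)

MIN_PERMUTATIONS = 100


@dataclass(frozen=True)
class DfdResult:
    """Outcome of one DFD significance test for one (scope, target) pair."""

    scope: str
    target: str
    observed_quality: float
    null_qualities: np.ndarray
    n_permutations: int
    p_value: float
    significant: bool
    alpha: float
    seed: int
    best_subgroup: SubgroupResult | None = None

    def __post_init__(self) -> None:
        assert len(self.null_qualities) == self.n_permutations


def _permutation_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """One child generator per permutation, stable under extension.

    Children are spawned from a single seed sequence, so the first k null
    qualities are identical whether n_permutations is k or 2k (streamed
    reproducibility).
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def _permute_target(
    y: np.ndarray, rng: np.random.Generator, groups: np.ndarray | None
) -> np.ndarray:
    if groups is None:
        return rng.permutation(y)
    out = y.copy()
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        out[idx] = y[idx[rng.permutation(len(idx))]]
    return out


def swap_randomize(
    case_table: CaseTable,
    target: str,
    seed: int,
    within_participant: bool = False,
) -> CaseTable:
    """Return a copy of the table with the target column permuted.

    All feature columns are untouched, preserving their joint distribution;
    only the link between descriptors and target is destroyed.  With
    ``within_participant=True`` targets are shuffled within each
    participant's cases only (preserving per-participant target marginals,
    the natural null for the pooled standardized table).
    """
    df = case_table.df
    if len(df) < 2:
        raise ValueError("need at least 2 cases to permute")
    col = target_column(target)
    rng = np.random.default_rng(seed)
    groups = df["participant_id"].to_numpy() if within_participant else None
    out = df.copy()
    out[col] = _permute_target(df[col].to_numpy(dtype=float), rng, groups)
    return CaseTable(out, {**case_table.provenance, "permuted": target, "seed": seed})


def dfd_null(
    case_table: CaseTable,
    target: str,
    n_permutations: int = 1000,
    seed: int = 0,
    size_bounds: tuple[float, float] = (0.10, 0.90),
    within_participant: bool = False,
    search: SubgroupSearch | None = None,
) -> np.ndarray:
    """Null distribution of best subgroup qualities under swap randomization.

    For each permutation the target is shuffled and the full exhaustive
    discovery re-run under identical constraints; the best explained
    variance is recorded (0 with a warning if no admissible condition
    exists, e.g. a constant permuted target).  Reproducible given ``seed``.
    """
    if n_permutations < MIN_PERMUTATIONS:
        raise ValueError(f"need at least {MIN_PERMUTATIONS} permutations")
    df = case_table.df
    if search is None:
        search = SubgroupSearch(df[case_table.feature_names], size_bounds)
    y = df[target_column(target)].to_numpy(dtype=float)
    groups = df["participant_id"].to_numpy() if within_participant else None
    nulls = np.empty(n_permutations)
    n_degenerate = 0
    for i, rng in enumerate(_permutation_rngs(seed, n_permutations)):
        y_perm = _permute_target(y, rng, groups)
        ev, ss_total = search.split_quality(y_perm)
        if ss_total == 0.0 or np.isnan(ev).all():
            nulls[i] = 0.0
            n_degenerate += 1
        else:
            nulls[i] = np.nanmax(ev)
    if n_degenerate:
        logger.warning(
            "%d/%d permutations had no admissible subgroup; quality 0 recorded",
            n_degenerate,
            n_permutations,
        )
    return nulls


def dfd_pvalue(observed: float, null_qualities: np.ndarray) -> float:
    """Add-one permutation p-value; ties count toward the numerator."""
    null_qualities = np.asarray(null_qualities, dtype=float)
    if null_qualities.size == 0:
        raise ValueError("null distribution is empty")
    return float(
        (1 + np.count_nonzero(null_qualities >= observed))
        / (1 + null_qualities.size)
    )


def dfd_test(
    case_table: CaseTable,
    target: str,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    size_bounds: tuple[float, float] = (0.10, 0.90),
    within_participant: bool = False,
    scope: str = "",
) -> DfdResult:
    """Discover the best subgroup and test it against its DFD null."""
    df = case_table.df
    search = SubgroupSearch(df[case_table.feature_names], size_bounds)
    best = discover_best(case_table, target, size_bounds, search=search)
    if best is None:
        raise ValueError("no admissible subgroup in the observed data")
    nulls = dfd_null(
        case_table,
        target,
        n_permutations,
        seed,
        size_bounds,
        within_participant,
        search=search,
    )
    p = dfd_pvalue(best.quality, nulls)
    return DfdResult(
        scope=scope or str(case_table.provenance.get("scope", "")),
        target=target,
        observed_quality=best.quality,
        null_qualities=nulls,
        n_permutations=n_permutations,
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
        seed=seed,
        best_subgroup=best,
    )


def calibrate(
    alpha: float,
    make_case_table,
    n_datasets: int = 500,
    n_permutations: int = 500,
    target: str = "light_sleep",
    seed: int = 0,
) -> float:
    """Empirical type-I error of the DFD test over independent null datasets.

    ``make_case_table(seed) -> CaseTable`` must generate an independent
    dataset with no descriptor-target association.  Returns the fraction of
    datasets whose best subgroup is declared significant at ``alpha``.
    """
    if alpha == 0.0:
        return 0.0
    rng_seeds = np.random.SeedSequence(seed).generate_state(2 * n_datasets)
    n_sig = 0
    for i in range(n_datasets):
        table = make_case_table(int(rng_seeds[2 * i] % (2**31)))
        res = dfd_test(
            table,
            target,
            n_permutations=n_permutations,
            seed=int(rng_seeds[2 * i + 1] % (2**31)),
            alpha=alpha,
        )
        n_sig += res.significant
    return n_sig / n_datasets
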