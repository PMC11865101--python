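"""Spearman screening of lagged activity features against sleep targets.

Every feature is rank-correlated with each sleep target, separately per
participant (individual mode) or on the pooled per-participant-standardized
table (group mode).  Two-sided p-values come from the t-distributed
statistic for a rank correlation, and the family-wise error over the
28 features x 2 targets tested within a scope is controlled with the
Holm-Bonferroni step-down procedure at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import CaseTable, TARGETS, target_column

logger = logging.getLogger(__name__)

GROUP_SCOPE = "GROUP"

#: |r| banding for the conventional qualitative strength labels.
STRENGTH_BANDS = ((0.10, "negligible"), (0.40, "weak"), (0.60, "moderate"))


class UndefinedCorrelationError(ValueError):
    """A vector has zero rank variance; the correlation is undefined."""


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_r(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks.  Raises
    :class:`UndefinedCorrelationError` when either vector has zero rank
    variance (a constant vector) — deliberately distinct from r = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3 observations")
    rx, ry = _midranks(x), _midranks(y)
    sx, sy = rx.std(ddof=1), ry.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero rank variance: correlation undefined")
    r = float(np.dot(rx - rx.mean(), ry - ry.mean()) / ((len(x) - 1) * sx * sy))
    return float(np.clip(r, -1.0, 1.0))


def spearman_r_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman r of each column of ``X`` with ``y`` (NaN where undefined)."""
    RX = np.apply_along_axis(_midranks, 0, np.asarray(X, dtype=float))
    ry = _midranks(np.asarray(y, dtype=float))
    RX = RX - RX.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((RX**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, RX.T @ ry / denom, np.nan)
    return np.clip(r, -1.0, 1.0)


def spearman_p(r: float, n: int) -> float:
    """Two-sided p-value for a rank correlation from the t approximation.

    Uses ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of
    freedom.  ``|r| = 1`` is reported as p = 0 (the statistic is infinite;
    the value is exact only up to the t approximation itself).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_p_exact(x, y) -> float:
    """Exact permutation p-value for |r|, for small samples (n <= 8).

    Enumerates all n! orderings of ``y``; intended as a testing aid, not
    the production path (the screen uses the t approximation throughout).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 8:
        raise ValueError("exact enumeration supported only for n <= 8")
    observed = abs(spearman_r(x, y))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = spearman_r(x, y[list(perm)])
        count += abs(r) >= observed - 1e-12
        total += 1
    return count / total


def holm_bonferroni(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down rejections, mapped back to input order.

    Sort p-values ascending; reject the i-th smallest (1-based) while
    ``p(i) <= alpha / (m - i + 1)``, stopping at the first failure.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject


def strength_label(r: float) -> str:
    """Qualitative label for |r|: negligible / weak / moderate / strong."""
    a = abs(r)
    if a > 1:
        raise ValueError("|r| must be <= 1")
    for bound, label in STRENGTH_BANDS:
        if a < bound:
            return label
    return "strong"


@dataclass(frozen=True)
class CorrelationResult:
    scope: str
    target: str
    feature: str
    n: int
    r: float
    p: float
    holm_reject: bool
    strength: str
    headline: bool


def run_correlation_screen(
    case_table: CaseTable,
    mode: str,
    alpha: float = 0.05,
    family: str = "per-scope",
) -> pd.DataFrame:
    """Screen every (feature, target) pair with Spearman + Holm.

    ``mode='individual'`` treats each participant as a scope (the table
    should already be eligibility-filtered and unstandardized);
    ``mode='group'`` pools all cases into the single scope ``GROUP`` (the
    table should be per-participant standardized).  The Holm family is all
    features x both targets within a scope (``family='per-scope'``, the
    default 56 tests) or per target (``family='per-target'``, 28 tests).
    Scopes with fewer than 3 cases are skipped with a warning.  Per
    (scope, target), the largest-|r| Holm-significant feature is flagged
    ``headline``.
    """
    if mode not in ("individual", "group"):
        raise ValueError("mode must be 'individual' or 'group'")
    if family not in ("per-scope", "per-target"):
        raise ValueError("family must be 'per-scope' or 'per-target'")
    feat_names = case_table.feature_names
    df = case_table.df
    scopes = (
        [(GROUP_SCOPE, df)]
        if mode == "group"
        else list(df.groupby("participant_id", sort=True))
    )
    rows: list[dict] = []
    for scope, sub in scopes:
        n = len(sub)
        if n < 3:
            logger.warning("scope %s has %d < 3 cases; skipped", scope, n)
            continue
        X = sub[feat_names].to_numpy(dtype=float)
        scope_rows: list[dict] = []
        for target in TARGETS:
            y = sub[target_column(target)].to_numpy(dtype=float)
            r = spearman_r_matrix(X, y)
            for j, feat in enumerate(feat_names):
                rj = r[j]
                if np.isnan(rj):
                    logger.warning(
                        "scope %s: %s vs %s has zero rank variance; excluded",
                        scope,
                        feat,
                        target,
                    )
                    continue
                scope_rows.append(
                    {
                        "scope": str(scope),
                        "target": target,
                        "feature": feat,
                        "n": n,
                        "r": rj,
                        "p": spearman_p(rj, n),
                        "strength": strength_label(rj),
                    }
                )
        if not scope_rows:
            continue
        sdf = pd.DataFrame(scope_rows)
        if family == "per-scope":
            sdf["holm_reject"] = holm_bonferroni(sdf["p"].to_numpy(), alpha)
        else:
            sdf["holm_reject"] = False
            for target in TARGETS:
                m = sdf["target"] == target
                if m.any():
                    sdf.loc[m, "holm_reject"] = holm_bonferroni(
                        sdf.loc[m, "p"].to_numpy(), alpha
                    )
        sdf["headline"] = False
        for target in TARGETS:
            sig = sdf[(sdf["target"] == target) & sdf["holm_reject"]]
            if len(sig):
                sdf.loc[sig["r"].abs().idxmax(), "headline"] = True
        rows.extend(sdf.to_dict("records"))
    out = pd.DataFrame(
        rows,
        columns=[
            "scope",
            "target",
            "feature",
            "n",
            "r",
            "p",
            "strength",
            "holm_reject",
            "headline",
        ],
    )
    return out.reset_index(drop=True)
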