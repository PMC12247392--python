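"""Validation of model-based small-area estimates against direct estimates.

Model-based estimates are benchmarked against design-based direct survey
estimates on the areas where both exist: agreement metrics (mean squared
error, mean absolute difference, Pearson and Spearman correlations),
distributional summaries (quartiles, IQR, range), and containment of each
model estimate in the direct estimate's 95% CI.

All metrics operate on the percentage scale (values like 65.0 for 65%),
matching the convention of published prevalence tables; MSE therefore
carries squared-percent units even though reports print it with a % sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import InputError

__all__ = [
    "SeriesSummary",
    "ValidationReport",
    "compare_estimates",
    "summarize_series",
    "containment_check",
]


@dataclass(frozen=True)
class SeriesSummary:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def range(self) -> float:
        return self.maximum - self.minimum

    def as_row(self) -> dict[str, float]:
        """Summary in the conventional table layout: Min 25% Median 75% Max IQR."""
        return {
            "Min": self.minimum,
            "25%": self.q1,
            "Median": self.median,
            "75%": self.q3,
            "Max": self.maximum,
            "IQR": self.iqr,
        }


def summarize_series(values: Sequence[float]) -> SeriesSummary:
    """Five-number summary with quartiles by linear interpolation."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise InputError("cannot summarize an empty series")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return SeriesSummary(float(v.min()), float(q1), float(med), float(q3), float(v.max()))


@dataclass
class ValidationReport:
    """Paired comparison of model-based (m) and direct (d) estimates."""

    areas: list[str]
    model: np.ndarray
    direct: np.ndarray
    mse: float
    mad: float
    pearson: float | None  # None when a series has zero variance
    spearman: float | None
    pearson_p: float | None = None
    spearman_p: float | None = None
    correlation_defined: bool = True
    model_summary: SeriesSummary | None = None
    direct_summary: SeriesSummary | None = None
    containment: pd.DataFrame | None = None

    def summary_table(self) -> pd.DataFrame:
        rows = {}
        if self.model_summary:
            rows["Model-based estimates"] = self.model_summary.as_row()
        if self.direct_summary:
            rows["Direct estimates"] = self.direct_summary.as_row()
        return pd.DataFrame(rows).T

    def to_dict(self) -> dict:
        out = {
            "n_areas": len(self.areas),
            "mse": self.mse,
            "mad": self.mad,
            "pearson": self.pearson,
            "spearman": self.spearman,
            "pearson_p": self.pearson_p,
            "spearman_p": self.spearman_p,
            "correlation_defined": self.correlation_defined,
        }
        if self.model_summary:
            out["model_summary"] = self.model_summary.as_row()
        if self.direct_summary:
            out["direct_summary"] = self.direct_summary.as_row()
        if self.containment is not None:
            out["n_model_in_direct_ci"] = int(self.containment["model_in_direct_ci"].sum())
        return out


def _align(
    model_est: Mapping[str, float], direct_est: Mapping[str, float]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    common = sorted(set(map(str, model_est)) & set(map(str, direct_est)))
    if len(common) < 2:
        raise InputError(
            f"need >= 2 areas common to both estimate sets; found {len(common)}"
        )
    m = np.array([float(model_est[a]) for a in common])
    d = np.array([float(direct_est[a]) for a in common])
    return common, m, d


def compare_estimates(
    model_est: Mapping[str, float],
    direct_est: Mapping[str, float],
    direct_ci: Mapping[str, tuple[float, float]] | None = None,
    model_ci: Mapping[str, tuple[float, float]] | None = None,
) -> ValidationReport:
    """Agreement metrics between model-based and direct estimates.

    Inputs map ``area_id`` to an estimate on the percentage scale; the
    comparison is restricted to the areas present in both.  MSE is
    ``mean((m - d)^2)`` and MAD ``mean(|m - d|)``; Spearman uses average
    ranks for ties.  A zero-variance series makes the correlations
    undefined: they are reported as ``None`` with
    ``correlation_defined=False``, never coerced to 0.
    """
    areas, m, d = _align(model_est, direct_est)
    mse = float(np.mean((m - d) ** 2))
    mad = float(np.mean(np.abs(m - d)))

    if np.ptp(m) == 0 or np.ptp(d) == 0:
        pearson = spearman = p_p = s_p = None
        defined = False
    else:
        pr = stats.pearsonr(m, d)
        sr = stats.spearmanr(m, d)
        pearson, p_p = float(pr.statistic), float(pr.pvalue)
        spearman, s_p = float(sr.statistic), float(sr.pvalue)
        defined = True

    containment = None
    if direct_ci is not None:
        containment = containment_check(
            dict(zip(areas, m)), dict(zip(areas, d)), direct_ci, model_ci
        )
    return ValidationReport(
        areas=areas,
        model=m,
        direct=d,
        mse=mse,
        mad=mad,
        pearson=pearson,
        spearman=spearman,
        pearson_p=p_p,
        spearman_p=s_p,
        correlation_defined=defined,
        model_summary=summarize_series(m),
        direct_summary=summarize_series(d),
        containment=containment,
    )


def containment_check(
    model_est: Mapping[str, float],
    direct_est: Mapping[str, float],
    direct_ci: Mapping[str, tuple[float, float]],
    model_ci: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Is each model estimate inside the direct estimate's CI (closed)?

    When model CIs are supplied the symmetric check (direct estimate
    inside model CI) is reported too.
    """
    rows = []
    for a in sorted(set(map(str, model_est)) & set(map(str, direct_ci))):
        lo, hi = (float(x) for x in direct_ci[a])
        if lo > hi:
            raise InputError(f"area {a!r}: malformed CI ({lo}, {hi}) with lower > upper")
        row = {
            "area_id": a,
            "model": float(model_est[a]),
            "direct_ci_lower": lo,
            "direct_ci_upper": hi,
            "model_in_direct_ci": bool(lo <= float(model_est[a]) <= hi),
        }
        if model_ci is not None and a in model_ci and a in direct_est:
            mlo, mhi = (float(x) for x in model_ci[a])
            if mlo > mhi:
                raise InputError(f"area {a!r}: malformed model CI ({mlo}, {mhi})")
            row["direct_in_model_ci"] = bool(mlo <= float(direct_est[a]) <= mhi)
        rows.append(row)
    if not rows:
        raise InputError("no areas with both a model estimate and a direct CI")
    return pd.DataFrame(rows).set_index("area_id")
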