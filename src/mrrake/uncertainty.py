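"""Bootstrap confidence intervals for post-stratified area estimates.

The resampling unit is the respondent, drawn with replacement within each
sampled area so per-area sample sizes (the survey's clustering) are
preserved.  Census-derived raked cell counts are treated as known and
held fixed across replicates; each replicate refits the multilevel model,
re-predicts the cell probabilities, and post-stratifies.  Intervals are
percentile intervals of the replicate estimates.

For areas *outside* the survey the point prediction sets the random
intercept to zero, but the true area effect is an unobserved draw from
N(0, sigma_mu^2); case-resampling alone captures only parameter noise and
systematically under-covers such areas.  By default each replicate
therefore also draws the unsampled areas' random intercepts from
N(0, sigma_hat_b^2), turning their intervals into prediction intervals
that account for between-area variation (``draw_unsampled_re=False``
restores pure case-resampling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import AreaEstimate, AreaCovariates, FittingError, RakedTable, SurveyDataset
from .model import GlmmFit, ModelSpec, fit_multilevel_logistic, predict_cell_probabilities
from .poststratify import poststratify

__all__ = ["BootstrapResult", "bootstrap_ci"]


@dataclass
class BootstrapResult:
    """Per-area percentile CIs plus replicate bookkeeping."""

    estimates: list[AreaEstimate]  # point estimate from the original data, CI from replicates
    replicates: np.ndarray  # (B_kept, n_areas) replicate estimates
    area_ids: list[str]
    n_requested: int
    n_failed: int
    seed: int
    level: float

    def metadata(self) -> dict:
        return {
            "bootstrap_replicates": self.n_requested,
            "failed_replicates": self.n_failed,
            "seed": self.seed,
            "level": self.level,
        }


def bootstrap_ci(
    survey: SurveyDataset,
    covariates: AreaCovariates,
    spec: ModelSpec,
    scheme,
    raked: RakedTable,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    re_policy: str = "conditional_blup",
    base_fit: GlmmFit | None = None,
    quadrature_points: int = 15,
    allow_unstable: bool = False,
    draw_unsampled_re: bool = True,
) -> BootstrapResult:
    """Stratified case-resampling bootstrap for area prevalence estimates.

    Parameters
    ----------
    raked
        Cell counts for the target areas, computed once from the census
        margins and reused by every replicate (population totals are
        known, not sampled).
    B
        Number of resamples (>= 2).
    seed
        Master seed; each replicate draws from an independent spawned
        substream, so results are bitwise-reproducible given (seed, B).
    level
        Central coverage of the percentile interval, e.g. 0.95.
    base_fit
        Optional fit on the original data, reused as the point estimate
        and as the warm start for replicate refits.
    allow_unstable
        Replicates whose refit fails (separation, non-convergence) are
        dropped and counted; more than 10% failures is an error unless
        this flag is set.
    draw_unsampled_re
        Draw the unobserved random intercept of areas absent from the
        survey from N(0, sigma_hat_b^2) in each replicate, so their
        intervals reflect between-area variation (prediction intervals),
        not only parameter noise.
    """
    if B < 2:
        raise ValueError(f"need B >= 2 bootstrap replicates, got {B}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")

    target_areas = raked.area_ids
    if base_fit is None:
        base_fit = fit_multilevel_logistic(
            survey, covariates, spec, scheme, quadrature_points=quadrature_points
        )
    preds = predict_cell_probabilities(base_fit, scheme, covariates, target_areas, re_policy)
    point = poststratify(preds, raked)
    point_by_area = {e.area_id: e for e in point}

    warm = (
        np.concatenate([base_fit.beta, base_fit.eta, [np.log(max(base_fit.sigma_mu, 1e-6))]])
        if base_fit.spec.random_intercept
        else None
    )
    unsampled = [a for a in target_areas if a not in base_fit.mu]
    streams = np.random.SeedSequence(seed).spawn(B)
    rows = []
    n_failed = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        try:
            boot = survey.resample_within_areas(rng)
            fit_b = fit_multilevel_logistic(
                boot,
                covariates,
                spec,
                scheme,
                quadrature_points=quadrature_points,
                start=warm,
                compute_se=False,
            )
            mu_override = None
            if draw_unsampled_re and unsampled and fit_b.sigma_mu > 0:
                draws = rng.normal(0.0, fit_b.sigma_mu, size=len(unsampled))
                mu_override = dict(zip(unsampled, draws))
            preds_b = predict_cell_probabilities(
                fit_b, scheme, covariates, target_areas, re_policy,
                mu_override=mu_override,
            )
            est_b = poststratify(preds_b, raked)
            rows.append([e.estimate for e in est_b])
        except FittingError:
            n_failed += 1

    if n_failed > 0.10 * B and not allow_unstable:
        raise FittingError(
            f"{n_failed}/{B} bootstrap replicates failed to converge; "
            "pass allow_unstable=True to accept the remaining replicates"
        )
    if n_failed:
        warnings.warn(
            f"{n_failed}/{B} bootstrap replicates dropped (non-convergent)",
            RuntimeWarning,
            stacklevel=2,
        )
    reps = np.asarray(rows)
    if reps.shape[0] < 2:
        raise FittingError("fewer than 2 usable bootstrap replicates")

    alpha = (1.0 - level) / 2.0
    lo = np.percentile(reps, 100 * alpha, axis=0)
    hi = np.percentile(reps, 100 * (1 - alpha), axis=0)
    out = []
    for j, a in enumerate(target_areas):
        e = point_by_area[a]
        out.append(
            AreaEstimate(
                area_id=a,
                estimate=e.estimate,
                ci_lower=float(min(lo[j], e.estimate)),
                ci_upper=float(max(hi[j], e.estimate)),
                N=e.N,
            )
        )
    return BootstrapResult(
        estimates=out,
        replicates=reps,
        area_ids=list(target_areas),
        n_requested=B,
        n_failed=n_failed,
        seed=seed,
        level=level,
    )
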