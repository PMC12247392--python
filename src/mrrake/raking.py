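"""Raking (iterative proportional fitting) of joint cell counts to known margins.

The estimation step that makes post-stratification possible when the
census publishes only marginal distributions: the unknown joint table of
population counts over all stratification cells is estimated by cyclically
rescaling a seed table until every supplied margin (which may be one-way,
e.g. education, or multi-way, e.g. a joint age-sex table) matches its
target.  At convergence the result is the minimum-discrimination-
information table consistent with the margins and the seed.

Unlike raking of survey weights, the seed need not come from the sample:
with a uniform seed every cell receives an estimated count, including
cells with no sampled respondents, so areas outside the survey can be
post-stratified too.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import (
    InputError,
    Margin,
    MarginSet,
    RakeInfo,
    RakedTable,
    StratificationScheme,
    SurveyDataset,
)

__all__ = ["rake", "rake_all_areas", "structural_zero_mask"]


def _margin_axes(scheme: StratificationScheme, margin: Margin) -> tuple[int, ...]:
    """Axes of the full grid that the margin is summed OVER (complement)."""
    keep = {scheme.factor_axis(f) for f in margin.factors}
    return tuple(ax for ax in range(len(scheme.factors)) if ax not in keep)


def _expand(scheme: StratificationScheme, margin: Margin, values: np.ndarray) -> np.ndarray:
    """Broadcast a margin-shaped array over the full cell grid."""
    shape = [1] * len(scheme.factors)
    for f, k in zip(margin.factors, values.shape):
        shape[scheme.factor_axis(f)] = k
    return values.reshape(shape)


def structural_zero_mask(scheme: StratificationScheme, margins: MarginSet) -> np.ndarray:
    """Boolean grid marking cells forced to zero by a zero margin slice."""
    zero = np.zeros(scheme.shape, dtype=bool)
    for m in margins.margins:
        zero |= _expand(scheme, m, m.table == 0)
    return zero


def rake(
    scheme: StratificationScheme,
    margins: MarginSet,
    seed: np.ndarray | str = "uniform",
    tol: float = 1e-8,
    max_iter: int = 1000,
    rescale: bool = False,
) -> RakedTable:
    """Estimate one area's joint cell counts from its margins by IPF.

    Parameters
    ----------
    scheme
        Cell layout; the returned counts are flat in canonical cell order.
    margins
        Raking targets for this area.  Margin order is the cyclic update
        order (immaterial at convergence).
    seed
        Starting table, either ``"uniform"`` (1 in every cell that is not
        structurally zero) or a nonnegative array of shape
        ``scheme.shape`` or flat ``(n_cells,)``.
    tol
        Convergence when every fitted margin entry is within
        ``tol * N_i`` of its target.
    max_iter
        Cap on full cycles through the margins.  Hitting the cap returns
        the final iterate flagged ``converged=False`` with a warning
        (rounded census margins can be mutually infeasible; estimates
        should degrade gracefully and visibly, not abort).
    rescale
        Proportionally rescale margins to a common total instead of
        erroring when totals disagree within rounding.
    """
    if rescale:
        margins = margins.rescaled()
    margins.validate(scheme)
    N = margins.total
    zero_mask = structural_zero_mask(scheme, margins)

    if isinstance(seed, str):
        if seed != "uniform":
            raise InputError(f"unknown seed policy {seed!r}; use 'uniform' or an array")
        table = np.ones(scheme.shape)
    else:
        table = np.asarray(seed, dtype=float).reshape(scheme.shape).copy()
        if (table < 0).any() or not np.isfinite(table).all():
            raise InputError("seed table must be finite and nonnegative")
    table[zero_mask] = 0.0
    if table.sum() <= 0:
        raise InputError(f"area {margins.area_id!r}: seed is all zero after structural zeros")

    deviations: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for m in margins.margins:
            axes = _margin_axes(scheme, m)
            current = table.sum(axis=axes)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(current > 0, m.table / np.where(current > 0, current, 1.0), 0.0)
            table *= _expand(scheme, m, ratio)
        dev = _max_margin_deviation(scheme, table, margins) / N
        deviations.append(dev)
        if dev < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"raking for area {margins.area_id!r} stopped after {max_iter} cycles "
            f"with relative margin deviation {deviations[-1]:.3g} (tol {tol:g}); "
            "the margin system may be infeasible",
            RuntimeWarning,
            stacklevel=2,
        )
    info = RakeInfo(
        iterations=it,
        max_deviation=deviations[-1] if deviations else 0.0,
        converged=converged,
        deviations=tuple(deviations),
    )
    return RakedTable(scheme, {margins.area_id: table.ravel()}, {margins.area_id: info})


def _max_margin_deviation(
    scheme: StratificationScheme, table: np.ndarray, margins: MarginSet
) -> float:
    dev = 0.0
    for m in margins.margins:
        fitted = table.sum(axis=_margin_axes(scheme, m))
        dev = max(dev, float(np.abs(fitted - m.table).max()))
    return dev


def rake_all_areas(
    scheme: StratificationScheme,
    margins_by_area: dict[str, MarginSet] | list[MarginSet],
    seed_policy: str = "uniform",
    survey: SurveyDataset | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    epsilon: float = 0.5,
    rescale: bool = False,
) -> RakedTable:
    """Rake every target area, seeding each per ``seed_policy``.

    ``"uniform"`` seeds every non-structurally-zero cell at 1, so the
    procedure covers weighting cells with or without sampled elements.
    ``"sample_counts_plus_epsilon"`` seeds with the area's observed survey
    cell counts plus ``epsilon`` (default 0.5), so empty sampled cells
    still receive mass; areas absent from the survey fall back to uniform.
    """
    if isinstance(margins_by_area, list):
        margins_by_area = {m.area_id: m for m in margins_by_area}
    if seed_policy not in ("uniform", "sample_counts_plus_epsilon"):
        raise InputError(f"unknown seed policy {seed_policy!r}")
    if seed_policy == "sample_counts_plus_epsilon" and survey is None:
        raise InputError("seed policy 'sample_counts_plus_epsilon' requires a survey")

    counts: dict[str, np.ndarray] = {}
    info: dict[str, RakeInfo] = {}
    sampled = set(survey.area_ids) if survey is not None else set()
    for area_id, mset in margins_by_area.items():
        if seed_policy == "sample_counts_plus_epsilon" and area_id in sampled:
            seed: np.ndarray | str = survey.cell_counts(area_id) + epsilon
        else:
            seed = "uniform"
        res = rake(scheme, mset, seed=seed, tol=tol, max_iter=max_iter, rescale=rescale)
        counts[area_id] = res.counts[area_id]
        info[area_id] = res.info[area_id]
    return RakedTable(scheme, counts, info)
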