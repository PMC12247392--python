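"""Post-stratification: combine cell predictions with cell population counts.

The area prevalence is the count-weighted mean of the per-cell predicted
probabilities,

    p_i = (1 / N_i) * sum_cells N_i(cell) * p_i(cell),

with the cell counts taken from the raked table.  Areas can further be
aggregated to coarser units (e.g. counties to metropolitan areas) by a
population-weighted mean.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .core import AreaEstimate, CellPredictions, InputError, RakedTable

__all__ = ["poststratify", "aggregate_areas"]


def poststratify(preds: CellPredictions, raked: RakedTable) -> list[AreaEstimate]:
    """Count-weighted mean of cell probabilities, one estimate per area."""
    pred_areas = set(preds.area_ids)
    raked_areas = set(raked.area_ids)
    if pred_areas != raked_areas:
        only_p = sorted(pred_areas - raked_areas)
        only_r = sorted(raked_areas - pred_areas)
        raise InputError(
            f"predictions and raked counts cover different areas: "
            f"only in predictions {only_p}, only in raked table {only_r}"
        )
    out = []
    for a in preds.area_ids:
        counts = raked.counts[a]
        N = counts.sum()
        if N <= 0:
            raise InputError(f"area {a!r} has zero total population; cannot post-stratify")
        p = float(counts @ preds.probs[a] / N)
        out.append(AreaEstimate(area_id=a, estimate=min(max(p, 0.0), 1.0), N=float(N)))
    return out


def aggregate_areas(
    estimates: Sequence[AreaEstimate],
    grouping: Mapping[str, str],
    raked: RakedTable | None = None,
) -> list[AreaEstimate]:
    """Population-weighted aggregation of area estimates to coarser units.

    ``grouping`` maps ``area_id -> unit_id``; each area may belong to one
    unit only (the mapping type enforces this).  Weights are the areas'
    raked population totals ``N_i`` — the census-derived sizes, consistent
    with the post-stratification logic — taken from the estimates' ``N``
    or from ``raked`` when supplied.
    """
    units: dict[str, list[tuple[float, float]]] = {}
    for e in estimates:
        if e.area_id not in grouping:
            continue
        unit = str(grouping[e.area_id])
        N = e.N
        if raked is not None and e.area_id in raked.counts:
            N = raked.total(e.area_id)
        if N is None or N <= 0:
            raise InputError(f"area {e.area_id!r} lacks a positive population total N")
        units.setdefault(unit, []).append((float(N), e.estimate))

    grouped_areas = set(grouping)
    estimated = {e.area_id for e in estimates}
    missing = sorted(grouped_areas - estimated)
    if missing:
        raise InputError(f"grouped areas without estimates: {missing}")

    out = []
    for unit in sorted(units):
        pairs = units[unit]
        N_tot = sum(N for N, _ in pairs)
        p = sum(N * p for N, p in pairs) / N_tot
        out.append(AreaEstimate(area_id=unit, estimate=float(np.clip(p, 0, 1)), N=N_tot))
    return out
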