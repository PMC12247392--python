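"""Shared domain types for small-area prevalence estimation.

The estimation problem is organised around *areas* (e.g. counties) and
*post-stratification cells*: one cell per combination of the levels of a
set of categorical stratification factors (for instance age-sex x
education x race/ethnicity).  All tables in the package share a single
canonical cell layout: row-major over the declared factor order, so cell
0 is the first level of every factor and the last factor varies fastest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InputError",
    "FittingError",
    "GenerationError",
    "StratificationScheme",
    "SurveyDataset",
    "AreaCovariates",
    "Margin",
    "MarginSet",
    "CellPredictions",
    "RakeInfo",
    "RakedTable",
    "AreaEstimate",
    "estimates_to_frame",
]


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class FittingError(RuntimeError):
    """Model estimation failed (separation, non-convergence, ...)."""


class GenerationError(ValueError):
    """Synthetic-data configuration is infeasible."""


@dataclass(frozen=True)
class StratificationScheme:
    """Ordered categorical factors defining post-stratification cells.

    Parameters
    ----------
    factors
        Ordered ``(name, levels)`` pairs.  Level order is meaningful: the
        first level of each factor is the dummy-coding reference, and the
        cell index is row-major over this declared order.
    """

    factors: tuple[tuple[str, tuple[str, ...]], ...]

    def __init__(self, factors: Iterable[tuple[str, Sequence[str]]]):
        canon = tuple((str(name), tuple(str(l) for l in levels)) for name, levels in factors)
        if not canon:
            raise InputError("a stratification scheme needs at least one factor")
        names = [name for name, _ in canon]
        if len(set(names)) != len(names):
            raise InputError(f"duplicate factor names in scheme: {names}")
        for name, levels in canon:
            if len(levels) < 2:
                raise InputError(f"factor {name!r} has {len(levels)} level(s); need >= 2")
            if len(set(levels)) != len(levels):
                raise InputError(f"factor {name!r} has duplicate levels: {levels}")
        object.__setattr__(self, "factors", canon)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.factors)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(levels) for _, levels in self.factors)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def levels(self, factor: str) -> tuple[str, ...]:
        for name, levels in self.factors:
            if name == factor:
                return levels
        raise InputError(f"unknown factor {factor!r}; scheme has {self.factor_names}")

    def factor_axis(self, factor: str) -> int:
        for ax, (name, _) in enumerate(self.factors):
            if name == factor:
                return ax
        raise InputError(f"unknown factor {factor!r}; scheme has {self.factor_names}")

    def level_codes(self, factor: str, values: Sequence[str]) -> np.ndarray:
        """Integer codes of ``values`` within ``factor``'s level list."""
        levels = self.levels(factor)
        lookup = {lv: i for i, lv in enumerate(levels)}
        codes = np.empty(len(values), dtype=np.int64)
        for i, v in enumerate(values):
            try:
                codes[i] = lookup[str(v)]
            except KeyError:
                raise InputError(
                    f"unknown level {v!r} for factor {factor!r}; valid levels: {levels}"
                ) from None
        return codes

    def cell_index(self, levels: Sequence[str] | Mapping[str, str]) -> int:
        """Map one level per factor to the canonical cell id (row-major)."""
        if isinstance(levels, Mapping):
            missing = set(self.factor_names) - set(levels)
            if missing:
                raise InputError(f"missing levels for factors {sorted(missing)}")
            seq = [levels[name] for name in self.factor_names]
        else:
            seq = list(levels)
            if len(seq) != len(self.factors):
                raise InputError(
                    f"expected {len(self.factors)} levels (one per factor), got {len(seq)}"
                )
        idx = [self.level_codes(name, [lv])[0] for (name, _), lv in zip(self.factors, seq)]
        return int(np.ravel_multi_index(idx, self.shape))

    def cell_levels(self, cell: int) -> tuple[str, ...]:
        """Inverse of :meth:`cell_index`."""
        if not 0 <= cell < self.n_cells:
            raise InputError(f"cell id {cell} out of range [0, {self.n_cells})")
        idx = np.unravel_index(cell, self.shape)
        return tuple(levels[i] for (name, levels), i in zip(self.factors, idx))

    def cell_frame(self) -> pd.DataFrame:
        """All cells as a DataFrame, one factor column each, in canonical order."""
        grids = np.meshgrid(*[np.arange(k) for k in self.shape], indexing="ij")
        data = {
            name: np.asarray(levels, dtype=object)[g.ravel()]
            for (name, levels), g in zip(self.factors, grids)
        }
        return pd.DataFrame(data)


@dataclass
class SurveyDataset:
    """Survey microdata: one row per respondent.

    ``data`` carries ``area_id`` (str), ``y`` (0/1) and one column per
    scheme factor holding level labels.  A ``weight`` column, if present,
    is preserved but never used by the fitter (analyses are unweighted).
    """

    scheme: StratificationScheme
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = ["area_id", "y", *self.scheme.factor_names]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise InputError(f"survey data is missing columns {missing}")
        y = df["y"].to_numpy()
        if not np.isin(y, (0, 1)).all():
            bad = sorted(set(y) - {0, 1})
            raise InputError(f"outcome y must be 0/1; found {bad}")
        if not ((y == 0).any() and (y == 1).any()):
            raise InputError("survey outcome is constant; the model is degenerate")
        # validates every level against the scheme as a side effect
        self._cell_ids = self._compute_cell_ids()

    def _compute_cell_ids(self) -> np.ndarray:
        shape = self.scheme.shape
        codes = [
            self.scheme.level_codes(name, self.data[name].astype(str).to_numpy())
            for name in self.scheme.factor_names
        ]
        return np.ravel_multi_index(codes, shape).astype(np.int64)

    @property
    def cell_ids(self) -> np.ndarray:
        return self._cell_ids

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def area_ids(self) -> list[str]:
        """Sampled area ids, in order of first appearance."""
        return list(dict.fromkeys(self.data["area_id"].astype(str)))

    def cell_counts(self, area_id: str) -> np.ndarray:
        """Respondent count per scheme cell within one sampled area."""
        mask = self.data["area_id"].astype(str).to_numpy() == str(area_id)
        return np.bincount(self._cell_ids[mask], minlength=self.scheme.n_cells).astype(float)

    def resample_within_areas(self, rng: np.random.Generator) -> "SurveyDataset":
        """Case-resample respondents with replacement within each area.

        Per-area sample sizes are held fixed, respecting the survey's
        clustering by area.
        """
        area = self.data["area_id"].astype(str).to_numpy()
        pieces = []
        for a in self.area_ids:
            idx = np.flatnonzero(area == a)
            take = rng.integers(0, len(idx), size=len(idx))
            pieces.append(idx[take])
        out = self.data.iloc[np.concatenate(pieces)].reset_index(drop=True)
        new = SurveyDataset.__new__(SurveyDataset)
        new.scheme = self.scheme
        new.data = out
        # resampling cannot create unseen levels; recompute ids directly
        new._cell_ids = new._compute_cell_ids()
        if not (out["y"].nunique() > 1):
            raise FittingError("bootstrap resample has a constant outcome")
        return new


@dataclass
class AreaCovariates:
    """Continuous area-level covariates, one row per area (``area_id`` index)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "area_id" in df.columns:
            df = df.set_index(df["area_id"].astype(str)).drop(columns="area_id")
        else:
            df = df.copy()
            df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise InputError(f"duplicate area_id rows in covariates: {dups}")
        df.index.name = "area_id"
        self.data = df

    @property
    def area_ids(self) -> list[str]:
        return list(self.data.index)

    def vector(self, area_id: str, names: Sequence[str]) -> np.ndarray:
        if str(area_id) not in self.data.index:
            raise InputError(f"no covariates for area {area_id!r}")
        row = self.data.loc[str(area_id)]
        missing = [n for n in names if n not in row.index]
        if missing:
            raise InputError(f"area {area_id!r} lacks covariates {missing}")
        z = row[list(names)].to_numpy(dtype=float)
        if not np.isfinite(z).all():
            raise InputError(f"non-finite covariate values for area {area_id!r}")
        return z

    def matrix(self, area_ids: Sequence[str], names: Sequence[str]) -> np.ndarray:
        return np.vstack([self.vector(a, names) for a in area_ids]) if names else np.zeros(
            (len(area_ids), 0)
        )


@dataclass(frozen=True)
class Margin:
    """A known population count table over a subset of scheme factors.

    ``table`` has one axis per factor in ``factors`` (scheme level order);
    factors must be listed in scheme-declared order.
    """

    factors: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "table", np.asarray(self.table, dtype=float))

    @property
    def total(self) -> float:
        return float(self.table.sum())

    def validate(self, scheme: StratificationScheme) -> None:
        order = [scheme.factor_axis(f) for f in self.factors]  # raises on unknown factor
        if order != sorted(order):
            raise InputError(
                f"margin factors {self.factors} must follow the scheme order "
                f"{scheme.factor_names}"
            )
        expected = tuple(len(scheme.levels(f)) for f in self.factors)
        if self.table.shape != expected:
            raise InputError(
                f"margin over {self.factors} has shape {self.table.shape}, expected {expected}"
            )
        if not np.isfinite(self.table).all():
            raise InputError(f"margin over {self.factors} contains non-finite counts")
        if (self.table < 0).any():
            raise InputError(f"margin over {self.factors} contains negative counts")


@dataclass
class MarginSet:
    """Per-area raking targets: margins on factor subsets plus the area total.

    All margins of one area must sum to the same population total ``N_i``
    (relative tolerance 1e-6 by default; census margins are often rounded
    independently, so :meth:`rescaled` offers a proportional repair).
    """

    area_id: str
    margins: list[Margin]

    RTOL: float = field(default=1e-6, repr=False)

    @property
    def total(self) -> float:
        return float(np.mean([m.total for m in self.margins]))

    def validate(self, scheme: StratificationScheme, rtol: float | None = None) -> None:
        if not self.margins:
            raise InputError(f"area {self.area_id!r} has no margins")
        rtol = self.RTOL if rtol is None else rtol
        for m in self.margins:
            m.validate(scheme)
        totals = np.array([m.total for m in self.margins])
        ref = totals.mean()
        if ref <= 0:
            raise InputError(f"area {self.area_id!r} has zero population in its margins")
        if np.abs(totals - ref).max() > rtol * ref:
            raise InputError(
                f"margins of area {self.area_id!r} disagree on the population total: "
                f"{totals.tolist()} (relative tolerance {rtol:g}); "
                "pass rescale to repair proportionally"
            )
        covered = set()
        for m in self.margins:
            covered.update(m.factors)
        missing = set(scheme.factor_names) - covered
        if missing:
            raise InputError(
                f"area {self.area_id!r}: factors {sorted(missing)} appear in no margin"
            )

    def rescaled(self) -> "MarginSet":
        """Proportionally rescale every margin to the mean total."""
        ref = self.total
        out = [Margin(m.factors, m.table * (ref / m.total)) for m in self.margins]
        return MarginSet(self.area_id, out)


@dataclass
class CellPredictions:
    """Predicted outcome probability for every (area, cell)."""

    scheme: StratificationScheme
    probs: dict[str, np.ndarray]  # area_id -> (n_cells,) in canonical cell order

    def __post_init__(self) -> None:
        n = self.scheme.n_cells
        for a, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (n,):
                raise InputError(f"area {a!r}: expected {n} cell probabilities, got {p.shape}")
            if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
                raise InputError(f"area {a!r}: cell probabilities must be finite in [0, 1]")
            self.probs[a] = p

    @property
    def area_ids(self) -> list[str]:
        return list(self.probs)


@dataclass(frozen=True)
class RakeInfo:
    """Convergence metadata for one raked area."""

    iterations: int
    max_deviation: float  # max |fitted - target| over all margin entries, / N_i
    converged: bool
    deviations: tuple[float, ...] = ()  # per-cycle history


@dataclass
class RakedTable:
    """Estimated joint cell counts per area, with convergence metadata."""

    scheme: StratificationScheme
    counts: dict[str, np.ndarray]  # area_id -> (n_cells,) canonical order
    info: dict[str, RakeInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.scheme.n_cells
        for a, c in self.counts.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (n,):
                raise InputError(f"area {a!r}: expected {n} cell counts, got {c.shape}")
            if (c < 0).any() or not np.isfinite(c).all():
                raise InputError(f"area {a!r}: raked counts must be finite and >= 0")
            self.counts[a] = c

    @property
    def area_ids(self) -> list[str]:
        return list(self.counts)

    def total(self, area_id: str) -> float:
        return float(self.counts[str(area_id)].sum())

    def grid(self, area_id: str) -> np.ndarray:
        return self.counts[str(area_id)].reshape(self.scheme.shape)


@dataclass
class AreaEstimate:
    """Post-stratified prevalence for one area, optionally with a CI."""

    area_id: str
    estimate: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    N: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.estimate <= 1.0) or not math.isfinite(self.estimate):
            raise InputError(f"area {self.area_id!r}: estimate {self.estimate} not in [0, 1]")
        if (self.ci_lower is None) != (self.ci_upper is None):
            raise InputError(f"area {self.area_id!r}: CI must have both bounds or neither")
        if self.ci_lower is not None:
            if not self.ci_lower <= self.estimate <= self.ci_upper:
                raise InputError(
                    f"area {self.area_id!r}: CI ({self.ci_lower}, {self.ci_upper}) "
                    f"does not bracket the estimate {self.estimate}"
                )


def estimates_to_frame(estimates: Sequence[AreaEstimate]) -> pd.DataFrame:
    """Tabulate estimates as ``area_id,estimate,ci_lower,ci_upper,N``."""
    return pd.DataFrame(
        {
            "area_id": [e.area_id for e in estimates],
            "estimate": [e.estimate for e in estimates],
            "ci_lower": [e.ci_lower for e in estimates],
            "ci_upper": [e.ci_upper for e in estimates],
            "N": [e.N for e in estimates],
        }
    )
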