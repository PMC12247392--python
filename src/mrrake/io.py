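"""Readers and writers for the package's CSV/YAML interfaces.

Schemas
-------
survey CSV
    ``area_id,y,<factor1>,<factor2>,...`` — one respondent per row,
    factor levels as strings.  An optional ``weight`` column is carried
    along but never used by the fitter.
margins CSV (long)
    ``area_id,margin_id,<one column per scheme factor>,count`` — factor
    columns are empty for factors outside the margin; all rows of one
    ``(area_id, margin_id)`` define one margin table.
covariates CSV
    ``area_id,<covariate columns>`` — continuous values.
estimates CSV
    ``area_id,estimate,ci_lower,ci_upper,N`` on the proportion scale at
    full precision, plus one-decimal ``*_pct`` display columns.
scheme YAML
    ``factors: [{name: ..., levels: [...]}, ...]``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    AreaCovariates,
    AreaEstimate,
    InputError,
    Margin,
    MarginSet,
    StratificationScheme,
    SurveyDataset,
    estimates_to_frame,
)

__all__ = [
    "read_scheme",
    "write_scheme",
    "read_survey",
    "write_survey",
    "read_margins",
    "write_margins",
    "read_covariates",
    "write_covariates",
    "read_estimates",
    "write_estimates",
    "read_direct_estimates",
    "write_manifest",
]


def read_scheme(path: str | Path) -> StratificationScheme:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        factors = [(f["name"], list(f["levels"])) for f in doc["factors"]]
    except (KeyError, TypeError) as exc:
        raise InputError(f"{path}: scheme YAML needs factors: [{{name, levels}}]") from exc
    return StratificationScheme(factors)


def write_scheme(scheme: StratificationScheme, path: str | Path) -> None:
    doc = {"factors": [{"name": n, "levels": list(lv)} for n, lv in scheme.factors]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_survey(path: str | Path, scheme: StratificationScheme) -> SurveyDataset:
    df = pd.read_csv(path, dtype=str)
    required = ["area_id", "y", *scheme.factor_names]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: survey file is missing columns {missing}")
    try:
        df["y"] = pd.to_numeric(df["y"])
    except ValueError as exc:
        raise InputError(f"{path}: outcome column y is not numeric: {exc}") from exc
    # pinpoint offending lines before handing off (line 1 is the header)
    for name in scheme.factor_names:
        valid = set(scheme.levels(name))
        bad = ~df[name].isin(valid)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputError(
                f"{path}, line {i + 2}: unknown level {df[name].iloc[i]!r} for factor "
                f"{name!r}; valid levels: {sorted(valid)}"
            )
    return SurveyDataset(scheme, df)


def write_survey(survey: SurveyDataset, path: str | Path) -> None:
    survey.data.to_csv(path, index=False)


def read_margins(
    path: str | Path, scheme: StratificationScheme, rescale: bool = False
) -> dict[str, MarginSet]:
    """Parse long-format margins into per-area :class:`MarginSet`.

    With ``rescale=True`` margins whose totals disagree (within rounding)
    are proportionally rescaled to their mean total instead of erroring.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("area_id", "margin_id", "count"):
        if col not in df.columns:
            raise InputError(f"{path}: margins file is missing column {col!r}")
    factor_cols = [f for f in scheme.factor_names if f in df.columns]
    if not factor_cols:
        raise InputError(f"{path}: no scheme factor columns found")
    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any():
        i = int(np.flatnonzero(counts.isna().to_numpy())[0])
        raise InputError(f"{path}, line {i + 2}: non-numeric count {df['count'].iloc[i]!r}")

    out: dict[str, MarginSet] = {}
    for area_id in df["area_id"].unique():
        sub_a = df[df["area_id"] == area_id]
        margins = []
        for margin_id in sub_a["margin_id"].unique():
            g = sub_a[sub_a["margin_id"] == margin_id]
            present = [
                f for f in factor_cols if g[f].notna().all() and (g[f] != "").all()
            ]
            if not present:
                raise InputError(
                    f"{path}: margin {margin_id!r} of area {area_id!r} names no factors"
                )
            sub_factors = tuple(
                f for f in scheme.factor_names if f in present
            )  # canonical order
            shape = tuple(len(scheme.levels(f)) for f in sub_factors)
            table = np.full(shape, np.nan)
            codes = [scheme.level_codes(f, g[f].to_numpy()) for f in sub_factors]
            flat = np.ravel_multi_index(codes, shape)
            dup = pd.Series(flat).duplicated()
            if dup.any():
                i = g.index[int(np.flatnonzero(dup.to_numpy())[0])]
                raise InputError(
                    f"{path}, line {i + 2}: duplicate margin cell for area {area_id!r}, "
                    f"margin {margin_id!r}"
                )
            table.ravel()[flat] = pd.to_numeric(g["count"]).to_numpy()
            if np.isnan(table).any():
                raise InputError(
                    f"{path}: margin {margin_id!r} of area {area_id!r} does not cover "
                    f"all level combinations of {sub_factors}"
                )
            margins.append(Margin(sub_factors, table))
        mset = MarginSet(str(area_id), margins)
        if rescale:
            mset = mset.rescaled()
        mset.validate(scheme)
        out[str(area_id)] = mset
    return out


def write_margins(margins: Mapping[str, MarginSet], path: str | Path,
                  scheme: StratificationScheme) -> None:
    rows = []
    for area_id, mset in margins.items():
        for mi, m in enumerate(mset.margins):
            it = np.ndindex(*m.table.shape)
            for idx in it:
                row = {"area_id": area_id, "margin_id": f"m{mi}"}
                for f, k in zip(m.factors, idx):
                    row[f] = scheme.levels(f)[k]
                row["count"] = m.table[idx]
                rows.append(row)
    cols = ["area_id", "margin_id", *scheme.factor_names, "count"]
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, index=False)


def read_covariates(path: str | Path) -> AreaCovariates:
    df = pd.read_csv(path)
    if "area_id" not in df.columns:
        raise InputError(f"{path}: covariates file is missing column 'area_id'")
    df["area_id"] = df["area_id"].astype(str)
    return AreaCovariates(df)


def write_covariates(covariates: AreaCovariates, path: str | Path) -> None:
    covariates.data.rename_axis("area_id").reset_index().to_csv(path, index=False)


def write_estimates(estimates: Sequence[AreaEstimate], path: str | Path) -> None:
    df = estimates_to_frame(estimates)
    df["estimate_pct"] = (100 * df["estimate"]).round(1)
    for c in ("ci_lower", "ci_upper"):
        vals = pd.to_numeric(df[c], errors="coerce")
        df[f"{c[3:]}_pct"] = (100 * vals).round(1)
    df.to_csv(path, index=False)


def read_estimates(path: str | Path) -> list[AreaEstimate]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        ci_lo = None if pd.isna(r.get("ci_lower")) else float(r["ci_lower"])
        ci_hi = None if pd.isna(r.get("ci_upper")) else float(r["ci_upper"])
        N = None if pd.isna(r.get("N")) else float(r["N"])
        out.append(
            AreaEstimate(str(r["area_id"]), float(r["estimate"]), ci_lo, ci_hi, N)
        )
    return out


def read_direct_estimates(
    path: str | Path,
) -> tuple[dict[str, float], dict[str, tuple[float, float]] | None]:
    """Direct (design-based) estimates on the percentage scale.

    Expects ``area_id,estimate[,ci_lower,ci_upper]`` with percentages
    (65.0 for 65%).  Returns estimates and, when CI columns are present,
    the CI mapping.
    """
    df = pd.read_csv(path)
    for col in ("area_id", "estimate"):
        if col not in df.columns:
            raise InputError(f"{path}: direct-estimates file is missing column {col!r}")
    est = {str(r["area_id"]): float(r["estimate"]) for _, r in df.iterrows()}
    cis = None
    if {"ci_lower", "ci_upper"} <= set(df.columns):
        cis = {
            str(r["area_id"]): (float(r["ci_lower"]), float(r["ci_upper"]))
            for _, r in df.iterrows()
            if not (pd.isna(r["ci_lower"]) or pd.isna(r["ci_upper"]))
        }
    return est, cis


def write_manifest(path: str | Path, **entries) -> None:
    """Machine-readable run manifest (versions, seeds, tolerances)."""
    import mrrake

    doc = {
        "mrrake_version": mrrake.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    doc.update(entries)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
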