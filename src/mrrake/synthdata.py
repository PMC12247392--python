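"""Synthetic multi-area populations, census-style margins, and survey draws.

Emulates the data a survey-plus-census small-area analysis consumes: a
state's worth of areas (counties) with *dependent* categorical
socio-demographics, a binary outcome following the random-intercept
logistic model, and a survey observed only in a handful of areas
(metro-style coverage) with unequal selection probabilities across cells.

Factor dependence is injected through pairwise log-linear interaction
terms, so the true joint distribution measurably differs from the product
of its margins — the regime raking exists for.  Everything (true joint,
true random effects, true cell probabilities, true prevalences) is
returned so estimates can be checked against the simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AreaCovariates,
    GenerationError,
    InputError,
    Margin,
    MarginSet,
    StratificationScheme,
    SurveyDataset,
)
from .model import cell_design

__all__ = [
    "GeneratorConfig",
    "Population",
    "default_scheme",
    "tiny_scheme",
    "default_config",
    "tiny_config",
    "generate_population",
    "derive_margins",
    "draw_survey",
    "generate_dataset",
]


def default_scheme() -> StratificationScheme:
    """The 240-cell stratification: age-sex (6x2) x education (4) x race (5)."""
    ages = ["18-24", "25-34", "35-44", "45-54", "55-64", "65+"]
    age_sex = [f"{a}_{s}" for a in ages for s in ("M", "F")]
    return StratificationScheme(
        [
            ("age_sex", age_sex),
            ("education", ["no_hs", "hs", "some_college", "college_grad"]),
            ("race", ["white", "black", "hispanic", "asian", "other"]),
        ]
    )


def tiny_scheme() -> StratificationScheme:
    """A 2x2x2 scheme for fast unit tests."""
    return StratificationScheme(
        [
            ("age", ["18-44", "45+"]),
            ("sex", ["M", "F"]),
            ("education", ["hs_or_less", "college"]),
        ]
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that defines a synthetic study.

    A single ``seed`` fixes the population, covariates, random effects and
    survey draw.  ``beta`` maps each factor to per-level outcome effects
    on the logit scale (first level 0, the reference); ``eta`` are the
    area-covariate coefficients per standardized unit; ``sigma_mu`` the
    between-area random-intercept SD.  ``dependence_strength`` scales the
    pairwise log-linear interactions among factors: 0 gives independent
    factors (raking's easy case), larger values make the joint deviate
    more from the product of margins.
    """

    scheme: StratificationScheme
    n_areas: int = 58
    n_sampled: int = 5
    pop_log_mean: float = 11.0  # lognormal adult-population sizes, median ~60k
    pop_log_sd: float = 1.0
    main_effect_sd: float = 0.5  # composition main effects (log scale)
    area_composition_sd: float = 0.15  # per-area jitter on composition
    dependence_strength: float = 0.3  # SD of pairwise log-linear interactions
    beta_intercept: float = 0.2
    beta: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    eta: tuple[float, ...] = (-0.6,)
    covariate_names: tuple[str, ...] = ("pct_poverty",)
    sigma_mu: float = 0.3
    sample_sizes: tuple[int, ...] | None = (3400, 830, 1512, 882, 533)
    sampling_rate: float | None = None  # alternative to sample_sizes
    design_tilt_sd: float = 0.2  # per-cell selection-probability heterogeneity
    margin_subsets: tuple[tuple[str, ...], ...] = ()
    seed: int = 20180

    def __post_init__(self) -> None:
        if self.n_sampled > self.n_areas:
            raise GenerationError(
                f"n_sampled={self.n_sampled} exceeds n_areas={self.n_areas}"
            )
        if self.sampling_rate is not None and not 0 < self.sampling_rate <= 1:
            raise InputError(f"sampling rate must be in (0, 1], got {self.sampling_rate}")
        if len(self.eta) != len(self.covariate_names):
            raise GenerationError("eta and covariate_names must have matching lengths")
        for f, effects in self.beta.items():
            levels = self.scheme.levels(f)  # raises on unknown factor
            if len(effects) != len(levels):
                raise GenerationError(
                    f"beta for factor {f!r} has {len(effects)} entries, "
                    f"expected {len(levels)} (first must be 0, the reference)"
                )
            if effects[0] != 0:
                raise GenerationError(f"beta for {f!r} must be 0 at the reference level")

    @property
    def effective_margin_subsets(self) -> tuple[tuple[str, ...], ...]:
        if self.margin_subsets:
            return self.margin_subsets
        return tuple((name,) for name in self.scheme.factor_names)


def default_config(**overrides) -> GeneratorConfig:
    """The headline study conditions: 58 areas, 5 surveyed, 240 cells.

    Sampled-area sample sizes follow the 2018 metro-survey pattern
    (3400/830/1512/882/533, ~7,200 respondents).  Outcome effects: a
    rising age gradient, a strong education gradient, moderate
    race/ethnicity contrasts, and a negative poverty effect per SD.
    """
    ages = [0.0, 0.15, 0.25, 0.35, 0.45, 0.55]
    age_sex = tuple(a + (0.15 if s == 1 else 0.0) for a in ages for s in (0, 1))
    beta = {
        "age_sex": age_sex,
        "education": (0.0, 0.35, 0.7, 0.9),
        "race": (0.0, -0.3, -0.4, 0.1, -0.2),
    }
    base = GeneratorConfig(
        scheme=default_scheme(),
        beta=beta,
        margin_subsets=(("age_sex",), ("education",), ("race",)),
    )
    return replace(base, **overrides) if overrides else base


def tiny_config(**overrides) -> GeneratorConfig:
    """A fast 6-area, 8-cell profile for unit tests."""
    base = GeneratorConfig(
        scheme=tiny_scheme(),
        n_areas=6,
        n_sampled=3,
        pop_log_mean=8.5,  # median ~5k
        pop_log_sd=0.6,
        beta_intercept=0.3,
        beta={"age": (0.0, 0.8), "sex": (0.0, -0.5), "education": (0.0, 0.4)},
        eta=(-0.6,),
        sigma_mu=0.3,
        sample_sizes=(400, 250, 150),
        seed=20180,
    )
    return replace(base, **overrides) if overrides else base


@dataclass
class Population:
    """A simulated multi-area population with full ground truth."""

    scheme: StratificationScheme
    area_ids: list[str]
    sampled_areas: list[str]
    joints: dict[str, np.ndarray]  # true joint counts, flat canonical order
    covariates: AreaCovariates
    mu: dict[str, float]  # true area random effects
    cell_probs: dict[str, np.ndarray]  # true per-cell outcome probabilities
    true_prevalence: dict[str, float]
    beta_full: np.ndarray  # aligned with model.cell_design(scheme, all factors)
    eta: np.ndarray
    sigma_mu: float
    config: GeneratorConfig

    def totals(self) -> dict[str, float]:
        return {a: float(self.joints[a].sum()) for a in self.area_ids}


def _full_beta(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Assemble the dummy-coded coefficient vector matching cell_design."""
    scheme = config.scheme
    parts = [config.beta_intercept]
    for name, levels in scheme.factors:
        if name in config.beta:
            effects = list(config.beta[name][1:])
        else:
            # unspecified factors get effects drawn once from the seed
            effects = list(rng.normal(0.0, 0.35, size=len(levels) - 1))
        parts.extend(effects)
    return np.asarray(parts, dtype=float)


def generate_population(
    config: GeneratorConfig, seed: int | None = None
) -> Population:
    """Draw the true joint composition, covariates, random effects, outcomes.

    Per area, cell counts are multinomial with probabilities from a
    log-linear model: factor main effects (shared across areas plus a
    small per-area jitter) and pairwise interactions scaled by
    ``dependence_strength``.  True cell outcome probabilities follow the
    logistic model at the configured coefficients.
    """
    scheme = config.scheme
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    s_struct, s_areas, s_outcome = master.spawn(3)
    rng = np.random.default_rng(s_struct)

    n_f = len(scheme.factors)
    shape = scheme.shape
    mains = [rng.normal(0.0, config.main_effect_sd, size=k) for k in shape]
    inters: dict[tuple[int, int], np.ndarray] = {}
    for a_ax in range(n_f):
        for b_ax in range(a_ax + 1, n_f):
            inters[(a_ax, b_ax)] = rng.normal(
                0.0, config.dependence_strength, size=(shape[a_ax], shape[b_ax])
            )
    beta_full = _full_beta(config, rng)
    Xcell, _ = cell_design(scheme, scheme.factor_names)

    area_ids = [f"area_{i + 1:02d}" for i in range(config.n_areas)]
    rng_a = np.random.default_rng(s_areas)
    pops = np.exp(rng_a.normal(config.pop_log_mean, config.pop_log_sd, config.n_areas))
    pops = np.maximum(np.round(pops).astype(int), 10 * scheme.n_cells)
    z = rng_a.standard_normal((config.n_areas, len(config.covariate_names)))
    mu = rng_a.normal(0.0, config.sigma_mu, config.n_areas)

    # log-linear cell weights shared structure
    log_w_base = np.zeros(shape)
    for ax, m in enumerate(mains):
        sl = [None] * n_f
        sl[ax] = slice(None)
        log_w_base += m[tuple(sl)]
    for (a_ax, b_ax), g in inters.items():
        log_w_base += _expand_pair(g, a_ax, b_ax, n_f)
    if np.abs(log_w_base).max() > 30:
        raise GenerationError(
            "log-linear cell weights overflow; reduce main_effect_sd or "
            "dependence_strength"
        )

    joints: dict[str, np.ndarray] = {}
    cell_probs: dict[str, np.ndarray] = {}
    true_prev: dict[str, float] = {}
    eta = np.asarray(config.eta, dtype=float)
    from scipy.special import expit

    for i, a in enumerate(area_ids):
        jitter = np.zeros(shape)
        for ax in range(n_f):
            j = rng_a.normal(0.0, config.area_composition_sd, size=shape[ax])
            sl = [None] * n_f
            sl[ax] = slice(None)
            jitter += j[tuple(sl)]
        logw = log_w_base + jitter
        w = np.exp(logw - logw.max())
        probs = (w / w.sum()).ravel()
        joints[a] = rng_a.multinomial(pops[i], probs).astype(float)
        lin = Xcell @ beta_full + float(z[i] @ eta) + mu[i]
        p = expit(lin)
        cell_probs[a] = p
        true_prev[a] = float(joints[a] @ p / joints[a].sum())

    covariates = AreaCovariates(
        pd.DataFrame(z, index=area_ids, columns=list(config.covariate_names))
    )
    # survey covers the most populous areas (metro-style coverage)
    order = np.argsort(-pops, kind="stable")
    sampled = [area_ids[j] for j in sorted(order[: config.n_sampled])]
    return Population(
        scheme=scheme,
        area_ids=area_ids,
        sampled_areas=sampled,
        joints=joints,
        covariates=covariates,
        mu={a: float(m) for a, m in zip(area_ids, mu)},
        cell_probs=cell_probs,
        true_prevalence=true_prev,
        beta_full=beta_full,
        eta=eta,
        sigma_mu=config.sigma_mu,
        config=config,
    )


def _expand_pair(g: np.ndarray, a_ax: int, b_ax: int, n_f: int) -> np.ndarray:
    """Broadcast a two-factor interaction table over the full cell grid."""
    shape = [1] * n_f
    shape[a_ax] = g.shape[0]
    shape[b_ax] = g.shape[1]
    return g.reshape(shape)


def derive_margins(
    joints: Mapping[str, np.ndarray] | Population,
    scheme: StratificationScheme | None = None,
    subsets: Sequence[Sequence[str]] | None = None,
) -> dict[str, MarginSet]:
    """Exact margins of the true joint over the given factor subsets.

    Sums the joint over every factor not in the subset, so each margin's
    total equals the area population exactly.  Subsets must jointly cover
    every scheme factor.
    """
    if isinstance(joints, Population):
        pop = joints
        scheme = pop.scheme
        subsets = subsets or pop.config.effective_margin_subsets
        joints = pop.joints
    if scheme is None:
        raise InputError("scheme required when passing raw joint tables")
    if subsets is None:
        subsets = [(name,) for name in scheme.factor_names]
    canon_subsets = []
    for sub in subsets:
        axes = sorted(scheme.factor_axis(f) for f in sub)  # raises on unknown factor
        canon_subsets.append(tuple(scheme.factor_names[ax] for ax in axes))
    covered = {f for sub in canon_subsets for f in sub}
    missing = set(scheme.factor_names) - covered
    if missing:
        raise InputError(f"margin subsets leave factors uncovered: {sorted(missing)}")

    n_f = len(scheme.factors)
    out: dict[str, MarginSet] = {}
    for a, flat in joints.items():
        grid = np.asarray(flat, dtype=float).reshape(scheme.shape)
        margins = []
        for sub in canon_subsets:
            keep = {scheme.factor_axis(f) for f in sub}
            axes = tuple(ax for ax in range(n_f) if ax not in keep)
            margins.append(Margin(sub, grid.sum(axis=axes)))
        out[a] = MarginSet(str(a), margins)
    return out


def draw_survey(
    population: Population,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> SurveyDataset:
    """Sample respondents from the sampled areas and draw their outcomes.

    Cells are sampled proportional to their true population counts times a
    lognormal per-cell tilt (SD ``design_tilt_sd`` on the log scale),
    emulating unequal selection probabilities of a disproportionate
    stratified design.  Outcomes are Bernoulli at the true cell
    probability.  A ``sampling_rate`` of exactly 1 returns the full area
    (the census case).  Deterministic given the seed.
    """
    config = config or population.config
    scheme = population.scheme
    master = np.random.SeedSequence(
        (config.seed + 1_000_003) if seed is None else seed
    )
    rng = np.random.default_rng(master)
    cell_frame = scheme.cell_frame()

    sampled = population.sampled_areas
    if config.sample_sizes is not None and config.sampling_rate is None:
        if len(config.sample_sizes) < len(sampled):
            raise InputError(
                f"{len(config.sample_sizes)} sample sizes for {len(sampled)} sampled areas"
            )
        # largest sample in the largest area
        totals = population.totals()
        by_pop = sorted(sampled, key=lambda a: -totals[a])
        sizes = {a: int(n) for a, n in zip(by_pop, config.sample_sizes)}
    else:
        sizes = None

    frames = []
    for a in sampled:
        joint = population.joints[a]
        tilt = (
            np.exp(rng.normal(0.0, config.design_tilt_sd, size=scheme.n_cells))
            if config.design_tilt_sd > 0
            else np.ones(scheme.n_cells)
        )
        if sizes is not None:
            n_a = min(sizes[a], int(joint.sum()))
            w = joint * tilt
            k = rng.multinomial(n_a, w / w.sum())
        else:
            rate = config.sampling_rate
            if rate == 1.0:
                k = joint.astype(int)
            else:
                p_sel = np.clip(rate * tilt, 0.0, 1.0)
                k = rng.binomial(joint.astype(int), p_sel)
        nz = np.flatnonzero(k)
        if nz.size == 0:
            continue
        y_counts = rng.binomial(k[nz], population.cell_probs[a][nz])
        reps = k[nz]
        rows = cell_frame.iloc[np.repeat(nz, reps)].reset_index(drop=True)
        y = np.zeros(reps.sum(), dtype=np.int64)
        stops = np.cumsum(reps)
        starts = stops - reps
        for s0, c in zip(starts, y_counts):
            y[s0 : s0 + c] = 1
        rows.insert(0, "y", y)
        rows.insert(0, "area_id", a)
        frames.append(rows)
    if not frames:
        raise GenerationError("survey draw produced no respondents")
    data = pd.concat(frames, ignore_index=True)
    return SurveyDataset(scheme, data)


def generate_dataset(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[Population, dict[str, MarginSet], SurveyDataset]:
    """Population, margins and survey in one call (all from one seed)."""
    base = config.seed if seed is None else seed
    pop = generate_population(config, seed=base)
    margins = derive_margins(pop)
    survey = draw_survey(pop, config, seed=base + 1_000_003)
    return pop, margins, survey
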