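import numpy as np
import pytest

import mrrake as m


@pytest.fixture(scope="session")
def tiny_bundle():
    """One fixed tiny synthetic study shared across tests."""
    cfg = m.tiny_config(seed=424242)
    pop, margins, survey = m.generate_dataset(cfg)
    return cfg, pop, margins, survey


@pytest.fixture(scope="session")
def tiny_fit(tiny_bundle):
    cfg, pop, margins, survey = tiny_bundle
    spec = m.ModelSpec(fixed=pop.scheme.factor_names, area_covariates=["pct_poverty"])
    fit = m.fit_multilevel_logistic(survey, pop.covariates, spec)
    return spec, fit


@pytest.fixture(scope="session")
def tiny_raked(tiny_bundle):
    _, pop, margins, _ = tiny_bundle
    return m.rake_all_areas(pop.scheme, margins)


@pytest.fixture
def scheme_2x2():
    return m.StratificationScheme([("row", ["a", "b"]), ("col", ["x", "y"])])


def random_feasible_marginset(scheme, rng, subsets):
    """Margins derived from a random strictly positive joint (always feasible)."""
    joint = rng.uniform(0.5, 5.0, size=scheme.shape)
    margins = []
    for sub in subsets:
        keep = {scheme.factor_axis(f) for f in sub}
        axes = tuple(ax for ax in range(len(scheme.factors)) if ax not in keep)
        margins.append(m.Margin(tuple(sub), joint.sum(axis=axes)))
    return m.MarginSet("A", margins), joint
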