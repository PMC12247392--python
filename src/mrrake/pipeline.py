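"""The end-to-end estimation pipeline: fit, predict, rake, post-stratify.

Driven by a single YAML-serialisable configuration so a run is fully
described by one document plus a master seed; the manifest written next
to the outputs records versions, seeds and tolerances for reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from . import io as mio
from .core import InputError
from .model import ModelSpec, fit_multilevel_logistic, predict_cell_probabilities
from .poststratify import poststratify
from .raking import rake_all_areas
from .uncertainty import bootstrap_ci
from .validation import compare_estimates

__all__ = ["PipelineError", "PipelineResult", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    estimates: list
    fit: Any
    raked: Any
    bootstrap: Any = None
    validation: Any = None


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: pipeline config must be a YAML mapping")
    return cfg


def run_pipeline(cfg: dict, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute fit -> predict -> rake -> post-stratify (+ bootstrap, validation).

    ``cfg`` keys: ``scheme``, ``survey``, ``margins``, ``covariates``
    (paths); ``model`` (``fixed``, ``area_covariates``,
    ``random_intercept``); optional ``re_policy``, ``rescale_margins``,
    ``raking`` (``tol``, ``max_iter``, ``seed_policy``), ``bootstrap``
    (``B``, ``seed``, ``level``), ``direct`` (path to direct estimates for
    validation), ``target_areas``.
    """

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    with stage("read-inputs"):
        scheme = mio.read_scheme(cfg["scheme"])
        survey = mio.read_survey(cfg["survey"], scheme)
        rescale = bool(cfg.get("rescale_margins", False))
        margins = mio.read_margins(cfg["margins"], scheme, rescale=rescale)
        covariates = mio.read_covariates(cfg["covariates"])
        mcfg = cfg.get("model", {})
        spec = ModelSpec(
            fixed=mcfg.get("fixed", list(scheme.factor_names)),
            area_covariates=mcfg.get("area_covariates", []),
            random_intercept=mcfg.get("random_intercept", True),
        )
        target_areas = [str(a) for a in cfg.get("target_areas", sorted(margins))]
        missing = [a for a in target_areas if a not in margins]
        if missing:
            raise InputError(f"target areas without margins: {missing}")

    with stage("fit"):
        fit = fit_multilevel_logistic(survey, covariates, spec, scheme)

    with stage("predict"):
        re_policy = cfg.get("re_policy", "conditional_blup")
        preds = predict_cell_probabilities(fit, scheme, covariates, target_areas, re_policy)

    with stage("rake"):
        rk = cfg.get("raking", {})
        raked = rake_all_areas(
            scheme,
            {a: margins[a] for a in target_areas},
            seed_policy=rk.get("seed_policy", "uniform"),
            survey=survey,
            tol=float(rk.get("tol", 1e-8)),
            max_iter=int(rk.get("max_iter", 1000)),
        )

    with stage("poststratify"):
        estimates = poststratify(preds, raked)

    boot = None
    if cfg.get("bootstrap"):
        with stage("bootstrap"):
            b = cfg["bootstrap"]
            boot = bootstrap_ci(
                survey,
                covariates,
                spec,
                scheme,
                raked,
                B=int(b.get("B", 1000)),
                seed=int(b.get("seed", 0)),
                level=float(b.get("level", 0.95)),
                re_policy=re_policy,
                base_fit=fit,
                allow_unstable=bool(b.get("allow_unstable", False)),
            )
            estimates = boot.estimates

    report = None
    if cfg.get("direct"):
        with stage("validate"):
            direct, direct_ci = mio.read_direct_estimates(cfg["direct"])
            model_pct = {e.area_id: 100 * e.estimate for e in estimates}
            report = compare_estimates(model_pct, direct, direct_ci)

    if out_dir is not None:
        with stage("write-outputs"):
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            mio.write_estimates(estimates, out / "estimates.csv")
            fit.summary_frame().to_csv(out / "fit_summary.csv", index=False)
            manifest = {
                "config": cfg,
                "fit": fit.metadata(),
                "raking": {
                    a: {
                        "iterations": raked.info[a].iterations,
                        "max_deviation": raked.info[a].max_deviation,
                        "converged": raked.info[a].converged,
                    }
                    for a in raked.area_ids
                },
            }
            if boot is not None:
                manifest["bootstrap"] = boot.metadata()
            if report is not None:
                manifest["validation"] = report.to_dict()
            mio.write_manifest(out / "manifest.json", **manifest)

    return PipelineResult(estimates=estimates, fit=fit, raked=raked, bootstrap=boot,
                          validation=report)
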