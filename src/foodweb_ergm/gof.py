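"""Simulation-based goodness of fit over a 32-statistic suite.

A fitted model is judged by whether networks simulated from it reproduce the
observed web's structure, including structure the model never explicitly
targeted.  For every statistic in the suite the heuristic t-ratio

    t = (observed - ensemble mean) / ensemble sd

is reported.  The fit passes when every *modelled* statistic has |t| <= 0.1
(the moment condition the estimator enforces) and every other defined
statistic has |t| < 2 (the simulated distribution covers the observation).

The suite size is fixed at 32; its membership covers the full modelled
catalogue, the raw star/path/triangle counts, the 13 connected triad classes
and the spread of both degree distributions, and can be replaced wholesale by
the caller.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .census import triad_census_array
from .config_statistics import (
    CONNECTED_TRIAD_CLASSES,
    ConfigurationStatistic,
    compute_values,
)
from .errors import ValidationError
from .foodweb import FoodWeb
from .graph_sampler import SamplerSettings, sample_networks

__all__ = ["GoFReport", "default_gof_suite", "goodness_of_fit"]

MODELLED_THRESHOLD = 0.1
UNMODELLED_THRESHOLD = 2.0


def default_gof_suite(lam: float = 2.0) -> list[ConfigurationStatistic]:
    """The default 32-statistic goodness-of-fit suite.

    10 modelled-catalogue statistics (alternating forms at the given lambda),
    7 raw counts, 13 connected triad classes, and the in-/out-degree standard
    deviations: 32 statistics in total.
    """
    model_family = [
        "arc", "reciprocity", "generalist", "highly_predated", "keystone",
        "tri_trophic", "apparent_competition", "exploitative_competition",
        "omnivory", "cyclic_triangle",
    ]
    raw = [
        "in_2star", "in_3star", "out_2star", "out_3star",
        "two_path", "transitive_triangle_raw", "cyclic_triangle_raw",
    ]
    triads = [f"triad_{c}" for c in CONNECTED_TRIAD_CLASSES]
    spread = ["in_degree_sd", "out_degree_sd"]
    return [ConfigurationStatistic(name, lam)
            for name in model_family + raw + triads + spread]


@dataclass(frozen=True)
class GoFReport:
    """Per-statistic comparison of the observed web with a fitted ensemble.

    ``t_ratios`` entries are NaN where the ensemble standard deviation is
    zero (t undefined; such statistics are excluded from pass/fail).
    ``passed`` is None when no statistic had a defined t-ratio.
    """

    names: tuple[str, ...]
    observed: np.ndarray
    ensemble_mean: np.ndarray
    ensemble_sd: np.ndarray
    t_ratios: np.ndarray
    modelled: np.ndarray
    ensemble_size: int
    seed: int
    passed: bool | None

    @property
    def n_failures(self) -> int:
        """Defined t-ratios violating their threshold."""
        defined = ~np.isnan(self.t_ratios)
        abs_t = np.abs(self.t_ratios)
        fails = np.where(
            self.modelled, abs_t > MODELLED_THRESHOLD, abs_t >= UNMODELLED_THRESHOLD
        )
        return int(np.sum(defined & fails))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "observed": self.observed,
                "ensemble_mean": self.ensemble_mean,
                "ensemble_sd": self.ensemble_sd,
                "t_ratio": self.t_ratios,
                "modelled": self.modelled,
            },
            index=list(self.names),
        )

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("statistic").to_csv(path)

    def to_json(self, path=None) -> str:
        doc = {
            "statistics": [
                {
                    "name": name,
                    "observed": float(self.observed[k]),
                    "ensemble_mean": float(self.ensemble_mean[k]),
                    "ensemble_sd": float(self.ensemble_sd[k]),
                    "t_ratio": None if np.isnan(self.t_ratios[k])
                    else float(self.t_ratios[k]),
                    "modelled": bool(self.modelled[k]),
                }
                for k, name in enumerate(self.names)
            ],
            "ensemble_size": self.ensemble_size,
            "seed": self.seed,
            "passed": self.passed,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def suite_values(A: np.ndarray, suite: list[ConfigurationStatistic]) -> np.ndarray:
    """Evaluate a statistic suite on one adjacency matrix."""
    return compute_values(A, suite)


def goodness_of_fit(
    web: FoodWeb,
    fit,
    suite: list[ConfigurationStatistic] | None = None,
    settings: SamplerSettings | None = None,
    warn_unconverged: bool = True,
) -> GoFReport:
    """Compare an observed web against an ensemble simulated at the fit.

    Simulates ``settings.sample_size`` networks from (fit.spec, fit.theta),
    evaluates the suite on each and on the observed web, and reports
    t-ratios.  Deterministic given ``settings.seed``.
    """
    suite = default_gof_suite() if suite is None else list(suite)
    if not suite:
        raise ValidationError("the GoF suite must be non-empty")
    if warn_unconverged and not fit.converged:
        warnings.warn("goodness of fit on a non-converged fit; interpret with care")
    settings = (settings or SamplerSettings(sample_size=1000, seed=fit.seed + 1)).resolve(web.n)
    ensemble = sample_networks(
        fit.spec, fit.theta, web.n, settings, start=web, keep_networks=True
    )
    values = np.empty((ensemble.sample_size, len(suite)))
    for r, A in enumerate(ensemble.adjacency):
        values[r] = compute_values(A, suite)
    observed = compute_values(web, suite)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if ensemble.sample_size > 1 else np.zeros(len(suite))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, (observed - mean) / sd, np.nan)
    modelled = np.array([s.name in fit.spec.names for s in suite])
    defined = ~np.isnan(t)
    if not defined.any():
        passed = None
    else:
        ok_model = np.abs(t[modelled & defined]) <= MODELLED_THRESHOLD
        ok_other = np.abs(t[~modelled & defined]) < UNMODELLED_THRESHOLD
        passed = bool(ok_model.all() and ok_other.all())
    return GoFReport(
        names=tuple(s.name for s in suite),
        observed=observed,
        ensemble_mean=mean,
        ensemble_sd=sd,
        t_ratios=t,
        modelled=modelled,
        ensemble_size=ensemble.sample_size,
        seed=settings.seed,
        passed=passed,
    )
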