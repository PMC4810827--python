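"""Goodness of fit: the 32-statistic suite and the pass rule."""

import numpy as np
import pytest

from foodweb_ergm import (
    baltic_model_spec,
    default_gof_suite,
    fit_ergm,
    goodness_of_fit,
)
from foodweb_ergm.config_statistics import from_names
from foodweb_ergm.errors import ValidationError
from foodweb_ergm.estimator import FitResult, RobbinsMonroSettings
from foodweb_ergm.graph_sampler import SamplerSettings
from foodweb_ergm.synthetic_data import simulate_study

QUICK_RM = RobbinsMonroSettings(phase3_samples=400, newton_polish=1, max_restarts=2)


class TestDefaultSuite:
    def test_has_exactly_32_unique_statistics(self):
        suite = default_gof_suite()
        names = [s.name for s in suite]
        assert len(suite) == 32
        assert len(set(names)) == 32

    def test_contains_every_modelled_configuration(self):
        names = {s.name for s in default_gof_suite()}
        assert set(baltic_model_spec().names) <= names

    def test_covers_triads_and_degree_spread(self):
        names = {s.name for s in default_gof_suite()}
        assert "triad_030T" in names and "triad_300" in names
        assert {"in_degree_sd", "out_degree_sd"} <= names


def _manual_fit(spec, theta, seed=0, n_nodes=30):
    theta = np.asarray(theta, dtype=float)
    return FitResult(
        spec=spec, theta=theta,
        standard_errors=np.full(spec.p, np.nan),
        convergence_t=np.zeros(spec.p), converged=True,
        seed=seed, n_nodes=n_nodes, observed=np.zeros(spec.p),
    )


class TestGoodnessOfFit:
    def test_empty_suite_rejected(self, baltic_like):
        fit = _manual_fit(from_names(["arc"]), [-1.0])
        with pytest.raises(ValidationError):
            goodness_of_fit(baltic_like, fit, [])

    def test_ensemble_of_one_has_all_t_undefined(self, baltic_like):
        fit = _manual_fit(from_names(["arc"]), [-1.3])
        report = goodness_of_fit(
            baltic_like, fit, settings=SamplerSettings(sample_size=1, seed=2)
        )
        assert np.isnan(report.t_ratios).all()
        assert report.passed is None

    def test_reproducible_given_seed(self, baltic_like):
        fit = _manual_fit(from_names(["arc"]), [-1.3])
        kw = dict(settings=SamplerSettings(sample_size=80, seed=6))
        a = goodness_of_fit(baltic_like, fit, **kw)
        b = goodness_of_fit(baltic_like, fit, **kw)
        assert np.array_equal(a.t_ratios, b.t_ratios, equal_nan=True)
        assert a.passed == b.passed

    def test_warns_on_non_converged_fit(self, baltic_like):
        fit = _manual_fit(from_names(["arc"]), [-1.3])
        object.__setattr__(fit, "converged", False)
        with pytest.warns(UserWarning, match="non-converged"):
            goodness_of_fit(baltic_like, fit,
                            settings=SamplerSettings(sample_size=30, seed=1))

    def test_misspecified_model_fails_triangle_statistics(self):
        """An arc-only fit to a strongly transitive web (a niche-model web:
        feeding on contiguous niche intervals makes diets nested and
        triangles abundant) cannot reproduce the triangle statistics."""
        from foodweb_ergm.synthetic_data import NicheParams, niche_model_web

        web = niche_model_web(NicheParams(25, 0.25, seed=2))
        fit = fit_ergm(web, from_names(["arc"]), SamplerSettings(seed=32),
                       QUICK_RM)
        report = goodness_of_fit(
            web, fit, settings=SamplerSettings(sample_size=500, seed=33),
            warn_unconverged=False,
        )
        frame = report.to_frame()
        assert abs(frame.loc["transitive_triangle_raw", "t_ratio"]) >= 2
        assert abs(frame.loc["triad_030T", "t_ratio"]) >= 2
        assert report.passed is False

    def test_matches_estimator_moment_condition(self, baltic_like):
        """For modelled statistics the GoF t-ratios re-measure the moment
        condition the estimator converged on: both must be small."""
        spec = from_names(["arc", "generalist"])
        fit = fit_ergm(baltic_like, spec, SamplerSettings(seed=9),
                       RobbinsMonroSettings(phase3_samples=1500, newton_polish=2))
        report = goodness_of_fit(
            baltic_like, fit,
            settings=SamplerSettings(sample_size=1500, seed=10),
            warn_unconverged=False,
        )
        frame = report.to_frame()
        modelled_t = frame.loc[list(spec.names), "t_ratio"].abs()
        # small up to the Monte-Carlo error of two independent ensembles
        assert (modelled_t < 0.5).all()

    def test_csv_and_json_outputs(self, tmp_path, baltic_like):
        import json

        fit = _manual_fit(from_names(["arc"]), [-1.3])
        report = goodness_of_fit(
            baltic_like, fit, settings=SamplerSettings(sample_size=50, seed=4)
        )
        report.to_csv(tmp_path / "gof.csv")
        doc = json.loads(report.to_json(tmp_path / "gof.json"))
        assert len(doc["statistics"]) == 32
        assert (tmp_path / "gof.csv").exists()
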