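"""Monte-Carlo MLE: Bernoulli closed form, enumeration oracle, contracts."""

import warnings

import numpy as np
import pytest
from scipy.special import logit, logsumexp

from foodweb_ergm import FoodWeb, exact_fit_small, fit_ergm
from foodweb_ergm.config_statistics import compute_statistics, from_names
from foodweb_ergm.errors import DegeneracyError, ValidationError
from foodweb_ergm.estimator import RobbinsMonroSettings, _enumerate_statistics
from foodweb_ergm.graph_sampler import SamplerSettings

QUICK_RM = RobbinsMonroSettings(phase3_samples=400, newton_polish=1, max_restarts=2)


class TestExactFit:
    def test_arc_only_half_density_is_zero(self):
        web = FoodWeb.from_arcs("ABC", [("A", "B"), ("B", "C"), ("C", "A")])
        theta = exact_fit_small(web, from_names(["arc"]))
        assert theta[0] == pytest.approx(0.0, abs=1e-7)

    def test_arc_only_closed_form(self):
        web = FoodWeb.from_arcs("ABC", [("A", "B"), ("B", "C")])
        theta = exact_fit_small(web, from_names(["arc"]))
        assert theta[0] == pytest.approx(logit(1 / 3), abs=1e-7)

    def test_returned_theta_is_a_likelihood_maximum(self):
        """Gradient vanishes and perturbations lower the enumerated
        log-likelihood (independent check of the optimiser output)."""
        web = FoodWeb.from_arcs("ABC", [("A", "B"), ("B", "A"), ("B", "C")])
        spec = from_names(["arc", "reciprocity"])
        theta = exact_fit_small(web, spec)
        z_obs = compute_statistics(web, spec)
        Z = _enumerate_statistics(3, spec)

        def loglik(th):
            return float(th @ z_obs - logsumexp(Z @ th))

        base = loglik(theta)
        rng = np.random.default_rng(1)
        for _ in range(50):
            assert loglik(theta + 0.05 * rng.normal(size=2)) <= base + 1e-12

    def test_boundary_statistic_warns_and_caps(self, chain3):
        spec = from_names(["arc", "reciprocity"])  # chain has zero mutuals
        with pytest.warns(UserWarning, match="boundary"):
            theta = exact_fit_small(chain3, spec)
        assert theta[spec.index("reciprocity")] == -20.0

    def test_too_many_nodes_rejected(self, rng, random_web_factory):
        with pytest.raises(ValidationError, match="n <= 4"):
            exact_fit_small(random_web_factory(rng, 5), from_names(["arc"]))


class TestFitContracts:
    def test_degenerate_density_raises(self):
        empty = FoodWeb.from_arcs("ABC", [])
        with pytest.raises(DegeneracyError):
            fit_ergm(empty, from_names(["arc"]))

    def test_arc_only_recovers_logit_density(self, baltic_like):
        fit = fit_ergm(baltic_like, from_names(["arc"]),
                       SamplerSettings(seed=5), QUICK_RM)
        assert fit.theta[0] == pytest.approx(logit(baltic_like.density), abs=0.02)
        assert fit.converged
        # the moment condition is what the convergence flag asserts
        assert np.max(np.abs(fit.convergence_t)) <= 0.1

    def test_significance_rule_is_two_standard_errors(self, baltic_like):
        fit = fit_ergm(baltic_like, from_names(["arc"]),
                       SamplerSettings(seed=5), QUICK_RM)
        assert list(fit.significant) == list(
            np.abs(fit.theta) >= 2 * fit.standard_errors
        )

    def test_seed_determinism(self, baltic_like):
        spec = from_names(["arc", "generalist"])
        a = fit_ergm(baltic_like, spec, SamplerSettings(seed=42), QUICK_RM)
        b = fit_ergm(baltic_like, spec, SamplerSettings(seed=42), QUICK_RM)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.convergence_t, b.convergence_t)

    def test_non_convergence_reported_not_raised(self, baltic_like):
        starved = RobbinsMonroSettings(
            subphase_lengths=(1,), gain0=0.01, phase1_samples=10,
            phase3_samples=30, newton_polish=0, max_restarts=0,
        )
        spec = from_names(["arc", "generalist", "tri_trophic", "keystone"])
        fit = fit_ergm(baltic_like, spec, SamplerSettings(seed=8), starved)
        assert fit.converged in (True, False)  # contract: never an exception
        assert fit.theta.shape == (4,)

    def test_json_round_trip_fields(self, baltic_like, tmp_path):
        import json

        fit = fit_ergm(baltic_like, from_names(["arc"]),
                       SamplerSettings(seed=5), QUICK_RM)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        doc = json.loads(path.read_text())
        assert doc["estimates"]["arc"] == pytest.approx(fit.theta[0])
        assert doc["converged"] == fit.converged


def test_mcmc_matches_enumeration_oracle():
    """On an interior n=3 web the stochastic MLE agrees with the exact
    enumeration MLE."""
    web = FoodWeb.from_arcs("ABC", [("A", "B"), ("B", "A"), ("B", "C")])
    spec = from_names(["arc", "reciprocity"])
    exact = exact_fit_small(web, spec)
    rm = RobbinsMonroSettings(phase3_samples=20000, newton_polish=2,
                              convergence_threshold=0.01, max_restarts=4)
    fit = fit_ergm(web, spec, SamplerSettings(seed=51), rm)
    assert np.abs(fit.theta - exact).max() < 0.05


def test_compare_model_specs_single_candidate_trivially_first(baltic_like):
    from foodweb_ergm import compare_model_specs

    spec = from_names(["arc"])
    table, fits, reports = compare_model_specs(
        baltic_like, [spec],
        settings=SamplerSettings(seed=2),
        rm_settings=QUICK_RM,
        gof_settings=SamplerSettings(sample_size=150, seed=3),
    )
    assert list(table["rank"]) == [1]
    assert len(fits) == len(reports) == 1


def test_compare_model_specs_prefers_the_generating_model(rng):
    """On a web with strong in-star concentration, the model including the
    generalist term beats the arc-only model on goodness of fit."""
    from foodweb_ergm import compare_model_specs
    from foodweb_ergm.synthetic_data import simulate_study

    gen_spec = from_names(["arc", "generalist"])
    web = simulate_study([-4.0, 2.0], gen_spec, n=25, replicates=1, seed=77,
                         settings=SamplerSettings(burn_in=400_000))[0]
    table, fits, reports = compare_model_specs(
        web, [from_names(["arc"]), gen_spec],
        settings=SamplerSettings(seed=4),
        rm_settings=RobbinsMonroSettings(phase3_samples=600, newton_polish=2),
        gof_settings=SamplerSettings(sample_size=600, seed=5),
    )
    best = table.iloc[0]
    assert best["configurations"] == "arc, generalist"
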