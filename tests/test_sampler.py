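"""Metropolis-Hastings sampler: kernel, distributional checks, determinism."""

import itertools

import numpy as np
import pytest
from scipy.special import logit

from foodweb_ergm import (
    DegeneracyWarning,
    FoodWeb,
    conditional_logodds,
    sample_networks,
)
from foodweb_ergm.config_statistics import compute_values, from_names
from foodweb_ergm.errors import ParameterError, ValidationError
from foodweb_ergm.graph_sampler import SamplerSettings


class TestConditionalLogOdds:
    def test_arc_only_model_is_constant(self, chain3):
        spec = from_names(["arc"])
        for i, j in itertools.permutations(range(3), 2):
            assert conditional_logodds(chain3, spec, [-1.0], i, j) == -1.0

    def test_zero_theta_gives_zero(self, chain3, full_model_spec):
        theta = np.zeros(full_model_spec.p)
        for i, j in itertools.permutations(range(3), 2):
            assert conditional_logodds(chain3, full_model_spec, theta, i, j) == 0.0

    def test_equals_dot_of_theta_and_delta(self, rng, random_web_factory,
                                           full_model_spec):
        from foodweb_ergm import change_statistics

        web = random_web_factory(rng, 8)
        theta = rng.normal(size=full_model_spec.p)
        lo = conditional_logodds(web, full_model_spec, theta, 2, 5)
        assert lo == pytest.approx(
            theta @ change_statistics(web, full_model_spec, 2, 5)
        )

    def test_non_finite_theta_rejected(self, chain3):
        spec = from_names(["arc"])
        with pytest.raises(ParameterError):
            conditional_logodds(chain3, spec, [np.inf], 0, 1)


class TestArcOnlyDistribution:
    """An arc-only ERGM is i.i.d. Bernoulli over dyads (closed form)."""

    @pytest.mark.parametrize("theta_arc, target", [(0.0, 0.5), (logit(0.2), 0.2)])
    def test_mean_density(self, theta_arc, target):
        spec = from_names(["arc"])
        n, size = 5, 1000
        ens = sample_networks(
            spec, [theta_arc], n,
            SamplerSettings(sample_size=size, seed=11), keep_networks=False,
        )
        dyads = n * (n - 1)
        dens = ens.statistics[:, 0] / dyads
        mc_se = np.std(dens) / np.sqrt(size / 5)  # conservative ESS
        assert abs(dens.mean() - target) < max(3 * mc_se, 0.01)


def test_seed_determinism():
    spec = from_names(["arc", "generalist"])
    kw = dict(n=12, settings=SamplerSettings(sample_size=50, seed=99))
    a = sample_networks(spec, [-1.0, 0.3], **kw)
    b = sample_networks(spec, [-1.0, 0.3], **kw)
    assert np.array_equal(a.statistics, b.statistics)
    assert np.array_equal(a.adjacency, b.adjacency)
    assert a.acceptance_rate == b.acceptance_rate


def test_statistics_rows_match_recomputation(rng, full_model_spec):
    ens = sample_networks(
        full_model_spec, np.full(full_model_spec.p, -0.25), 15,
        SamplerSettings(sample_size=20, seed=7),
    )
    for r in range(20):
        assert ens.statistics[r] == pytest.approx(
            compute_values(ens.adjacency[r], full_model_spec.configurations),
            abs=1e-8,
        )


def test_acceptance_rate_strictly_interior():
    spec = from_names(["arc"])
    ens = sample_networks(spec, [-1.0], 10, SamplerSettings(sample_size=100, seed=3))
    assert 0.0 < ens.acceptance_rate < 1.0


def test_degenerate_drift_warns():
    spec = from_names(["arc"])
    with pytest.warns(DegeneracyWarning):
        ens = sample_networks(spec, [8.0], 8,
                              SamplerSettings(sample_size=50, seed=1))
    assert ens.degenerate


def test_invalid_inputs_rejected():
    spec = from_names(["arc"])
    with pytest.raises(ParameterError):
        sample_networks(spec, [np.nan], 5)
    with pytest.raises(ParameterError):
        sample_networks(spec, [0.0, 1.0], 5)
    with pytest.raises(ValidationError):
        sample_networks(spec, [0.0], 1)


def test_detailed_balance_against_enumeration():
    """On 3 nodes the 64 digraphs can be enumerated exactly; a long chain's
    empirical distribution must match the ERGM probabilities in total
    variation."""
    spec = from_names(["arc", "reciprocity"])
    theta = np.array([-0.4, 0.8])
    dyads = [(i, j) for i in range(3) for j in range(3) if i != j]
    probs = np.empty(64)
    stats = np.empty((64, 2))
    A = np.zeros((3, 3), dtype=np.uint8)
    for code in range(64):
        for b, (i, j) in enumerate(dyads):
            A[i, j] = code >> b & 1
        stats[code] = compute_values(A, spec.configurations)
    scores = stats @ theta
    probs = np.exp(scores - scores.max())
    probs /= probs.sum()

    ens = sample_networks(
        spec, theta, 3,
        SamplerSettings(burn_in=10_000, thinning=5, sample_size=200_000, seed=17),
    )
    codes = np.zeros(ens.sample_size, dtype=np.int64)
    for b, (i, j) in enumerate(dyads):
        codes |= ens.adjacency[:, i, j].astype(np.int64) << b
    emp = np.bincount(codes, minlength=64) / ens.sample_size
    tv = 0.5 * np.abs(emp - probs).sum()
    assert tv < 0.02


def test_generalist_effect_raises_alternating_instars():
    """A positive generalist parameter concentrates prey on few predators
    relative to a density-matched Bernoulli model."""
    spec = from_names(["arc", "generalist"])
    settings = SamplerSettings(thinning=2 * 900, sample_size=300, seed=23)
    ens = sample_networks(spec, [-2.0, 0.5], 30, settings, keep_networks=False)
    mean_density = ens.statistics[:, 0].mean() / (30 * 29)

    arc_only = from_names(["arc", "generalist"])  # same stats, generalist off
    theta0 = [float(logit(mean_density)), 0.0]
    base = sample_networks(arc_only, theta0, 30,
                           SamplerSettings(thinning=2 * 900, sample_size=300,
                                           seed=29), keep_networks=False)
    assert ens.statistics[:, 1].mean() > base.statistics[:, 1].mean()
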