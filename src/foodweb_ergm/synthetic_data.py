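"""Synthetic food webs: canonical fixtures, niche-model webs, and ERGM draws.

Three generators cover the test inputs the analysis needs:

* :func:`fixture_web` returns tiny hand-built webs with exactly known
  statistics, plus a frozen 30-species, 180-arc web shipped as a data file
  (``baltic_like_30``, a synthetic stand-in at the scale and connectance of a
  ~30-node brackish-sea food web; it is committed, not regenerated, so
  numbers attached to it are stable).
* :func:`niche_model_web` draws webs from the classic niche model: each
  species receives a niche value in [0, 1] and consumes every species whose
  niche value falls in a beta-distributed feeding range centred below its
  own, producing the triangular trophic structure (many basal, few top
  species) typical of real webs.  Self-links (cannibalism) are deleted.
* :func:`simulate_study` draws replicate webs from a known ERGM
  (theta_true, spec) for parameter-recovery experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .config_statistics import ModelSpec
from .errors import DegeneracyError, FoodWebError, ValidationError
from .foodweb import FoodWeb, read_foodweb
from .graph_sampler import SamplerSettings, sample_networks

__all__ = ["NicheParams", "fixture_web", "niche_model_web", "simulate_study"]


def _fixture_chain3() -> FoodWeb:
    return FoodWeb.from_arcs("ABC", [("A", "B"), ("B", "C")], {"source": "fixture"})


def _fixture_omnivory3() -> FoodWeb:
    return FoodWeb.from_arcs(
        "ABC", [("A", "B"), ("B", "C"), ("A", "C")], {"source": "fixture"}
    )


def _fixture_pred_star4() -> FoodWeb:
    return FoodWeb.from_arcs(
        ["a", "b", "c", "P"], [("a", "P"), ("b", "P"), ("c", "P")],
        {"source": "fixture"},
    )


def _fixture_prey_fan4() -> FoodWeb:
    return FoodWeb.from_arcs(
        ["R", "x", "y", "z"], [("R", "x"), ("R", "y"), ("R", "z")],
        {"source": "fixture"},
    )


def _fixture_baltic_like_30() -> FoodWeb:
    path = resources.files("foodweb_ergm.data").joinpath("baltic_like_30.csv")
    with resources.as_file(path) as p:
        web = read_foodweb(p, "edge-list", {"source": "frozen synthetic fixture"})
    return web


_FIXTURES = {
    "chain3": _fixture_chain3,
    "omnivory3": _fixture_omnivory3,
    "pred_star4": _fixture_pred_star4,
    "prey_fan4": _fixture_prey_fan4,
    "baltic_like_30": _fixture_baltic_like_30,
}


def fixture_web(name: str) -> FoodWeb:
    """Return a registered fixture web by name.

    Known names: ``chain3`` (A->B->C), ``omnivory3`` (chain plus shortcut),
    ``pred_star4`` (three prey feeding one predator), ``prey_fan4`` (one
    resource feeding three predators), ``baltic_like_30`` (frozen 30-species,
    180-arc synthetic web).
    """
    try:
        build = _FIXTURES[name]
    except KeyError:
        raise FoodWebError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}"
        ) from None
    return build()


@dataclass(frozen=True)
class NicheParams:
    """Niche-model parameters: species count, target connectance L/n^2, seed."""

    n: int = 30
    connectance: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError("need at least 2 species")
        if not 0.0 < self.connectance < 1.0:
            raise ValidationError("connectance must lie strictly in (0, 1)")


def niche_model_web(params: NicheParams) -> FoodWeb:
    """Draw a food web from the niche model (deterministic given the seed).

    Each species i gets a niche value n_i ~ U(0, 1) and a feeding range
    r_i = x * n_i with x ~ Beta(1, 1/(2C) - 1) (so E[x] = 2C and the
    expected pre-removal link count is about C * n^2), centred at
    c_i ~ U(r_i / 2, n_i).  Species j is eaten by i when n_j falls inside
    i's feeding interval.  Cannibalistic self-links are deleted, not redrawn.
    """
    n, C = params.n, params.connectance
    rng = np.random.default_rng(params.seed)
    beta_b = 1.0 / (2.0 * C) - 1.0
    if beta_b <= 0:
        warnings.warn(
            f"connectance {C} >= 0.5 leaves no beta mass; using near-uniform ranges"
        )
        beta_b = 1e-6
    niche = rng.uniform(0.0, 1.0, size=n)
    x = rng.beta(1.0, beta_b, size=n)
    r = x * niche
    centre = rng.uniform(r / 2.0, niche)
    lo, hi = centre - r / 2.0, centre + r / 2.0
    # arc j -> i (prey j eaten by predator i) when n_j in i's feeding interval
    A = ((niche[None, :] >= lo[:, None]) & (niche[None, :] <= hi[:, None])).T
    A = A.astype(np.uint8)
    np.fill_diagonal(A, 0)  # cannibalism removed
    species = [f"sp{i:02d}" for i in range(n)]
    realized = A.sum() / (n * n)
    if A.sum() == 0:
        warnings.warn(
            f"niche model produced no links (target connectance {C}); "
            f"achieved {realized:.3f}"
        )
    return FoodWeb(
        species, A,
        {"source": "niche_model", "target_connectance": C, "seed": params.seed,
         "realized_connectance": float(realized)},
    )


def simulate_study(
    theta_true,
    spec: ModelSpec,
    n: int = 30,
    replicates: int = 1,
    seed: int = 0,
    settings: SamplerSettings | None = None,
) -> list[FoodWeb]:
    """Draw replicate webs from a known ERGM for recovery experiments.

    Each replicate is the final state of an independent chain (independent
    sub-seeds spawned from ``seed``); theta_true is recorded in each web's
    metadata for later recovery scoring.  Raises :class:`DegeneracyError` if
    every replicate comes out empty or complete.
    """
    theta_true = np.asarray(theta_true, dtype=np.float64)
    base = settings or SamplerSettings()
    seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31 - 1)
    webs = []
    n_degenerate = 0
    for k in range(replicates):
        s = SamplerSettings(
            burn_in=base.burn_in, thinning=base.thinning or 1,
            sample_size=1, seed=int(seeds[k]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ens = sample_networks(spec, theta_true, n, s, keep_networks=True)
        A = ens.adjacency[0]
        L = int(A.sum())
        if L == 0 or L == n * (n - 1):
            n_degenerate += 1
        webs.append(
            FoodWeb(
                [f"sp{i:02d}" for i in range(n)], A,
                {"source": "ergm_simulation", "theta_true": theta_true.tolist(),
                 "configurations": list(spec.names), "seed": int(seeds[k])},
            )
        )
    if n_degenerate == replicates:
        raise DegeneracyError(
            f"all {replicates} simulated webs are empty or complete at "
            f"theta = {theta_true.tolist()}"
        )
    return webs
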