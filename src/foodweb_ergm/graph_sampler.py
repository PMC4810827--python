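"""Metropolis-Hastings simulation of directed networks from an ERGM.

The ERGM assigns probability P(G) proportional to exp(sum_s theta_s z_s(G)).
The sampler proposes a uniformly random ordered dyad and toggles its arc with
probability min(1, exp(+/- theta . delta)), where delta is the change
statistic vector of the dyad; the normalising constant is never computed.
The same kernel drives estimation, goodness of fit, and synthetic-data
generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels
from .config_statistics import ModelSpec, change_statistics, compute_values
from .errors import ParameterError, ValidationError
from .foodweb import FoodWeb

__all__ = [
    "SamplerSettings",
    "SampleEnsemble",
    "sample_networks",
    "conditional_logodds",
    "DegeneracyWarning",
]


class DegeneracyWarning(UserWarning):
    """The chain spent most retained samples on empty or complete graphs."""


@dataclass(frozen=True)
class SamplerSettings:
    """Chain settings; ``burn_in`` and ``thinning`` default to multiples of
    the dyad count (50 n^2 and 10 n^2 proposals respectively)."""

    burn_in: int | None = None
    thinning: int | None = None
    sample_size: int = 100
    seed: int = 0

    def resolve(self, n: int) -> "SamplerSettings":
        burn = self.burn_in if self.burn_in is not None else 50 * n * n
        thin = self.thinning if self.thinning is not None else 10 * n * n
        if burn <= 0 or thin <= 0 or self.sample_size <= 0:
            raise ValidationError("sampler settings must be positive")
        return replace(self, burn_in=burn, thinning=thin)


@dataclass(frozen=True)
class SampleEnsemble:
    """Retained networks/statistics from one chain.

    ``statistics`` has one row per retained sample, columns aligned to the
    model specification.  ``adjacency`` is a (sample_size, n, n) uint8 stack
    when networks were retained, else None.
    """

    spec: ModelSpec
    statistics: np.ndarray
    adjacency: np.ndarray | None
    acceptance_rate: float
    settings: SamplerSettings
    degenerate: bool = False

    @property
    def sample_size(self) -> int:
        return self.statistics.shape[0]

    def networks(self, species: Sequence[str] | None = None) -> list[FoodWeb]:
        if self.adjacency is None:
            raise ValidationError("networks were not retained for this ensemble")
        n = self.adjacency.shape[1]
        species = species or [f"sp{i:02d}" for i in range(n)]
        return [FoodWeb(species, A) for A in self.adjacency]

    def statistics_frame(self):
        import pandas as pd

        return pd.DataFrame(self.statistics, columns=list(self.spec.names))


def _chain_state(start: FoodWeb | np.ndarray | None, n: int, spec: ModelSpec):
    if start is None:
        A = np.zeros((n, n), dtype=np.uint8)
    else:
        A = (start.adjacency if isinstance(start, FoodWeb) else start).astype(np.uint8).copy()
        if A.shape != (n, n):
            raise ValidationError(f"start network has {A.shape[0]} nodes, expected {n}")
    din = A.sum(axis=0).astype(np.int64)
    dout = A.sum(axis=1).astype(np.int64)
    z = compute_values(A, spec.configurations)
    return A, din, dout, z


def run_chain(
    A: np.ndarray,
    din: np.ndarray,
    dout: np.ndarray,
    z: np.ndarray,
    spec: ModelSpec,
    theta: np.ndarray,
    burn: int,
    thinning: int,
    n_samples: int,
    seed: int,
    keep_nets: bool = False,
):
    """Advance an in-place chain; low-level building block for the estimator."""
    codes, lams = spec.codes_and_lambdas()
    return _kernels.mh_chain(
        A, din, dout, z, np.asarray(theta, dtype=np.float64), codes, lams,
        int(burn), int(thinning), int(n_samples), int(seed) % (2**31 - 1),
        keep_nets,
    )


def sample_networks(
    spec: ModelSpec,
    theta: Sequence[float],
    n: int,
    settings: SamplerSettings | None = None,
    start: FoodWeb | None = None,
    keep_networks: bool = True,
) -> SampleEnsemble:
    """Draw an ensemble of networks from the ERGM (spec, theta) on n nodes.

    The trace is deterministic given ``settings.seed``.  If the chain is
    pinned at the empty or complete graph for more than 90% of retained
    samples, a :class:`DegeneracyWarning` is issued and the ensemble is
    flagged degenerate.
    """
    theta = np.asarray(theta, dtype=np.float64)
    if theta.shape != (spec.p,):
        raise ParameterError(f"theta has shape {theta.shape}, expected ({spec.p},)")
    if not np.isfinite(theta).all():
        raise ParameterError("theta must be finite")
    if n < 2:
        raise ValidationError("need at least 2 nodes")
    settings = (settings or SamplerSettings()).resolve(n)
    A, din, dout, z = _chain_state(start, n, spec)
    stats, nets, accepted, proposals = run_chain(
        A, din, dout, z, spec, theta,
        settings.burn_in, settings.thinning, settings.sample_size,
        settings.seed, keep_networks,
    )
    arc_col = spec.index("arc")
    counts = stats[:, arc_col]
    pinned = np.mean((counts == 0) | (counts == n * (n - 1)))
    degenerate = bool(pinned > 0.9)
    if degenerate:
        warnings.warn(
            f"chain degenerate: {pinned:.0%} of samples at density 0 or 1",
            DegeneracyWarning,
            stacklevel=2,
        )
    return SampleEnsemble(
        spec=spec,
        statistics=stats,
        adjacency=nets if keep_networks else None,
        acceptance_rate=accepted / proposals,
        settings=settings,
        degenerate=degenerate,
    )


def conditional_logodds(
    web: FoodWeb, spec: ModelSpec, theta: Sequence[float], i: int, j: int
) -> float:
    """Log-odds of arc i -> j conditional on the rest of the web.

    Equals theta . delta(G, i, j); this is the sampler's acceptance kernel
    and is exposed for unit testing and diagnostics.
    """
    theta = np.asarray(theta, dtype=np.float64)
    if not np.isfinite(theta).all():
        raise ParameterError("theta must be finite")
    return float(theta @ change_statistics(web, spec, i, j))
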