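"""Monte-Carlo maximum-likelihood estimation of food-web ERGMs.

The MLE solves the moment equation E_theta[z(G)] = z(G_obs).  It is found by
three-phase Robbins-Monro stochastic approximation:

* **Phase 1** simulates briefly at the initial theta to estimate a scaling
  matrix D (the statistic covariance, i.e. the derivative of the moment map;
  the alternating statistics are strongly correlated with the arc count, so
  the full covariance conditions the updates far better than its diagonal).
* **Phase 2** iterates ``theta <- theta - a * D^{-1} (z(G_sim) - z(G_obs))``
  over subphases of increasing length and halving gain ``a``; at the end of
  each subphase theta is replaced by its subphase average (Polyak averaging),
  which strongly reduces Monte-Carlo noise in the final estimate.
* **Phase 3** draws a large sample at the final theta to compute convergence
  t-ratios ``t_s = (mean z_s - z_obs,s) / sd z_s`` and standard errors from
  the inverse covariance of the sampled statistics (the Fisher information of
  an exponential family is the covariance of its sufficient statistics).

Convergence requires max |t_s| <= 0.1; on failure the procedure restarts
phase 2 from the last theta (up to ``max_restarts`` times) before reporting
``converged=False``.  A parameter is flagged significant when
|estimate| >= 2 SE.

For webs of at most 4 species the likelihood can be maximised exactly by
enumerating all digraphs (:func:`exact_fit_small`); this serves as an
independent oracle for the stochastic estimator.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .config_statistics import ModelSpec, compute_statistics, compute_values
from .errors import DegeneracyError, ValidationError
from .foodweb import FoodWeb
from .graph_sampler import SamplerSettings, run_chain

__all__ = [
    "RobbinsMonroSettings",
    "FitResult",
    "fit_ergm",
    "exact_fit_small",
    "compare_model_specs",
]


@dataclass(frozen=True)
class RobbinsMonroSettings:
    """Stochastic-approximation schedule.

    ``subphase_lengths`` are multiplied by the parameter count p; the gain is
    halved at each subphase starting from ``gain0``.  ``steps_per_update`` is
    the number of chain proposals between successive theta updates (defaults
    to 2 n^2).  Phase 3 retains ``phase3_samples`` networks spaced
    ``phase3_thinning`` proposals apart (defaults: 1000 and 5 n^2; the longer
    spacing keeps the Monte-Carlo noise of the convergence t-ratios near
    0.03, well under the 0.1 convergence threshold).
    """

    subphase_lengths: tuple[int, ...] = (2, 4, 8, 16)
    gain0: float = 0.1
    steps_per_update: int | None = None
    phase1_samples: int = 100
    phase3_samples: int = 1000
    phase3_thinning: int | None = None
    convergence_threshold: float = 0.1
    newton_polish: int = 2
    max_restarts: int = 3


@dataclass(frozen=True)
class FitResult:
    """Parameter estimates and diagnostics for one fitted web.

    ``converged`` is True iff every convergence t-ratio is at most
    ``0.1`` in magnitude; ``significant`` flags satisfy
    |estimate| >= 2 * SE (NaN SEs are never significant).
    """

    spec: ModelSpec
    theta: np.ndarray
    standard_errors: np.ndarray
    convergence_t: np.ndarray
    converged: bool
    seed: int
    n_nodes: int
    observed: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    web_metadata: dict = field(default_factory=dict)

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.abs(self.theta) >= 2.0 * self.standard_errors

    @property
    def names(self) -> tuple[str, ...]:
        return self.spec.names

    def __getitem__(self, name: str) -> float:
        return float(self.theta[self.spec.index(name)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "estimate": self.theta,
                "std_error": self.standard_errors,
                "convergence_t": self.convergence_t,
                "significant": self.significant,
            },
            index=list(self.names),
        )

    def to_json(self, path=None) -> str:
        doc = {
            "configurations": [
                {"name": c.name, "lambda": c.lam} for c in self.spec.configurations
            ],
            "estimates": dict(zip(self.names, map(float, self.theta))),
            "standard_errors": dict(zip(self.names, map(float, self.standard_errors))),
            "convergence_t": dict(zip(self.names, map(float, self.convergence_t))),
            "significant": dict(zip(self.names, map(bool, self.significant))),
            "converged": self.converged,
            "seed": self.seed,
            "n_nodes": self.n_nodes,
            "diagnostics": self.diagnostics,
            "web_metadata": self.web_metadata,
        }
        text = json.dumps(doc, indent=2, default=float)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _logit(x: float) -> float:
    return float(np.log(x / (1.0 - x)))


def fit_ergm(
    web: FoodWeb,
    spec: ModelSpec,
    settings: SamplerSettings | None = None,
    rm_settings: RobbinsMonroSettings | None = None,
) -> FitResult:
    """Fit the ERGM to an observed web by Robbins-Monro MCMC-MLE.

    Deterministic given ``settings.seed``.  Raises
    :class:`DegeneracyError` on an empty or complete web (the MLE diverges);
    non-convergence after the allowed restarts yields ``converged=False``
    rather than an exception.
    """
    n = web.n
    settings = (settings or SamplerSettings()).resolve(n)
    rm = rm_settings or RobbinsMonroSettings()
    dens = web.density
    if dens == 0.0 or dens == 1.0:
        raise DegeneracyError(
            f"web density is {dens:g}: arc parameter MLE is not finite"
        )

    z_obs = compute_statistics(web, spec)
    p = spec.p
    theta = np.zeros(p)
    theta[spec.index("arc")] = _logit(dens)

    rng = np.random.default_rng(settings.seed)

    def subseed() -> int:
        return int(rng.integers(2**31 - 1))

    steps = rm.steps_per_update or 2 * n * n
    phase3_thin = rm.phase3_thinning or 5 * n * n

    # the chain runs continuously from the observed web
    A = web.adjacency.copy()
    din = A.sum(axis=0).astype(np.int64)
    dout = A.sum(axis=1).astype(np.int64)
    z = compute_values(A, spec.configurations)
    accepted = proposals = 0

    def advance(th, burn, thinning, n_samples, keep=False):
        nonlocal accepted, proposals
        stats, nets, acc, props = run_chain(
            A, din, dout, z, spec, th, burn, thinning, n_samples, subseed(), keep
        )
        accepted += acc
        proposals += props
        return stats, nets

    # Phase 1: scaling matrix from the statistic covariance at theta0 (the
    # Fisher information of the exponential family, i.e. the derivative of
    # the moment map), regularised towards its diagonal for stability.
    def scaling(stats_matrix):
        cov = np.cov(stats_matrix.T).reshape(p, p)
        diag = np.clip(np.diag(cov), 1e-8, None)
        cov = 0.9 * cov + 0.1 * np.diag(diag)
        return np.linalg.pinv(cov)

    stats1, _ = advance(theta, settings.burn_in, max(steps, 1), rm.phase1_samples)
    Dinv = scaling(stats1)

    gains = [rm.gain0 / 2**k for k in range(len(rm.subphase_lengths))]
    subphase_lengths = [m * p for m in rm.subphase_lengths]

    def phase2(th):
        for a, length in zip(gains, subphase_lengths):
            trace = np.empty((length, p))
            for it in range(length):
                advance(th, steps, 1, 0)
                th = th - a * (Dinv @ (z - z_obs))
                trace[it] = th
            th = trace.mean(axis=0)
        return th

    def phase3(th, factor=1):
        # successive restarts double the sample size (capped at 4x): near the
        # solution the residual is dominated by Monte-Carlo error, so extra
        # precision is spent exactly where it pays.
        stats3, _ = advance(
            th, settings.burn_in, phase3_thin, rm.phase3_samples * min(factor, 4)
        )
        mean = stats3.mean(axis=0)
        sd = stats3.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, (mean - z_obs) / sd, np.inf * np.sign(mean - z_obs))
        cov = np.cov(stats3.T) if p > 1 else np.array([[stats3.var(ddof=1)]])
        return t, cov, mean

    restarts = 0
    theta = phase2(theta)
    t, cov, mean3 = phase3(theta)

    def newton(th, cov_, mean_):
        diag = np.clip(np.diag(cov_), 1e-8, None)
        Dinv_ = np.linalg.pinv(0.9 * cov_ + 0.1 * np.diag(diag))
        return th - Dinv_ @ (mean_ - z_obs)

    # Mandatory Newton polish: a fixed number of Newton steps on the moment
    # equation using growing phase-3 ensembles, applied unconditionally.  A
    # stop-when-measured-converged rule alone is optimistically biased (it
    # halts on downward noise fluctuations of |t|); the fixed polish leaves a
    # residual that is symmetric Monte-Carlo noise of the final ensemble.
    iters = 0
    for _ in range(rm.newton_polish):
        iters += 1
        theta = newton(theta, cov, mean3)
        t, cov, mean3 = phase3(theta, factor=2**iters)
    # Restarts from the last theta on non-convergence: further Newton steps,
    # re-checked on fresh ensembles.
    while np.max(np.abs(t)) > rm.convergence_threshold and restarts < rm.max_restarts:
        restarts += 1
        iters += 1
        theta = newton(theta, cov, mean3)
        t, cov, mean3 = phase3(theta, factor=2**iters)

    converged = bool(np.max(np.abs(t)) <= rm.convergence_threshold)
    try:
        se = np.sqrt(np.diag(np.linalg.inv(cov)))
    except np.linalg.LinAlgError:
        warnings.warn("singular statistic covariance: standard errors unavailable")
        se = np.full(p, np.nan)

    return FitResult(
        spec=spec,
        theta=theta,
        standard_errors=se,
        convergence_t=t,
        converged=converged,
        seed=settings.seed,
        n_nodes=n,
        observed=z_obs,
        diagnostics={
            "gains": gains,
            "subphase_lengths": subphase_lengths,
            "steps_per_update": steps,
            "phase3_samples": rm.phase3_samples,
            "phase3_thinning": phase3_thin,
            "restarts": restarts,
            "acceptance_rate": accepted / proposals if proposals else float("nan"),
        },
        web_metadata=dict(web.metadata),
    )


# -- exact enumeration oracle ------------------------------------------------------

def _enumerate_statistics(n: int, spec: ModelSpec) -> np.ndarray:
    """Statistic matrix over all 2^(n(n-1)) loop-free digraphs on n nodes."""
    dyads = [(i, j) for i in range(n) for j in range(n) if i != j]
    m = len(dyads)
    Z = np.empty((2**m, spec.p))
    A = np.zeros((n, n), dtype=np.uint8)
    for code in range(2**m):
        for b, (i, j) in enumerate(dyads):
            A[i, j] = code >> b & 1
        Z[code] = compute_values(A, spec.configurations)
    return Z


def exact_fit_small(web: FoodWeb, spec: ModelSpec, cap: float = 20.0) -> np.ndarray:
    """Exact MLE by full enumeration of the digraph space (n <= 4 only).

    Maximises l(theta) = theta . z_obs - log sum_G exp(theta . z(G)).  If an
    observed statistic lies on the boundary of its attainable range the MLE
    diverges; a warning is issued and the estimate capped at +/- ``cap``.
    """
    from scipy.optimize import minimize
    from scipy.special import logsumexp, softmax

    if web.n > 4:
        raise ValidationError(
            f"exact enumeration limited to n <= 4 (got n = {web.n})"
        )
    z_obs = compute_statistics(web, spec)
    Z = _enumerate_statistics(web.n, spec)
    boundary = (z_obs <= Z.min(axis=0)) | (z_obs >= Z.max(axis=0))
    if boundary.any():
        names = [spec.names[k] for k in np.flatnonzero(boundary)]
        warnings.warn(
            f"observed statistics on range boundary ({names}): MLE diverges, "
            f"estimate capped at +/-{cap}"
        )

    def negll(theta):
        scores = Z @ theta
        return float(logsumexp(scores) - theta @ z_obs)

    def grad(theta):
        w = softmax(Z @ theta)
        return w @ Z - z_obs

    res = minimize(negll, np.zeros(spec.p), jac=grad, method="BFGS",
                   options={"gtol": 1e-9, "maxiter": 500})
    theta = np.clip(res.x, -cap, cap)
    return theta


def compare_model_specs(
    web: FoodWeb,
    candidates: list[ModelSpec],
    settings: SamplerSettings | None = None,
    rm_settings: RobbinsMonroSettings | None = None,
    gof_settings: SamplerSettings | None = None,
):
    """Fit each candidate model and rank them.

    Ranking is lexicographic: converged fits first, then fewer
    goodness-of-fit failures (|t| >= 2 over the default 32-statistic suite),
    then fewer parameters.  Returns (ranked DataFrame, fits, reports); final
    model selection remains the user's responsibility.
    """
    from .gof import default_gof_suite, goodness_of_fit

    if not candidates:
        raise ValidationError("need at least one candidate specification")
    suite = default_gof_suite()
    rows, fits, reports = [], [], []
    for k, spec in enumerate(candidates):
        fit = fit_ergm(web, spec, settings, rm_settings)
        report = goodness_of_fit(web, fit, suite, gof_settings, warn_unconverged=False)
        rows.append(
            {
                "model": k,
                "configurations": ", ".join(spec.names),
                "p": spec.p,
                "converged": fit.converged,
                "gof_failures": report.n_failures,
                "max_abs_t": float(np.max(np.abs(fit.convergence_t))),
            }
        )
        fits.append(fit)
        reports.append(report)
    import pandas as pd

    table = pd.DataFrame(rows).sort_values(
        by=["converged", "gof_failures", "p"], ascending=[False, True, True],
        kind="stable",
    )
    table["rank"] = range(1, len(table) + 1)
    return table, fits, reports
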