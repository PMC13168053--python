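"""Adaptive-Metropolis sampling, posterior predictive bands, and
per-constraint satisfaction fractions.

Sampling is random-walk Metropolis with multivariate normal proposals in
the sampling space (log10 for rate constants and scaling factors, linear
for sigma).  A run has three phases: burn-in (diagonal proposal with scalar
step-size tuning toward a target acceptance band), adaptation (the proposal
covariance is repeatedly re-estimated from the chain history as
(2.38^2 / d) * Cov + jitter), and production (the kernel is frozen, so the
production draws form a valid fixed-kernel Markov chain).  Burn-in and
adaptation draws are excluded from all inference outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import diagnostics
from .params import ParameterSet
from .properties import ComparisonProperty, PropertySet
from .simulate import SimulationError, simulate_variant

__all__ = [
    "McmcConfig",
    "PosteriorSample",
    "run_chain",
    "sample_posterior",
    "posterior_predictive",
    "constraint_satisfaction_fraction",
]

LogDensity = Callable[[np.ndarray], float]


@dataclass
class McmcConfig:
    """Chain-length and proposal settings."""

    burn_in: int = 25_000
    adaptation: int = 25_000
    production: int = 250_000
    chains: int = 5
    seed: int = 0
    initial_scale: float = 0.05      # fraction of each box width
    target_acceptance: Tuple[float, float] = (0.2, 0.5)
    adapt_interval: int = 100        # covariance refresh cadence
    jitter: float = 1e-10

    def __post_init__(self) -> None:
        for name in ("burn_in", "adaptation", "production"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class PosteriorSample:
    """Draws and metadata of one or more chains (production phase only).

    ``chains`` holds per-chain draw matrices in sampling space
    (iteration x parameter); ``chains_theta`` the same draws mapped back to
    the original parameter scale.
    """

    names: List[str]
    chains: List[np.ndarray]
    chains_theta: List[np.ndarray]
    log_posterior: List[np.ndarray]
    acceptance: List[Dict[str, float]]
    seed: int = 0

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def stacked_theta(self) -> np.ndarray:
        """All production draws pooled, original scale, shape (N, d)."""
        return np.vstack(self.chains_theta)

    def parameter_array(self, name: str, scale: str = "theta") -> np.ndarray:
        """(chain, draw) array for one parameter."""
        j = self.names.index(name)
        src = self.chains_theta if scale == "theta" else self.chains
        return np.stack([c[:, j] for c in src])

    def diagnostics(self) -> Dict[str, Dict[str, float]]:
        """R-hat and bulk/tail ESS per parameter (sampling scale)."""
        out = {}
        for name in self.names:
            arr = self.parameter_array(name, scale="sampling")
            out[name] = {
                "rhat": diagnostics.rhat(arr),
                "ess_bulk": diagnostics.ess_bulk(arr),
                "ess_tail": diagnostics.ess_tail(arr),
            }
        return out

    def credible_interval(
        self, name: str, level: float = 0.95
    ) -> Tuple[float, float]:
        draws = self.parameter_array(name).ravel()
        a = (1.0 - level) / 2.0
        return float(np.quantile(draws, a)), float(np.quantile(draws, 1 - a))


def _init_point(
    log_post: LogDensity,
    bounds: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> Tuple[np.ndarray, float]:
    for _ in range(max_tries):
        x = bounds[:, 0] + rng.uniform(size=len(bounds)) * (
            bounds[:, 1] - bounds[:, 0]
        )
        lp = log_post(x)
        if np.isfinite(lp):
            return x, lp
    raise RuntimeError(
        "could not find a finite-posterior initialization point "
        f"in {max_tries} tries"
    )


def run_chain(
    log_post: LogDensity,
    bounds: np.ndarray,
    config: McmcConfig,
    seed: int,
    names: Optional[Sequence[str]] = None,
    to_theta: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    init: Optional[Sequence[float]] = None,
) -> Dict[str, object]:
    """One adaptive-Metropolis chain.

    ``log_post`` is the log target density over the sampling space;
    ``bounds`` (d x 2) is the prior box in that space, used for
    initialization and the initial proposal scale.  ``init`` (sampling
    space) replaces the default random-within-prior initialization, e.g. to
    start chains at a maximum-likelihood estimate.  Returns a dict with the
    production draws, log-posterior trace and per-phase acceptance rates.
    """
    rng = np.random.default_rng(seed)
    bounds = np.asarray(bounds, dtype=float)
    d = bounds.shape[0]
    if init is not None:
        x = np.asarray(init, dtype=float)
        lp = log_post(x)
        if not np.isfinite(lp):
            raise ValueError("initialization point has -inf posterior")
    else:
        x, lp = _init_point(log_post, bounds, rng)

    width = bounds[:, 1] - bounds[:, 0]
    step = config.initial_scale
    cov_chol = np.diag(step * width)
    lam = 1.0                     # global scale of the adapted kernel
    cov_hat: Optional[np.ndarray] = None
    target = 0.234                # classic random-walk optimum

    history: List[np.ndarray] = []
    production = np.empty((config.production, d))
    lp_trace = np.empty(config.production)
    acceptance: Dict[str, float] = {}

    phases = (
        ("burn_in", config.burn_in),
        ("adaptation", config.adaptation),
        ("production", config.production),
    )
    lo_acc, hi_acc = config.target_acceptance
    for phase, length in phases:
        accepted = 0
        window_accepted = 0
        for it in range(length):
            prop = x + cov_chol @ rng.standard_normal(d)
            lp_prop = log_post(prop)
            if np.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
                accepted += 1
                window_accepted += 1
            if phase != "production":
                history.append(x.copy())
            else:
                production[it] = x
                lp_trace[it] = lp
            if phase == "burn_in" and (it + 1) % config.adapt_interval == 0:
                # scalar step tuning toward the target acceptance band
                rate = window_accepted / config.adapt_interval
                if rate < lo_acc:
                    step *= 0.7
                elif rate > hi_acc:
                    step *= 1.4
                cov_chol = np.diag(step * width)
                window_accepted = 0
            if phase == "adaptation" and (it + 1) % config.adapt_interval == 0:
                hist = np.asarray(history)
                cov = np.cov(hist.T) if d > 1 else np.atleast_2d(
                    np.var(hist, axis=0)
                )
                cov_hat = (2.38**2 / d) * np.atleast_2d(cov) \
                    + config.jitter * np.eye(d)
                # Robbins-Monro global scale keeps acceptance near the
                # random-walk optimum even when the early history is poor
                rate = window_accepted / config.adapt_interval
                lam *= float(np.exp(rate - target))
                window_accepted = 0
                try:
                    cov_chol = np.linalg.cholesky(lam * cov_hat)
                except np.linalg.LinAlgError:
                    pass  # keep the previous kernel
        acceptance[phase] = accepted / length if length else float("nan")
    theta = (
        np.apply_along_axis(to_theta, 1, production)
        if to_theta is not None and config.production
        else production.copy()
    )
    return {
        "samples": production,
        "samples_theta": theta,
        "log_posterior": lp_trace,
        "acceptance": acceptance,
        "seed": seed,
        "names": list(names) if names else [f"p{i}" for i in range(d)],
    }


def sample_posterior(
    log_posterior, config: Optional[McmcConfig] = None,
    init_theta: Optional[Sequence[float]] = None,
) -> PosteriorSample:
    """Run independent adaptive-Metropolis chains on a LogPosterior.

    ``log_posterior`` is a :class:`mekfit.objective.LogPosterior` (or any
    object exposing ``__call__`` over sampling space, ``sampling_bounds()``,
    ``from_sampling_space()`` and ``names``).  Chains are seeded
    independently from ``config.seed``.  ``init_theta`` (original scale)
    optionally starts every chain from the same point, e.g. the MLE;
    the default is an independent random point within the prior per chain.
    """
    config = config or McmcConfig()
    bounds = log_posterior.sampling_bounds()
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    init = (
        log_posterior.to_sampling_space(init_theta)
        if init_theta is not None
        else None
    )
    chains, thetas, lps, accs = [], [], [], []
    for k in range(config.chains):
        chain_seed = int(seeds[k].generate_state(1)[0] % (2**31 - 1))
        res = run_chain(
            log_posterior,
            bounds,
            config,
            chain_seed,
            names=log_posterior.names,
            to_theta=log_posterior.from_sampling_space,
            init=init,
        )
        chains.append(res["samples"])
        thetas.append(res["samples_theta"])
        lps.append(res["log_posterior"])
        accs.append(res["acceptance"])
    return PosteriorSample(
        names=list(log_posterior.names),
        chains=chains,
        chains_theta=thetas,
        log_posterior=lps,
        acceptance=accs,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# posterior predictive

DEFAULT_QUANTILE_LEVELS = (0.10, 0.25, 0.50, 0.75, 0.90, 0.95)


def _thin_indices(n: int, max_draws: int, rng: np.random.Generator) -> np.ndarray:
    if n <= max_draws:
        return np.arange(n)
    stride = int(np.ceil(n / max_draws))
    return np.arange(0, n, stride)


def posterior_predictive(
    samples: PosteriorSample,
    base: ParameterSet,
    variants: Sequence[str],
    observables: Sequence[str],
    times: Sequence[float],
    levels: Sequence[float] = DEFAULT_QUANTILE_LEVELS,
    max_draws: int = 2000,
    rtol: float = 1e-6,
    atol: float = 1e-1,
    seed: int = 0,
) -> Dict[str, object]:
    """Nested central credible bands of simulated trajectories.

    Each retained draw is simulated deterministically (parametric
    uncertainty only; no measurement noise is injected).  Returns, per
    variant and observable, the per-time median and a band (lo, hi) for each
    central quantile level; failed simulations are dropped and counted.
    """
    rng = np.random.default_rng(seed)
    theta = samples.stacked_theta()
    idx = _thin_indices(theta.shape[0], max_draws, rng)
    times = np.asarray(sorted(set(map(float, times))))
    curves: Dict[str, Dict[str, list]] = {
        v: {o: [] for o in observables} for v in variants
    }
    n_failed = 0
    for i in idx:
        p = base.replace(**dict(zip(samples.names, map(float, theta[i]))))
        try:
            per = {
                v: simulate_variant(p, v, times, rtol=rtol, atol=atol)
                for v in variants
            }
        except SimulationError:
            n_failed += 1
            continue
        for v in variants:
            for o in observables:
                curves[v][o].append(per[v].observables[o])
    bands: Dict[str, object] = {"times": times, "n_draws": len(idx) - n_failed,
                                "n_failed": n_failed, "levels": list(levels)}
    for v in variants:
        bands[v] = {}
        for o in observables:
            arr = np.asarray(curves[v][o])  # (draws, times)
            entry = {"median": np.median(arr, axis=0)}
            for lev in levels:
                a = (1.0 - lev) / 2.0
                entry[lev] = (
                    np.quantile(arr, a, axis=0),
                    np.quantile(arr, 1.0 - a, axis=0),
                )
            bands[v][o] = entry
    return bands


def constraint_satisfaction_fraction(
    samples: PosteriorSample,
    props: PropertySet | Sequence[ComparisonProperty],
    base: ParameterSet,
    max_draws: int = 500,
    rtol: float = 1e-6,
    atol: float = 1e-1,
) -> List[float]:
    """Fraction of posterior draws satisfying each qualitative statement."""
    rng = np.random.default_rng(samples.seed)
    theta = samples.stacked_theta()
    idx = _thin_indices(theta.shape[0], max_draws, rng)
    props = list(props)
    req: Dict[str, set] = {}
    for p in props:
        for c in (p.left, p.right):
            req.setdefault(c.variant, set()).add(c.time)
    counts = np.zeros(len(props))
    n_used = 0
    for i in idx:
        pset = base.replace(**dict(zip(samples.names, map(float, theta[i]))))
        try:
            trajs = {
                v: simulate_variant(pset, v, sorted(ts), rtol=rtol, atol=atol)
                for v, ts in req.items()
            }
        except SimulationError:
            continue
        n_used += 1
        for j, p in enumerate(props):
            delta = (
                trajs[p.left.variant].at(p.left.observable, p.left.time)
                - trajs[p.right.variant].at(p.right.observable, p.right.time)
            )
            predicted = 1 if delta >= 0 else 0
            counts[j] += predicted == p.z
    if n_used == 0:
        raise RuntimeError("all posterior-predictive simulations failed")
    return list(counts / n_used)
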