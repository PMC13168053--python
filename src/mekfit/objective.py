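"""Hybrid quantitative + qualitative likelihood and penalty objective.

Quantitative records are compared to scaled wild-type outputs under an
i.i.d. homoscedastic Gaussian noise model; the negative log-likelihood is

    (n/2) ln(2 pi sigma^2) + Fquant / (2 sigma^2),
    Fquant = sum_i (y_i - f(c_i, theta))^2.

Each qualitative observation z_i in {0, 1} is Bernoulli with a logistic link
on the model-output difference delta_i = g(a_i) - g(b_i):

    p_i = 1 / (1 + exp(-delta_i / s_i)),
    -ln L(theta | z) = sum_i [ ln(1 + exp(-delta_i/s_i)) + (1-z_i) delta_i/s_i ].

The hinge penalty used during optimization replaces each term by

    w_i [ max(0, -delta_i) + (1 - z_i) delta_i ],  w_i = 1/s_i,

which is w_i |delta_i| when the sign of delta_i contradicts z_i and 0
otherwise; with w_i = 1/s_i it brackets the exact term from below within
ln 2.  The total fitting objective is F = Fquant + Fqual.

Scaling factors apply only to quantitative comparisons (the wild-type
model); qualitative differences are computed on raw copy numbers, so
cross-variant comparisons of the same observable are scale-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .data import QuantDataset, QuantRecord
from .params import ParameterSet, REFERENCE_PARAMS, RATE_NAMES, INITIAL_NAMES
from .properties import ComparisonProperty, PropertySet
from .simulate import SimulationError, Trajectory, simulate_variant

__all__ = [
    "SCALED_OBSERVABLES",
    "ObjectiveBreakdown",
    "logistic_prob",
    "qual_nll_terms",
    "qual_penalty_terms",
    "f_quant",
    "gaussian_nll",
    "qual_nll",
    "qual_penalty",
    "model_output",
    "simulate_for",
    "total_objective",
    "HybridObjective",
    "LogPosterior",
]

log = logging.getLogger(__name__)

#: Observable name -> scaling-factor parameter for quantitative comparisons.
SCALED_OBSERVABLES: Dict[str, str] = {
    "pEGFR": "ScalepEGFR",
    "pERK1_2_wt": "ScalepERK",
    "pSOS1": "ScalepSOS1",
}


# ---------------------------------------------------------------------------
# elementary likelihood pieces

def logistic_prob(delta, s):
    """P(z = 1) = 1 / (1 + exp(-delta/s)); stable for large |delta/s|."""
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("scale s must be > 0")
    x = np.asarray(delta, dtype=float) / s
    # expit via logaddexp keeps both tails stable
    return np.exp(-np.logaddexp(0.0, -x))


def qual_nll_terms(delta, s, z):
    """Per-observation negative log Bernoulli-logistic likelihood."""
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("scale s must be > 0")
    x = np.asarray(delta, dtype=float) / s
    z = np.asarray(z, dtype=float)
    return np.logaddexp(0.0, -x) + (1.0 - z) * x


def qual_penalty_terms(delta, s, z):
    """Per-observation hinge penalty with weight w = 1/s."""
    s = np.asarray(s, dtype=float)
    delta = np.asarray(delta, dtype=float)
    z = np.asarray(z, dtype=float)
    return (np.maximum(0.0, -delta) + (1.0 - z) * delta) / s


def f_quant(residuals: Sequence[float]) -> float:
    """Sum of squared residuals (missing records contribute nothing)."""
    r = np.asarray(residuals, dtype=float)
    return float(np.dot(r, r))


def gaussian_nll(fquant: float, n: int, sigma: float) -> float:
    """Negative log-likelihood of the quantitative data.

    ``fquant`` is the residual sum of squares over the ``n`` non-missing
    records.  An empty dataset has zero negative log-likelihood.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if n == 0:
        return 0.0
    return 0.5 * n * np.log(2.0 * np.pi * sigma**2) + fquant / (
        2.0 * sigma**2
    )


# ---------------------------------------------------------------------------
# model-facing pieces

def model_output(
    params: ParameterSet, record: QuantRecord,
    trajectories: Mapping[str, Trajectory],
) -> float:
    """Scaled prediction f(c_i, theta) for one quantitative record."""
    try:
        scale_name = SCALED_OBSERVABLES[record.observable]
    except KeyError:
        raise KeyError(
            f"no scaling factor defined for observable {record.observable!r}"
        ) from None
    raw = trajectories[record.variant].at(record.observable, record.time)
    return raw * params[scale_name]


def simulate_for(
    params: ParameterSet,
    data: Optional[QuantDataset],
    props: Optional[PropertySet],
    rtol: float = 1e-6,
    atol: float = 1e-1,
) -> Dict[str, Trajectory]:
    """One simulation per required variant, on the union of required times."""
    req: Dict[str, set] = {}
    if data is not None:
        for v, ts in data.required_times().items():
            req.setdefault(v, set()).update(ts)
    if props is not None:
        for v, ts in props.required_times().items():
            req.setdefault(v, set()).update(ts)
    return {
        v: simulate_variant(params, v, sorted(ts), rtol=rtol, atol=atol)
        for v, ts in req.items()
    }


@dataclass
class ObjectiveBreakdown:
    """Decomposed value of the hybrid objective at one parameter point."""

    fquant: float
    fqual: float
    residuals: List[float]
    penalties: List[float]
    deltas: List[float]
    n: int
    failed: bool = False
    trajectories: Dict[str, Trajectory] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.fquant + self.fqual

    def nll(self, sigma: float) -> float:
        """Exact negative log-likelihood (Gaussian + Bernoulli-logistic)."""
        return gaussian_nll(self.fquant, self.n, sigma) + self.fqual_exact

    @property
    def fqual_exact(self) -> float:
        # recomputed from stored deltas; scales live with the properties
        return float("nan") if self._props is None else float(
            np.sum(qual_nll_terms(
                self.deltas,
                [p.scale for p in self._props],
                [p.z for p in self._props],
            ))
        )

    _props: Optional[Sequence[ComparisonProperty]] = None


def qual_nll(params_deltas, props: PropertySet) -> float:
    """Exact qualitative negative log-likelihood given per-property deltas."""
    if len(props) == 0:
        return 0.0
    return float(np.sum(qual_nll_terms(
        params_deltas, [p.scale for p in props], [p.z for p in props]
    )))


def qual_penalty(params_deltas, props: PropertySet) -> float:
    """Hinge-penalty Fqual given per-property deltas."""
    if len(props) == 0:
        return 0.0
    return float(np.sum(qual_penalty_terms(
        params_deltas, [p.scale for p in props], [p.z for p in props]
    )))


def total_objective(
    params: ParameterSet,
    data: Optional[QuantDataset] = None,
    props: Optional[PropertySet] = None,
    rtol: float = 1e-6,
    atol: float = 1e-1,
    keep_trajectories: bool = False,
) -> ObjectiveBreakdown:
    """F(theta) = Fquant + Fqual with its full per-item decomposition.

    Each required variant is simulated once per evaluation and reused across
    all records and properties.  A failed simulation yields an infinite
    objective (flagged and logged), never an exception.
    """
    try:
        trajs = simulate_for(params, data, props, rtol=rtol, atol=atol)
    except SimulationError as e:
        log.warning("simulation failure during objective evaluation: %s", e)
        bd = ObjectiveBreakdown(
            fquant=np.inf, fqual=np.inf, residuals=[], penalties=[],
            deltas=[], n=0, failed=True,
        )
        return bd

    residuals: List[float] = []
    n = 0
    if data is not None:
        for rec in data:
            if rec.missing:
                continue
            residuals.append(rec.value - model_output(params, rec, trajs))
            n += 1
    deltas: List[float] = []
    penalties: List[float] = []
    if props is not None and len(props) > 0:
        for p in props:
            d = (trajs[p.left.variant].at(p.left.observable, p.left.time)
                 - trajs[p.right.variant].at(p.right.observable, p.right.time))
            deltas.append(d)
        penalties = list(qual_penalty_terms(
            deltas, [p.scale for p in props], [p.z for p in props]
        ))
    bd = ObjectiveBreakdown(
        fquant=f_quant(residuals),
        fqual=float(np.sum(penalties)) if penalties else 0.0,
        residuals=residuals,
        penalties=penalties,
        deltas=deltas,
        n=n,
        trajectories=trajs if keep_trajectories else {},
    )
    bd._props = list(props) if props is not None else None
    return bd


# ---------------------------------------------------------------------------
# vector-facing objective and posterior

#: Parameters whose value changes the ODE solution (anything that is not a
#: scaling factor or sigma).
_MODEL_NAMES = set(RATE_NAMES) | set(INITIAL_NAMES)


class HybridObjective:
    """F(theta) over a free-parameter vector, for optimizers.

    ``free_names`` are the coordinates of the vector (in order); all other
    parameters are pinned to ``base``.  Evaluations are pure and independent
    (no shared mutable state beyond counters), so they may be dispatched
    concurrently.
    """

    def __init__(
        self,
        data: Optional[QuantDataset],
        props: Optional[PropertySet],
        free_names: Sequence[str],
        base: ParameterSet = REFERENCE_PARAMS,
        rtol: float = 1e-6,
        atol: float = 1e-1,
    ):
        self.data = data
        self.props = props
        self.free_names = list(free_names)
        self.base = base
        self.rtol = rtol
        self.atol = atol
        self.n_evaluations = 0
        self.n_failures = 0

    def params_from_vector(self, x: Sequence[float]) -> ParameterSet:
        if len(x) != len(self.free_names):
            raise ValueError(
                f"expected {len(self.free_names)} coordinates, got {len(x)}"
            )
        return self.base.replace(**dict(zip(self.free_names, map(float, x))))

    def breakdown(self, x: Sequence[float]) -> ObjectiveBreakdown:
        return total_objective(
            self.params_from_vector(x), self.data, self.props,
            rtol=self.rtol, atol=self.atol,
        )

    def __call__(self, x: Sequence[float]) -> float:
        self.n_evaluations += 1
        bd = self.breakdown(x)
        if bd.failed:
            self.n_failures += 1
        return bd.total


class LogPosterior:
    """Log posterior over the sampled parameter subset.

    The sampled set defaults to (d3, u3, ScalepEGFR, ScalepERK, ScalepSOS1,
    sigma).  Rate constants and scaling factors are sampled in log10 space;
    sigma stays linear.  The prior is uniform on the *original* scale inside
    the box (the log-transform Jacobian is included), so posterior ratios
    inside the box equal likelihood ratios.

    Simulations are cached on the model-parameter subvector: proposals that
    move only scales/sigma reuse the cached trajectories.
    """

    def __init__(
        self,
        data: Optional[QuantDataset],
        props: Optional[PropertySet],
        prior: Mapping[str, Tuple[float, float]],
        base: ParameterSet,
        rtol: float = 1e-6,
        atol: float = 1e-1,
        cache_size: int = 8,
    ):
        self.data = data
        self.props = props
        self.names = list(prior)
        self.bounds = {n: (float(lo), float(hi)) for n, (lo, hi) in prior.items()}
        for n, (lo, hi) in self.bounds.items():
            if not (0 <= lo < hi):
                raise ValueError(f"invalid prior box for {n}: [{lo}, {hi}]")
        self.base = base
        self.rtol = rtol
        self.atol = atol
        self.log10_names = [n for n in self.names if n != "sigma"]
        self._model_idx = [
            i for i, n in enumerate(self.names) if n in _MODEL_NAMES
        ]
        self._cache: Dict[tuple, Dict[str, Trajectory]] = {}
        self._cache_size = cache_size
        self.n_evaluations = 0
        self.n_failures = 0
        # flat-prior normalization over the original-scale box
        self._log_prior_const = -float(
            np.sum([np.log(hi - lo) for lo, hi in self.bounds.values()])
        )

    # -- transforms --------------------------------------------------------
    def to_sampling_space(self, theta: Sequence[float]) -> np.ndarray:
        phi = np.array(theta, dtype=float)
        for i, n in enumerate(self.names):
            if n in self.log10_names:
                phi[i] = np.log10(phi[i])
        return phi

    def from_sampling_space(self, phi: Sequence[float]) -> np.ndarray:
        theta = np.array(phi, dtype=float)
        for i, n in enumerate(self.names):
            if n in self.log10_names:
                theta[i] = 10.0 ** theta[i]
        return theta

    def sampling_bounds(self) -> np.ndarray:
        """Box in sampling space, shape (d, 2)."""
        out = np.empty((len(self.names), 2))
        for i, n in enumerate(self.names):
            lo, hi = self.bounds[n]
            if n in self.log10_names:
                out[i] = (np.log10(lo), np.log10(hi))
            else:
                out[i] = (lo, hi)
        return out

    def params_from_theta(self, theta: Sequence[float]) -> ParameterSet:
        return self.base.replace(**dict(zip(self.names, map(float, theta))))

    # -- evaluation --------------------------------------------------------
    def _trajectories(self, params: ParameterSet, theta: np.ndarray):
        key = tuple(theta[i] for i in self._model_idx)
        if key not in self._cache:
            if len(self._cache) >= self._cache_size:
                self._cache.pop(next(iter(self._cache)))
            self._cache[key] = simulate_for(
                params, self.data, self.props, rtol=self.rtol, atol=self.atol
            )
        return self._cache[key]

    def log_posterior_theta(self, theta: Sequence[float]) -> float:
        """Log posterior density at a point on the original scale."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(self.names),):
            raise ValueError(
                f"expected {len(self.names)} parameters, got {theta.shape}"
            )
        for v, n in zip(theta, self.names):
            lo, hi = self.bounds[n]
            if not (lo <= v <= hi):
                return -np.inf
        self.n_evaluations += 1
        params = self.params_from_theta(theta)
        try:
            trajs = self._trajectories(params, theta)
        except SimulationError as e:
            self.n_failures += 1
            log.warning("simulation failure in posterior evaluation: %s", e)
            return -np.inf

        residuals = []
        n = 0
        if self.data is not None:
            for rec in self.data:
                if rec.missing:
                    continue
                residuals.append(rec.value - model_output(params, rec, trajs))
                n += 1
        sigma = params.sigma
        nll = gaussian_nll(f_quant(residuals), n, sigma)
        if self.props is not None and len(self.props) > 0:
            deltas = [
                trajs[p.left.variant].at(p.left.observable, p.left.time)
                - trajs[p.right.variant].at(p.right.observable, p.right.time)
                for p in self.props
            ]
            nll += qual_nll(deltas, self.props)
        return -nll + self._log_prior_const

    def __call__(self, phi: Sequence[float]) -> float:
        """Log posterior density in sampling space (includes the Jacobian)."""
        theta = self.from_sampling_space(phi)
        lp = self.log_posterior_theta(theta)
        if not np.isfinite(lp):
            return lp
        # d theta / d phi = theta * ln 10 for each log10 coordinate
        jac = sum(
            np.log(theta[i]) + np.log(np.log(10.0))
            for i, n in enumerate(self.names) if n in self.log10_names
        )
        return lp + jac
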