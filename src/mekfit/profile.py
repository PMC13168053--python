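"""Profile-likelihood identifiability analysis.

A profile re-minimizes the hybrid objective along a grid of fixed values of
one parameter, re-optimizing all remaining adjustable parameters at each
grid point.  A bounded sub-threshold region around the optimum implies
practical identifiability; the region itself is the profile confidence
interval.

The threshold is applied on the negative-log-likelihood scale: the hybrid
objective F is converted with the plug-in noise variance
``sigma_hat^2 = Fquant(theta_hat) / n`` so that a change of
``Delta = chi2_{1,0.95} / 2 = 1.92`` corresponds to an approximate 95%
profile interval.  The raw curves are always reported so any other
threshold can be applied post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .optimize import FitConfig, fit

__all__ = ["ProfileCurve", "profile_parameter", "classify_identifiability",
           "profile_interval", "CHI2_95_HALF"]

#: chi-squared(1 dof) 95% quantile divided by two, on the -ln L scale.
CHI2_95_HALF = 1.9207


@dataclass
class ProfileCurve:
    """Minimized objective along a grid of fixed values of one parameter."""

    parameter: str
    grid: np.ndarray                 # ascending fixed values
    values: np.ndarray               # minimized objective per grid value
    argmins: List[Dict[str, float]]  # re-optimized remaining parameters
    mle_value: float                 # parameter value at the global MLE
    mle_objective: float             # global minimum objective
    fquant_at_mle: float = 0.0
    n_quant: int = 0

    def nll_scale_factor(self) -> float:
        """Factor converting objective differences to -ln L differences.

        With the plug-in variance sigma_hat^2 = Fquant(theta_hat)/n the
        Gaussian part of -ln L changes by Delta F / (2 sigma_hat^2); when no
        quantitative data are present the objective is used as-is.
        """
        if self.n_quant > 0 and self.fquant_at_mle > 0:
            sigma2 = self.fquant_at_mle / self.n_quant
            return 1.0 / (2.0 * sigma2)
        return 1.0


def profile_parameter(
    make_objective: Callable[[str, float], Callable[[np.ndarray], float]],
    name: str,
    bounds: Dict[str, Tuple[float, float]],
    mle: Dict[str, float],
    mle_objective: float,
    grid: Optional[Sequence[float]] = None,
    n_grid: int = 20,
    config: Optional[FitConfig] = None,
    fquant_at_mle: float = 0.0,
    n_quant: int = 0,
) -> ProfileCurve:
    """Profile one adjustable parameter.

    ``make_objective(name, value)`` must return the reduced objective over
    the remaining parameters (ordered as ``[n for n in bounds if n != name]``)
    with ``name`` held at ``value``.  ``mle`` is the full MLE assignment used
    for warm starts; the sweep proceeds outward from the grid point nearest
    the MLE, warm-starting each optimization from its neighbor's optimum.

    The default grid is 20 log-spaced points spanning the parameter's bounds.
    """
    if name not in bounds:
        raise KeyError(f"{name!r} is not an adjustable parameter")
    lo, hi = bounds[name]
    if grid is None:
        if lo > 0:
            grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
        else:
            grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(sorted(map(float, grid)))
    if grid.size == 0:
        raise ValueError("empty profile grid")
    reduced_names = [n for n in bounds if n != name]
    reduced_bounds = {n: bounds[n] for n in reduced_names}
    config = config or FitConfig(popsize=10, generations=30)

    values = np.empty(grid.size)
    argmins: List[Optional[Dict[str, float]]] = [None] * grid.size
    start = int(np.argmin(np.abs(grid - mle[name])))
    order: List[int] = [start]
    for off in range(1, grid.size):
        if start + off < grid.size:
            order.append(start + off)
        if start - off >= 0:
            order.append(start - off)

    warm: Dict[int, np.ndarray] = {}
    mle_reduced = np.array([mle[n] for n in reduced_names])
    for idx in order:
        if reduced_names:
            neighbor = idx - 1 if idx > start else idx + 1
            x0 = warm.get(neighbor, mle_reduced)
            res = fit(
                make_objective(name, float(grid[idx])),
                reduced_bounds,
                FitConfig(
                    popsize=config.popsize,
                    generations=config.generations,
                    mutation=config.mutation,
                    crossover=config.crossover,
                    seed=config.seed + idx,
                    target_objective=config.target_objective,
                ),
                x0=x0,
            )
            warm[idx] = res.x
            values[idx] = res.fun
            argmins[idx] = dict(zip(reduced_names, map(float, res.x)))
        else:
            # nothing left to optimize: evaluate the objective directly
            obj = make_objective(name, float(grid[idx]))
            values[idx] = obj(np.empty(0))
            argmins[idx] = {}
    return ProfileCurve(
        parameter=name,
        grid=grid,
        values=values,
        argmins=[a if a is not None else {} for a in argmins],
        mle_value=float(mle[name]),
        mle_objective=float(mle_objective),
        fquant_at_mle=fquant_at_mle,
        n_quant=n_quant,
    )


@dataclass
class IdentifiabilityVerdict:
    identifiable: bool
    ci_low: float
    ci_high: float
    threshold: float            # on the objective scale
    inside: np.ndarray          # boolean mask over the grid


def profile_interval(
    curve: ProfileCurve, delta: float = CHI2_95_HALF
) -> Tuple[float, float]:
    """Sub-threshold interval with linear interpolation between grid points.

    Finer-grained than the grid-based interval of
    :func:`classify_identifiability`; useful for comparing interval widths
    between parameters.  Log-spaced grids are interpolated in log space.
    """
    g = curve.grid
    logspace = bool(np.all(g > 0))
    x = np.log10(g) if logspace else g
    f = curve.values
    thr = float(np.min(f)) + delta / curve.nll_scale_factor()
    inside = f <= thr
    i_lo = int(np.argmax(inside))
    i_hi = len(f) - 1 - int(np.argmax(inside[::-1]))
    lo = x[i_lo]
    if i_lo > 0 and f[i_lo - 1] > thr:
        lo = np.interp(thr, [f[i_lo], f[i_lo - 1]], [x[i_lo], x[i_lo - 1]])
    hi = x[i_hi]
    if i_hi < len(f) - 1 and f[i_hi + 1] > thr:
        hi = np.interp(thr, [f[i_hi], f[i_hi + 1]], [x[i_hi], x[i_hi + 1]])
    if logspace:
        return float(10.0 ** lo), float(10.0 ** hi)
    return float(lo), float(hi)


def classify_identifiability(
    curve: ProfileCurve, delta: float = CHI2_95_HALF
) -> IdentifiabilityVerdict:
    """Practical-identifiability verdict and profile confidence interval.

    ``delta`` is the allowed increase on the -ln L scale (default the 95%
    chi-squared threshold).  The parameter is identifiable iff the
    sub-threshold region is bounded away from both box bounds, i.e. the
    first and last grid points lie above the threshold.  Larger ``delta``
    never yields a smaller interval.
    """
    if curve.grid.size < 3:
        raise ValueError("need at least 3 grid points to classify")
    f_threshold = float(np.min(curve.values)) + delta / curve.nll_scale_factor()
    inside = curve.values <= f_threshold
    if not np.any(inside):
        # numerical guard: the minimum itself is always inside
        inside = curve.values <= np.min(curve.values)
    ci_low = float(curve.grid[inside][0])
    ci_high = float(curve.grid[inside][-1])
    identifiable = bool(not inside[0] and not inside[-1])
    return IdentifiabilityVerdict(
        identifiable=identifiable,
        ci_low=ci_low,
        ci_high=ci_high,
        threshold=f_threshold,
        inside=inside,
    )
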