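"""Independent numerical oracles used only by the test suite.

The fixed-step RK4 integrator below is deliberately separate from the
package's adaptive-solver path: it builds its own sparse stoichiometry
directly from the reaction list and steps the mass-action ODEs with a
classic fourth-order Runge-Kutta scheme at a constant dt.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from mekfit.network import ReactionNetwork, build_network, apply_variant
from mekfit.params import ParameterSet


@njit(cache=True)
def _rk4_kernel(x0, kf, i1, i2, s_ptr, s_spec, s_coef, dt, record_steps):
    ns = x0.shape[0]
    nr = kf.shape[0]
    x = x0.copy()
    out = np.empty((record_steps.shape[0], ns))
    rec = 0
    n_total = record_steps[-1]

    def rhs(x, dx):
        for i in range(ns):
            dx[i] = 0.0
        for j in range(nr):
            v = kf[j] * x[i1[j]]
            if i2[j] >= 0:
                v *= x[i2[j]]
            for q in range(s_ptr[j], s_ptr[j + 1]):
                dx[s_spec[q]] += s_coef[q] * v

    k1 = np.empty(ns)
    k2 = np.empty(ns)
    k3 = np.empty(ns)
    k4 = np.empty(ns)
    if record_steps[rec] == 0:
        out[rec] = x
        rec += 1
    for step in range(1, n_total + 1):
        rhs(x, k1)
        rhs(x + 0.5 * dt * k1, k2)
        rhs(x + 0.5 * dt * k2, k3)
        rhs(x + dt * k3, k4)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if rec < record_steps.shape[0] and step == record_steps[rec]:
            out[rec] = x
            rec += 1
    return out


def rk4_observables(
    variant: str, params: ParameterSet, times, dt: float = 1e-3
) -> dict:
    """Observable series from a fixed-step RK4 integration at step ``dt``.

    ``times`` must be integer multiples of ``dt``.
    """
    net: ReactionNetwork = build_network(variant)
    p = apply_variant(params, variant)
    nr = len(net.reactions)
    kf = np.empty(nr)
    i1 = np.empty(nr, dtype=np.int64)
    i2 = np.full(nr, -1, dtype=np.int64)
    ptr = [0]
    spec: list = []
    coef: list = []
    for j, r in enumerate(net.reactions):
        kf[j] = p[r.rate] * r.factor
        i1[j] = net.index[r.reactants[0]]
        if len(r.reactants) == 2:
            i2[j] = net.index[r.reactants[1]]
        change: dict = {}
        for sp in r.reactants:
            change[net.index[sp]] = change.get(net.index[sp], 0.0) - 1.0
        for sp in r.products:
            change[net.index[sp]] = change.get(net.index[sp], 0.0) + 1.0
        for k, v in sorted(change.items()):
            if v != 0.0:
                spec.append(k)
                coef.append(v)
        ptr.append(len(spec))
    times = sorted(float(t) for t in times)
    record_steps = np.array([int(round(t / dt)) for t in times], dtype=np.int64)
    for t, s in zip(times, record_steps):
        if abs(s * dt - t) > 1e-9:
            raise ValueError(f"time {t} is not a multiple of dt={dt}")
    states = _rk4_kernel(
        net.initial_state(p), kf, i1, i2,
        np.array(ptr, dtype=np.int64), np.array(spec, dtype=np.int64),
        np.array(coef), float(dt), record_steps,
    )
    w = net.observable_matrix()
    obs = states @ w.T  # (times, observables)
    from mekfit.network import OBSERVABLE_NAMES

    return {
        "times": np.array(times),
        **{name: obs[:, i] for i, name in enumerate(OBSERVABLE_NAMES)},
    }
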