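"""Study-shaped synthetic datasets from known ground-truth parameters.

The generator emulates the shape of the real calibration problem: 18
relative-intensity wild-type measurements (three readouts, six time points,
values in (0, 1]) and 90 binary comparison statements spanning the five
cell-line variants at 300/1800/3600 s.

Quantitative data follow the Gaussian noise model: the wild-type model is
simulated at the ground truth, outputs are scaled into arbitrary units,
i.i.d. N(0, sigma*^2) noise is added, and each observable series is divided
by its noise-free maximum and clipped into (0, 1] (floor 1e-6).  Because of
that max-normalization the scaling factors that reproduce the data exactly
are the raw truth scales divided by the per-observable normalization
constant; the bundle records these *effective* scales as the fitting ground
truth, and derives scale boxes around them (the published scale boxes
encode the original study's data normalization, not the generator's).

Qualitative data follow the Bernoulli-logistic noise model: deterministic
mode sets each observation to the Heaviside outcome H(delta(theta*)) so the
truth satisfies every statement; stochastic mode draws
z ~ Bernoulli(1 / (1 + exp(-delta/s*))).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import QuantDataset, QuantRecord, write_exp_file
from .network import VARIANTS
from .objective import SCALED_OBSERVABLES, logistic_prob
from .params import (
    OPTIMIZATION_BOUNDS,
    BAYES_BOUNDS,
    ParameterSet,
    REFERENCE_PARAMS,
)
from .properties import (
    ComparisonProperty,
    Condition,
    PropertySet,
    write_prop_file,
)
from .simulate import simulate_variant

__all__ = [
    "GroundTruth",
    "SyntheticBundle",
    "DEFAULT_QUANT_TIMES",
    "QUAL_TIMES",
    "default_templates",
    "gen_quant",
    "gen_qual",
    "draw_outcome",
    "make_bundle",
]

#: Measurement times (s) spanning the rise, peak and relaxation of the
#: wild-type phospho-readouts.
DEFAULT_QUANT_TIMES: Tuple[float, ...] = (60.0, 300.0, 600.0, 1200.0, 1800.0, 3600.0)

#: Times (s) at which qualitative comparisons are made.
QUAL_TIMES: Tuple[float, ...] = (300.0, 1800.0, 3600.0)

#: Observables used by the default qualitative templates.
QUAL_OBSERVABLES: Tuple[str, ...] = ("MEK_pRDS", "pERK1_2_wt")

# the ground-truth scaling factors: mid-box for ScalepEGFR (the published
# best fit lies outside the published box), published best fit otherwise
_TRUTH_SCALES = {"ScalepEGFR": 4.5e-5, "ScalepERK": 3.2e-6, "ScalepSOS1": 1.1e-4}


@dataclass
class GroundTruth:
    """Everything needed to regenerate and score a synthetic dataset."""

    params: ParameterSet          # raw truth (model rates + raw scales)
    sigma: float                  # quantitative noise SD, AU
    prop_scale: float             # logistic scale s* shared by all statements
    seed: int
    norm_constants: Dict[str, float] = field(default_factory=dict)

    @property
    def params_effective(self) -> ParameterSet:
        """Truth with max-normalization folded into the scaling factors."""
        eff = {}
        for obs, scale_name in SCALED_OBSERVABLES.items():
            m = self.norm_constants.get(obs)
            if m:
                eff[scale_name] = self.params[scale_name] / m
        return self.params.replace(**eff)


@dataclass
class SyntheticBundle:
    """A full study-shaped dataset plus its ground-truth record."""

    truth: GroundTruth
    data: QuantDataset
    props: PropertySet
    mode: str

    def optimization_bounds(self) -> Dict[str, Tuple[float, float]]:
        """Published rate boxes; scale boxes centered on the effective truth."""
        bounds = dict(OPTIMIZATION_BOUNDS)
        eff = self.truth.params_effective
        for scale_name in _TRUTH_SCALES:
            v = eff[scale_name]
            bounds[scale_name] = (v / 1.8, v * 1.8)
        return bounds

    def bayes_bounds(self) -> Dict[str, Tuple[float, float]]:
        """Published d3/u3/sigma boxes; scale boxes as in optimization."""
        bounds = dict(BAYES_BOUNDS)
        eff = self.truth.params_effective
        for scale_name in _TRUTH_SCALES:
            v = eff[scale_name]
            bounds[scale_name] = (v / 1.8, v * 1.8)
        return bounds

    def manifest(self) -> Dict[str, object]:
        return {
            "seed": self.truth.seed,
            "mode": self.mode,
            "sigma": self.truth.sigma,
            "prop_scale": self.truth.prop_scale,
            "params": self.truth.params.as_dict(),
            "norm_constants": self.truth.norm_constants,
            "n_quant": self.data.n,
            "n_props": len(self.props),
        }

    def write(self, outdir) -> Dict[str, str]:
        """Write EXP, PROP and manifest files; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "exp": str(outdir / "WT.exp"),
            "prop": str(outdir / "synthetic.prop"),
            "manifest": str(outdir / "manifest.json"),
            "truth_params": str(outdir / "truth_params.json"),
        }
        write_exp_file(paths["exp"], self.data)
        write_prop_file(paths["prop"], self.props)
        with open(paths["manifest"], "wt", encoding="utf-8") as fh:
            json.dump(self.manifest(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(paths["truth_params"], "wt", encoding="utf-8") as fh:
            json.dump(self.truth.params_effective.as_dict(), fh, indent=1,
                      sort_keys=True)
            fh.write("\n")
        return paths


def gen_quant(
    truth: GroundTruth,
    times: Sequence[float] = DEFAULT_QUANT_TIMES,
    observables: Sequence[str] = tuple(SCALED_OBSERVABLES),
    rng: Optional[np.random.Generator] = None,
    missing: Sequence[Tuple[str, float]] = (),
    rtol: float = 1e-8,
    atol: float = 1e-2,
) -> QuantDataset:
    """Noisy, max-normalized wild-type measurements.

    Updates ``truth.norm_constants`` with the per-observable normalization
    (the maximum of the noisy AU series).  ``missing`` lists
    (observable, time) cells written as ``nan``.
    """
    rng = rng or np.random.default_rng(truth.seed)
    times = sorted(map(float, times))
    traj = simulate_variant(truth.params, "WT", times, rtol=rtol, atol=atol)
    records: List[QuantRecord] = []
    missing = set(missing)
    for obs in observables:
        scale = truth.params[SCALED_OBSERVABLES[obs]]
        series = traj.observables[obs] * scale
        noisy = series + truth.sigma * rng.standard_normal(len(times))
        # normalization constant = noise-free series maximum, so noise on
        # the relative scale is exactly N(0, (sigma/m)^2) before clipping
        m = float(np.max(series))
        if m <= 0:
            raise ValueError(
                f"non-positive maximum for observable {obs}; cannot normalize"
            )
        truth.norm_constants[obs] = m
        y = np.clip(noisy / m, 1e-6, 1.0)
        for t, v in zip(times, y):
            val = None if (obs, t) in missing else float(v)
            records.append(QuantRecord("WT", obs, t, val))
    return QuantDataset(records, provenance=f"synthetic(seed={truth.seed})")


def default_templates(
    variants: Sequence[str] = VARIANTS,
    observables: Sequence[str] = QUAL_OBSERVABLES,
    times: Sequence[float] = QUAL_TIMES,
) -> List[Tuple[Condition, Condition]]:
    """90 comparison templates: 60 cross-variant (pairs of variants, same
    observable and time) plus 30 within-variant (pairs of times)."""
    out: List[Tuple[Condition, Condition]] = []
    for obs in observables:
        for t in times:
            for i, va in enumerate(variants):
                for vb in variants[i + 1:]:
                    out.append(
                        (Condition(va, obs, t), Condition(vb, obs, t))
                    )
    time_pairs = [(times[0], times[1]), (times[1], times[2]),
                  (times[0], times[2])]
    for obs in observables:
        for v in variants:
            for ta, tb in time_pairs:
                out.append((Condition(v, obs, ta), Condition(v, obs, tb)))
    return out


def draw_outcome(
    delta: float, scale: float, mode: str, rng: np.random.Generator
) -> int:
    """One binary observation from a model-output difference.

    Deterministic mode returns the Heaviside outcome H(delta) (with
    H(0) = 1); stochastic mode draws z ~ Bernoulli(1/(1+exp(-delta/scale))).
    """
    if mode == "deterministic":
        return 1 if delta >= 0 else 0
    if mode == "stochastic":
        return int(rng.uniform() < logistic_prob(delta, scale))
    raise ValueError(f"unknown mode {mode!r}")


def gen_qual(
    truth: GroundTruth,
    templates: Optional[Sequence[Tuple[Condition, Condition]]] = None,
    mode: str = "deterministic",
    rng: Optional[np.random.Generator] = None,
    rtol: float = 1e-8,
    atol: float = 1e-2,
) -> PropertySet:
    """Binary comparison statements consistent with (or drawn around) truth.

    Deterministic mode asserts the true ordering (z = H(delta), relation
    '>' for delta >= 0 else '<'); stochastic mode draws each z from the
    Bernoulli-logistic model at scale ``truth.prop_scale``.
    """
    templates = list(templates) if templates is not None else default_templates()
    rng = rng or np.random.default_rng(truth.seed + 1)
    req: Dict[str, set] = {}
    for a, b in templates:
        req.setdefault(a.variant, set()).add(a.time)
        req.setdefault(b.variant, set()).add(b.time)
    trajs = {
        v: simulate_variant(truth.params, v, sorted(ts), rtol=rtol, atol=atol)
        for v, ts in req.items()
    }
    props: List[ComparisonProperty] = []
    for a, b in templates:
        delta = trajs[a.variant].at(a.observable, a.time) - trajs[
            b.variant
        ].at(b.observable, b.time)
        z = draw_outcome(delta, truth.prop_scale, mode, rng)
        relation = ">" if z == 1 else "<"
        props.append(
            ComparisonProperty(a, b, relation, weight=1.0 / truth.prop_scale)
        )
    return PropertySet(props, provenance=f"synthetic(seed={truth.seed},{mode})")


def make_bundle(
    seed: int,
    mode: str = "study",
    params: Optional[ParameterSet] = None,
    sigma: Optional[float] = None,
    prop_scale: float = 1.0,
) -> SyntheticBundle:
    """Full study-shaped dataset (18 measurements, 90 statements).

    Modes: ``deterministic`` (noise-free data, truth-consistent statements;
    the truth is an exact global minimizer of the hybrid objective),
    ``study`` (sigma* = 1 AU Gaussian noise, truth-consistent statements),
    ``stochastic`` (sigma* = 1 plus Bernoulli-drawn statements).
    """
    if mode not in ("deterministic", "study", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    base = params or REFERENCE_PARAMS.replace(**_TRUTH_SCALES)
    if sigma is None:
        sigma = 0.0 if mode == "deterministic" else 1.0
    truth = GroundTruth(
        params=base, sigma=float(sigma), prop_scale=float(prop_scale),
        seed=int(seed),
    )
    rng = np.random.default_rng(seed)
    data = gen_quant(truth, rng=rng)
    qual_mode = "stochastic" if mode == "stochastic" else "deterministic"
    props = gen_qual(truth, mode=qual_mode, rng=rng)
    return SyntheticBundle(truth=truth, data=data, props=props, mode=mode)
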