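"""Run configuration, stage dispatch, and result serialization.

A run configuration is a flat key-value text file (one `key value...` pair
per line, '#' comments, repeated keys for lists), in the spirit of the
plain-text job files used by fitting tools in this field::

    stage fit
    seed 7
    output out/fit
    exp WT data/WT.exp
    prop data/synthetic.prop
    adjustable d3 8.0e-5 3.0e-2
    adjustable u3 8.0e-5 3.0e-2
    popsize 12
    generations 40

Stages: ``synth`` (generate a synthetic bundle), ``check`` (evaluate the
qualitative statements and the objective at a fixed parameter point),
``fit`` (differential-evolution MLE), ``profile`` (profile likelihood for
one parameter), ``sample`` (Bayesian MCMC).  Every run writes a manifest
(config hash, seed, package version) sufficient to reproduce it exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import __version__
from .data import QuantDataset, read_exp_file
from .mcmc import McmcConfig, sample_posterior
from .objective import HybridObjective, LogPosterior, total_objective
from .optimize import FitConfig, fit
from .params import (
    ADJUSTABLE_NAMES,
    BEST_FIT_PARAMS,
    REFERENCE_PARAMS,
    ParameterSet,
)
from .profile import classify_identifiability, profile_parameter
from .properties import PropertySet, count_satisfied, read_prop_file
from .simulate import simulate_variant
from .synth import make_bundle
from .network import VARIANTS

__all__ = ["RunConfig", "ConfigError", "load_config", "run"]

log = logging.getLogger(__name__)

STAGES = ("synth", "check", "fit", "profile", "sample", "simulate")

_INT_KEYS = {
    "popsize", "generations", "profile_points", "burn_in", "adaptation",
    "production", "chains", "n_runs", "max_draws",
}
_FLOAT_KEYS = {"mutation", "crossover", "rtol", "atol", "target_objective",
               "prop_scale", "sigma"}
_STR_KEYS = {"profile_parameter", "mode", "base", "params_file"}


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    stage: str
    seed: int = 0
    output: str = "out"
    variants: List[str] = field(default_factory=list)
    exp_files: Dict[str, str] = field(default_factory=dict)
    prop_files: List[str] = field(default_factory=list)
    adjustable: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    settings: Dict[str, object] = field(default_factory=dict)
    source_text: str = ""

    def config_hash(self) -> str:
        return hashlib.sha256(self.source_text.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Parse and validate a run-configuration file.

    Unknown keys are errors, not warnings; referenced files must exist; in
    the study-shaped layout only the WT variant may carry an EXP file
    (quantitative time series exist only for unperturbed signaling).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    cfg = RunConfig(stage="", source_text=text)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, *rest = line.split()
        where = f"{path}:{lineno}"
        if key == "stage":
            cfg.stage = _one(rest, where)
        elif key == "seed":
            cfg.seed = int(_one(rest, where))
        elif key == "output":
            cfg.output = _one(rest, where)
        elif key == "variant":
            v = _one(rest, where)
            if v not in VARIANTS:
                raise ConfigError(f"{where}: unknown variant {v!r}")
            cfg.variants.append(v)
        elif key == "exp":
            if len(rest) != 2:
                raise ConfigError(f"{where}: expected 'exp <variant> <path>'")
            v, p = rest
            if v != "WT":
                raise ConfigError(
                    f"{where}: only the WT variant may carry an EXP file"
                )
            cfg.exp_files[v] = p
        elif key == "prop":
            cfg.prop_files.append(_one(rest, where))
        elif key == "adjustable":
            if len(rest) != 3:
                raise ConfigError(
                    f"{where}: expected 'adjustable <name> <low> <high>'"
                )
            name, lo_s, hi_s = rest
            if name not in ADJUSTABLE_NAMES + ("sigma",):
                raise ConfigError(f"{where}: unknown parameter {name!r}")
            lo, hi = float(lo_s), float(hi_s)
            if lo >= hi:
                raise ConfigError(
                    f"{where}: lower bound >= upper bound for {name!r}"
                )
            cfg.adjustable[name] = (lo, hi)
        elif key in _INT_KEYS:
            cfg.settings[key] = int(_one(rest, where))
        elif key in _FLOAT_KEYS:
            cfg.settings[key] = float(_one(rest, where))
        elif key in _STR_KEYS:
            cfg.settings[key] = _one(rest, where)
        else:
            raise ConfigError(f"{where}: unknown key {key!r}")
    if cfg.stage not in STAGES:
        raise ConfigError(f"{path}: missing or unknown stage {cfg.stage!r}")
    base = path.parent
    for v, p in cfg.exp_files.items():
        if not (base / p).exists() and not Path(p).exists():
            raise ConfigError(f"EXP file not found: {p}")
    for p in cfg.prop_files:
        if not (base / p).exists() and not Path(p).exists():
            raise ConfigError(f"PROP file not found: {p}")
    cfg.settings["_basedir"] = str(base)
    return cfg


def _one(rest: List[str], where: str) -> str:
    if len(rest) != 1:
        raise ConfigError(f"{where}: expected exactly one value")
    return rest[0]


def _resolve(cfg: RunConfig, p: str) -> Path:
    cand = Path(cfg.settings.get("_basedir", ".")) / p
    return cand if cand.exists() else Path(p)


def _load_inputs(cfg: RunConfig) -> Tuple[Optional[QuantDataset], Optional[PropertySet]]:
    data = None
    if "WT" in cfg.exp_files:
        data = read_exp_file(_resolve(cfg, cfg.exp_files["WT"]), variant="WT")
    props = None
    if cfg.prop_files:
        all_props = []
        for p in cfg.prop_files:
            all_props.extend(read_prop_file(_resolve(cfg, p)).properties)
        props = PropertySet(all_props, provenance=";".join(cfg.prop_files))
    return data, props


def _base_params(cfg: RunConfig) -> ParameterSet:
    name = cfg.settings.get("base", "reference")
    if name == "reference":
        base = REFERENCE_PARAMS
    elif name == "best_fit":
        base = BEST_FIT_PARAMS
    else:
        raise ConfigError(f"unknown base parameter set {name!r}")
    pf = cfg.settings.get("params_file")
    if pf:
        p = _resolve(cfg, pf)
        if not p.exists():
            raise ConfigError(f"params file not found: {pf}")
        overrides = json.loads(p.read_text())
        base = base.replace(**overrides)
    return base


def run(config: RunConfig, seed: Optional[int] = None) -> Dict[str, object]:
    """Execute a configured stage; writes artifacts under ``config.output``.

    Returns a summary dict (also written as JSON).  ``seed`` overrides the
    configured seed.
    """
    t_start = time.time()
    seed = config.seed if seed is None else seed
    outdir = Path(config.output)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = config.stage
    s = config.settings
    summary: Dict[str, object] = {"stage": stage, "seed": seed}

    if stage == "synth":
        bundle = make_bundle(
            seed,
            mode=s.get("mode", "study"),
            sigma=s.get("sigma"),
            prop_scale=s.get("prop_scale", 1.0),
        )
        paths = bundle.write(outdir)
        summary.update(paths)
        summary["n_quant"] = bundle.data.n
        summary["n_props"] = len(bundle.props)

    elif stage == "simulate":
        base = _base_params(config)
        times = sorted({0.0, 300.0, 1800.0, 3600.0})
        rows = []
        for v in (config.variants or list(VARIANTS)):
            traj = simulate_variant(base, v, times)
            for name, series in traj.observables.items():
                for t, val in zip(times, series):
                    rows.append((v, name, t, val))
        import pandas as pd

        frame = pd.DataFrame(rows, columns=["variant", "observable", "time", "value"])
        frame.to_csv(outdir / "observables.csv", index=False)
        summary["n_rows"] = len(frame)

    elif stage == "check":
        data, props = _load_inputs(config)
        base = _base_params(config)
        bd = total_objective(base, data, props, keep_trajectories=True)
        summary.update(
            fquant=bd.fquant, fqual=bd.fqual, total=bd.total, n_quant=bd.n
        )
        if props is not None:
            n_sat, report = count_satisfied(props, bd.trajectories)
            summary["satisfied"] = n_sat
            summary["n_props"] = len(props)
            with open(outdir / "check_report.csv", "wt") as fh:
                fh.write("statement\tdelta\tsatisfied\n")
                for r in report:
                    src = r["property"].source or "?"
                    fh.write(f"{src}\t{r['delta']:.10g}\t{int(r['satisfied'])}\n")

    elif stage == "fit":
        data, props = _load_inputs(config)
        if not config.adjustable:
            raise ConfigError("fit stage needs adjustable parameters")
        base = _base_params(config)
        obj = HybridObjective(
            data, props, list(config.adjustable), base=base,
            rtol=s.get("rtol", 1e-6), atol=s.get("atol", 1e-1),
        )
        fc = FitConfig(
            popsize=s.get("popsize", 50),
            generations=s.get("generations", 500),
            mutation=s.get("mutation", 0.85),
            crossover=s.get("crossover", 0.7),
            seed=seed,
            target_objective=s.get("target_objective"),
        )
        res = fit(obj, config.adjustable, fc)
        summary.update(
            best_objective=res.fun,
            n_evaluations=obj.n_evaluations,
            n_failures=obj.n_failures,
            estimate=res.as_dict(),
        )
        with open(outdir / "fit_result.csv", "wt") as fh:
            fh.write("parameter,estimate\n")
            for k, v in res.as_dict().items():
                fh.write(f"{k},{v:.10g}\n")
        np.savetxt(
            outdir / "fit_history.csv",
            np.asarray(res.history),
            header="best_objective_per_generation", comments="# ",
        )

    elif stage == "profile":
        data, props = _load_inputs(config)
        name = s.get("profile_parameter")
        if not name or name not in config.adjustable:
            raise ConfigError(
                "profile stage needs 'profile_parameter' among the adjustables"
            )
        base = _base_params(config)
        free = list(config.adjustable)
        fc = FitConfig(
            popsize=s.get("popsize", 10),
            generations=s.get("generations", 30),
            seed=seed,
        )
        full = HybridObjective(data, props, free, base=base)
        mle_res = fit(full, config.adjustable, fc)
        bd = full.breakdown(mle_res.x)

        def make_objective(fixed_name, value):
            reduced = [n for n in free if n != fixed_name]
            return HybridObjective(
                data, props, reduced, base=base.replace(**{fixed_name: value})
            )

        curve = profile_parameter(
            make_objective, name, config.adjustable,
            mle=mle_res.as_dict(), mle_objective=mle_res.fun,
            n_grid=s.get("profile_points", 20), config=fc,
            fquant_at_mle=bd.fquant, n_quant=bd.n,
        )
        verdict = classify_identifiability(curve)
        summary.update(
            parameter=name,
            identifiable=verdict.identifiable,
            ci=[verdict.ci_low, verdict.ci_high],
            mle=curve.mle_value,
        )
        with open(outdir / f"profile_{name}.csv", "wt") as fh:
            fh.write(f"{name},objective\n")
            for g, v in zip(curve.grid, curve.values):
                fh.write(f"{g:.10g},{v:.10g}\n")

    elif stage == "sample":
        data, props = _load_inputs(config)
        if not config.adjustable:
            raise ConfigError("sample stage needs adjustable parameters")
        base = _base_params(config)
        lp = LogPosterior(
            data, props, config.adjustable, base=base,
            rtol=s.get("rtol", 1e-6), atol=s.get("atol", 1e-1),
        )
        mc = McmcConfig(
            burn_in=s.get("burn_in", 25_000),
            adaptation=s.get("adaptation", 25_000),
            production=s.get("production", 250_000),
            chains=s.get("chains", 5),
            seed=seed,
        )
        sample = sample_posterior(lp, mc)
        diag = sample.diagnostics()
        summary.update(
            diagnostics=diag,
            acceptance=sample.acceptance,
            n_evaluations=lp.n_evaluations,
        )
        for k, (chain, lptr) in enumerate(zip(sample.chains_theta,
                                              sample.log_posterior)):
            with open(outdir / f"chain_{k}.csv", "wt") as fh:
                fh.write("iteration," + ",".join(sample.names)
                         + ",log_posterior\n")
                for i, (row, l) in enumerate(zip(chain, lptr)):
                    cells = ",".join(f"{v:.10g}" for v in row)
                    fh.write(f"{i},{cells},{l:.10g}\n")
        with open(outdir / "diagnostics.json", "wt") as fh:
            json.dump(diag, fh, indent=1, sort_keys=True)
            fh.write("\n")

    else:  # pragma: no cover - guarded by load_config
        raise ConfigError(f"unknown stage {stage!r}")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "stage": stage,
        "version": __version__,
    }
    with open(outdir / "run_manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(outdir / "summary.json", "wt") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
    log.info("stage %s finished in %.1f s", stage, time.time() - t_start)
    return summary
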