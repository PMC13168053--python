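"""Shared fixtures: synthetic bundles and the replicated recovery study.

The replicated study (10 seeded replicates of MLE fitting plus scaled-down
Bayesian sampling on study-shaped synthetic data) is expensive, so it runs
once per session and is shared by the recovery and coverage tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import pytest

from mekfit.mcmc import McmcConfig, PosteriorSample, sample_posterior
from mekfit.objective import HybridObjective, LogPosterior
from mekfit.optimize import FitConfig, fit
from mekfit.synth import SyntheticBundle, make_bundle

#: truth values of the free parameters in all recovery studies
TRUE_D3 = 1.0e-3
TRUE_U3 = 1.0e-3

#: rate bounds used when only d3 and u3 are free (published optimization box)
RECOVERY_BOUNDS = {"d3": (8.0e-5, 3.0e-2), "u3": (8.0e-5, 3.0e-2)}

#: prior boxes for the scaled-down Bayesian recovery (published boxes for the
#: two rate constants and sigma; scales pinned at truth for tractability)
RECOVERY_PRIOR = {"d3": (1e-5, 1e-1), "u3": (1e-5, 1e-1), "sigma": (0.1, 10.0)}


@dataclass
class RecoveryReplicate:
    seed: int
    bundle: SyntheticBundle
    mle: Dict[str, float]
    mle_objective: float
    sample: PosteriorSample


@pytest.fixture(scope="session")
def det_bundle() -> SyntheticBundle:
    """Noise-free bundle whose truth is an exact global minimizer."""
    return make_bundle(11, mode="deterministic")


@pytest.fixture(scope="session")
def study_bundle() -> SyntheticBundle:
    """Study-shaped bundle with sigma* = 1 AU Gaussian noise."""
    return make_bundle(7, mode="study")


def run_recovery_replicate(seed: int) -> RecoveryReplicate:
    """One seeded replicate: generate data, fit (d3, u3), then sample.

    Chains are initialized at the MLE; chain lengths are scaled down to
    desk size (200 burn-in / 300 adaptation / 800 production draws).
    """
    bundle = make_bundle(100 + seed, mode="study")
    truth = bundle.truth.params_effective
    obj = HybridObjective(
        bundle.data, bundle.props, ["d3", "u3"], base=truth,
        rtol=1e-5, atol=1.0,
    )
    res = fit(obj, RECOVERY_BOUNDS, FitConfig(popsize=8, generations=20,
                                              seed=seed))
    lp = LogPosterior(
        bundle.data, bundle.props, RECOVERY_PRIOR, base=truth,
        rtol=1e-5, atol=1.0,
    )
    mc = McmcConfig(
        burn_in=200, adaptation=300, production=800, chains=1, seed=seed,
        adapt_interval=50,
    )
    sample = sample_posterior(
        lp, mc, init_theta=[res.as_dict()["d3"], res.as_dict()["u3"], 1.0]
    )
    return RecoveryReplicate(
        seed=seed, bundle=bundle, mle=res.as_dict(),
        mle_objective=res.fun, sample=sample,
    )


@pytest.fixture(scope="session")
def recovery_replicates() -> List[RecoveryReplicate]:
    return [run_recovery_replicate(k) for k in range(10)]
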