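"""Sampler mechanics, posterior predictive bands, and per-constraint
satisfaction fractions."""

import numpy as np
import pytest

from mekfit.mcmc import (
    McmcConfig,
    PosteriorSample,
    constraint_satisfaction_fraction,
    posterior_predictive,
    run_chain,
)

GAUSS_BOUNDS = np.array([[-10.0, 10.0], [-10.0, 10.0]])


def gauss_lp(x):
    return -0.5 * float(np.dot(x, x))


class TestRunChain:
    def test_identical_seeds_give_identical_chains(self):
        cfg = McmcConfig(burn_in=100, adaptation=100, production=300, chains=1)
        r1 = run_chain(gauss_lp, GAUSS_BOUNDS, cfg, seed=42)
        r2 = run_chain(gauss_lp, GAUSS_BOUNDS, cfg, seed=42)
        np.testing.assert_array_equal(r1["samples"], r2["samples"])
        np.testing.assert_array_equal(r1["log_posterior"], r2["log_posterior"])

    def test_vanishing_proposal_scale_freezes_the_chain(self):
        cfg = McmcConfig(burn_in=0, adaptation=0, production=200,
                         initial_scale=1e-12)
        res = run_chain(gauss_lp, GAUSS_BOUNDS, cfg, seed=0)
        s = res["samples"]
        assert res["acceptance"]["production"] > 0.99
        assert np.ptp(s, axis=0).max() < 1e-9

    def test_draws_respect_the_box(self):
        bounds = np.array([[-0.5, 0.5], [-0.5, 0.5]])

        def lp(x):
            if np.any(np.abs(x) > 0.5):
                return -np.inf
            return 0.0

        cfg = McmcConfig(burn_in=100, adaptation=100, production=500)
        res = run_chain(lp, bounds, cfg, seed=1)
        assert np.all(np.abs(res["samples"]) <= 0.5)

    def test_explicit_init_point(self):
        cfg = McmcConfig(burn_in=0, adaptation=0, production=1,
                         initial_scale=1e-12)
        res = run_chain(gauss_lp, GAUSS_BOUNDS, cfg, seed=0,
                        init=np.array([1.0, -1.0]))
        np.testing.assert_allclose(res["samples"][0], [1.0, -1.0], atol=1e-6)
        with pytest.raises(ValueError):
            run_chain(lambda x: -np.inf, GAUSS_BOUNDS, cfg, seed=0,
                      init=np.array([0.0, 0.0]))

    def test_impossible_initialization_raises(self):
        with pytest.raises(RuntimeError):
            run_chain(lambda x: -np.inf, GAUSS_BOUNDS,
                      McmcConfig(burn_in=1, adaptation=1, production=1),
                      seed=0)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            McmcConfig(burn_in=-1)
        with pytest.raises(ValueError):
            McmcConfig(chains=0)


def tight_sample(bundle, n=12, rel_jitter=1e-3, names=("d3", "u3")):
    """A small posterior sample concentrated at the bundle truth."""
    truth = bundle.truth.params_effective
    rng = np.random.default_rng(0)
    center = np.array([truth[n_] for n_ in names])
    draws = center * (1.0 + rel_jitter * rng.standard_normal((n, len(names))))
    return PosteriorSample(
        names=list(names),
        chains=[np.log10(draws)],
        chains_theta=[draws],
        log_posterior=[np.zeros(n)],
        acceptance=[{"production": 0.3}],
        seed=0,
    )


class TestPosteriorPredictive:
    def test_identical_draws_collapse_bands_onto_median(self, det_bundle):
        sample = tight_sample(det_bundle, n=5, rel_jitter=0.0)
        bands = posterior_predictive(
            sample, det_bundle.truth.params_effective, ["WT"],
            ["pERK1_2_wt"], [300.0, 1800.0],
        )
        entry = bands["WT"]["pERK1_2_wt"]
        for lev in bands["levels"]:
            lo, hi = entry[lev]
            np.testing.assert_allclose(lo, entry["median"])
            np.testing.assert_allclose(hi, entry["median"])

    def test_bands_are_nested_and_contain_median(self, det_bundle):
        sample = tight_sample(det_bundle, n=10, rel_jitter=0.05)
        bands = posterior_predictive(
            sample, det_bundle.truth.params_effective, ["WT"],
            ["pERK1_2_wt", "pEGFR"], [300.0, 1800.0, 3600.0],
        )
        for obs in ("pERK1_2_wt", "pEGFR"):
            entry = bands["WT"][obs]
            levels = sorted(bands["levels"])
            for narrow, wide in zip(levels, levels[1:]):
                assert np.all(entry[wide][0] <= entry[narrow][0] + 1e-9)
                assert np.all(entry[narrow][1] <= entry[wide][1] + 1e-9)
                assert np.all(entry[narrow][0] - 1e-9 <= entry["median"])
                assert np.all(entry["median"] <= entry[narrow][1] + 1e-9)


class TestConstraintFractions:
    def test_truth_centered_sample_satisfies_deterministic_statements(
        self, det_bundle
    ):
        sample = tight_sample(det_bundle, n=8, rel_jitter=1e-3)
        fractions = constraint_satisfaction_fraction(
            sample, det_bundle.props, det_bundle.truth.params_effective,
            max_draws=8,
        )
        assert len(fractions) == 90
        assert all(f >= 0.9 for f in fractions)

    def test_complementary_pair_fractions_sum_to_one(self, det_bundle):
        """For tie-free draws, exactly one of {A < B, A >= B} holds."""
        from dataclasses import replace

        sample = tight_sample(det_bundle, n=4, rel_jitter=1e-3)
        p = det_bundle.props[0]
        negation = replace(p, relation="<" if p.z == 1 else ">=")
        f, f_neg = constraint_satisfaction_fraction(
            sample, [p, negation], det_bundle.truth.params_effective,
            max_draws=4,
        )
        assert f + f_neg == pytest.approx(1.0)

    def test_mirrored_statement_has_identical_fraction(self, det_bundle):
        sample = tight_sample(det_bundle, n=4, rel_jitter=1e-3)
        p = det_bundle.props[0]
        f, f_m = constraint_satisfaction_fraction(
            sample, [p, p.mirrored()], det_bundle.truth.params_effective,
            max_draws=4,
        )
        assert f == f_m
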