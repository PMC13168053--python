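"""Synthetic-data generator: study shapes, noise-model faithfulness, and
exact regeneration."""

import json

import numpy as np
import pytest
from scipy.special import expit

from mekfit.network import VARIANTS
from mekfit.objective import total_objective
from mekfit.params import OPTIMIZATION_BOUNDS, RATE_NAMES
from mekfit.properties import read_prop_file
from mekfit.synth import (
    GroundTruth,
    default_templates,
    draw_outcome,
    gen_quant,
    make_bundle,
)


class TestShapes:
    def test_study_shape(self, study_bundle):
        assert study_bundle.data.n == 18
        assert all(r.variant == "WT" for r in study_bundle.data)
        assert len(study_bundle.props) == 90
        variants_used = {
            c.variant for p in study_bundle.props
            for c in (p.left, p.right)
        }
        assert variants_used == set(VARIANTS)
        times_used = {
            c.time for p in study_bundle.props for c in (p.left, p.right)
        }
        assert times_used == {300.0, 1800.0, 3600.0}

    def test_default_templates_structure(self):
        t = default_templates()
        assert len(t) == 90
        cross = sum(1 for a, b in t if a.variant != b.variant)
        within = sum(1 for a, b in t if a.variant == b.variant)
        assert cross == 60 and within == 30
        for a, b in t:
            if a.variant == b.variant:
                assert a.time != b.time

    def test_truth_rates_inside_optimization_bounds(self, study_bundle):
        p = study_bundle.truth.params
        for name in RATE_NAMES:
            lo, hi = OPTIMIZATION_BOUNDS[name]
            assert lo <= p[name] <= hi, name


class TestQuantitativeNoise:
    def test_noise_free_data_equal_scaled_outputs_with_unit_max(self):
        bundle = make_bundle(5, mode="deterministic")
        values = np.array([r.value for r in bundle.data.non_missing()])
        assert values.max() == pytest.approx(1.0)
        assert np.all((values > 0) & (values <= 1.0))
        # the effective-scale truth reproduces the data exactly
        bd = total_objective(
            bundle.truth.params_effective, bundle.data, None, rtol=1e-8,
            atol=1e-2,
        )
        assert bd.fquant < 1e-9

    def test_empirical_noise_sd_matches_sigma_over_max(self):
        """Pooled SD of (y - noiseless) approximates sigma*/max away from
        the clipping boundary at 1."""
        sigma = 0.1
        base = make_bundle(6, mode="deterministic")
        noiseless = {
            (r.observable, r.time): r.value for r in base.data.non_missing()
        }
        sq, count = {}, {}
        for rep in range(300):
            truth = GroundTruth(
                params=base.truth.params, sigma=sigma, prop_scale=1.0,
                seed=rep,
            )
            ds = gen_quant(truth, rng=np.random.default_rng(1000 + rep))
            for r in ds.non_missing():
                ref = noiseless[(r.observable, r.time)]
                if ref > 0.9:  # top cells feel the clip at 1.0
                    continue
                key = r.observable
                sq[key] = sq.get(key, 0.0) + (r.value - ref) ** 2
                count[key] = count.get(key, 0) + 1
        for obs in sq:
            sd = np.sqrt(sq[obs] / count[obs])
            expected = sigma / base.truth.norm_constants[obs]
            assert sd == pytest.approx(expected, rel=0.05), obs

    def test_missing_value_injection(self):
        truth = GroundTruth(
            params=make_bundle(5, mode="deterministic").truth.params,
            sigma=0.0, prop_scale=1.0, seed=0,
        )
        ds = gen_quant(truth, missing=[("pEGFR", 60.0)])
        assert ds.n == 17
        assert len(ds) == 18


class TestQualitativeNoise:
    def test_deterministic_statements_have_zero_penalty_at_truth(
        self, det_bundle
    ):
        bd = total_objective(
            det_bundle.truth.params_effective, None, det_bundle.props,
            rtol=1e-8, atol=1e-2,
        )
        assert bd.fqual == 0.0

    def test_stochastic_flip_rate_matches_logistic_model(self):
        rng = np.random.default_rng(0)
        for delta, s in [(2.0, 1.0), (-1.0, 0.5), (0.5, 2.0)]:
            draws = np.array([
                draw_outcome(delta, s, "stochastic", rng)
                for _ in range(10_000)
            ])
            p = expit(delta / s)
            se = np.sqrt(p * (1 - p) / draws.size)
            assert abs(draws.mean() - p) < 3 * se

    def test_tiny_scale_makes_flips_vanish(self):
        rng = np.random.default_rng(1)
        draws = [draw_outcome(5.0, 1e-9, "stochastic", rng)
                 for _ in range(100)]
        assert all(d == 1 for d in draws)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            draw_outcome(1.0, 1.0, "guess", np.random.default_rng(0))


class TestBundle:
    def test_same_seed_regenerates_byte_identical_files(self, tmp_path):
        p1 = make_bundle(9, mode="stochastic").write(tmp_path / "a")
        p2 = make_bundle(9, mode="stochastic").write(tmp_path / "b")
        for key in ("exp", "prop", "manifest"):
            with open(p1[key], "rb") as f1, open(p2[key], "rb") as f2:
                assert f1.read() == f2.read(), key

    def test_manifest_round_trip(self, tmp_path, study_bundle):
        paths = study_bundle.write(tmp_path)
        manifest = json.loads(open(paths["manifest"]).read())
        assert manifest["seed"] == study_bundle.truth.seed
        assert manifest["n_quant"] == 18 and manifest["n_props"] == 90
        back = read_prop_file(paths["prop"])
        assert list(back) == list(study_bundle.props)

    def test_bundle_scale_boxes_contain_effective_truth(self, study_bundle):
        eff = study_bundle.truth.params_effective
        for name, (lo, hi) in study_bundle.optimization_bounds().items():
            if name.startswith("Scale"):
                assert lo < eff[name] < hi
        for name, (lo, hi) in study_bundle.bayes_bounds().items():
            if name.startswith("Scale"):
                assert lo < eff[name] < hi

    def test_unknown_bundle_mode(self):
        with pytest.raises(ValueError):
            make_bundle(0, mode="nope")
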