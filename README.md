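# mekfit

Calibration and uncertainty quantification for ordinary-differential-equation
models of the EGFR → SOS1 → RAS → RAF → MEK1/2 → ERK signaling cascade, using
**both** quantitative time-series data and formalized qualitative (up/down)
observations.

The package is aimed at systems biologists who want to parameterize a
mechanistic signaling model when quantitative data are scarce but ordinal
knowledge is plentiful: immunoblot-style case–control comparisons such as
"phospho-MEK in the MEK1-knockout line exceeds wild type at 300 s" carry real
information, and `mekfit` turns them into likelihood terms instead of leaving
them as prose.

## The model family

A mass-action reaction network for the MAPK/ERK cascade with MEK-isoform
detail is generated programmatically from ~27 rules (ligand engagement,
receptor dimerization and transphosphorylation, SOS1 recruitment, RAS/RAF
activation, MEK1/MEK2 homo- and heterodimerization, ERK activation, and two
ERK-driven negative feedbacks: SOS1 phosphorylation and MEK1-Thr292
phosphorylation with PHP-phosphatase-mediated silencing). Five cell-line
variants are structural transformations of one parameter set:

| variant | meaning |
|---------|---------|
| WT      | parental line, unchanged |
| KO      | MEK1 knockout (`MEK1(0) = 0`) |
| N78G    | MEK1 cannot dimerize with itself or MEK2 (`b2 = b4 = 0`) |
| T292A   | no ERK feedback phosphorylation of MEK1 (`p4 = 0`) |
| T292D   | phosphomimetic: all MEK1 starts Thr292-phosphorylated, permanently (`u4 = 0`) |

## The statistical machinery

For quantitative records *y<sub>i</sub>* ∈ (0, 1] (relative intensities,
wild type only) with scaled model outputs *f*(*c<sub>i</sub>*, θ) and
homoscedastic Gaussian noise σ:

−ln L(θ|y) = (n/2) ln(2πσ²) + F<sub>quant</sub>/(2σ²),  F<sub>quant</sub> = Σ (y<sub>i</sub> − f(c<sub>i</sub>, θ))².

Each qualitative observation z<sub>i</sub> ∈ {0, 1} compares two readouts with
difference δ<sub>i</sub> = g(a<sub>i</sub>, θ) − g(b<sub>i</sub>, θ) under a
Bernoulli–logistic model p<sub>i</sub> = 1/(1 + e^(−δ<sub>i</sub>/s<sub>i</sub>)):

−ln L(θ|z) = Σ [ln(1 + e^(−δ<sub>i</sub>/s<sub>i</sub>)) + (1 − z<sub>i</sub>) δ<sub>i</sub>/s<sub>i</sub>],

which the optimizer replaces by the hinge penalty
F<sub>qual</sub> = Σ w<sub>i</sub>[max(0, −δ<sub>i</sub>) + (1 − z<sub>i</sub>)δ<sub>i</sub>]
(with w<sub>i</sub> = 1/s<sub>i</sub> the two differ by at most ln 2 per
term). The fitting objective is F = F<sub>quant</sub> + F<sub>qual</sub>,
minimized by seeded rand/1/bin differential evolution in log₁₀ search space
under box constraints. Practical identifiability comes from profile
likelihoods; Bayesian uncertainty from adaptive-Metropolis MCMC (covariance
adapted, then frozen) with rank-normalized split-R̂ and bulk/tail ESS
diagnostics and posterior predictive credible bands.

Qualitative statements use a plain-text grammar, one per line:

```
WT.MEK_pRDS at time=300 < N78G.MEK_pRDS at time=300
N78G.pERK1_2_wt at time=300>T292D.pERK1_2_wt at time=300
```

Quantitative tables are whitespace-delimited text with a `time` column and
`nan` for missing values.

## Worked example

```python
import numpy as np
from mekfit import REFERENCE_PARAMS, simulate_variant, fit, FitConfig
from mekfit.objective import HybridObjective, total_objective
from mekfit.synth import make_bundle

# a study-shaped synthetic dataset: 18 wild-type measurements, 90 statements
bundle = make_bundle(seed=1, mode="study")
truth = bundle.truth.params_effective

bd = total_objective(truth, bundle.data, bundle.props)
print(f"F = {bd.total:.3f} (Fquant = {bd.fquant:.3f}, Fqual = {bd.fqual:.3f})")

obj = HybridObjective(bundle.data, bundle.props, ["d3", "u3"], base=truth)
res = fit(obj, {"d3": (8e-5, 3e-2), "u3": (8e-5, 3e-2)},
          FitConfig(popsize=8, generations=20, seed=0))
print({k: f"{v:.2e}" for k, v in res.as_dict().items()}, f"F = {res.fun:.3f}")
```

prints

```
F = 0.021 (Fquant = 0.021, Fqual = 0.000)
{'d3': '9.53e-04', 'u3': '9.25e-04'} F = 0.024
```

The objective at the generating truth is small but nonzero (measurement
noise) and every qualitative statement is satisfied there; the
two-parameter refit recovers the receptor-degradation rate `d3` and the
SOS1-dephosphorylation rate `u3` within a few percent of their true value
1.0e-03. On noisier draws `u3` wanders more than `d3` — it is the
less-constrained of the two, which the profile-likelihood and posterior
widths quantify.

A `mekfit` command-line tool exposes the same pipeline as subcommands
(`synth`, `check`, `fit`, `profile`, `sample`, `simulate`) driven by
plain-text configuration files; see `mekfit --help`.

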