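# Methods

This note documents the model, the statistical machinery, the synthetic-data
generator, and the numerical and design choices behind `mekfit`, in enough
detail to judge what the test suite does and does not establish.

## Reaction network

The cascade is defined as a rule set, not a hand-enumerated reaction list.
Species are structured labels (molecule, activation-site state, Thr292
state, PHP occupancy, dimer partner, SOS1 occupancy of receptor dimers), and
`build_network` iterates rule application to a fixpoint starting from the
variant's initially populated species, so the inventory is exactly the
reachable set: 62 species / 301 reactions for the wild type, fewer for the
variants (the knockout has no MEK1 material at all, N78G no MEK1-containing
dimers, T292A no Thr292-phosphorylated species). Dimers are canonicalized by
sorting protomer descriptors, making rule expansion confluent (AB ≡ BA).

Modeling conventions worth making explicit:

- **Mass action without symmetry factors.** A bimolecular reaction between
  identical species contributes rate k·x²; site multiplicity (e.g. two free
  SOS1 slots on a phosphorylated receptor dimer) enters as an integer factor
  on the rate constant. These conventions define this package's normative
  network.
- **Receptor coarse-graining.** Transphosphorylation switches a whole dimer
  (both subunits) at rate `t1`; the `pEGFR` observable counts two
  phosphorylated subunits per phosphorylated dimer. Degradation (`d3`)
  removes the dimer and returns any bound SOS1 — phosphorylated or not — to
  the free pool, so SOS1 material is conserved.
- **Feedback scope.** ERK phosphorylates SOS1 both free and receptor-bound
  (`p3`), and the reversal `u3` likewise acts in both contexts;
  receptor-bound phospho-SOS1 cannot catalyze RAS activation. The Thr292
  reversal `u4` acts only while no PHP is bound. `u3` and `u4` are treated
  as unimolecular (first-order) steps — their printed units suggest an
  implicit phosphatase that is not modeled explicitly.
- **PHP action in cis and trans.** A PHP-bound MEK1 protomer
  dephosphorylates the activation sites of its own protomer and of its dimer
  partner at `u5`. Only this trans action lets the Thr292 feedback silence
  MEK2 through heterodimers, which is what gives the N78G variant its
  phenotype; the slow constitutive dephosphorylation `u1` is the background.
- **ERK in one step.** ERK activation is modeled as a single
  phosphorylation step to the doubly phosphorylated form (`p2a` by MEK1,
  `p2b` by MEK2, reversal `u2`); `pERK1_2_wt` counts the active form.
- **Pre-stimulation convention.** No equilibration run: the t = 0 state is
  exactly the initial copy numbers and the ligand-engagement rate switches
  from `c1init` (= 0) to `c1L` at t = 0. The receptor/SOS1 turnover
  constants (s1, d1, s2, d2) are carried as inert parameters: those pools
  are fixed at their plateau values.

## Simulation

The network is compiled once per variant into index arrays; the mass-action
right-hand side and its analytic Jacobian are dense linear algebra, and
integration uses the stiff-capable adaptive LSODA solver. Defaults are
rtol 1e-8 / atol 1e-2 molecules for reference simulations; optimization and
MCMC loops use rtol 1e-6–1e-5 / atol 0.1–1, which agree with the tight
setting to ≲1e-4 relative on all observables (verified against a fixed-step
RK4 oracle at dt = 1e-3 s in the test suite). Required output times are
evaluated exactly (the simulation grid is the union of requested times; no
interpolation). A non-finite state raises a diagnostic error naming the
first failing time; objective evaluations convert that into an infinite
objective with a logged warning so optimizers continue.

## Likelihood, penalty, posterior

The quantitative part is an i.i.d. homoscedastic Gaussian likelihood over
the non-missing records (rows marked `nan` contribute nothing, also not to
n). Model outputs are copy numbers times one of three scaling factors
(pEGFR, pERK, pSOS1), applied to wild-type outputs only. The qualitative
part is a Bernoulli–logistic likelihood on output differences computed from
**raw copy numbers** — cross-variant comparisons of the same observable are
then scale-free. The tie convention is H(0) = 1: a tie satisfies ≥ and
violates <. Both `>`/`>=` map to z = 1 and `<`/`<=` to z = 0 (the penalty
has no notion of strictness). Default statement scale s = 1 (weight
w = 1/s = 1), overridable per line via a `weight=` annotation.

The hinge penalty equals w|δ| when the sign of δ contradicts z and 0
otherwise; with w = 1/s the exact negative log-likelihood term exceeds the
penalty term by a gap in (0, ln 2], maximal as δ → 0. All logistic terms
use log-sum-exp forms stable to |δ/s| ≈ 1e3 and beyond.

The Bayesian posterior samples (by default) d3, u3, the three scaling
factors, and σ, with all other parameters pinned to a supplied point
estimate. Rate constants and scaling factors are sampled in log₁₀ space
with the Jacobian included so the box prior remains uniform **on the
original scale**; σ is sampled linearly. Simulations are cached on the
model-parameter subvector, so proposals that move only scales/σ are free.

## Optimizer

Differential evolution, rand/1/bin: mutant = x_r1 + F·(x_r2 − x_r3) with
distinct random members, binomial crossover with one guaranteed mutant
coordinate, out-of-bounds coordinates reflected back into the box (no
boundary pile-up), greedy selection. Coordinates whose positive range spans
at least a decade are searched in log₁₀ space; initial populations are
(log-)uniform. Defaults population 50, F = 0.85, CR = 0.7, 500 generations —
robust textbook settings at this dimensionality, all configurable. Runs are
bitwise reproducible for a fixed seed. The objective contract is pure and
stateless, so evaluations may be dispatched concurrently by a caller; this
package specifies the contract and runs serially.

## Profile likelihood

A profile fixes one parameter on a grid (default 20 log-spaced points
spanning its box) and re-minimizes over the rest, sweeping outward from the
grid point nearest the MLE with warm starts from each neighbor's optimum.
Identifiability uses a threshold on the −ln L scale, default
χ²₁(95%)/2 = 1.92, converted to the objective scale with the plug-in
variance σ̂² = F_quant(θ̂)/n; a parameter is identifiable iff the
sub-threshold region is bounded away from both box edges. The raw curves
are always reported so any other threshold can be applied post hoc;
`profile_interval` additionally interpolates the threshold crossings so
interval widths are not grid-quantized.

## Adaptive-Metropolis sampler

Three phases per chain: burn-in (diagonal proposal, scalar step tuning
toward an acceptance band), adaptation (the proposal covariance is
re-estimated from the chain history as (2.38²/d)·Ĉ + jitter on a fixed
cadence, with a Robbins–Monro global scale steering acceptance toward
0.234), and production with the kernel frozen — production draws therefore
form a valid fixed-kernel Markov chain, and only they enter inference.
Chains initialize at independent random points in the prior by default; a
caller may initialize at a point estimate (the recovery studies below
initialize at the MLE, standard practice that shortens burn-in without
informing the chain about the generating truth).

Convergence diagnostics (rank-normalized split-R̂ with the folded variant,
bulk ESS on rank-normalized split chains, tail ESS from the 5%/95% quantile
indicators) are implemented in the package and cross-checked against the
arviz reference implementation in the tests.

Posterior predictive bands simulate each retained draw deterministically
(parametric uncertainty only, no measurement-noise injection), thinned to a
configurable simulation budget; bands are nested central quantile intervals
from 10% to 95% with the median always inside. Per-statement satisfaction
fractions are the fraction of retained draws whose predicted ordering
matches each observation.

## Synthetic data generator

The generator emulates the study-shaped calibration problem: 18 wild-type
relative-intensity measurements (3 readouts × 6 times) and 90 binary
comparison statements (60 cross-variant pairs over two observables at
300/1800/3600 s, plus 30 within-variant time comparisons — times chosen to
span the rise, peak and relaxation of the responses, since the real
measurement grid is not public). Ground truth defaults to the literature
reference rates with mid-box scaling factors; quantitative noise is
N(0, σ*²) in arbitrary units added to scaled outputs, then normalized by
the **noise-free** series maximum and clipped into (0, 1] (floor 1e-6).
Normalizing by the noise-free maximum makes the noise on the relative scale
exactly N(0, (σ*/m)²) away from the clip and makes the max-normalization an
exact rescaling of the scaling factors: the bundle records these
*effective* scales as the fitting ground truth. The published scale boxes
encode the original data's normalization, not the generator's, so synthetic
bundles derive scale boxes around the effective truth (factor 1.8 each
side, comparable to the published box widths); the d3/u3/σ boxes are used
as published. Default σ* = 1 AU for study-shaped bundles (≈ 0.03–0.12 on
the relative scale depending on the readout), σ* = 0 for deterministic
bundles, whose truth is then an exact global minimizer of the hybrid
objective. Qualitative statements are truth-consistent (z = H(δ(θ*))) in
deterministic/study modes or Bernoulli draws at scale s* in stochastic
mode.

What passing these tests shows — and does not. The generator reproduces the
assumed noise models exactly, so recovery and coverage results demonstrate
the correctness and calibration of the inference machinery under its own
assumptions. Real immunoblot data bring saturation, blot-to-blot
normalization artifacts, correlated errors and model misspecification that
the generator deliberately does not emulate; results on it say nothing
about those.

## Problem sizes in the tests and acceptance script

The replicated studies run at desk scale, chosen once as the package's
standard verification protocol: 10 seeded replicates; two-parameter
(d3, u3) DE fits with population 8 × 20 generations; single-chain
adaptive-Metropolis runs of 200 burn-in / 300 adaptation / 800 production
draws sampling (d3, u3, σ) with scales pinned at truth; 9-point profile
grids; posterior predictive bands from 60 thinned draws. The analytic
sampler benchmark uses 4 chains × 5000 production draws on a 2-D standard
normal. Full-scale settings (25k/25k/250k × 5 chains, the 31-parameter
fit) remain the library defaults.

## Known limitations

- The reaction inventory is a reconstruction from per-parameter
  descriptions of the underlying model; published machine-readable versions
  of that model may differ in mechanistic detail (e.g. the exact scope of
  PHP action or the order of SOS1 binding events). The reconstruction here
  is normative for this package, and the reaction list/species inventory
  export exists precisely to make auditing against other encodings easy.
- Only the comparison subset of the property language is implemented —
  no temporal operators, window thresholds, or peak-time constraints.
- The optimizer is a single global metaheuristic; there is no local
  gradient polish or multistart scatter search.
- σ enters the Bayesian likelihood through the Gaussian part only; the
  qualitative scales s_i stay fixed during sampling.
- The prior boxes are implemented exactly as published, including the
  published ScalepEGFR best-fit value lying outside its own sampling box.
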