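# Methods

`fossilbisse` is a self-contained reimplementation of a simulation study
asking whether fossil data improve extinction-rate estimation under the
binary-state speciation and extinction model (BiSSE), by combining it
with the fossilized birth–death (FBD) process. This note documents the
models, the algorithms, the defaults, and the choices made where the
design was genuinely open.

## The generating process

Species diversify under BiSSE: a lineage in state *i* ∈ {0, 1} speciates
at rate λᵢ, goes extinct at rate μᵢ, and switches state at rate q₀₁
(0→1) or q₁₀ (1→0). Simulation is exact and event-driven: with n₀
lineages in state 0 and n₁ in state 1, the next event time is
exponential with rate n₀(λ₀+μ₀+q₀₁) + n₁(λ₁+μ₁+q₁₀); the affected
lineage and event type are drawn proportionally to rates. The first
lineage starts at time 0 in state 0 (a calibration option draws the root
state instead); a child inherits its parent's state at speciation.

**Stopping rule.** The simulation stops at the instant of the speciation
event that brings the number of coexisting lineages to the target
(default 100); that instant is the present. Replicates that go fully
extinct first are discarded and resimulated (counts recorded). This is
the simplest reading of sampling a tree conditioned on its extant size;
the convention is recorded in every run manifest.

**Scenarios.** Four rate templates share λ₀ = 0.1, μ₁ = 0.03,
q₀₁ = 0.01: S1 (control, all rates state-independent), S2 (λ₁ = 2λ₀),
S3 (μ₀ = 2μ₁), S4 (q₁₀ = q₀₁/2). Neutral binary traits (symmetric rate
q ∈ {0.01, 0.1, 1}; slow/medium/fast) evolve along the finished tree,
root state 0, without touching the rates.

**Fossils.** Occurrences fall as a Poisson process with rate ψ
(∈ {0, 0.01, 0.05, 0.1}) along every branch of the complete tree,
each stamped with all trait states at its time.

**Two observable views.** The *extant* view prunes extinct lineages,
giving an ultrametric binary tree. The *FBD* view prunes extinct
lineages with no sampled material and truncates each remaining extinct
lineage at its last fossil: that fossil becomes a terminal *fossil tip*;
every fossil with sampled material anywhere below it (including on the
same lineage) becomes a degree-2 *sampled ancestor*. Extant species are
always sampled (ρ = 1).

**Rejection filter.** A dataset is accepted only when each trait has
each state in at least 10% of the sampled taxa of each available view
(threshold ⌈0.10 × taxa⌉; "taxa" counts extant tips plus fossil tips
plus sampled ancestors). A failing focal trait discards the whole tree,
because tree and focal trait are generated jointly; a failing neutral
trait is resimulated on the accepted tree, because it is independent of
the tree — resimulating the tree too would waste compute without
changing the joint distribution. Whether sampled ancestors count as
"taxa" was an open choice; they are included here.

## Likelihood

Both models are evaluated by pruning with per-branch ODE integration of
the standard state-dependent system, for i ∈ {0,1}, j = 1−i, in age a
(time before present):

    dEᵢ/da = μᵢ − (λᵢ + μᵢ + ψᵢ + q_ij) Eᵢ + λᵢ Eᵢ² + q_ij E_j
    dDᵢ/da = −(λᵢ + μᵢ + ψᵢ + q_ij) Dᵢ + 2 λᵢ Eᵢ Dᵢ + q_ij D_j

Eᵢ is the probability that a lineage alive at age a leaves no sampled
material at all; Dᵢ the density of the observed subtree. Initial and
node conditions: extant tip in state s: Dᵢ = ρ δ(i,s), Eᵢ = 1−ρ; fossil
tip of age t: Dᵢ = ψᵢ δ(i,s) Eᵢ(t) (the unobserved continuation to true
extinction must leave no samples); sampled ancestor: Dᵢ ← ψᵢ δ(i,s) Dᵢ;
bifurcation: Dᵢ ← λᵢ Dᵢ(left) Dᵢ(right); root: log L = log Σᵢ πᵢ Dᵢ
with π = (π₀, 1−π₀) and π₀ a free parameter. The extant model sets
ψ = 0; the FBD model requires ψ in the ODEs. Per-node renormalisation
of D with an accumulated log-scale prevents underflow; parameter sets
with zero likelihood return −inf.

**Conditioning.** Default "survival": the root sum is divided by
Σᵢ πᵢ λᵢ (1−Eᵢ(root))² for a bifurcating root (both crown lineages leave
samples), or Σᵢ πᵢ (1−Eᵢ) for a degenerate (sampled-ancestor) root.
"none" is available; the choice is logged in every trace. The reference
tooling's conditioning is not documented, so this is exposed rather than
asserted.

**Integrators.** The default backend is an adaptive Cash–Karp RK4(5)
compiled with numba (relative tolerance 1e-8, absolute 1e-10 for direct
likelihood calls; 1e-7/1e-9 inside the sampler, where the induced log-L
error ≈ 1e-4 is far below Monte-Carlo noise). The system is non-stiff
at study rates, so speed wins; scipy's LSODA (stiff-capable) is exposed
via `integrator="lsoda"` and the test suite cross-validates the two
backends to ~1e-7 on full-size trees. E is clamped to [0,1] against
roundoff; excursions beyond 1e-6 abort with an error carrying the
offending parameters.

**Validation.** With state-independent diversification rates the model
factorises into (single-type birth–death or FBD tree likelihood) ×
(two-state Markov-chain likelihood of the trait pattern). The test suite
checks this identity on random 5–10-tip trees against an independent
closed-form implementation (the hyperbolic q-function propagator and
matrix-exponential pruning) to 1e-6, and branch integrals against
pure-birth/pure-death closed forms to 1e-8.

## Priors

Transition rates get exponential priors with mean 0.01 (the simulated
focal rate); π₀ is uniform on (0,1); ψ gets lognormal(ln 0.05, 1).
The diversification rates λᵢ, μᵢ get lognormal(location ln 0.01,
scale 2) — a deliberately vague prior spanning several orders of
magnitude, centred below the expected rate scale. The reasoning: on
extant-only 100-tip trees the profile likelihood in μ is nearly flat
between 0 and ≈ λ (a few log-units), so the μ posterior is largely
prior-driven; a prior concentrated at or above the true value would
manufacture accurate-looking extinction estimates that such data cannot
support, and would contradict the well-documented behaviour of these
models (extinction estimates from ultrametric trees collapsing toward
zero). A vague low-centred prior reproduces that behaviour while
leaving informative likelihoods (the FBD view) free to dominate. All
hyperparameters are overridable per parameter and recorded in each
trace's metadata.

## MCMC

Random-scan Metropolis–Hastings with a per-iteration budget of 29
weighted single-parameter moves (echoing the reference tool's
scheduling): multiplicative scale moves on rates (Hastings-corrected)
and a reflected slide on π₀. Proposal scales adapt toward ≈ 0.44
acceptance every 200 iterations during burn-in only, keeping the
retained chain Markovian. Defaults: 100 000 iterations, 25% burn-in,
thinning to ≈ 1000 retained samples; initial states are prior draws
redrawn until the posterior is finite. Runs are bit-reproducible from
their seed. Effective sample sizes use arviz's rank-normalised bulk
estimator; any parameter with ESS < 200 flags the analysis in the
convergence report and run manifest (flagged, never silently dropped).

## Summaries

Posterior means with equal-tailed 95% credible intervals (2.5%/97.5%
quantiles, the convention of the reference tooling; HPD could be added
without schema changes). Coverage uses closed endpoints. Relative error
is reported both as the study's |mean − truth| / truth and signed,
(mean − truth)/truth, since the direction (under- vs over-estimation)
carries the scientific point. Trait–rate association uses the posterior
probability P(λ₁ > λ₀) (or P(μ₀ > μ₁)), ties counting ½. Turnover
τᵢ = λᵢ + μᵢ and extinction fraction εᵢ = μᵢ/λᵢ are computed samplewise
(ε-undefined samples dropped with a count); ROC curves sweep thresholds
over the observed probabilities with trapezoid area (equal to the
Mann–Whitney U statistic, which the tests assert).

## Study orchestration and scales

The full factorial design is 4 scenarios × 4 ψ values × 100 replicates
= 1600 trees, each with 4 trait sets = 6400 datasets; each replicate
gets an independent seed via counter-based spawn keys from the master
seed, so any replicate regenerates in isolation, byte-identically. ψ = 0
cells have only the extant view; each ψ > 0 cell simulates its own
complete trees and derives both views from the same tree (the extant
tree of a fossil cell is the ψ = 0 analysis of that same tree).

Desk-scale runs shrink replicates and chain length with `--scale` (or
explicit settings); the shipped test suite and acceptance script use 4–6
replicates per cell, 100-tip trees, 1200-iteration chains (29 moves per
iteration), and a 20–30-run calibration at 30 tips with 700–800
iteration chains — sizes chosen so a complete validation pass runs on a
single CPU in minutes. At these sizes the directional conclusions
(extinction underestimated without fossils; improved with ψ = 0.1;
speciation/transition unaffected; neutral traits spuriously detected)
are testable, but per-replicate posterior summaries are noisier than the
full study's.

**Calibration.** Prior-predictive coverage runs draw all free
parameters (including the root state, via π₀) from the priors, simulate
30-tip extant trees, and re-infer under the same priors. Parameter draws
whose process cannot reach the tip target within a capped number of
attempts are redrawn; this approximates exact survival conditioning and
slightly downweights parameter regions of negligible survival
probability. The inference conditions on survival of the crown, not on
the exact tip count — a deliberate mismatch shared with the emulated
workflow; pooled coverage is compared against the exact binomial band
around 0.95.

## What the generator does and does not emulate

The synthetic data reproduce: exact BiSSE event histories conditioned on
extant size, state-stamped Poisson fossil records, complete extant
sampling (ρ = 1), the two tree views with sampled ancestors, and the
10% state-representation filter. Not emulated: incomplete or biased
extant sampling, time- or state-dependent fossil recovery, stratigraphic
ranges (occurrences are points), anagenetic species identity (lineages
are branches of the bifurcating tree), and topology/divergence-time
uncertainty — trees are fixed at their true values for inference, so
passing tests say nothing about errors introduced by tree estimation on
real data.

## Behaviour of the association statistic for neutral traits

Two opposing forces shape P(λ₁ > λ₀) when the analysed trait is neutral
but the tree's diversification is heterogeneous (S2). Slowly evolving
neutral traits are clade-clustered, and the minority state is more
likely to occupy a large clade — which is precisely a fast-diversifying
clade — so slow traits are spuriously "detected" (P near 1). Fast
neutral traits are well mixed; there the dominant signal is the root
state: state 1 occupancy grows from 0 toward ½ along the tree, and a
free root-state probability lets the model explain state-0 prevalence
with a higher λ₀, pushing P toward 0. In this implementation the
balance depends on the trait's rate: the slow (q = 0.01) neutral trait
often shows the classic spurious association (P near 1) but the outcome
is clade-coincidence-driven and therefore bimodal across replicates,
and the medium (q = 0.1) trait yields a broad mixture of directions.
What holds robustly is separation: the effect trait's probabilities
rank above the neutral traits', which the test suite asserts via the
ROC area; the acceptance script reports the high-probability fractions
for both neutral rates.

## Known limitations

- The μ posterior on extant-only trees is prior-sensitive by nature;
  conclusions about its *direction* depend on the vague-prior choice
  documented above.
- Fossil information about μ₁ (the rare state's extinction rate) varies
  strongly across replicates; at desk scales its medians are noisy.
- The MCMC is single-chain; between-chain diagnostics (R-hat) are not
  computed. ESS flags stand in for convergence assessment.
- The sampler and likelihood assume two observed states; hidden-state
  or multi-state extensions are out of scope.
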