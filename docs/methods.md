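# Methods

## Model structure and assumptions

The model is a deterministic ODE description of the canonical TNFα → IKK →
IκBα → NF-κB axis in a population-averaged microglial cell, built on the
Lipniacki-type single-feedback architecture and extended with an explicit
IκBα degradation chain.  Eighteen dynamic species (state ordering in
`nfkbsim.model.SPECIES`):

* IKK in three interconverting forms — neutral (IKKn), active (IKKa),
  inactivated (IKKi).  TNFα is a binary input gating the activation flux
  `ka·TNF·IKKn`; there is no receptor/TRAF layer and no basal IKK activity
  (justified by near-undetectable resting phospho-IκBα).  Inactivation is
  `(ki + kiA20·A20)·IKKa`; recovery `kp·IKKi` is slow, so the stimulated
  IKKa transient decays intrinsically as the pool drains into IKKi.  The
  A20 term is the **only** route by which downstream signaling feeds back
  on IKK — a deliberate structural commitment shared by the model family,
  which makes early IKK activation provably insensitive to any downstream
  perturbation.
* IκBα free and NF-κB-bound, in cytoplasm and nucleus, plus a three-step
  tagged chain for each cytoplasmic branch: phosphorylated (kc2a on the
  complex, kc1a on free IκBα) → E3-engaged (kua1) → poly-ubiquitinated
  (kuc1) → proteasome (kupd).  Degradation of a complexed IκBα moiety
  frees NF-κB.  Two structural refinements: every tagged intermediate is
  also degraded constitutively (kdpi), and the cytoplasmic IκBα:NF-κB
  complex may be imported into the nucleus (i2a).
* NF-κB free in cytoplasm and nucleus; nuclear import i1, no free export
  (retention until sequestered by nuclear IκBα and exported as complex,
  e2a).
* IκBα and A20 mRNA and A20 protein.  Both genes are under identical
  NF-κB control: transcription is Hill-2 in nuclear NF-κB with shared
  half-saturation Ka.  Cooperative (rather than linear) induction is the
  package's own design choice: κB-driven promoters carry multiple binding
  sites, and the quadratic low-end response is what buffers resting
  nuclear NF-κB against changes in the total pool — the experimentally
  observed behaviour (resting activity similar at 70% p65) that linear
  induction cannot reproduce.

Total NF-κB and total IKK are conserved exactly (no synthesis/turnover of
either backbone); both conservation laws are enforced by tests at ≤1e-6
relative drift.  Nuclear and cytoplasmic concentrations share one volume
reference, so conserved totals are plain sums and transport is first-order
both ways.

## Simulation protocol

`equilibrate` integrates without stimulus from the canonical initial
condition (whole NF-κB pool as cytoplasmic complex, whole IKK pool
neutral, all else zero) over a 1e5-min horizon (one 10× extension before
failing) and accepts the state when every per-species relative rate
|dx/dt|/max(|x|, floor) falls below 1e-8/min.  Long-horizon integration
was chosen over algebraic root finding because it mirrors the stated
experimental protocol and cannot land on a spurious root.  `run_stimulus`
then integrates 0–150 min with TNF = 1 from that fixed point.

Integrator: `scipy.integrate.solve_ivp` with LSODA, rtol 1e-8,
atol 1e-10 (exposed via `SolverSettings`).  The tolerances are tight
because downstream analyses are ratios of trajectory features; halving
them moves the nominal nuclear NF-κB peak by <1e-4 relative.  Output grid:
1-min spacing on [0, 150] densified to 0.25 min on [0, 10] for the early
IKK transient.  Concentrations more negative than −1e-9 µM abort;
smaller negatives are clipped to zero (warned above solver-noise level).

## Parameters

Values live in `src/nfkbsim/data/parameters.json`, one entry per rate with
units and a provenance tag: `lipniacki-family` (adopted from the canonical
parameter family, seconds→minutes), `calibrated` (fixed during model
construction so the *control* simulation reproduces the published
control-cell phenotype: basal nuclear NF-κB ≈ 10% of the stimulated
maximum, NF-κB peak at ~18 min, total IκBα trough at ~15–20 min with
recovery to near basal by 90 min, transcript induction peaking 30–60 min
and declining by 120 min), or `assumed` (order-of-magnitude, no direct
anchor — e.g. the fast kua1/kuc1/kupd chain, which only needs to be fast
enough that tagged intermediates are transient).  Calibration used only
those control-cell behaviours; the parameter set was then frozen before
any scenario-level checks were run.  Conserved pools: 0.06 µM NF-κB,
0.2 µM IKK.

## Scenario catalog and plausibility

Scenarios are multiplicative factors (never absolute overwrites), so they
compose with any parameter file and invert exactly.  The shipped catalog
(`data/catalog.json`, 50 entries) covers: the ka scan {1, 1/2, 1/4, 1/8,
1/16}; hypothetical kp/ki/kiA20 scans (dyadic factors); the kc2a scan
{1/5, 1/6, 1/10, 1/32}; kua1/kuc1/kupd reduction scans; IκBα translation
c2a × 1/30; NF-κB pool × 0.70; IKK pool × {0.055, 1/8, 1/18}; and the
combined scenarios (pool+IKK-pool, pool+kiA20×10+kc2a/6, pool+upstream
only, pool+downstream only, IKK-pool+downstream).

`evaluate_scenario` computes four ratios against the nominal run and
classifies: *reduced* means scenario/nominal ≤ 0.95 (the 5% margin keeps
solver-level differences from counting as reductions), and resting NF-κB
is *preserved* within ±15% of nominal.  Both thresholds are package
choices — the underlying reports state directions, not margins — and are
recorded in every verdict.

## Uncertainty ensemble

`sample_parameters` draws every rate constant and both pools independently
and uniformly from ±20% around nominal (fraction and n configurable;
defaults 0.20 and 100).  Each draw is equilibrated under its own values
before stimulation.  Paired mode reuses one draw's factors for the nominal
and the scenario model, isolating the scenario effect from sampling noise;
unpaired use is available via `run_ensemble` directly.  Failed draws are
excluded and counted; >5% failures aborts.  All randomness flows through
`numpy.random.default_rng(seed)`.

## Synthetic assay data

The generator emulates the *statistical and normalization structure* of the
population-level assays, not their biochemistry: replicate value = model
observable at the sampled time × exp(N(0, σ²)) with σ² = ln(1 + CV²)
(default CV 0.15), both cell types normalized by the control replicates'
mean at the assay's reference time (p65 ELISA: 20 min, n = 6; IKK ELISA:
5 min, n = 6; total IκBα: 0 min, n = 9; phospho-IκBα: 5 min, n = 9).
The lognormal family is an assumption (only mean ± SD bars are reported
for the real assays) and is recorded in each dataset.  qPCR tables are
generated as Ct = offset − log2(relative transcript) + N(0, 0.25 cycles),
with a stimulus-independent reference gene, and analyzed by
ΔΔCt: fold = 2^(−ΔΔCt).  With CV = 0 the full pipeline reproduces the
model's normalized observables exactly.

What passing tests on such data do **not** show: anything about real
measurement error structure (additive components, plate effects,
between-day variation), single-cell heterogeneity (the model is a
population average; real cells oscillate asynchronously), or the true
biology of the discordant IκBα transcript induction seen in
Hsp72-overexpressing cells, which the model structure cannot produce.

## Statistics

Per time point, independently (independent populations are harvested per
time): one-way ANOVA (via `scipy.stats.f_oneway`, with explicit handling
of the zero-within-variance degeneracies), then — only when the omnibus
test rejects — Newman–Keuls stepwise comparisons on ordered means using
studentized-range quantiles, harmonic-mean n for unbalanced groups, and
span-blocking (a non-significant span silences all nested pairs).  For two
groups the procedure reduces exactly to the pooled two-sample t decision.
Ratio-normalized quantifications use the two-sided one-sample t against
mean 1.  Sidedness is two-sided throughout (a recorded assumption).  No
correction is applied across time points, by design.

## Numerical choices and degenerate inputs

* Peak finding: grid argmax, earliest time on ties, restricted to the
  simulated window; agreement with a 10×-refined spline oracle is tested
  at 0.5%.
* Steady-state ratios and tagged fractions return NaN (flagged, not
  raised) when the denominator is numerically zero.
* Equilibrium-uniqueness heuristic: redistributed starting states with the
  same conserved totals must converge to the same fixed point within 1e-4
  relative, else the run is flagged.
* ParameterSet is immutable and validates names and nonnegativity on
  construction; scenarios touching unknown names fail with the valid-name
  list.

## Problem sizes

Default runs use the 181-point output grid over 150 min; ensembles use
100 draws at ±20% (a 76-point 2-min grid in the ensemble test keeps the
paired 200-simulation check under a minute); the statistics calibration
uses 1e4 simulated null tables.  These sizes match the figures the package
reproduces while keeping a full test run in a few minutes.

## Known limitations

* Parameter values are not the original fitted set (the fitted values were
  not machine-readable from the source); they are a documented
  reconstruction within the same model family, so agreement with the
  reproduced analyses is qualitative/structural plus the two quantitative
  headline ratios — not curve-level.
* The IKK module is a coarse three-state approximation; conclusions that
  depend on the detailed shape of the IKK transient (e.g. peak-delay
  effects under strong ka reduction) are model-family artifacts.
* Hsp72 is never an explicit species: scenarios assert *where* constant
  overexpression acts, not binding kinetics.
* No single-cell stochasticity, no delay terms, no SBML export.
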