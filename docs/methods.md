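# Methods

`cfaphys` implements the analysis chain used to study how delayed malaise
signals reactivate and stabilize flavour representations in amygdala
population recordings, together with a synthetic session generator that
provides ground truth for every stage.  This note documents the models,
parameters, numerical conventions and the design choices that were
genuinely open.

## Task model

A simulated session reproduces the two-reward conditioning paradigm:

* 5 min of acclimation (session clock starts at 0).
* A cued consumption period.  Each trial draws an integer inter-trial
  interval uniformly from 10–20 s, cues one port, and delivers a 20-µl
  reward after a uniform 0.5–2 s port-entry latency.  Every consecutive
  block of ten rewards is split 5/5 between the flavour and the water port
  (random order within block), and the period ends at exactly 60 rewards
  (1.2 ml).  All cued trials are rewarded; omission trials are not
  modelled.
* The consumption epoch is defined to end 10 s after the final reward so
  that the last trial's 10-s response window lies inside the epoch used
  for normalization statistics.
* A 30-min delay epoch (second context).
* Either a 45-min stimulation epoch composed of 3-s bouts whose gaps are
  drawn from a shifted exponential (minimum 1 s, mean 3 s) with rejection
  above 7.8 s — the realized mean gap is ≈2.77 s, slightly below 3 s,
  because the nominal parameters over-determine the truncated
  distribution — or a single LiCl-style injection event at the end of the
  delay, or nothing (training/familiarization days).

## Spiking model

Each neuron is an inhomogeneous Poisson process generated by thinning with
piecewise-constant ceilings (tight per-epoch bounds keep rejection rates
low; a configurable hard ceiling of 500 sp/s guards against parameter
errors).  The rate is

```
rate_u(t) = b_u · s(t) · (1 + Σ kernels)
```

* `b_u` — baseline rate, lognormal across neurons (median 2 sp/s,
  σ=0.5), typical of extracellular units in the central amygdala.
* `s(t)` — 1 until the consumption epoch ends, then a constant
  suppression factor 0.6, emulating the drop in activity after
  consumption.  The magnitude of this drop is a free parameter of the
  generator; 0.6 gives a clearly visible but not silencing suppression.
* Reward kernels — flavour-preferring neurons (30% of the population)
  respond to flavour deliveries, water-preferring neurons (10%) to water
  deliveries, with an alpha-function gain `g·(Δt/τ)·e^(1−Δt/τ)` (peak `g`
  at lag τ=2 s, truncated at 8τ).  Response-peak gains are lognormal
  (median 2, σ=0.25).  The 30%/10% split mirrors the observed proportions
  of flavour- and water-preferring neurons qualitatively; the response
  shape is a modelling choice (only response windows, not shapes, are
  constrained by the experimental analyses).
* Bout gain — during each stimulation bout, flavour-preferring neurons
  gain a boxcar rate factor `(1 + g_bout)` with per-neuron `g_bout` drawn
  from a gamma distribution (shape 2, mean 1).  Setting the mean to 0
  yields the no-reactivation null.

What the generator deliberately does **not** model: correlated (shared)
variability across neurons, slow drift, bursting/refractoriness,
behavioural learning dynamics, and licking microstructure.  Passing tests
therefore demonstrate correctness of the analysis chain under
independent-Poisson statistics, not robustness to the full correlation
structure of real recordings (see "Known limitations").

## Cross-day plasticity

The retrieval-day change in each flavour-preferring neuron's *measured*
flavour response is the modelled quantity: the generator sets the day-2
kernel gain so that

```
E[Δ response_u] = β · E[stimulation response_u] + slope_u · ε_u ,
```

where both responses are on the scales the analysis reports (consumption-
normalized z for reward responses with day-1 statistics; final-20-min-
of-delay z for the stimulation response), `ε_u ~ N(0, 0.2)` is plasticity
noise on the kernel-gain scale, and `slope_u` converts gains to measured
response units.  The conversion uses closed-form expectations computed
from each day's realized event log (alpha-kernel integrals over the
response and per-trial baseline windows, including spill-over from
neighbouring rewards, and the Poisson approximation to the count s.d.).
Defining plasticity on the measured-response scale — rather than adding
`β·g_bout` to the gain directly — makes the downstream regression of
response change on stimulation response estimate β itself; a gain-space
rule would make the estimated slope a condition-dependent multiple of β.
Using both days' realized event statistics removes the session-level
response-scale factor that otherwise inflates the across-seed variance of
the fitted slope.  Day-2 gains are clipped at zero (effectively never
binds at the default parameters).

The familiarization variant multiplies flavour gains by a decay factor
(default 0.3) and leaves water responses unchanged.

## Analysis conventions

* **Binning.** 10-ms bins, left-closed/right-open; a spike exactly at the
  range end is dropped, so binning conserves in-range spike counts.
* **Normalization.** All z-scoring uses the population (divide-by-N)
  standard deviation; the convention, epoch and granularity are recorded
  in `NormStats.provenance`.  Zero-variance neurons z-score to zero rows
  with a warning.
* **Smoothing.** Causal half-Gaussian (σ=100 ms), truncated at 4σ and
  renormalized to unit sum; near the start of a trace the kernel is
  renormalized over the available samples so constant inputs are
  preserved exactly.  No sample depends on future samples.
* **Selectivity.** Mean z over `(delivery, delivery+10 s]` per trial;
  Wilcoxon rank-sum (midranks, tie-corrected normal approximation with
  continuity correction) between flavour and water trials; two-stage
  Benjamini–Krieger–Yekutieli step-up at q=0.05 across all neurons pooled
  in one call (per-animal pooling is the caller's choice of what to pass).
  Rejected neurons are labelled flavour-preferring on a strict inequality
  of means; exact ties fall to water.  The 10-s window is fixed regardless
  of overlap with the next trial.
* **PETHs.** Reward PETHs span −5 to +10 s; stimulation-bout PETHs span
  −1 to +4 s (−1 to +2 s for response typing) and subtract the per-neuron
  (−1, 0) s baseline.  Events whose windows extend past the recorded data
  are dropped from the average (never zero-padded) and counted.
  Whole-experiment and event-locked minute traces use the final 20 min of
  the delay for normalization by default (full-delay statistics are
  available by flag; the choice between the two is ambiguous in the
  source analyses) and non-overlapping minute means aligned to segment
  starts.
* **Decoder.** Training features are per-neuron 1-s spike counts after
  each reward delivery and before each cue onset, centred by the mean
  pre-cue count and scaled by the s.d. of 1-s counts tiled over the
  consumption epoch (the granularity of "consumption-period s.d." was an
  open choice; non-overlapping tiling is the simplest deterministic one).
  All cue onsets contribute baseline examples.  The model minimizes the
  *total* multinomial negative log-likelihood plus λ·Σ|W| (intercepts
  unpenalized), matching the objective scaling of the reference library
  the original analysis used; λ=1 is the default and a nine-point
  log-spaced grid over 1e−4…1e4 with stratified 10-fold cross-validation
  is provided.  The solver is a monotone accelerated proximal-gradient
  method (step 1/L with L = 0.5·σmax²; momentum restarts whenever a step
  would increase the objective), converged at relative tolerance 1e−6 or
  flagged with diagnostics after 5000 iterations.  Evaluation uses 1-s
  windows stepped by 150 ms over the whole session, z-scored with
  delay-period 1-s-count statistics.  Reactivation events are strict
  local maxima of a class posterior above 0.5 (plateaus contribute their
  first index; endpoints are eligible), counted in 1-min windows stepped
  by 30 s.
* **PCA.** Input: smoothed reward PETHs of reward-selective neurons,
  baseline-subtracted over (−5, −4) s averaged across both reward types,
  peak-normalized per neuron by the maximum absolute value across both
  reward types, 0–5 s segments concatenated (1000 columns).  Every column
  (time bin) is centred across neurons; components live in neuron space
  (time bins as observations), which is the orientation consistent with
  projecting population vectors at each time bin.  Signs are fixed so the
  flavour trajectory's largest-magnitude projection is positive.
  Stimulation PETHs are baseline-subtracted over (−1, 0) s and
  peak-normalized by their own maximum before projection with frozen
  loadings; day-2 projections reuse day-1 loadings and normalization
  constants.  Trajectory similarity is summarized as the cosine between
  the time-averaged (PC1, PC2) vectors over post-event lags.
* **Cross-day analyses.** Units are matched across days by identity (the
  concatenated-sorting correspondence is taken as given).  Responses are
  per-trial baseline-subtracted over (−10, −5) s so baseline-rate changes
  cancel; classification comes from day 1 only.  The linear fit is OLS
  with Pearson r, a t-based two-sided p (validated against a permutation
  oracle in tests) and a t-based 95% CI for the slope.
* **Response typing.** Four-component Gaussian mixture on the 0–1 s
  stimulation-PETH bins, diagonal covariances with a 1e−5 variance floor,
  EM from random responsibilities with 100 restarts keeping the best
  log-likelihood.  Components are labelled by their mean response: most
  negative → inhibited, nearest zero among the rest → unmodulated, the
  remaining two → strongly/weakly activated by magnitude; a structure
  mismatch raises a warning but labels are still assigned by the rule.
* **Photometry.** Zero-phase second-order Butterworth low-passes (2 Hz
  for calcium, 1 Hz for the PKA sensor; the filter family/order was an
  open choice and is recorded in the output provenance), decimation to
  100 Hz, then either subtraction of the least-squares linear map of the
  isosbestic channel (calcium) or the 488/405 ratio (PKA).  The PKA
  per-event normalization divides by the s.d. of the concatenated
  (−5, −1) s baseline epochs pooled across both ports of a recording.

## Reproducibility

All randomness flows through named substreams derived from one master
seed (`SeedSequence([seed, crc32(name)])`), so events, spikes, plasticity
noise and photometry noise can be regenerated independently and every
output is byte-identical across runs.  `pipeline.run_pipeline` writes a
manifest with the config hash and SHA-256 checksums of every artifact.

## Verification studies and problem sizes

`scripts/acceptance.py` re-runs the studies below from scratch
(`--seed` controls all randomness) and writes their measured quantities;
`tests/test_acceptance.py` asserts them.  The sizes are fixed study
designs:

* Task structure: 100 event simulations (reward count, block balance).
* Oracle equivalence: rank-sum vs full enumeration (continuous samples,
   sizes 3–6), BKY mask vs an independent two-stage reference on 1000
   random p-vectors, decoder gradient vs central differences (1e−6), PCA
   vs an eigendecomposition oracle (1e−8), peak detection vs a brute
   scan.
* FDR control: 100 null populations of 1000 neurons each
   (consumption-only sessions); fraction labelled selective ≤ 7%.
* Classifier recovery: one default 300-neuron session; balanced accuracy
   vs ground truth ≥ 0.9.
* Decoder specificity: 10 planted + 10 null full sessions; event counts
   pooled across seeds (the null ratio uses add-one smoothing so it is
   defined at near-zero counts).
* Trajectory similarity: one planted session; cosine of the stimulation
   trajectory to the flavour vs water consumption trajectories.
* Plasticity-slope coverage: 100 paired sessions of 150 neurons for each
   β ∈ {0.2, 0.5, 1.0}; fraction of 95% CIs containing β.
* Response typing: 240 synthetic PETHs with four planted types; adjusted
   Rand index and per-restart EM monotonicity.
* Photometry: exact debleaching of a perfectly linear bleach; port
   discrimination of planted PKA transients over 100 seeds.

## Known limitations

* **Null reactivation-rate symmetry.**  With the default 30%/10% class
  split, the L1 decoder at λ=1 must concentrate a similar total weight
  mass on three-fold fewer water-coding neurons, so the water logit has
  roughly twice the variance of the flavour logit under null
  fluctuations.  Threshold-crossing rates are approximately exponential
  in that variance, so in the *absence* of any planted reactivation the
  water posterior produces several-fold more noise peaks than the flavour
  posterior (≈3–4× under the default conditions).  This asymmetry follows
  from the class imbalance, the λ=1 penalty scale and the 0.5 peak
  threshold, not from a defect of a particular simulation; it persists at
  higher coding strengths because L1 weight scales are set by the penalty
  rather than by effect size.  The planted-reactivation contrast (flavour
  rate ≥ 5× water) is unaffected and holds with a wide margin.
* Independent-neuron Poisson noise understates the false-positive
  clustering that shared variability produces in real recordings.
* The measured-response calibration of cross-day plasticity relies on the
  Poisson approximation to the consumption-count s.d.; strongly
  non-Poisson firing would bias the recovered slope by the corresponding
  variance ratio.
* The PCA orientation (neuron-space loadings with per-time-bin centring)
  is one of two defensible readings of the original description; variance
  fractions under the alternative orientation would differ.
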