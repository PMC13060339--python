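# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of the package.  Everything
here describes what the code does; no empirical claim is made beyond what
the test suite and `scripts/acceptance.py` themselves compute.

## 1. The categorical-loudness surface family

All three consumers of a loudness surface — the synthetic listeners, the
adaptive procedure's hypothesis grid, and the profile fitter — share one
parametric family:

    CU(f, L) = g( L − B · β(f, L); T(f), s )

* `g` is a two-segment piecewise-linear growth of categorical units
  (CU, 0–10) in level: CU = 0.5 at the threshold level `T` (the
  "Can't Hear"/"Very Soft" crossing), growing at half the main slope up
  to the knee at CU = 1.5 and at the main slope `s` (cat/dB) above it,
  clamped to [0, 10].  The shallow segment models the compressed
  near-threshold region; the upper segment carries the loudness-growth
  slope that the analyses report.
* `T(f)` is piecewise linear in log2 frequency.  Listeners specify it at
  the 10 audiometric frequencies (audiogram in dB HL plus fixed
  insert-earphone reference levels); the fitting family specifies it at
  three anchors (0.5, 1, 4 kHz) with linear extrapolation beyond them —
  this extrapolation is what produces 8-kHz predictions although 8 kHz is
  never sampled.
* `s` is shared across frequency.  The generator draws one slope per
  listener, so the shared-slope family is the correctly specified nested
  model; per-anchor slopes would also make the bandwidth-offset amplitude
  `B` unidentifiable from a single run, because over a typical sampled
  level window the offset is nearly linear in level and would be absorbed
  by a local slope change.
* `β(f, L)` is a unit-height Gaussian bump in (log2 f, L), centered at
  1 kHz and 60 dB SPL with spreads of 1 octave and 25.4 dB.  `B` (dB)
  scales it; `B = 0` for tones.

The level spread 25.4 dB is a calibrated constant: it makes a 7-dB-peak
quarter-octave offset average 4.08 dB across the ten category-boundary
levels of a representative default NH listener, so that the peak offset
(7 dB at 60 dB SPL) and the pooled-across-categories mixed-model contrast
(≈4.1 dB) are simultaneously consistent.

Categorical responses are `clamp(round(CU + ε), 0, 10)` with
`ε ~ N(0, response_sd)`, `response_sd` defaulting to 0.8 CU (no published
value exists; 0.8 CU produces plausible trial-to-trial scatter).  The
implied category probabilities are differences of Gaussian CDFs.

## 2. Synthetic cohorts

Defaults mirror the study conditions: 32 normal-hearing listeners
(PTA ≤ 15 dB HL) and 68 with slight-to-moderate loss (16–55 dB HL).
Audiograms are flat-to-sloping random profiles (base level, independent
high- and low-frequency tilts, 1.5-dB per-frequency jitter), resampled
until the PTA constraint holds.  Slopes are N(0.10, 0.01) cat/dB for NH
and N(0.12, 0.01) for HL — elevated thresholds plus steeper growth is the
recruitment pattern.  The bandwidth offset has a 7-dB NH quarter-octave
peak; one-octave noise receives 4/7 of the quarter-octave offset (3-dB
quarter-vs-octave difference at the peak), HL listeners 0.6 of the NH
offset, and each listener carries a multiplicative jitter
(N(1, 0.15), clipped).

What the generator does *not* emulate: lapses and response biases,
category-width idiosyncrasies, frequency-dependent slopes, age effects,
ear asymmetries, or any dependence of response noise on level.  Passing
recovery tests therefore shows that the pipeline is consistent and
unbiased *under this response model*, not that it is robust to every
behavior of real listeners.

## 3. The adaptive procedure

The hypothesis grid crosses per-anchor thresholds (0–60 dB SPL in 7.5-dB
steps), shared slopes (0.07–0.17 in 0.02 steps) and, for noise
conditions, bump amplitudes (0–10 dB in 2.5-dB steps).  The prior is
uniform.  Each trial selects, from a lattice of 9 frequencies
(0.25–6 kHz; 8 kHz is never presented) × 2-dB level steps (0–100 dB SPL),
the candidate maximizing the mutual information between the categorical
response and the hypothesis — equivalently the expected reduction in
posterior entropy; ties break to the lowest level, then lowest frequency.
The update is multiplicative Bayes with a 1e-6 likelihood floor
(robustness against responses far outside the model).

The default selection path quantizes each hypothesis's predicted CU into
256 bins so the per-trial cost is a sparse matrix–vector product (and,
once the posterior has concentrated, a histogram over the surviving
hypotheses only).  An exact path is kept alongside and the test suite
checks (i) the exact path equals a brute-force expected-entropy oracle
and (ii) the fast path's choice is within 0.02 nat of the optimum.
Grid spacing matters for placement quality: with 15-dB threshold spacing
the never-resolvable quantization mismatch dominates the information
landscape and the bump dimension is never probed; 7.5 dB restores
sensible sampling (most quarter-octave-condition trials land near 1 kHz).

After 50 trials the grid is refined: a new grid is built around the
posterior mode (thresholds ±9 dB in 3-dB steps per anchor, slope ±0.02 in
0.01 steps, bump 0–10 dB in 1.25-dB steps), the prior is reset to uniform
on it, and the 50 recorded trials are replayed through Bayes updates.
Without refinement the posterior reaches the coarse cell's resolution and
stops valuing low presentation levels, which leaves the threshold
extrapolated and the bump amplitude collinear with it; the refined grid
restores within-cell information gain, so the second half of a run spreads
over the listener's dynamic range.  Refined engines are cached and shared
by listeners whose coarse mode falls in the same cell.

## 4. Profile fitting and derived statistics

Profiles are maximum-a-posteriori fits of the same family (L-BFGS-B,
multi-start from the posterior mean, the posterior mode, and restarts in
the bump amplitude, which has a shallow likelihood).  Boundary k at each
of the 10 standard frequencies is the level where the fitted CU crosses
k − 0.5, solved by bisection; columns are projected onto strict
monotonicity if numerics ever violate it (with a warning).

Loudness functions are inverted by piecewise-linear interpolation between
the ten boundaries.  Loudness reduction at (f, L) is
`L − (equally loud tone level)`, positive when the narrow-band stimulus
is softer; spectral summation is the analogous quarter-vs-octave
difference.  Growth slopes regress boundary CU on boundary level using
boundaries 2–9 (the extremes are floor/ceiling-distorted); a `max_level`
option restricts the regression, e.g. below 80 dB SPL.

The mixed model is `level ~ group * bandwidth * category` with a random
intercept per participant, fitted by REML (statsmodels MixedLM) with
sum-to-zero factor coding.  Type III tests are reported as Wald F
statistics with large-sample denominator degrees of freedom; statsmodels
provides no Satterthwaite approximation, and with thousands of rows the
denominator df is immaterial for detection.  The quarter-vs-tone contrast
is a design-based linear contrast of the fixed effects, averaged over
categories for the NH group.

## 5. The ensemble-averaging loudness model

Chain: gammatone filterbank at Greenwood-mapped CFs (place span
5–31.5 mm, CFs ≈ 0.18–12.7 kHz, the numerically stable range of the
44.1-kHz IIR designs) → instantaneous broken-stick compression (knee
45 dB SPL, exponent 0.55) → half-wave rectification → 1-kHz IHC low-pass
→ three-store diffusion synapse → Poisson spiking in 1-ms bins →
ensemble averaging.

The synapse treats the three permeabilities (global→local 10/s,
local→immediate 300/s, release 0.9–60.9/s driven by a saturating function
of the drive) as conductances in series; the closed-form equilibrium flux
is `1/(1/p_g + 1/p_l + 1/p_r)`, which the tests compare against long
simulations.  Reservoir volumes set a rapid time constant of ~10 ms and a
short-term constant of ~60 ms; integration is implicit Euler (stable at
dt = 1 ms).  The resting equilibrium defines the spontaneous rate
(30 sp/s); saturation is ~270 sp/s.  Depletion during envelope peaks with
slow recovery during dips — the rapid constant is deliberately
commensurate with narrow-band envelope periods — is one of the two
mechanisms converting envelope fluctuation into loudness loss; the other
is the concavity of the compressive stages.

Ensembles tile the place axis in 2-mm non-overlapping groups of channels
(14 ensembles at 70 channels; at the reduced 20-channel setting every
channel is its own ensemble).  N1 fibers per ensemble (default 50) are
spread evenly over the ensemble's channels; the fiber mean of N1 iid
Poisson fibers is sampled exactly as a scaled Poisson.  Loudness is

    L = Σ_ensembles  c · [ mean_t ( mean_fibers R )^p ]^q

Fiber averaging precedes the compressive power law: per-fiber 1-ms counts
are almost always 0 or 1, and any power law is the identity on {0, 1}, so
compressing per fiber would be inert; averaging first preserves the
Jensen mechanism (fluctuating ensemble rates lose loudness under a
concave `x^p`).  Time averaging uses the steady-state window
(0.2–0.8 s), excluding the ramps.

**Calibration.**  The expansion scale `c` cannot affect an equal-loudness
*match* (it cancels), so the two calibration targets are met with the two
exponents: for each candidate `p`, `q` is solved (Brent) so that the
1-kHz tone's log-loudness grows at ln 2 per 10 dB between 50 and 70 dB
SPL; `p` is then solved so that flat quarter-octave noise at
(1 kHz, 60 dB) matches a tone ~7 dB lower; finally `c` anchors 1 sone at
a 40-dB 1-kHz tone.  At the reduced setting this lands near `p ≈ 0.08`,
`q ≈ 70` — functionally a log-like compression undone by a strong
expansion; the pair should be read as a calibrated operator, not as
physiology.  Equal-loudness matches interpolate the *geometric-mean*
loudness of the reference tone (matching mean-log on both sides, so
trial-to-trial skew cancels), and the shared reference curve is averaged
over 4× as many Poisson draws as the test replicates, because its error
would otherwise bias every replicate of a run coherently.  All
calibration searches reuse cached Poisson ensemble draws, so the whole
procedure costs little more than the underlying rate simulations.

The model's untuned prediction for the five-tone complex (which has a
smaller envelope-fluctuation index, ~0.47, than Gaussian band noise,
~0.53) comes out around 4–5.5 dB of reduction at the reduced setting.
Low-noise noise is a caution: its *broadband* envelope is nearly flat
(index ~0.06), but cochlear filters narrower than the stimulus band
regenerate envelope fluctuations at their outputs, so its modeled
reduction is close to that of ordinary band noise — the reduction tracks
the fluctuation *seen by the periphery*, not the broadband index.
Note the five components are log-spaced and hence non-harmonic, so the
deterministic component phases (Schroeder by default) barely affect the
envelope statistics over a 1-s stimulus; zero phases would not produce a
flat envelope either.

## 6. Problem sizes and seeds

Simulation sizes used by the test suite and the acceptance script are the
package's own defaults: the full cohort run is 32 + 68 listeners × 3
conditions × 100 trials; replicate cohorts for interaction-detection use
16 + 34 listeners with the tone and quarter-octave conditions (a
half-size cohort chosen by a power calculation on the full-cohort
contrast noise); the ensemble model runs at 20 channels × 20 fibers with
10 Monte-Carlo replicates.  Every random stage is driven by explicit
integer seeds (numpy `SeedSequence` children of the experiment seed), and
rerunning a configuration reproduces byte-identical artifacts.

## 7. Known limitations

* The periphery is a linear filterbank with a static compressive
  nonlinearity — no suppression, no level-dependent tuning, no efferents,
  no fine-structure/phase-locking code.
* One fiber type per channel (no spontaneous-rate classes); Poisson
  spiking without refractoriness.
* The adaptive procedure's greedy information gain concentrates sampling
  where hypotheses disagree most; near-threshold levels are visited less
  than a human-subjects protocol might, so absolute threshold-boundary
  estimates lean on the family's structure.
* The data-driven surface family is the generator's own family;
  recovery results quantify pipeline consistency, not robustness to
  model misspecification.
* Satterthwaite degrees of freedom are not computed (large-sample Wald
  tests instead).
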