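# Methods

This package implements a source-level analysis of the 40 Hz auditory
steady-state response (ASSR) and the sustained event-related field
(ERF) in a developmental MEG cohort, together with a synthetic cohort
generator that reproduces the statistical structure such a study
assumes. The pipeline starts at clean source-space epochs: sensor
preprocessing (artifact removal, filtering, head modelling, inverse
solution) is upstream of this package and is replaced here by the
generator or by an externally prepared HDF5 epoch container.

## Stimulus model

The stimulus is a 1 s amplitude-modulated tone,

    A(t) = sin(2π f_c t) · (1 + m·cos(2π f_m t)),

with carrier f_c = 1000 Hz, modulation depth m = 1 and modulation rate
f_m = 40 Hz at 44.1 kHz. Its spectrum is the carrier plus sidebands at
f_c ± f_m with relative magnitude m/2, which `stimgen.validate_spectrum`
checks by DFT. The sample grid starts at t = 0 with
`round(duration · rate)` samples. No onset/offset ramp or dither is
applied by default (a cosine ramp is available but off); WAV export
peak-normalizes to 0.95 full scale, since presentation level (dB SPL)
is a hardware calibration outside software scope.

## Generative model of the synthetic cohort

Each simulated child has a trials × vertices × time epoch array over a
−1.5…+1.5 s window. Vertex clouds are jittered cubic grids (spacing
4 mm, jitter ±1 mm) around per-hemisphere centroids placed at
grand-average auditory-cortex locations in MNI-like coordinates, left
(−49.47, −22.25, 6.53) mm and right (52.46, −23.85, 10.51) mm, so
coordinate summaries come out on a realistic scale.

The single-trial time course at vertex v is

    x_r(v, t) = G(v) · [ a_erf · env(t − δ_r) + a_assr · gate(t) · sin(2π·40·t + φ_r) ] + ε(t)

* `env`/`gate`: 0 before stimulus onset, raised-cosine rise over
  0–200 ms (the auditory cortex reaches a steady state after roughly
  200 ms of 40 Hz entrainment), plateau 1 until the 1 s offset,
  exponential decay (τ = 100 ms) after it.
* φ_r ~ von Mises(0, κ), one draw per trial and hemisphere. The von
  Mises concentration κ is the latent that produces phase locking; it
  was chosen because it is the standard circular-statistics dispersion
  model and gives the closed-form expected resultant I₁(κ)/I₀(κ),
  which both the ITPC and the evoked-attenuation tests exploit.
  κ grows linearly with age and is larger on the right:
  κ_left = 0.4 + 0.5·(age − 7), κ_right = κ_left + 0.8. These defaults
  keep both hemispheres on the informative part of the resultant curve
  (≈0.2–0.85) over the 7–12-year age range; concentrations ≥ 1e6 are
  treated as perfect locking (φ_r = 0 exactly).
* a_erf = 3.0 − 0.3·(age − 7) source units: the sustained field
  declines with age. The component is simulated unipolar; polarity is
  immaterial because the downstream measure rectifies z-scores.
  Trial-wise onset latency jitter δ_r (±5 ms by default, configurable
  to ±20 ms) makes averaging attenuation realistic.
* G(v): Gaussian spatial profile (σ = 10 mm by default) centred on the
  subject's true peak; the right-hemisphere peak's Y coordinate drifts
  posteriorly by 2 mm/year, emulating an age-dependent topography.
* ε(t): white noise (SD 1) plus 1/f-power noise (SD 1), independent
  across trials and vertices.

Ages are uniform on 7.06–12.03 years; trial counts uniform on 72–87.
The default sampling rate is 500 Hz rather than the 1000 Hz of a real
recording — the 35–45 Hz analysis retains a ≥ 6× Nyquist margin and the
suite stays fast; 1000 Hz is a configuration away. Reproducibility
uses one master seed with per-subject streams
`default_rng([seed, subject_index])`, so any subject can be
regenerated alone.

What the generator does *not* emulate: sensor-space forward fields and
inverse-solution leakage (noise is spatially independent, real source
estimates are not), induced baseline gamma, artifacts, and any
behavioural covariates. Passing tests therefore demonstrate that the
analysis machinery recovers the assumed generative structure, not that
real cortical data satisfy those assumptions.

## Time-frequency analysis and ITPC

Morlet kernels are parameterised by their *time resolution*: the FWHM
of the Gaussian envelope at the central frequency, 0.3 s at 40 Hz, so
σ_t = FWHM/(2√(2 ln 2)) ≈ 0.127 s, and σ_t(f) = σ_t(f₀)·f₀/f (constant
cycles). This FWHM reading of "time resolution" is the module's most
consequential convention and is pinned by a test measuring the
constructed kernel's envelope on the sample grid. Kernels are
energy-normalised, truncated at ±5σ, and applied by zero-padded FFT
convolution with exact center alignment; coefficients within one
envelope FWHM of an epoch edge are flagged invalid, and window
operations refuse to touch them. All analysis windows sit ≥ 0.6 s from
the epoch edges, so flagging never intersects analysis.

ITPC at each (vertex, frequency, time) is the resultant length of the
trial-wise unit phase vectors, ITPC = n⁻¹|Σ_r e^{i k_{t,r}}| ∈ [0, 1].
TF maps are normalised per vertex and frequency as percent change from
the −500…−200 ms baseline mean, (x − mean)/mean·100 (a baseline ending
well before onset avoids wavelet edge and smearing effects). The
scalar per vertex is the mean over the closed 39–41 Hz × 200–900 ms
window; the default 1 Hz grid from 35–45 Hz places bins exactly at
39/40/41. Normalisation precedes window averaging; the two orders
agree only when baseline means are equal across frequencies, and the
test suite documents the chosen order.

The expected baseline ITPC of n noise-driven trials is ≈ √(π/(4n))
(≈ 0.10 at n = 80), so normalized steady-state ITPC values land in the
hundreds of percent — the scale on which the cohort statistics operate.

## Sustained-field amplitude

Per trial and vertex the −100…−2 ms mean is subtracted (DC correction);
trials are averaged; each vertex's evoked time course is z-scored
against its own −100…−2 ms baseline (sample SD, n − 1); the amplitude
is the mean of |z| over 200–1000 ms (rectify-then-average, making the
measure polarity-free); finally a Gaussian spatial smoother
(FWHM 3 mm, σ = FWHM/(2√(2 ln 2)), weights renormalised to sum 1) acts
on the per-vertex amplitudes. Two deliberate simplifications: the
smoother uses Euclidean distances on the vertex cloud (no cortical
mesh exists in scope, and at 3 mm FWHM geodesic and Euclidean
distances are close), and smoothing is applied after window averaging
(the reverse order is a configuration change away).

With von Mises phase jitter, the evoked 40 Hz amplitude after
averaging shrinks by the factor I₁(κ)/I₀(κ) — the same circular
statistic ITPC estimates — which links the two branches of the
pipeline and is asserted by a Monte-Carlo test.

## ROI selection

Per child and hemisphere, the k = 15 vertices with the highest
window-averaged normalized 40 Hz ITPC form the ROI (ties broken by
ascending vertex id; a hemisphere with fewer than k vertices
contributes all of them with a warning). Hemisphere ITPC, ERF
amplitude and coordinates are arithmetic means over that set, and the
sustained field is extracted at the identical ITPC-selected vertices —
never independently peak-picked — so both measures describe the same
patch. The per-child coordinate is the mean of the selected vertices
(not the single peak).

A consequence of ITPC's amplitude invariance deserves emphasis: with
no noise, every vertex shows ITPC = 1 and the selection map is flat —
the spatial profile grades the ITPC map only through vertex-level
phase SNR. Peak recovery is therefore tested under graded-SNR
conditions (sharp source, sub-unit amplitude against unit noise,
strong locking, many trials), where the selected centroid typically
lands within one grid spacing of the true peak; a "noiseless recovery"
check would be vacuous, and the percent-change baseline denominator
keeps an irreducible multiplicative scatter per vertex at any trial
count, so recovery rates plateau near ~90%, not 100%.

## Statistical layer

The central model is

    ITPC ~ 1 + Hemisphere/ERF + (1 | subject)

with the intercept on the right hemisphere and the ERF slope nested in
each hemisphere, coded explicitly as
{1, 1[left], ERF·1[left], ERF·1[right]} to avoid formula-dialect
ambiguity. Fitting is REML via statsmodels `MixedLM`; because gradient
optimizers can stall (or falsely converge) when the random-intercept
variance sits on the 0 boundary, a derivative-free Powell refit always
runs and the better REML criterion wins. Fixed-effect standard errors
are the model-based GLS form √diag((XᵀV̂⁻¹X)⁻¹) at the fitted variance
components — well defined on the boundary, where the numerical Hessian
is not, and equal to the classical lmer output. p-values use t with
the residual-df approximation df = n_obs − n_fixed (Satterthwaite is
not available on this backend). ICC = τ²/(τ² + σ²); marginal and
conditional R² follow the Nakagawa variance decomposition. At the
τ² = 0 boundary the fixed effects reduce to OLS exactly, which the
suite checks to 1e−6.

Age associations are two-sided Pearson correlations per hemisphere.
Bonferroni correction is applied within declared families: the
coordinate-by-age family has 6 tests (X, Y, Z × 2 hemispheres); the
ITPC-by-age and ERF-by-age correlations are reported uncorrected
(family size 1), mirroring standard practice for a-priori directional
hypotheses. Hemispheric summaries use sample SD (n − 1), reported as
missing for a single observation.

## Problem sizes for repeated-simulation studies

Replicate studies use deliberately reduced cohorts, chosen once:

* **Smoke/recovery scale** — 30 subjects × 40 trials × 8 vertices per
  hemisphere at 250 Hz, analysis grid 38–43 Hz, k = 5, single-precision
  convolution. Used to estimate the joint recovery rate of the built-in
  age effects over 100 seeds.
* **Null scale** — 12 subjects × 20 trials × 6 vertices, k = 4, all
  slopes zero. Used for 400-seed type-I calibration of the
  age-correlation tests.
* **Table-shape check** — the full 30-subject, 72–87-trial study layout
  with a 20-vertex-per-hemisphere cloud at 500 Hz.

The 250 Hz replicate rate keeps a > 3× Nyquist margin over the 45 Hz
analysis ceiling, and trimming the analysis grid to 38–43 Hz changes
nothing downstream because normalisation is per frequency and the
averaging band is 39–41 Hz.

## Numerical choices and edge cases

* Window membership is closed-interval, by bin center, everywhere.
* A zero-magnitude wavelet coefficient has no phase: ITPC computation
  raises by default (synthetic data never produces exact zeros once
  any noise is present) or can exclude the trial at that bin with a
  local count adjustment.
* Percent-change normalisation raises, naming the vertex and
  frequency, when a baseline mean is ~0; z-scoring raises on a
  zero-SD baseline vertex.
* Rank-deficient fixed-effect designs (e.g. an all-zero ERF column)
  raise with the aliased terms listed.
* The fused single-precision ITPC path agrees with the double-precision
  reference to ~1e−6 — far below the trial-sampling noise floor of the
  statistic (~1e−2 at 80 trials).
* Configurations are validated (windows inside the epoch, band inside
  the grid, grid below Nyquist) before any simulation starts, and every
  output carries a SHA-256 hash of the full configuration plus the
  master seed.

## Known limitations

* The generator's noise is white + 1/f and spatially independent;
  real source-space noise is spatially correlated through the inverse
  operator, so real-data ROI selection behaves differently near the
  ROI boundary.
* The ERF branch analyses only the sustained component; transient
  M50/M100 peaks are present in real data and would require their own
  latency analysis.
* Mixed-model p-values use residual df, which is mildly liberal for
  small subject counts; with 30 subjects and 60 observations the
  difference from Satterthwaite is small but nonzero.
* Euclidean (not geodesic) smoothing distances, as noted above.
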