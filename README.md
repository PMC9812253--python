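# assr-pipeline

Source-level analysis of the **40 Hz auditory steady-state response
(ASSR)** and the **sustained event-related field (ERF)** for
developmental MEG studies, with a synthetic cohort generator providing
ground truth for end-to-end validation.

When a child hears a 1000 Hz tone amplitude-modulated at 40 Hz, the
auditory cortex entrains at the modulation rate. The strength of that
entrainment is measured by **inter-trial phase consistency** (ITPC,
also called the phase-locking factor): at each source vertex, frequency
f and time t, the resultant length of the unit phase vectors across the
n trials,

    ITPC(f, t) = (1/n) | Σ_{r=1..n} exp(i·k_{t,r}) | ∈ [0, 1],

with phases k taken from Morlet-wavelet coefficients (central frequency
40 Hz, envelope FWHM 0.3 s). ITPC maps are normalized as percent change
from the −500…−200 ms baseline, averaged over 39–41 Hz × 200–900 ms,
and the 15 highest-ITPC vertices per hemisphere form each child's
individual ROI. The sustained ERF is the mean rectified z-score
(baseline −100…−2 ms) over 200–1000 ms at those same vertices. The
statistical layer fits the mixed model

    ITPC ~ 1 + Hemisphere/ERF + (1 | subject)      (intercept = right)

by REML and correlates ITPC, ERF amplitude and ROI coordinates with age
(Pearson, Bonferroni within declared families). In typical
developmental data this yields right-hemisphere dominance of the ASSR,
an age-related ITPC *increase*, an age-related sustained-field
*decrease*, and a negative ITPC–ERF coupling on the right — the pattern
the synthetic generator builds in and the test suite recovers.

Because no public dataset accompanies this paradigm, all inputs are
synthetic: the generator draws trial phases from a von Mises
distribution whose concentration κ grows with age (right > left),
scales a sustained plateau that declines with age, and adds white + 1/f
noise on a spatial Gaussian profile over MNI-like vertex clouds.
Externally preprocessed source epochs can enter the identical pipeline
through a documented HDF5 container (see `assr.synthcohort`).

## Worked example

```python
from assr.pipeline import RunConfig, run_all
from assr.synthcohort import CohortParams

config = RunConfig(
    cohort=CohortParams(n_vertices_per_hemisphere=20, seed=7),
    single_precision=True,
).with_seed(7)            # 30 children, 72-87 trials each, 500 Hz
bundle = run_all(config)

m = bundle["mixed_model"]
hs = bundle["hemispheric_summary"]
print(f"observations: {m.n_observations}  (subjects: {m.n_subjects})")
print(f"mean normalized ITPC  left {hs.loc['left', ('itpc', 'mean')]:.1f}  "
      f"right {hs.loc['right', ('itpc', 'mean')]:.1f}")
print(f"Hemisphere_Left beta = {m.fixed_effects['Hemisphere_Left']['estimate']:.1f}, "
      f"right-nested ERF slope = "
      f"{m.fixed_effects['Hemisphere_Right:Amplitude']['estimate']:.1f}")
for c in bundle["age_correlations"]:
    print(f"age ~ {c.variable:4s} ({c.hemisphere:5s}): r = {c.r:+.2f}, p = {c.p_raw:.4f}")
```

prints (seed 7):

```
observations: 60  (subjects: 30)
mean normalized ITPC  left 676.7  right 860.2
Hemisphere_Left beta = 598.6, right-nested ERF slope = -27.2
age ~ itpc (left ): r = +0.88, p = 0.0000
age ~ itpc (right): r = +0.70, p = 0.0000
age ~ erf  (left ): r = -0.99, p = 0.0000
age ~ erf  (right): r = -0.99, p = 0.0000
```

Reading: the analysis table has one row per child × hemisphere
(30 × 2 = 60); normalized ITPC sits in the hundreds of percent because
the pre-stimulus baseline resultant of ~80 noise-driven trials is only
≈ √(π/320) ≈ 0.10; the right hemisphere phase-locks more strongly than
the left (860 vs 677); ITPC rises and the sustained field falls with
age, and higher right-hemisphere ITPC goes with a weaker sustained
field (negative nested slope). Note the hemisphere *coefficient* is
the left–right contrast extrapolated to ERF = 0 — far outside the
observed ERF range — so with nested slopes its sign need not match the
difference in hemisphere means.

The same pipeline is scriptable from the shell:

```bash
assr stimgen -o tone.wav                     # the 40 Hz AM stimulus
assr simulate --seed 7 -o cohort.h5          # synthetic cohort (HDF5)
assr roi cohort.h5 -k 15 -o table.csv        # TFR + ERF + ROI table
assr stats table.csv -o results/             # mixed model + correlations
assr run --seed 7 -o results/                # everything in one step
```

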