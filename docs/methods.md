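# Methods

This note documents the models, conventions and design choices behind
`gaitersp`. It covers (1) the synthetic cohort generator, (2) the
epoching and artifact-handling conventions, (3) the time-frequency and
ERSP computations, (4) the band/ROI/window aggregation, (5) the
split-plot ANOVA machinery, and (6) the simulation studies the package
uses to demonstrate that the full chain recovers known effects at
calibrated error rates. No empirical claim in this note goes beyond what
the test suite and `scripts/acceptance.py` themselves compute.

## 1. The task model and the synthetic cohort generator

The generator (`gaitersp.simulate`) emulates a mobile-EEG obstacle-avoidance
experiment: participants walk a 6 m path; motion sensors (a laser beam
0.5 m after the path start by default) trigger the projection of an
obstacle that must be stepped over. Three conditions are modeled:

* `no_adjustment` — free walking, no obstacle;
* `preset` — obstacle visible from trial onset, 2.5 m beyond the beam;
* `online` — obstacle appears only when the walker breaks the beam,
  at 1.6 m or 3.1 m beyond it (drawn uniformly per trial).

Each trial records four events — `start`, `approach` (the beam),
`crossing` (stepping over the obstacle; absent in free walking) and
`stop` — with latencies that follow from a per-trial walking speed drawn
from a group x condition normal distribution truncated at 0.3 m/s
(rejection sampling, so the draw is exactly truncated-normal). The
default speed means/SDs are those of the study population the package
models: a parkinsonian-like group (PD, ~0.81 m/s in all conditions) and
a neurotypical-control-like group (NC, 1.06–1.16 m/s). Subjects complete
160 trials in 4 blocks by default (conditions allocated near-equally and
shuffled per subject); the scaled-down study configuration uses 40.

The continuous signal per subject is, in uV:

1. **1/f background** — channel-independent Gaussian noise shaped to a
   `f^-1` power spectral density above 1 Hz (flat below), scaled to
   15 uV RMS per channel. 15 uV is a realistic broadband amplitude for
   ambulatory scalp EEG after component-based cleaning; the slope and
   scale are configurable.
2. **Cadence-locked gait artifact** — a sinusoid at the step frequency
   (speed / 0.65 m step length, i.e. ~1.2–1.8 Hz) plus a 0.3-amplitude
   second harmonic, 2 uV by default, present from `start` to `stop` with
   50 ms raised-cosine ramps. It is deliberately small relative to the
   neural effects: it stresses the pipeline (it is time-locked to gait,
   not to the crossing) without dominating it, and its harmonics stay
   below the theta band.
3. **Oscillatory effects**, each multiplied by a per-effect attenuation
   factor in [0, 1] for the PD-like group (1 = no group difference):
   * a **theta burst**: Hann-windowed 6 Hz sinusoid, 5 uV, 2.0 s,
     starting at obstacle appearance — in the online condition only,
     anchored at `approach`. The 2 s duration makes the injected
     elevation span the interval from obstacle appearance to the
     crossing at typical speeds, i.e. a sustained planning-phase theta
     increase rather than a brief transient; this matches the reported
     phenomenology this generator is meant to emulate (online-condition
     group differences across several successive planning windows).
   * **planning beta suppression** (obstacle conditions): the 13–35 Hz
     component of the signal itself is band-pass filtered (4th-order
     Butterworth, zero-phase) and a `-0.3 x` windowed copy is added over
     `approach -> crossing`, changing beta band amplitude by exactly the
     configured fraction (variance by `(1 + g)^2`).
   * **post-crossing beta rebound**: `+0.4 x` over [0, 0.6] s after the
     crossing in obstacle conditions, half that gain in free walking
     (anchored at `approach + 2 s` there, the same anchor the analysis
     uses as virtual crossing).
   * **post-crossing theta increase**: `+0.3 x` over the same window.

   Implementing fractional band changes as scaled copies of the
   signal's own band-limited content makes the injected effect sizes
   verifiable: band variance over an effect window rises by
   `(1 + gain)^2` up to filter leakage and the 50 ms window ramps, which
   the tests confirm to a few percent.

Cohorts are a pure function of the configuration (including its seed):
per-subject child seeds are spawned from a root `SeedSequence`, and a
repeated run is byte-identical. What the generator does **not** model:
ocular/cardiac artifacts or ICA-separable sources, volume conduction and
realistic channel covariance (channels are independent noise plus
identical effects), biomechanics beyond the cadence sinusoid, and
subject-level random effects in walking speed (Table-level SDs act at
the trial level; subject means differ only through sampling). Passing
recovery tests therefore show that the *analysis chain* is correct and
sensitive at realistic SNR — not that it is robust to every artifact
class of real ambulatory recordings.

## 2. Epoching conventions

Epochs are cut on the half-open window [-5.0, +3.0) s around each
crossing at the session sampling rate (exactly `8 fs` samples; sample
`round(t_c * fs)` is time 0, so the lock is within half a sample).
Free-walking trials first receive a **virtual crossing** at
`approach + 2.000 s`; applying the operation twice is an error, so the
marker can never be silently double-shifted. Trials whose window exceeds
the recording are dropped and logged, not zero-padded — padding would
bias the whole-epoch baseline.

The visual artifact screening used with real recordings is replaced by a
deterministic criterion: an epoch is rejected when any channel's
peak-to-peak amplitude exceeds 1000 uV or falls below 0.1 uV (flat
channel). Both thresholds are configurable; rejection is per epoch,
mirroring trial-level exclusion. The criterion is not calibrated to
reproduce any particular retention count on real data.

Walking speed is path length divided by the `start -> stop` interval,
computed from event timestamps; on generated data this recovers the
sampled speed to ~1e-12 relative.

## 3. Spectrograms, time-warping, ERSP

**Decomposition.** Morlet wavelets on a 3–40 Hz grid (1 Hz steps by
default), with cycles `clip(f / 2, 3, 10)` — frequency resolution scales
with frequency, and the lowest-frequency wavelet spans 1 s. Power is
reported as dB (`10 log10`), the package-wide convention. Wavelet
construction is delegated to `mne.time_frequency.morlet`; the
convolution is a batched FFT with decimation performed by spectral
folding (mathematically identical to subsampling the full convolution)
because the simulation studies decompose ~240 000 epoch-channels. The
implementation agrees with `mne.time_frequency.tfr_array_morlet` to
~1e-12 relative in double precision and ~1e-4 in the default single
precision (≈0.002 dB, far below any quantity interpreted here); the
equivalence is asserted in the test suite. The spectrogram time axis is
decimated to at most 50 ms steps. Samples closer to an epoch edge than
half the nominal wavelet extent (`n_cycles / 2f`, maximized over
frequencies: 0.5 s at 3 Hz) are flagged as edge-contaminated, and
baselines and analysis windows must avoid them.

**Time-warping.** To average trials with different walking speeds, each
trial's spectrogram is remapped along time by a piecewise-linear
monotone function that sends the trial's `start` and `approach`
latencies to the cohort-pooled median latencies, with the crossing
(t = 0) and the epoch edges as fixed anchors; values are resampled onto
the original grid by linear interpolation along time only. Warping both
events (not `approach` alone) keeps the planning windows — which are
anchored at the median `start` — commensurable across trials. Pooling
is across all trials, subjects, groups and conditions by default (one
common warped timeline), with per-condition pooling behind a flag. An
anchor that falls outside a trial's epoch (very slow walkers) is dropped
for that trial. An identity warp is exact; a constant field is a fixed
point; anchors land on their targets within one grid step (exactly, when
the anchors are grid points).

**ERSP.** For each subject x condition, every trial's mean dB over the
baseline interval — the whole usable epoch, [-4.5, +2.0] s by default —
is subtracted per channel and frequency, and the corrected spectrograms
are averaged. This forces the ERSP to average exactly zero over the
baseline (the module's hardest invariant, held to 1e-10 dB; the
averaging is done in double precision even when trial spectrograms are
stored as float32). An alternative reading of a "mean baseline
spectrum" — subtracting the across-trial mean baseline instead — yields
the *identical* trial-averaged ERSP (the two differ per trial by a
term whose trial average is zero), so the ambiguity is immaterial; both
modes exist behind a flag and a test proves their equivalence.

## 4. Aggregation

Bands: theta 4–7 Hz, beta 13–35 Hz, both edges inclusive (a bin at a
band edge belongs to the band). ROIs: frontal (FC1, FC2, Fz), central
(CP1, CP2, Cz), posterior (P3, P4, POz). The planning phase
[median start, 0) is split into four equal consecutive windows T1–T4 —
the phase's extent is genuinely ambiguous (it could start at `approach`
instead), and anchoring at the median `start` puts obstacle appearance
inside the early windows under the default geometry while keeping four
non-degenerate windows; boundaries are fully configurable. Resetting
windows are fixed: T5 [0, 0.6) s, T6 [0.6, 1.2) s. Window membership is
half-open, matching the epoching convention. A cell value is the plain
arithmetic mean of ERSP dB over ROI channels x in-band frequency bins x
in-window time samples, and the resulting tidy table must be fully
crossed (validated; missing ROI channels are named in the error).

## 5. Split-plot ANOVA, Greenhouse-Geisser, post hoc tests

`mixed_anova` handles one between-subject factor (group) and any number
of fully crossed within-subject factors. Implementation: the within
cells are projected onto orthonormal Helmert contrasts (Kronecker
products per effect); for each within-involving effect the contrast
scores are regressed on the between design (intercept + effect-coded
group), the effect is the intercept test, its group interaction is the
group test, and the shared error stratum is the residual — the
univariate mixed-model approach, equivalent for equal group sizes to the
classical effect x subject(group) sums-of-squares decomposition (the
test suite verifies every F, df and partial eta^2 against a brute-force
inclusion-exclusion oracle on 50 random designs, along with total-SS
conservation). Group sizes may differ (e.g. 14 vs 17) as long as the
within design is complete; hypotheses are then Type-III-style
(unweighted means), and total-SS conservation no longer holds — which is
expected, not a defect.

Greenhouse-Geisser epsilon is computed per within-involving effect from
the pooled error covariance of its contrast scores,
`eps = tr(M)^2 / (q tr(M^2))`, bounded by [1/q, 1] with q the effect's
degrees of freedom; it equals 1 exactly for two-level effects and
attains 1/q for rank-one data. Because the sphericity test that would
normally gate the correction is unspecified for this design, the
correction is applied **unconditionally** to every within-involving
effect with more than two levels — deterministic and conservative —
and uncorrected p-values are reported alongside. Degenerate zero-variance
strata report F = 0, p = 1 rather than erroring, so null sweeps never
crash.

Post hoc tests are classical (pooled-variance independent,
difference-score paired) t-tests, Bonferroni-adjusted over the declared
contrast family (`p_adj = min(1, m p)`); identical samples return t = 0,
p = 1. The walking-speed analysis is the 3 (condition) x 2 (group)
split-plot ANOVA on per-subject condition means plus the three
per-condition between-group comparisons as one Bonferroni family.

## 6. Simulation studies and their problem sizes

The recovery studies run the entire chain (simulate -> epoch -> TFR ->
warp -> ERSP -> aggregate -> ANOVA) on a scaled-down configuration
chosen to keep hundreds of replicates tractable on one CPU: 15 subjects
per group, 40 trials per subject, 128 Hz, the nine ROI electrodes only
(aggregation uses no others), a 2 Hz frequency grid over 3–39 Hz (both
band edges land on bins; a 1 Hz grid was verified to give the same
detection rate), and ~47 ms spectrogram steps.

* **Theta interaction recovery** — 100 cohorts with the PD-like theta
  burst halved (attenuation 0.5): the planning-phase theta
  condition x group interaction (GG-corrected) is expected significant
  at alpha = 0.05 in >= 80 of 100; with attenuation 1.0 the rejection
  rate must stay within the binomial calibration band [1 %, 11 %].
* **Beta rebound recovery** — on the same cohorts (the +0.4 rebound is
  at its default there): central-ROI T5 beta must be positive and exceed
  the free-walking value in >= 90 of 100; under the null, per-window
  group t-tests on T5/T6 beta must reject at no more than the
  calibrated rate.
* **Speed analysis** — 100 cohorts of 14 + 17 subjects drawn from the
  default group speeds (12 trials per condition suffice, since with
  trial-level speed sampling the subject-mean SE shrinks as
  `sd/sqrt(trials)`): the group main effect is expected at p < 0.001 in
  >= 95 of 100; with identical group distributions the alpha = 0.05
  rejection rate must fall in [1 %, 11 %].
* **Determinism** — two end-to-end pipeline runs with the same config
  and seed must produce byte-identical CSV/JSON/TSV artifacts (figures
  and the timing log are excluded).

`scripts/acceptance.py --seed N --out results/acceptance.json`
recomputes all of these from scratch, plus the exact invariants
(ERSP baseline, warp errors, SS conservation, GG bounds), deriving every
stream of randomness from the given seed.

## 7. Numerical choices and degenerate inputs

* dB throughout; an all-zero epoch (log of zero power) is an error, not
  a NaN.
* Truncated-normal speeds via rejection sampling; the floor (0.3 m/s)
  guards physicality even for the high-variance NC online condition.
* Effect windows use 50 ms raised-cosine ramps (ramps shrink for very
  short windows); band extraction for injection runs in single
  precision.
* The EDF writer quantizes to 16 bits with per-channel symmetric
  physical ranges; round-trip error is bounded by one digitization step
  and checked through `mne.io.read_raw_edf` as an independent parser.
* Warp anchors must be strictly inside the epoch, non-zero, strictly
  increasing, and on the same side of the crossing as their targets.
* `gg_epsilon` requires at least as many subjects as levels; rank
  deficiency maps to the lower bound rather than an error.

## 8. Known limitations

* Channel independence means scalp topography carries no information;
  ROI averaging is exercised structurally, not physiologically.
* The automatic rejection criterion models amplitude artifacts only.
* No inter-trial coherence, multitaper or Hilbert alternatives; no
  linear mixed-effects models or cluster-based permutation statistics.
* With unequal group sizes the ANOVA's unweighted-means hypotheses are
  one of several defensible conventions (they match common statistical
  packages' defaults for this design).
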