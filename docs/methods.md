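# Methods

## Signal model and BGA extraction

Trial-epoched voltages (µV) are processed per electrode. Line noise is
removed with second-order IIR notches at 60 and 120 Hz (2 Hz bandwidth)
before band-passing, because a 60 Hz residual sits inside the gamma band
of interest. The 60–120 Hz band-pass is a minimum-order elliptic design
with 0.5 dB passband ripple and ≥ 30 dB stopband attenuation at 55/125 Hz
transition edges; the exact order/ripple of the original analysis chain is
not documented, so the design is specified by its constraints rather than
its coefficients. All filters run forward–backward (`sosfiltfilt`), which
doubles the attenuation and ripple in dB but, crucially, zeroes the group
delay so downstream onset-latency estimates are not biased. Epochs are
reflection-padded by 0.5 s around filtering to suppress edge transients.

The envelope is the magnitude of the Hilbert analytic signal, smoothed
with a 5th-order Savitzky–Golay FIR. The published frame length of
"155 samples" is ambiguous across the two sampling rates in use (1000 and
2000 Hz); the default interprets it as a fixed **155 ms duration**
converted to an odd sample count, which keeps the smoothing bandwidth
rate-independent, with `frame_mode="samples"` available for exact
sample-count replication.

"Percent-power change" names a power quantity while the smoothing is
applied to the analytic amplitude; the implementation follows the stated
operation order — smooth the amplitude, then square to power — before
normalizing: `100 · (P(t) − P̄_base)/P̄_base` with the baseline mean taken
over −700…−200 ms. An `quantity="amplitude"` option exists for
sensitivity checks. Percent change is scale-free (gain invariance is a
tested property), so electrode-level amplifier gain cannot leak into the
statistics.

## d′, permutation null, FDR

The selectivity statistic per electrode and category *j* is

d′ = (u_j − mean_{i≠j} u_i) / sqrt(½ (o_j² + mean_{i≠j} o_i²)),

where u/o are the mean and across-trial sample SD (ddof = 1; the SD
convention is not documented upstream, the unbiased default is used) of
the 100–400 ms window-mean BGA. The denominator uses the square root of
the averaged variances — the standard d′ definition — although the
published equation renders without a visible radical.

The null shuffles category labels jointly across all trials (preserving
per-category counts) and recomputes all five d′ values; 10,000 shuffles
by default. The p-value is the **strictly greater** exceedance fraction,
exactly as the estimator is defined in the source analysis: p = 0 is
attainable and ties count as not-greater. A `conservative=True` option
applies the (+1)/(n+1) correction. Shuffling operates on the window-mean
scalars, not the full time-series pipeline — the only reading under which
10,000 recomputations are feasible.

FDR control is Benjamini–Hochberg step-up at q = 0.01 within each
region × hemisphere family, pooling categories and electrodes; word tests
exist only in left-hemisphere families because the word task was run only
in the left-hemisphere cohort. An electrode may be flagged for multiple
categories.

## Onset latency

Pointwise contrasts are **unpaired two-tailed Welch t-tests** of the
target category's trials against the pooled other-category trials. The
source description ("paired two-way t-tests") cannot mean trial pairing —
trial counts differ across categories — so "two-way" is read as
two-tailed; a pooled-variance Student option is provided. Time points
where both groups have zero variance get p = 1. BH correction runs across
all samples in a 0–700 ms search window (the correction family for the
time dimension is not documented; the window is configurable), and the
onset is the first sample opening a run of corrected-significant samples
spanning strictly more than 100 ms — rate-aware: > 100 samples at 1 kHz,
> 200 at 2 kHz. Detected onsets sit slightly *early* relative to a planted
step (up to ~ half the 155 ms smoothing frame) because smoothing spreads
post-onset power backwards; the planted-onset recovery test budgets
±40 ms for this.

Latency summaries report per region × hemisphere × category medians and
SDs (singleton cells report SD 0). Pairwise category comparisons use the
asymptotic Wilcoxon rank-sum test: onsets come from distinct electrodes,
so signed-rank pairing is unavailable, and with cells as small as n = 3
only the asymptotic variant can reach q ≤ 0.05 at all.

## Mixed-effects topology models

Each category/region/hemisphere cell is modelled as
d′ ~ 1 + c₁ + c₂ + c₁:c₂ + (1 | subject) with coordinates mean-centered
per hemisphere × region. The axes are fixed per region — (x, y) in VTC
(z dropped), (z, y) in LOC (x dropped) — because one axis pair per region
is strongly rank-correlated along the cortical sheet; the Spearman screen
is always reported alongside rather than used to select axes.

Estimation is REML with the single subject-to-residual variance ratio λ
profiled out: at fixed λ the fixed effects are closed-form GLS (per-subject
block inverses, `V_i⁻¹ = I − λ/(1+λn_i)·J`), and λ is found by a coarse
grid scan plus bounded scalar search on [0, 10³] (tolerance 1e-10), with
the λ = 0 endpoint always compared. Fixed-effect p-values use t statistics
with **Satterthwaite** degrees of freedom computed from finite-difference
gradients of the coefficient variances and the inverse REML information —
this reproduces lme4 + lmerTest output to ~8 significant digits on test
problems, matching the estimation conventions of the original analysis
software. λ̂ on the zero boundary is flagged and the fit then equals OLS
with residual degrees of freedom; one-electrode-per-subject designs make
the random intercept unidentifiable and are flagged degenerate (OLS
reported) rather than returning an arbitrary variance split.

## Synthetic data generator

The generator emulates the study conditions: 26 subjects (16
left-hemisphere), 3–10 electrodes per subject split ~65/35 between VTC and
LOC, five categories at post-rejection trial counts (face 46, animate 31,
place 49, tool 29, word 38; word trials only in left-hemisphere subjects),
1000 Hz sampling, epochs −1…+2 s around stimulus onset. Trials are
generated independently (no inter-stimulus structure; all analyses are
epoch-based). Trial rejection is not simulated; the trial counts are the
post-rejection values directly.

Per trial the signal is: Fourier-synthesized 1/f² background (icEEG-like
spectrum; exponent configurable) + white noise + a 60–120 Hz band-limited
Gaussian carrier + optional 60 Hz line. Category selectivity is injected
as a multiplicative envelope on the carrier — 1 before the configured
onset (default 150 ms), ramping linearly over 50 ms to 1 + g — which
produces a realistic BGA step without phase artifacts. The gain g for an
electrode's preferred category follows a linear gradient in |coordinate|
(faces/animate increasing laterally, places/tools medially, words along
y) times a log-normal subject random effect, and the *choice* of preferred
category is softmax-weighted by the local gains, so selectivity clusters
along the gradient as in cortex. Coordinates are uniform per region with
one derived collinear axis per region (VTC z rises with laterality in both
hemispheres; LOC |x| tracks y), giving the screen realistic |r_s| ≈
0.8–0.95. One global seed drives a per-electrode substream
(`default_rng([seed, electrode_index])`), so any electrode subset is
bit-reproducible regardless of cohort layout.

What the generator does **not** emulate: eye-movement/EMG artifacts,
inter-ictal spikes, continuous recordings, non-stationary baselines,
spatially correlated noise between electrodes, and any dependence of the
noise on the stimulus. Passing tests therefore demonstrate correctness of
the statistical machinery and calibration under the stated noise model,
not robustness to every artifact structure of clinical recordings.

## Problem sizes and numerical choices

The acceptance run uses the study-sized cohort (26 subjects, ~190
electrodes) with n_perm = 2,000 for the permutation stage and a separate
400-electrode scalar null study at n_perm = 500 — sizes chosen so the full
recomputation stays around a minute while keeping Monte-Carlo error well
inside the tolerances asserted. The test suite uses smaller cohorts per
test with fixed seeds; hypothesis-based property tests run derandomized.
Degenerate inputs are errors, not NaNs: zero baseline power, zero pooled
variance, inverted windows, singular designs (reported with the collinear
columns named). p-values from the permutation stage may be exactly 0 by
construction; mixed-model p-values are clipped away from 0 only by
floating-point underflow.

## Deposited-data reproduction

The deposited per-electrode matrices (d′ per category, coordinates, and
the 10,000 stored shuffled d′ per electrode, per-subject cell arrays) are
read by pattern-matched variable discovery — only the left-VTC file's
variable names are documented, so cohorts are identified by the
`{L,R}H_{VTC,LOC}` tag and classified by name content — with electrode
counts validated across variables and against the published per-subject
tallies. Both MAT v5 and v7.3 (HDF5) containers are supported. Stored
shuffles allow exact recomputation of the permutation p-values and the
grouped BH calls; the coordinate mixed models are refit from the stored
d′ and coordinates. Raw traces were not deposited, so BGA extraction and
latency detection are validated against the synthetic generator's ground
truth instead.

## Known limitations

- The latency time-dimension FDR family and search window are configurable
  defaults, not documented properties of the original analysis.
- Published coefficient reproduction is expected to be close but not
  bit-exact: the original ML/REML switch, optimizer and df method are
  implied by software citations only.
- Anatomical boundary counts (lateral/medial to the mid-fusiform sulcus)
  require a user-supplied boundary coordinate; no surface meshes are
  handled.
- No parametric selectivity alternative, no multivariate pattern analysis,
  no spectrogram/ERP analyses, no re-referencing (inputs are assumed
  already referenced).
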