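# gammatopo

Grouped intracranial-EEG (icEEG/ECoG) analysis of **category selectivity in
higher-order visual cortex** and its relation to cortical topology.

Subdural electrodes (SDEs) over ventral temporal cortex (VTC) and lateral
occipital cortex (LOC) respond preferentially to specific classes of visual
stimuli — faces, animate non-face, places, tools, written words. This
package implements the full statistical pipeline for quantifying that
preference from trial-epoched voltage recordings and for modelling how it
varies with electrode position in Talairach space, together with a
synthetic-data generator with known ground truth so every stage is testable
without patient data.

## Pipeline

1. **Broadband-gamma activity (BGA).** Per trial: 60 Hz notch (+harmonics),
   zero-phase elliptic band-pass 60–120 Hz, Hilbert analytic amplitude,
   Savitzky–Golay smoothing (order 5, 155 ms frame), squared to power and
   expressed as percent change from the −700…−200 ms pre-stimulus baseline.
2. **d′ selectivity index.** With per-category means *u* and across-trial
   SDs *o* of the 100–400 ms window-mean BGA, the index for target
   category *j* against the *N* = 4 others is

   d′ = ( u_j − (1/N) Σ_{i≠j} u_i ) / sqrt( ½ ( o_j² + (1/N) Σ_{i≠j} o_i² ) )

   Significance: 10,000 joint label shuffles per electrode; one-sided
   p = (# shuffled d′ > observed)/10,000; Benjamini–Hochberg FDR at
   q = 0.01 within each region × hemisphere family (categories and
   electrodes pooled).
3. **Onset latency.** Pointwise Welch contrasts of the target category
   against the pooled others on the BGA time series, BH-corrected across
   time points (α = 0.05); onset is the earliest run of significant
   samples spanning > 100 ms.
4. **Topology.** Spearman collinearity screen among x/y/z per
   region × hemisphere, then random-intercept linear mixed models

   d′ ~ c₁ + c₂ + c₁:c₂ + (1 | subject)

   with mean-centered coordinates ((x, y) in VTC, (z, y) in LOC), REML
   with the subject-variance ratio profiled out and
   Satterthwaite-approximated degrees of freedom (verified against
   lme4/lmerTest conventions).

## Worked example

```bash
python analysis/01_simulate_dataset.py --seed 1   # 26 subjects, 192 SDEs
python analysis/02_extract_bga.py
python analysis/03_score_selectivity.py --seed 1
python analysis/04_detect_latencies.py
python analysis/05_model_topology.py
```

prints (seed 1):

```
112/192 electrodes significant for >=1 category (58%)
planted recovery: 112/112; false positives: 0
onsets detected for 112/112 flagged electrode-categories; median 146 ms (planted 150 ms)
collinear axis pairs (|r_s| > 0.8):
   LOC  L  x-y   -0.824     VTC  L  x-z   -0.953
   LOC  R  x-y    0.819     VTC  R  x-z    0.902
significant coordinate effects (5):
    face  VTC  L  x  -0.0991  p=0.0012
    tool  VTC  L  x   0.0940  p=2.5e-05
    ...
```

Reading: 58% of simulated electrodes carry a significant d′ for at least
one category; every planted selective electrode is recovered with no false
positives at q = 0.01; the detected median onset (146 ms) matches the
planted 150 ms modulation onset to within the smoothing width; one axis
pair per region is strongly rank-correlated (hence dropped from the
models); and the fitted coordinate slopes recover the planted
selectivity-vs-laterality gradients (in the left hemisphere x is negative,
so a *negative* face slope means face selectivity increases laterally).

`analysis/06_reproduce_supplementary.py` reproduces the published
electrode-level results (significant-electrode counts per cohort, dual
selectivity, word-selective electrodes, coordinate-model coefficients)
when the deposited per-electrode MAT-files are placed under
`data/supplementary/` as `S1_Dataset.mat` … `S3_Dataset.mat`. Raw voltage
traces were not deposited, so the BGA and latency stages run only on
simulated or user-supplied recordings.

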