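# mstates

Resting-state EEG **microstate** analysis for three-group cohort studies
(patients with mild cognitive impairment vs. healthy older and younger
controls), built as a fully testable pipeline: every stage can be run
against synthetic EEG with *planted* microstate structure, so recovery of
maps, temporal parameters and group effects is verifiable without access to
clinical recordings.

## What it computes

Microstates are brief (~50–100 ms) periods during which the scalp potential
topography stays quasi-stable. The pipeline implements the standard
two-stage segmentation and everything downstream of it:

1. **Preprocessing** — zero-phase 2nd-order Butterworth bandpass (1–40 Hz),
   polyphase resampling to 250 Hz, Perrin spherical-spline interpolation of
   bad channels, average reference, global field power
   GFP(t) = √(1/C Σ_c u_c(t)²).
2. **Subject-level clustering** — polarity-invariant modified k-means on
   the topographies at GFP peaks: frames are assigned by max |spatial
   correlation|, centroids are first principal components of their assigned
   maps, and the solution maximizes the global explained variance
   GEV = Σ_t (GFP_t · corr_t)² / Σ_t GFP_t². The number of clusters is
   chosen by a three-criterion median vote (Krzanowski–Lai,
   cross-validation criterion, dispersion elbow).
3. **Group-level clustering** — all subjects' retained maps pooled into one
   clustering (separate per-group clusterings inflate false positives);
   the canonical group maps are ordered against idealized A–D templates.
4. **Backfitting** — winner-takes-all labeling of *every* frame
   (|corr| ≥ 0.5, polarity ignored), temporal smoothing with an 11-frame
   window and smoothness weight 15, and rejection of segments ≤ 5 frames
   (20 ms), split half to the preceding and half to the following segment.
5. **Temporal parameters** — per subject and state: GEV (%), mean duration
   (ms), time coverage (%), occurrence rate (/s). The identity
   `coverage = duration × occurrence / 10` holds exactly.
6. **Source imaging** — analytic dipole-in-homogeneous-sphere lead field on
   a quasi-uniform interior grid, Laplacian-weighted minimum-norm
   (LORETA-type) inverse, per-point temporal standardization, and averaging
   over frames of one microstate that pass a 0.9 correlation gate.
7. **Statistics** — one-way ANOVA (from raw values *or* printed
   mean/SD/n summaries), pooled-t post hocs with Benjamini–Hochberg FDR,
   Cohen's d, Pearson correlation, and Amsterdam Resting-State
   Questionnaire (ARSQ) domain scoring (10 domains × 3 Likert items).

The synthetic generator (`mstates.simulate`) plants all of it: smooth
template topographies, semi-Markov state sequences with gamma dwell times,
rectified-oscillation amplitude envelopes, spatially correlated sensor
noise at a chosen SNR, group-wise multipliers on duration/occurrence, and
questionnaire scores correlated with one state's occurrence.

## Worked example

```python
import numpy as np, mstates as ms

montage   = ms.demo_montage(24)
templates = ms.make_template_maps(montage, 4, seed=11)
spec      = ms.SimulationSpec(n_channels=24, duration_s=60.0, snr=5.0)
rng       = np.random.default_rng(7)
seq       = ms.simulate_state_sequence(spec, rng)
rec       = ms.simulate_eeg(templates, seq, spec, montage, rng)

sol = ms.subject_segmentation(
    rec, ms.ClusterParams(k_range=tuple(range(1, 9)), n_restarts=20, seed=5))
print(sol.k, round(sol.gev, 3))
# -> 4 0.982        (the planted number of maps, explaining 98% of GFP² variance)

group = ms.MicrostateMapSet(maps=templates.maps,
                            channel_names=templates.channel_names, level="group")
seg = ms.backfit_subject(rec, group)
print(round(float(np.mean(seg.labels == seq.labels)), 2))
# -> 0.87           (frame agreement with the planted sequence at SNR 5;
#                    ~0.92 at SNR 10 — the <=20 ms rejection rule and
#                    boundary blur bound what is recoverable)
print(round(ms.duration_ms(seg, 2), 1), round(ms.coverage_pct(seg, 2), 1))
# -> 56.6 27.9      (mean duration in ms and coverage in % of the third state)
```

The numbered scripts under `analysis/` run the full study-shaped analysis
on a 24/24/24 synthetic cohort: `01_simulate_cohort.py` (ground truth),
`02_run_microstate_pipeline.py` (maps, backfitting, parameters),
`03_group_statistics.py` (ANOVA + FDR + ARSQ correlation),
`04_source_imaging.py` (point-spread localization),
`05_summary_anovas.py` (F statistics from printed group summaries). Outputs
are tab-separated tables under `results/`.

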