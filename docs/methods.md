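# Methods

## Signal model and what the generator emulates

The synthetic EEG is `x(t) = a(t) · m_{s(t)} + n(t)`, with

- `s(t)` a semi-Markov state sequence over K = 4 states: dwell times are
  gamma-distributed with shape 2 and state-specific means (defaults
  55/60/70/65 ms, inside the 50–80 ms range typical of resting microstates);
  successors are drawn from a zero-diagonal transition matrix (uniform by
  default). Shape 2 was chosen over a first-order Markov chain because
  microstate durations are not geometric, and it lets mean durations be
  planted directly. Its left tail is heavier than real duration histograms,
  which matters for the segment-rejection stage (below).
- `a(t)` a rectified sinusoid at 10 Hz: GFP waxes and wanes twice per alpha
  cycle, which is what makes GFP-peak clustering meaningful.
- `m_k` average-referenced, unit-norm template maps built from low-degree
  spherical-harmonic fields of the sensor positions, redrawn until all
  pairwise |spatial correlations| ≤ 0.6.
- `n(t)` white sensor noise blended with the mean of each channel's four
  nearest neighbours (spatial correlation), average-referenced, and scaled
  so that map-signal RMS / noise RMS equals the requested SNR (default 5;
  the studies this emulates report no SNR, so the default is a testability
  choice, not an estimate).

Cohorts: three groups (defaults 30/60/60 subjects at study scale; the
experiments below run 24/24/24) with group multipliers applied to the
generator's mean durations and to the transition probabilities *into* a
state (occurrence), plus per-subject lognormal jitter (σ = 0.10) on mean
durations so that group tests face realistic between-subject variance
(reported between-subject CVs for duration are ≈ 15–20%, so 10% is
conservative). Questionnaire scores: the designated domain's latent score
is a linear function of the subject's true occurrence of the designated
state calibrated to a target correlation (default 0.21), split into three
items with noise, rounded and clipped to 1–5, then summed (range 3–15).
The other nine domains are effect-free. Ground-truth temporal parameters
are computed by an independent scan over the label array, deliberately
sharing no code with the metrics module.

What the generator does **not** emulate: 1/f background spectra, eye/heart
artifacts, electrode drift, non-stationary vigilance, or volume-conducted
source mixtures behind the template maps. Passing recovery tests therefore
demonstrates the correctness of the algorithms under the stated model, not
performance on clinical data.

## Preprocessing

Bandpass: 2nd-order Butterworth (per band edge, −12 dB/octave), applied
forward and backward (`sosfiltfilt`) with reflection padding of
3 · fs / low_hz samples so the 1 Hz edge's transient dies out before the
data start. Resampling: polyphase with any rational ratio. Bad channels:
Perrin-style spherical splines (m = 4, 7 Legendre terms, ridge 1e-5 on the
kernel diagonal; all configurable). GFP uses the population
(divide-by-N) convention, the dominant one in the microstate literature,
so GFP of average-referenced data equals the RMS over channels. An
ICA-based artifact-correction step is *not* reimplemented; the pipeline
expects cleaned input (the hook is simply that every stage accepts a
`Recording`).

## Clustering

The modified k-means is polarity-invariant: assignment by max |Pearson
spatial correlation|, and the centroid update is the first principal
component of the assigned topographies weighted by GFP², which is the
exact maximizer of the GEV contribution of a fixed partition. Topographies
whose best |correlation| falls below 0.5 stay unassigned and are excluded
from updates (they still count in every GEV denominator). Restarts seed
from k distinct observed topographies; empty clusters are reseeded from
the worst-fit topography. Convergence: relative GEV improvement < 1e-6 or
300 iterations. Best-of-restarts by GEV; study-scale defaults are 100
restarts over k = 1–12 (subject) and 200 over 1–15 (group); the desk-scale
experiments in the test suite and acceptance script use 10–60 restarts
over k ranges bracketing the planted K = 4, which the brute-force oracle
test shows is ample at these problem sizes.

Cluster-number selection: the toolbox meta-criterion used in the source
studies is unpublished, so selection here is a documented ensemble — the
median vote of (i) Krzanowski–Lai on the GFP²-weighted dispersion curve,
(ii) Pascual-Marqui's predictive-residual cross-validation criterion, and
(iii) the dispersion-curve elbow (max second difference). The full
per-criterion table is returned as diagnostics. This is an approximation
and labelled as such.

Group stage: every subject's optimal-k map set is pooled (not one map per
subject, matching common usage), clustered once across all groups, and the
winning maps are ordered by Hungarian matching against idealized A–D
scalp patterns built from the montage (right-frontal→left-posterior,
left-frontal→right-posterior, frontal→occipital, frontocentral focal);
extra maps keep their order after the matched four.

## Backfitting

Every frame (not only GFP peaks) is labelled winner-takes-all at
|corr| ≥ 0.5. Temporal smoothing is a windowed-vote rescoring: each
assigned frame's score for state s is
`(GFP_t · corr_st)² / (2·σ̂²) + 15 · (window fraction labelled s)`, with
σ̂² the mean unexplained GFP² (the residual-variance normalization makes
the published smoothness weight of 15 act as the intended gentle
tie-break); the 11-frame window excludes the current frame; sweeps run
left-to-right to a fixed point (cap 50). Frames whose neighbourhood is
unanimous are never changed, and unassigned frames never gain a label.
The exact cost function of the original toolbox is unpublished; this
rescoring is our documented interpretation.

Segment rejection: segments ≤ 5 frames are split — first ⌊n/2⌋ frames to
the directly adjacent preceding segment, the rest to the following; a
short segment at a recording edge or against an unassigned gap is wholly
absorbed by its single adjacent neighbour, and with no adjacent labelled
neighbour it becomes unassigned. Segments are processed one at a time
(leftmost first) with runs re-derived after each absorption: rewriting all
short segments simultaneously can oscillate between mirror configurations
and never reach a fixed point.

Recovery under this rule is structurally limited: with gamma(2) dwell
times, ~3–4% of true frames live in segments the ≤ 20 ms rule destroys by
design, and boundary blur costs a few percent more, so frame agreement at
SNR 10 averages ≈ 0.92 with seed-to-seed spread of ± 0.03. Group
differences in mean duration are likewise attenuated (a planted 25%
reduction typically survives as an 8–15% recovered reduction) — an honest
property of the method, which is why the planted-effect experiments run
24 subjects per group.

## Temporal parameters

"Labelled time" (the denominator of coverage and occurrence) excludes
unassigned frames; GEV's denominator is total GFP² over *all* frames, so
ΣGEV over states ≤ 100% with equality only for a perfect labelling. The
identity `coverage_pct = duration_ms × occurrence_per_s / 10` is exact
because the three quantities share denominators. Duration of an absent
state is a missing value, not zero, to avoid biasing group means.

## Source imaging

The head model is a single homogeneous conducting sphere: the monopole
Green's function of the insulated unit sphere has the closed form
`4πσR·V = 2/d + ln(2/(1 − f·cosγ + d))` (constants drop under average
reference), and dipole topographies are central finite differences of two
monopoles (δ = 1e-4 radii). Solution points are quasi-uniform inside
radius 0.85 (Fibonacci directions, cube-root radii — default 800 points;
experiments use 400). The inverse is Tikhonov-regularized minimum norm
weighted by the squared kNN graph Laplacian (k = 6) over the grid with a
small identity mix (1e-2): `T = A Lᵀ(L A Lᵀ + λ·tr/n·I)⁻¹`. λ defaults to
0.1 (≈ 1/SNR² at SNR 3); the point-spread experiments use λ = 1e-4 since
they are noiseless. An optional lead-field depth weighting (exponent
configurable) exists but defaults off: on this model the Laplacian prior
alone localizes interior point sources to ≈ 1 grid spacing on average,
and depth weighting overcorrects. Sources on the outermost grid shell
are biased inward by the one-sided smoothness penalty — localization
claims are therefore made for interior sources (radius 0.2–0.6).
Orientation is free; magnitudes are Euclidean norms over the three
components. Standardization z-scores each point across time *before* any
rectification (the norm-reduction already happened), so standardized
averages compare temporal selectivity, not raw gain; microstate averages
then take frames of one state with winning correlation > 0.9.

## Statistics

`anova_from_summary` uses SSb = Σ nᵢ(mᵢ − m̄)², SSw = Σ (nᵢ − 1)sdᵢ², and is
algebraically identical to the raw-data ANOVA — this is what makes the two
printed-summary F statistics exactly recomputable. Post hocs are pooled-
variance t tests (Welch by flag); Cohen's d uses the (n−1)-weighted pooled
SD. The FDR family defaults to the three pairwise p values of one
parameter × state panel (matching figure-wise reporting); per-parameter
and global families are available. The ARSQ item→domain mapping ships as
an editable table (consecutive item triples by default) because the
instrument's full mapping is not reproduced here.

## Pipeline, determinism, problem sizes

`run_pipeline(config)` wires simulate → preprocess → segment → group maps
→ backfit → metrics → statistics, validates the nested config (unknown
keys rejected), stamps every run with a config hash, and reuses cached
stage outputs when the hash matches. All randomness flows from
`numpy.random.Generator`s seeded from the config seed (subject streams are
spawned from a root `SeedSequence`), so fixed seeds give bit-identical
artifacts. The experiment sizes used throughout (24-channel montages, 30–60
s recordings, 12–24 subjects per group, 400-point source grids) were chosen
as the smallest scales at which the respective effects are statistically
decidable; they are stated with each result.

## Known limitations

- The cluster-number meta-criterion and the smoothing cost are documented
  approximations of unpublished toolbox internals.
- The spherical head model preserves the algorithmic chain but supports no
  anatomical claims whatsoever.
- Segment rejection biases mean durations upward (strongly so below
  ~50 ms), so recovered group effects are attenuated relative to planted
  ones; between-group *direction* is preserved.
- Per-subject occurrence estimates from short (30–45 s) recordings carry
  enough estimation noise that a weak (r ≈ 0.2) correlation planted on
  true occurrence is invisible after backfitting (corr between true and
  recovered occurrence ≈ 0.4 at that length); correlation claims are
  therefore evaluated on ground-truth label sequences at study scale
  (5-minute recordings), where the planted value is recovered.
- EDF support is deliberately minimal: 16-bit quantization, one data
  record, µV/mV/V physical dimensions only.
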