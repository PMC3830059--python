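# Methods

This note documents the models, statistics and design choices behind
`p3attn`: what is computed, under which assumptions, and what the bundled
synthetic data can and cannot establish.

## Scientific setting

The package analyses event-related potentials (ERPs) from an auditory word
oddball paradigm designed to dissociate two attentional processes:

* **Exogenous (bottom-up) orienting**, indexed by the **P3a** — a
  fronto-central positivity in the 100–400 ms window evoked by salient
  stimuli regardless of task relevance.
* **Endogenous (top-down) control**, indexed by the **P3b** — a
  centro-parietal positivity in the 400–700 ms window evoked only by
  stimuli the subject is actively monitoring.

In the paradigm, blocks of 90–100 spoken monosyllabic words contain two
equiprobable target words (YES and NO, 13–16 presentations each) embedded
among distractors from a 50-word lexicon. One target word per block is
designated the *explicit* target (to be counted); the other becomes the
*implicit* target — equally salient but task-irrelevant. Apparent spatial
location is manipulated with interaural timing differences (ITDs): targets
at ±660 µs (±90°), distractors uniformly over
{−495, −330, −165, 0, 165, 330, 495} µs, mapping linearly onto azimuths
`az = 90·ITD/660` (±67.5°, displayed as ±68°). A healthy subject therefore
shows a P3a to every word class but a P3b only to explicit targets; the
analysis pipeline classifies a subject's *exogenous* and *endogenous*
capabilities from that dissociation. The intended application is
single-subject inference in patients with disorders of consciousness,
where behavioural report is absent and statistics must be trustworthy at
the individual level.

## Statistics

All tests are reference-free, operating on Global Field Power
(GFP) — the spatial standard deviation of the scalp field at each time
point, `GFP(t) = sqrt(mean_i (v_i(t) − v̄(t))²)`.

### Temporal-cluster randomization test

Two sets of items (single epochs for one subject; subject-wise averages
for a group) are averaged per set and the GFP difference `D(t)` is formed
over a window of interest. The null ensemble relabels items (preserving
set sizes) `n_iter` times (default 1000, the convention for this family of
tests); each iteration yields a difference curve and its **window
maximum**. Pointwise, `p(t) = (1 + #{max_k ≥ D(t)}) / (n_iter + 1)` —
comparison to the maxima is what provides familywise-error control across
time. Contiguous runs with `p(t) < α` form clusters scored by the sum of
pointwise t-values; the largest observed score is referred to the null
distribution of largest scores obtained by re-applying the identical
clustering procedure to every iteration (each judged against the
*remaining* iterations' maxima, a leave-one-out convention that avoids the
small optimistic bias of letting an iteration compete against itself; the
cheaper all-iterations variant is available as an option).

Choices needing documentation:

* **Pointwise t.** The randomization ensemble defines it as the z-score of
  `D(t)` against the pointwise null ensemble. Only the *p*-values decide
  cluster membership, so conclusions are insensitive to this definition;
  both the cluster-level sum and mean of t are reported.
* **Directionality.** Condition-vs-baseline tests are one-sided
  (response > baseline). Condition-vs-condition contrasts default to
  two-sided |D|; the explicit>implicit contrast used for classification is
  run one-sided because the hypothesis is directional.
* **Ties** in the Monte-Carlo tail count as exceedances, and every p-value
  uses the plus-one convention `p = (1 + #exceed)/(n_iter + 1)`; p is never
  zero by construction.
* **Exhaustive mode** enumerates the full permutation group (all label
  splits, or all 2^n segment swaps) when it is small; the first enumerated
  element is the observed labelling, making observed-vs-itself ties exact.
* **Unequal trial counts** between conditions are used as-is; permutations
  preserve the original set sizes.

### Condition-vs-baseline variant

Each epoch contributes two equal-duration segments — the analysis window
(e.g. 100–400 ms) and the baseline (−300–0 ms) — and the randomization
swaps the two labels independently per epoch (2^n group). Equal segment
length is enforced; the windows are half-open `[start, end)` in ms, so a
300-ms window holds exactly 75 samples at 250 Hz.

**Centering and validity.** The pipeline always feeds this test
whole-epoch-centered epochs, regardless of the display baseline mode.
Classical prestim baseline correction subtracts the *baseline-window*
mean per epoch, which deflates the baseline segment's GFP and inflates
the one-sided test far above its nominal level (measured ≈37% rejections
at α=0.05 on null data, vs ≈7% with whole-epoch centering, which treats
the two segments symmetrically). Conversely, whole-epoch centering is the
wrong preprocessing for *cross-condition* contrasts: a condition with a
late component has that component's map folded into its epoch mean, and
subtracting it shifts the early window systematically. Each test is
therefore run under the centering for which it is valid: vs-baseline
swaps on whole-epoch-centered data, condition contrasts / TCT / peak
topographies on the configured mode (default prestim, which is symmetric
across conditions). Even so, the swap test is approximate rather than
exact on strongly autocorrelated noise — the baseline and analysis
segments are cross-correlated over the 100-ms gap between them (AR(1)
0.95 ⇒ ρ ≈ 0.28), and segment swapping is then not a perfect
distributional symmetry; the measured null rejection rate is ≈7–8% at
α=0.05 under the default noise model (the condition-split permutation,
which is exactly exchangeable, calibrates at the nominal rate). Group-level tests apply
the same machinery to subject-wise averages, with the unpaired pooled
shuffle for condition contrasts (a paired sign-flip would also be
defensible for within-subject conditions; the pooled shuffle is the
convention followed here, and the two agree closely at these effect
sizes).

### Topographic Consistency Test (TCT)

Tests whether single epochs share a common scalp topography: per
iteration, each epoch's channel values are destroyed by a fresh random
channel permutation, epochs are re-averaged, and the surrogate GFP is
compared to the observed GFP pointwise; a window-level p applies the same
comparison to the window-mean GFP (the aggregation into one p per window
is a package choice; pointwise p-values are always available in the
result).

**Known limitation (by design of the statistic):** the TCT's null is
channel *exchangeability*. Real EEG background — and this package's
synthetic noise — is spatially correlated by volume conduction, which is
not channel-exchangeable. On pure spatially-smoothed noise the TCT
therefore rejects above the nominal rate (≈20% at α=0.05 under the default
noise model; verified against an independent re-implementation, which
agrees exactly). On channel-exchangeable data it is calibrated (the test
suite verifies both facts). Consequently a significant TCT should be read
as "spatially structured activity is present", and the pipeline never uses
the TCT alone: classification always requires a significant cluster test
*and* a significant TCT.

### Multiple comparisons

Cohort-level control uses the step-down Holm procedure across subjects
(via `statsmodels`), applied separately to the exogenous and endogenous
familywise p-values. A conjunction ("cluster significant AND contrast
significant") is summarised by its largest constituent p before
correction.

## Classification rules

Table-style subject classification is an interpretive distillation — the
underlying report always carries every p-value so the rules can be
re-derived:

* **Exogenous attention**: significant implicit-target P3a cluster vs
  baseline (100–400 ms) *and* significant implicit-target TCT in that
  window.
* **Endogenous attention**: significant explicit-target P3b cluster vs
  baseline (400–700 ms) *and* significant explicit>implicit contrast in
  400–700 ms *and* significant explicit-target TCT in that window.

## Synthetic data generator

The simulator emulates 91-channel scalp EEG at 250 Hz, epoched
−300…800 ms (276 samples, both endpoints included):

* **Montage**: deterministic golden-angle lattice on the spherical cap
  z ∈ [−0.15, 1] (a schematic stand-in for the scalp portion of a
  high-density geodesic net); +x right, +y anterior, +z superior.
* **Components** are rank-one spatial-map ⊗ temporal-kernel products.
  Spatial maps are spherical Gaussians (P3a fronto-central, FWHM 70°; P3b
  centro-parietal, FWHM 80°; "diffuse parietal" 90°), mean-removed and
  normalised to unit GFP so a gain of g µV contributes ≈ g µV of peak GFP
  to a noise-free average. Temporal kernels are raised cosines supported
  *exactly* on their canonical windows (P3a: 100–400 ms peaking at 250 ms;
  P3b: 400–700 ms peaking at 550 ms). Confining each kernel to its window
  keeps cross-window contrasts clean — with broader tails the explicit
  P3b would bleed into the 100–400 ms window and produce an early
  explicit-vs-implicit difference that the emulated healthy group must
  not show. The diffuse-parietal kernel is a plateau (full amplitude
  200–600 ms with 200-ms cosine ramps) emulating temporally indiscriminate
  patient responses.
* **Noise** = spatially smoothed AR(1) + white sensor noise. The AR(1)
  coefficient 0.95 at 250 Hz approximates the 0.5–20 Hz-filtered EEG
  passband; the process starts from its exact stationary distribution so
  baseline and analysis segments are statistically identical. Spatial
  smoothing is a Gaussian on the sphere (FWHM 60°, row-normalised so every
  channel keeps unit marginal variance), giving adjacent-channel
  correlations ≈ 0.85, typical of volume-conducted EEG at this sensor
  density. Defaults: 10 µV correlated SD + 2 µV sensor SD.
* **Gains** (µV): healthy P3a 4, P3b 5 — set once so that single-subject
  tests resolve the components at realistic trial counts (~240 per
  target condition, ~500 distractors) while single trials remain
  noise-dominated (single-trial SNR ≈ 0.4 at the component peak). Patient
  profiles reuse these levels: the P1-like profile (P3b to explicit, P3a
  to implicit, distractor ≈ 0.5), P10-like (equal P3a everywhere),
  P11-like (diffuse parietal everywhere), P20-like (P3a with distractor
  gain 1.5 < target gain 4), and NULL (all zeros).
* Simulation is seed-deterministic (bit-identical for equal seeds); the
  heavy noise arrays are drawn in single precision with the SFC64
  generator for speed.

What the generator does **not** emulate: ocular/muscle artifacts (ICA
rejection is out of scope — the pipeline accepts externally cleaned data),
latency jitter across trials, inter-subject topographic variability,
habituation, and non-stationary arousal. Passing tests on synthetic data
therefore demonstrate the statistical machinery and its calibration, not
robustness to real-world artifacts.

## Preprocessing

* **Filter**: zero-phase windowed-sinc FIR (Hamming), 0.5–20 Hz, −6 dB at
  the cutoffs, kernel length set by the 0.25 Hz low-edge transition
  (~1650 taps at 250 Hz), applied with reflective padding; channel DC is
  removed. A linear-phase FIR was chosen over an (unknown) original filter
  because it cannot distort ERP latencies.
* **Epoching**: −300…800 ms inclusive of both endpoint samples; all later
  window selections are half-open `[start, end)` ms. Events too close to
  the recording edge are skipped (error in strict mode).
* **Baseline**: per epoch and channel, subtract the mean over −300–0 ms
  (or the whole epoch in `whole_epoch` mode, the robustness variant);
  idempotent. Within the statistical battery the vs-baseline tests
  re-centre on the whole epoch internally (see above).
* **Rejection**: normalised variance (item variance / median across
  items); defaults ×5 median for channels, ×4 for epochs. Thresholds are
  configurable; no interactive confirmation step exists.
* **Interpolation**: Perrin-type spherical splines (order m=4, Legendre
  series to degree 7, ridge 10⁻⁵), refusing to interpolate more than 20%
  of channels. Constants are reproduced exactly; low-degree spherical
  harmonics within 5% RMS.
* **Average reference** last; GFP is unaffected by the reference by
  construction, which the tests verify numerically.

For group analysis, averaging commutes with the linear reference and
baseline steps, so they are applied to subject ERPs directly.

## Calibration and problem sizes

The test suite runs Monte-Carlo calibrations at 200 simulations × 500
iterations on 100-epoch, 91-channel, 276-sample NULL data — sizes chosen
to give the binomial 95% band [4, 16] rejections around the nominal 10 —
and pattern-recovery checks over 20 seeds per profile at 400 iterations
(250 for the TCT), enough to resolve p < 0.05 decisions while keeping the
default suite within a practical runtime. Calibration feeds simulated
epochs to the tests directly, without the per-epoch baseline-correction
step: baseline subtraction deliberately zeroes the baseline-segment mean
and would itself break the analysis-vs-baseline exchangeability being
verified. The conventional default of 1000 iterations remains the
config default for actual analyses. Degenerate inputs are errors, not
warnings: windows shorter than 3 samples, unequal baseline/analysis
segment lengths, single-channel GFP, zero-variance maps in correlations.

## Known limitations

* The TCT anticonservativity under spatially correlated noise, above.
* The cluster-level p is conditional on a cluster forming; the combined
  "cluster exists AND its p < α" decision is what the calibration suite
  verifies at the nominal rate.
* Pearson topography correlations use the t-distribution p with N−2 df;
  spatial autocorrelation inflates apparent significance, so results carry
  an explicit caveat flag and should be read descriptively.
* EDF input is read via `mne`; only the 91-channel schematic montage is
  bundled, so external recordings must either match it or provide a
  compatible montage programmatically.
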