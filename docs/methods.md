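# Methods

This note records the models behind each stage, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was open.

## Recording model and single-unit chain

A recording block is a channels × samples matrix in µV at 24.414 kHz. The
hardware band (300–3000 Hz) is treated as part of the signal model: the
generator emits already-band-limited data, and the analysis applies its own
zero-phase 4th-order Butterworth band-pass only when a block's metadata
marks it unfiltered.

The chain runs in a fixed order: common-median reference → −4σ detection →
over-range rejection → coincidence rejection → waveform extraction →
clustering → Vpp validation → metrics. The two rejections are pure filters
on the detected event set and commute.

* **σ estimation.** The detection threshold needs a spike-robust noise
  scale; we use σ = median(|x|)/0.6745 of the referenced trace. On a
  median-referenced 16-channel array this statistic runs ~7% below the true
  standard deviation (the reference subtracts a correlated order statistic,
  which lightens the centre of the distribution), so the effective
  threshold sits nearer 3.7 true σ and single-channel noise crossings are
  somewhat more frequent than a textbook 4σ rate. Those crossings are
  cheap: their aligned means have Vpp near the 40 µV validation floor and
  are largely discarded there. We accept this rather than "correcting" the
  estimator, because the robust-σ convention is what practitioners apply.
* **Detection.** Negative-going only; one event per sub-threshold segment,
  at its minimum; 1.0 ms lockout.
* **Coincidence window.** 0.5 ms total width. Sub-millisecond simultaneity
  across > 14 of 16 channels distinguishes motion artifacts from
  physiological propagation; the generator's motion artifacts are jittered
  within 0.2 ms and therefore always fall inside the window.
* **Waveforms.** 0.6 ms before to 1.8 ms after the trough (≈ 59 samples).
* **Clustering.** Snippets are projected onto two principal components and
  k-means is scanned over k = 1…5 with mean-silhouette selection; k ≥ 2
  needs at least 8 snippets and silhouette ≥ 0.5, and the k-means seed is
  fixed, so sorting is deterministic. This is a reproducible stand-in for
  interactive sorter workflows; it makes no claim to resolve overlapping
  or drifting units.
* **Metrics.** Noise RMS excises ±1.2 ms around every detected event (not
  only those assigned to surviving units). Spike rate is 1/median(ISI) and
  is undefined below two spikes; such units are excluded from rate
  averages. Manual unit verification is replaced by the deterministic
  40 µV floor — no subjective step remains, at the cost of occasionally
  admitting small multi-unit clusters just above the floor.
* **Outlier pass.** Pooled unit SNRs go through a ROUT-style filter:
  location = median, scale RSDR = 68.27th percentile of |residuals| ×
  N/(N−1), two-sided p-values from t(N−1), and a Benjamini–Hochberg
  step-up at Q = 5% flagging the most extreme residuals first. Fewer than
  three values pass through unfiltered. The pass is applied to the pooled
  unit SNRs of a cohort/phase, matching how outliers are screened across
  treatments and phases rather than per channel.

## Study model and yield statistics

Each arm specifies a mean weekly probability that a channel is active in
each phase (weeks 1–4, weeks 5–8), a dead-channel probability (default
0.045), and a mean units-per-active-channel (default 1.8, shifted Poisson).
Within a phase the weekly probability ramps linearly at (p₂ − p₁)/4 per
week, centred so the phase mean equals the specified value exactly — only
phase aggregates are treated as truths, the weekly path is a modelling
choice. Weekly activity is independent Bernoulli given the ramp.

Default arm trajectories (phase-1, phase-2 active probability):
DEXSPPIN (0.610, 0.506), PIN (0.520, 0.390), DILUENT (0.450, 0.2835),
Free DEXSP (0.470, 0.216), with 7/7/7/8 animals × 16 channels. These are
two-point calibrations to the published phase declines (17/25/37/54%) and
the treated-vs-vehicle ratios; with the dead-channel rate they also land
the viable-channel counts near the published weekly Ns (e.g. ≈107 of 112).

Viability is judged over the whole study: a channel is excluded if dead
from the outset or never active in any week. Because weekly activity is
independent across weeks, this conditioning scales both phase proportions
by the same factor and leaves the expected decline unchanged.

The two-proportion z-test uses the pooled variance and no continuity
correction. The exhaustive-enumeration check in the tests shows the normal
approximation deviating from the exact binomial enumeration by up to ~0.25
in p at n = 5 — the test documents that band; at the study's hundreds of
channel-weeks the approximation error is negligible. Mixed-effects models,
ANOVA/Tukey and Kruskal–Wallis/Dunn comparisons are deliberately not
reimplemented; the pipeline exports tidy CSVs for standard statistics
tools.

## Histology model and ring quantification

Ring labels come from the Euclidean distance transform of the hole
complement, i.e. distance from each outside pixel to the nearest hole
pixel ("from the outer edge of the hole"), binned half-open into thirteen
50 µm annuli on [0, 650) µm. A hole nearer than 650 µm to the image border
is an error — truncated rings would bias means — while partial rings due to
artifact masking are allowed. Artifact pixels are excluded from intensity
means, from centroid counts *and* from the area denominator of densities;
excluding them from counts but not area would bias densities low wherever
artifacts fall.

Intensity normalization maps the 600–650 µm background bin exactly to the
marker factor: normalizedᵢ = meanᵢ/mean_bg − (1 − f) with f = 1 for
markers present in healthy tissue (GFAP, NeuN) and f = 0 for markers
absent from it (CD68, IgG). The transform is invariant to global intensity
scaling.

Neuron centroids come from a single-scale Laplacian-of-Gaussian detector
matched to the configured soma diameter, thresholded at a fixed fraction
(0.25) of the strongest blob response, with non-maximum suppression at one
blob σ. It is a deterministic stand-in for learned segmentation and
assumes roughly soma-sized, locally sparse bright blobs; centroid CSVs
from external segmentation tools are accepted equivalently and flow
through the identical density math. Hole masks can be supplied manually or
segmented from the dark hole interior (low-quantile threshold, speckle
opening, closing, largest component, fill).

Synthetic NeuN images draw an inhomogeneous Poisson soma process whose
per-bin density is a step function over the thirteen bins (defaults ramp
linearly from the arm's 0–50 µm retention — 0.59 treated, 0.21 vehicle —
to 1.0 at background; background density 1500/mm²), rendered as Gaussian
blobs (8 µm diameter) over dim neuropil with additive sensor noise, inside
a 2480-px, 0.65 µm/px frame around a 150 µm-radius hole. Step-function
truths make the bin-level expectation exact, so recovery error measures
the pipeline, not profile discretisation. At these settings soma overlap
is rare enough that detector efficiency is uniform across bins to well
under a percent, which the density normalization then cancels. What the
generator does not emulate: staining gradients, anisotropic tissue tears,
out-of-focus planes, soma-size variation — so passing tests demonstrate
correctness of the geometry and counting math, not robustness to real
stain variability.

## Release and encapsulation model

The dialysis sink is simulated exactly: cumulative released mass follows
the biexponential law between sample times; at each sampling, aliquot
mass C·V_aliquot leaves the system permanently and blank buffer replaces
it. Conservation (withdrawn + bath + unreleased = loaded) holds to machine
precision and is asserted to 1e-9 in tests. The analysis-side
reconstruction Mᵢ = Cᵢ·V_bath + Σ_{j<i} Cⱼ·V_aliquot inverts this
bookkeeping exactly, so the two implementations cross-validate each other;
an uncorrected variant (bath term only) is available as an option since
some release studies omit the correction.

Default kinetics f_b = 0.62, k_b = 3.78 d⁻¹, k_s = 0.1227 d⁻¹ are the
unique two-point solution matching 65% release at 1 day and 98% at
24 days. The fitter is unweighted least squares on fractions, initialised
from the log-linear tail slope; when the two rates are not separable
(ratio < 1.5) it collapses to a single-exponential fit reported as a pure
burst. Measurement noise is multiplicative lognormal (default CV 3%),
mean-corrected so it is unbiased in the concentration.

HPLC batches draw a true EE from N(78.7, 5.5²)% truncated to [0, 100],
assay the implied unencapsulated mass (4 mg load, 20 mL assay volume,
100 µg/mL internal standard) through a linear detector response (slope
0.85, intercept 0.01, 2% multiplicative area noise) over a standards grid
of concentration ratios 0–2. Negative back-computed concentrations clip to
zero with a logged warning.

## Determinism and problem sizes

Every generator takes an explicit seed and uses one `numpy` Generator per
call; no global random state. The pipeline fans one global seed out to
per-stage child seeds by fixed offsets, so any stage can be rerun alone.
The default desk-scale sizes — 5 s recordings (10 per cohort in the
acceptance script), 20 simulated studies, 20 seven-batch HPLC campaigns,
12 histology images per arm — were chosen so each recovered quantity's
sampling error is comfortably inside its stated tolerance (e.g. the 0–50 µm
density estimator has SE ≈ 0.015 at 12–16 images) while a full
reproduction stays in the minutes range on one core.

## Known limitations

- The sorter is per-channel; no tetrode-style cross-channel sorting, no
  drift tracking, no template matching.
- The ROUT implementation follows the published description of the
  procedure (robust scale + FDR on t-tail p-values); it is not guaranteed
  to reproduce any proprietary implementation decision-for-decision.
- The study generator models channels as independent Bernoulli given the
  weekly ramp; real electrode failure is correlated within animals and
  over time, so between-study variance here understates reality.
- The LoG detector requires locally sparse somata; at densities where
  somata routinely touch, counts bias low in dense regions and the
  normalized profile inflates near sparse bins.
- Proprietary acquisition formats are out of scope; recordings enter as
  float32 binary + JSON sidecar.
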