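# Methods

This note documents the models, parameterizations and design choices
behind the `longcall` package: what each stage computes, which knobs
matter, what the synthetic generator does and does not emulate, and the
numerical conventions adopted where the underlying methods leave room.

## The scientific problem

A graded vocal repertoire has no sharp boundaries between call types:
intermediate sounds sit on a continuum between archetypes. For orangutan
long calls the question is whether the six historically named pulse types
(HU, VO, HR, LR, IN, SI) are discrete categories or samples from two
loose frequency clusters — a high cluster (huitus, volcano, high roar;
center frequencies roughly 440–483 Hz) and a low cluster (low roar,
intermediary, sigh; roughly 203–266 Hz) — bridged by graded pulses. The
package quantifies discreteness three ways: agreement among human
labelers (kappa statistics), separability by supervised classifiers
(SVM confusion), and structure found by unsupervised clustering (hard and
soft), with fuzzy-membership **typicality coefficients** as the per-pulse
gradedness measure.

## Synthetic data generator

`SyntheticSpec` fixes the study conditions; the defaults are the
conditions under which all tests and the acceptance script run.

- **Feature tables.** Each pulse carries a gradedness coordinate
  λ ∈ [0, 1] (0 = low-cluster archetype, 1 = high-cluster archetype).
  Non-graded pulses (1 − `graded_fraction` of the sample, default 90%)
  draw features from their class's normal distribution, using the
  published per-class frequency means as defaults; graded pulses draw
  λ ~ U(0, 1) and interpolate the two archetype mean vectors linearly in
  λ — the simplest continuum consistent with points lying along a bridge
  between two clusters. Archetypes are the unweighted means of the
  per-class means within each cluster set. Labels follow λ banding
  (λ ≤ 0.3 low classes, λ ≥ 0.7 high classes, in between IN). Class
  probabilities default to the strongly unbalanced composition typical of
  real long-call datasets (sighs ≈ 47%, huitus/volcano ≈ 4% each).
- **Extra features.** Beyond the 8 core features (duration, 5 spectral
  features, F0 extrema) the generator can append noisy linear readouts of
  λ (half informative, half pure noise; default 38, for 46 total),
  standing in for the large battery of correlated spectral measurements a
  real pipeline extracts. They give feature-subsampling sweeps something
  realistic to subsample.
- **F0 contours.** Four shape families realize the pulse-type
  definitions: *roar* (smooth rise to a single maximum near mid-duration,
  then fall), *sigh* (maximum at the first frame, monotone descent),
  *huitus* (roar with an unvoiced gap between the ascending and
  descending parts), *intermediate* (variant a: start maximum with a
  later ascending bump that stays below the start; variant b: roar-shaped
  with a sub-350 Hz peak). Contours are sampled at 100 frames/s.
- **Audio.** A phase-continuous harmonic stack follows the contour
  (default 2 harmonics, 6 dB/harmonic rolloff) with a smoothed voicing
  gate, 20 ms edge ramps, and white noise at a stated SNR (default
  30 dB; the original study reports no amplitude statistics, so this is
  a package choice). The canonical sample rate is 5512.5 Hz — the rate at
  which a 512-sample window spans 92.9 ms — and supports 2 harmonics of
  the highest generated F0 (1 kHz) below Nyquist. WAV output rounds the
  rate to an integer as the container requires.
- **Recordings.** Long calls concatenate pulses with inter-pulse
  silences drawn uniformly from 0.5–3 s (unconstrained by the study;
  configurable), with per-male identifiers and tight Raven-style
  annotations. The default sampling structure is 13 males × 10 calls.

What the generator does **not** emulate: vocal-tract acoustics (formants,
jitter/shimmer, nonlinear phenomena), reverberation and habitat noise
spectra, the sub-0.2 s grumble/bubble sounds excluded by the pulse
threshold, and within-male identity signatures. Passing tests therefore
demonstrate that the analysis chain recovers planted statistical
structure — not that it would resolve every ambiguity of field
recordings.

## Acoustic measurement conventions

- Spectrograms use power-spectral-density scaling converted to dB via
  10·log₁₀ with a −120 dB floor (avoids log-of-zero; all values finite).
- Annotation times are seconds from recording start; intervals are
  half-open [begin, end), making slicing unambiguous.
- The F0 tracker's 85% "threshold" is interpreted as a relative
  amplitude gate: a frame is unvoiced when its in-band peak amplitude
  falls below 85% of the clip's maximum frame amplitude. The underlying
  tools do not define this unambiguously; the gate is configurable. A
  second, tonality gate (peak power ≥ 10× the frame's mean in-band
  power) rejects broadband noise, whose peak-to-mean ratio is far below
  that of a harmonic sound; without it a pure-noise clip would always
  have at least one "voiced" frame (the reference frame itself).
- Center and quartile frequencies follow energy-distribution semantics:
  the power spectrum is summed over frames within the selection band and
  the reported frequency is the smallest bin at which cumulative energy
  reaches 25/50/75%. For a bin-centered tone all quantiles coincide; a
  tone between bins splits across two adjacent bins (leakage), which is
  why round-trip tests assert agreement within one bin.
- `spectral_resolution` reports the arithmetic implied by a window
  length: bin spacing 1/window_s (10.8 Hz for the 92.9 ms window), Hann
  3 dB bandwidth 1.44/window_s (15.5 Hz), hop = window·(1 − overlap).
  For the 92.9 ms window at 90% overlap this yields a 9.29 ms hop.

## Reliability statistics

Cohen's κ = (p_o − p_e)/(1 − p_e) on the union label alphabet; labels
absent from one rater contribute zero marginal mass, matching the
cross-table convention. The degenerate case p_e = 1 (both raters
constant and identical) is defined as κ = 1 and flagged rather than
returned as NaN. Light's κ is the arithmetic mean of pairwise Cohen's κ
over all unordered observer pairs. The agreement index counts, per
pulse, the observers (reference included) matching the reference
observer's label; with three observers it lies in {1, 2, 3}.

## Supervised protocol

Splits are uniform and unstratified (60/40 by default), with iteration
seeds `seed, seed+1, …` so the whole protocol replays from one number.
Features are z-standardized before the SVM (fit on the training fold);
this is configurable and logged since library defaults differ across
ecosystems. Cost and gamma stay at library defaults for all four kernels.
Reported percentages round half-up, matching how confusion tables are
conventionally printed. The driver defaults to 20 iterations (the final
protocol); 10 is available for kernel comparisons. SVM-RFE scores each
surviving feature by its summed squared weight across the one-vs-one
linear decision functions and removes the weakest per step; the criterion
is undefined for non-linear kernels, which are rejected. Dunn's post-hoc
z uses mean ranks with tie-corrected variance
(N(N+1)/12 − Σ(t³−t)/(12(N−1)))·(1/nᵢ + 1/nⱼ); note that with three
groups of three observations even fully separated groups leave adjacent
pairs non-significant at α = 0.05 — the rank arithmetic, not a defect.
Benjamini–Hochberg adjustment is applied within each feature's pairwise
family.

## Hard clustering

Affinity propagation is implemented from the message-passing updates
(responsibilities and availabilities, damping 0.9, at most 1000 sweeps,
convergence after 100 sweeps with a stable exemplar set — apcluster-like
defaults). Similarities are negative squared Euclidean distances; the
shared preference is the q-quantile (linear interpolation) of the
off-diagonal similarities, so q = 0 (minimum) favors few clusters. A
deterministic 1e-12-scale jitter breaks degenerate ties; there is no
random initialization, so identical inputs give identical solutions.
Clusters are named by exemplar row index. On small problems the damped
fixed point can sit within ~1% of the exhaustively optimal same-size
exemplar set; tests allow that margin. Silhouettes use the standard
(b − a)/max(a, b) with s = 0 for singleton-cluster members.

## Soft clustering and model selection

Fuzzy c-means is the Bezdek formulation on Euclidean features
(alternating closed-form membership and centroid updates; convergence on
|ΔJ| < 1e-6; best of 5 seeded restarts). The original analysis used a
dissimilarity-based FANNY variant; memberships can differ between the
two formulations, which is why tests assert structural properties
(descent, normalization, recovery) rather than exact membership values.
Typicality is the gap between the largest and second-largest membership,
equal to |m₁ − m₂| for c = 2; thresholding supports explicit cut points
(e.g., typical > 0.976, atypical < 0.855) and distribution-quantile
rules — how such cut points were derived in prior work is not specified
beyond citation, so neither rule claims to reproduce them.

Model selection scores each (c, µ) candidate with seven measures:
connectivity (Σ 1/j over the L = 10 nearest neighbors violating the
partition; minimized), Dunn index and mean silhouette (maximized), and
four leave-one-feature-out stability measures (APN: mean proportion of
points changing cluster; AD: mean distance to reduced-data co-members;
ADM: mean distance between full- and reduced-data cluster centroids;
FOM: root mean intra-cluster variance of the deleted column; all
minimized). The winner takes the majority of measures; ties break toward
fewer clusters, then smaller µ. Candidates whose hard partition
collapses (large µ merging clusters) are flagged and excluded from
voting. Standardization before clustering defaults on.

## Embedding and clusterability

Spectrogram vectors use a 50 ms Hann window at 50% overlap (20 Hz bins,
25 ms hop), dB-floored at −120, band-limited to 50–1000 Hz and flattened
row-major. UMAP runs at default neighbor settings with a logged seed; the
embedding is used for visualization and Hopkins computation only —
clustering always operates on the feature table. The Hopkins statistic
samples m = ⌈0.1·n⌉ real points and m uniform points in the data
bounding box (the convex-hull alternative is not implemented; the
bounding box is the common convention and slightly biases H downward,
i.e., conservatively, for non-box-shaped supports). Orientation: H ≈ 0.5
for spatial uniformity, H → 1 for clusterable data.

## Rule classifier

The revised three-type scheme is operationalized as: **Roar** — maximum
inside the central 40% of the voiced span, preceded by a cumulative
ascent ≥ 21.5 Hz (≈2 bins at 10.8 Hz resolution, suppressing
quantization jitter), with max > 350 Hz (strict inequality: a 350.0 Hz
peak is not a Roar); **Sigh** — maximum within the first 10% of voiced
frames and no later ascending run ≥ the ascent threshold; **Intermediate**
— start-maximum with a later ascent, or a mid-pulse maximum ≤ 350 Hz;
contours matching neither pattern (e.g., maximum at 80% of duration)
fall to Intermediate unless they are descent-only, which reads as Sigh.
Every contour with ≥ 3 voiced frames receives exactly one label; fewer
voiced frames give a flagged "Unclassifiable" sentinel. "Near the
midpoint" and "start" tolerances are configurable and reported in the
rule trace. An optional four-class mode recognizes huitus by an interior
unvoiced gap ≥ 30 ms. Raising the 350 Hz threshold can only convert
Roars to Intermediates, never create Roars — a monotonicity property the
tests check.

## Bootstrap sweeps

Observation sweeps default to n = 100…900 (step 100) and feature sweeps
to p ∈ {2, 4, 6, 8, 16, 32, 40}, 25 iterations each, sampling without
replacement; each iteration's subsample is reconstructible from
(master seed, grid value, iteration) via seed sequences. Inside the
bootstrap, the fuzzy cluster count is selected by the internal-validity
vote (stability measures off, to keep the inner loop linear in p) and
the SVM stage uses a single 60/40 split per iteration to bound runtime.
Balanced subsampling draws a fixed count per class (39 by default, the
convention of sizing all classes to the smallest).

## Problem sizes and determinism

Tests and the acceptance script run at deliberately modest sizes —
n = 500 pulses (8 core features) for parameter recovery, 5 seeds for the
model-selection sweep, 100 seeds for the Hopkins null, 3–4 grid values ×
5 iterations for bootstrap checks — chosen so the full suite completes
in a few minutes on one CPU while keeping every statistical conclusion
stable across seeds. Every stochastic stage takes an explicit seed, and
the pipeline manifest records all of them; identical configurations
reproduce outputs byte-for-byte.

## Known limitations

- Headline statistics of the original field study (κ = 0.554/0.825,
  71.1%/84.2% SVM accuracy, Hopkins 0.940/0.957) depend on the
  undeposited recordings and are not reproduced here; the package
  reproduces the printed-derivable arithmetic and the qualitative
  findings on synthetic data.
- The 46-feature battery of the original analysis is represented by a
  core set plus synthetic extras; harmonicity/entropy features are not
  implemented.
- The F0 tracker is a per-frame peak picker, adequate for harmonic
  synthetic pulses; real noisy recordings would warrant pitch tracking
  with continuity constraints.
- FANNY-style dissimilarity-based fuzzy clustering is not implemented;
  only the Bezdek objective is.
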