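# Methods

## The design being modeled

Each trial is a 14-s movie epoch (−0.5 to 13.5 s around movie onset) with
a fixed internal schedule: the first Sim alone (0–2 s), the first Sim
acting in its context (2–5 s), a fixation gap (5–6 s), the second Sim
alone (6–8 s), and both Sims interacting in the context (8–13 s).  Time
zero is the onset of the first Sim display; the 1-s leading fixation sits
at [−1, 0) and is only partly inside the epoch.  This convention is the
one under which early feature-selection effects align with the first Sim's
presentation; the alternative (t = 0 at fixation onset) would shift every
segment by one second and is not supported by where the analysis windows
fall.

Movies come in triads.  An AB movie and its corresponding BC movie share
the B character (same `triad_id`); XY movies share nothing with any AB
movie and serve as the novel-encoding control.  With M AB movies and R
repetitions, coherence feature selection uses C(R,2) within-movie
repetition pairs per movie and (M−1)·C(R,2) between-movie pairs per
anchor movie — the unordered rep₁ < rep₂ scheme is used on both sides, as
it is the only convention under which the per-movie and total pair counts
(10, 230, 240, 5520 at M = 24, R = 5) are mutually consistent.

## Time-frequency decomposition

Complex Morlet wavelets with 5 cycles (σ_t = 5/(2πf)), unit-energy
normalized and zero-mean corrected, on the integer frequency grid
3, 4, …, 30 Hz — the only grid with exactly 28 bins.  The transform is a
batched FFT convolution whose output is decimated by stride
round(0.02 · f_s); it agrees with `mne.time_frequency.tfr_array_morlet`
to ~10⁻¹⁵ relative error on interior timepoints (the test suite asserts
this), but runs in single precision and amortizes the FFTs across trials,
which the simulation studies need.  Timepoints closer to an epoch edge
than half the wavelet support (n_cycles/(2f)) are flagged invalid rather
than silently zero-padded; they are excluded from dB epoch means, cluster
tests and similarity series.

dB normalization is 10·log₁₀(P / mean_t P) per channel and frequency,
with the mean taken over edge-valid timepoints of the whole epoch
(including the short pre-stimulus part that survives the validity mask).
Both choices — edge handling and the inclusion of the pre-stimulus window
in the mean — are configurable assumptions, not measurements.

## Wavelet coherence and feature selection

Magnitude-squared coherence |S(W_x W̄_y)|² / (S(|W_x|²)·S(|W_y|²)) from
the same Morlet family.  S smooths along time with a kernel whose standard
deviation is 3 wavelet periods at each frequency, and across frequency
with a ±1-bin boxcar.  The time kernel is realized as a variance-matched
box filter (`SmoothingSpec.n_passes = 1` by default; three passes give a
Gaussian to within a few percent) because box passes cost O(n) regardless
of bandwidth — at 3 Hz the kernel spans seconds and a direct Gaussian
convolution would dominate the pipeline's runtime.  Since numerator and
denominator share the same nonnegative kernel, Cauchy–Schwarz keeps the
estimate in [0, 1], with equality at identical inputs (both are asserted
as tests).  Magnitude-squared coherence (not absolute coherency) is the
assumed estimator.

Coherence is evaluated on a decimated time grid — 0.08 s in the desk
profile, 0.04 s in the full profile — because the smoothing bandwidth
(≥ 3 periods ≥ 0.1 s) makes the estimate heavily oversampled at the TFR's
0.02 s step.  Feature-template time supports are mapped back to the TFR
grid by nearest-neighbor expansion.

Within- and between-movie pair coherences are averaged per participant
(the participant is the inferential unit), and the two maps are contrasted
with a paired cluster permutation test separately inside each of the four
AB-segment windows.  Positive significant clusters (within > between)
become the boolean feature templates.  Clustering spans the channel
dimension by default — templates index individual
channel × frequency × time cells — with a channel-collapsed mode available.

## Cluster-based permutation testing

Element-wise paired/one-sample t statistics; supra-threshold elements
(two-tailed t quantile at cluster-forming α = 0.05, the FieldTrip-style
default) are clustered under the declared adjacency: montage neighbor
graph across channels plus ±1 bin in frequency and time (orthogonal
connectivity).  Cluster mass is the summed t.  The null is the sign-flip
permutation distribution of the maximum cluster mass — for two-sided
inference, the maximum absolute mass over positive and negative clusters
jointly, which keeps the familywise error at α without a per-tail
correction.  p = (1 + #{null ≥ observed}) / (1 + n_permutations), so the
observed labeling is always in the null and p > 0.  When
2^n_participants ≤ n_permutations the flips are enumerated exactly.
Default n_permutations = 1000 (500 in the desk profile).  The acceptance
suite verifies type-I calibration against the exact binomial interval;
a unit test cross-checks observed cluster masses against
`mne.stats.permutation_cluster_1samp_test`.

Implementation note: all permutations in a batch are labeled in one
connected-components call on a block-diagonal sparse graph, and the t
statistics for all sign flips come from a single matrix product (the
per-element sum of squares is flip-invariant).

## Time-resolved RSA

Anchor features: repetition-averaged dB cube of an AB movie, masked by a
segment template, median over the template's time support per
(channel, frequency) cell — the median is the shift-robust summary for
repetition jitter — flattened channel-major.  The primary anchor segment
is the joint interaction (8–13 s), which contains the full event; the
other three segments run behind a flag.  The anchor-segment template alone
(not the union of all four) defines the cells used when correlating at
BC/XY timepoints.

At each target timepoint the same cells are read out, Pearson-correlated
with the anchor, and Fisher-z transformed (r clipped at 1 − 10⁻⁷).
Timepoints with zero pattern variance, or where more than half the cells
are edge-invalid, propagate as missing — never as zeros.  Baselines
(AB↔XY; AB↔non-corresponding BC) are averaged in z space and subtracted
from the anchor↔corresponding-BC series, repetition-matched; repetition
zero of BC/XY trials is excluded throughout (no reactivation is expected
on first exposure).  A searchlight variant computes the correlation per
channel using only that channel's and its graph neighbors' template
cells.

## Bayesian evidence accumulation

Prior: Normal-Inverse-Gamma with μ₀ = 0, v = 30, α = 15, β = 15 — v acts
as a 30-pseudo-observation weight shrinking the mean toward zero, and
α = β = 15 centers the residual variance near 1; together they make the
per-timepoint test deliberately skeptical, which is what controls false
discoveries across ~700 timepoints without an explicit multiplicity
correction.  The conjugate update is order-invariant (asserted to 10⁻¹²),
so "consecutive" updating equals the batch formula.

BF₁₀ is the Savage–Dickey ratio of the marginal density of μ at zero
under prior versus posterior; the marginal is a scaled t (2α df, scale
√(β/(αv))).  The identity BF₁₀ = marginal-likelihood ratio holds under
the nesting where the null model inherits the prior's conditional σ²
distribution given μ = 0 (an IG(α + ½, β)); the test suite checks the
closed form against grid integration to 1%.

The evidence trace updates, by default, with **trial-level** contrast
values pooled across participants at each timepoint.  With this prior's
fixed residual scale, participant-level means (n ≈ tens) cannot move the
posterior enough to cross BF₁₀ = 3 at realistic Fisher-z magnitudes
(~10⁻²); only trial-level pooling (n in the hundreds to thousands)
produces threshold crossings of the kind the method is designed to
detect.  A per-participant mode remains available
(`trace_level="participant"`).  Windows are maximal runs with BF₁₀ ≥ 3
and consistent posterior-mean sign, kept only if strictly longer than
0.1 s (a 5-sample run at 0.02 s is dropped, a 6-sample run kept).

## Trial-level regression

Multivariate NIG prior: m₀ = 0, Λ₀ = 30·I, α = β = 15 (the regression
analogue of the trace prior).  Posterior Λ_n = XᵀX + 30·I,
m_n = Λ_n⁻¹Xᵀy, α_n = α + n/2, β_n = β + (yᵀy − m_nᵀΛ_n m_n)/2;
per-coefficient BF₁₀ by Savage–Dickey on the marginal t densities.
Outcome and predictors are z-scored within the analysis sample after
exclusions; binary accuracies enter the Gaussian conjugate model as-is
(a linear-probability treatment, not logistic).  Participants with
outcome accuracy above 0.9 are excluded first — with almost no incorrect
trials the accuracy regressor is nearly constant within participant and
the estimate is driven by an unbalanced handful of trials.  Rank-deficient
designs raise an error naming the collinear columns.

## Univariate contrast

Per participant, linear-scale power averaged over BC and over XY trials
(repetition zero excluded), contrasted elementwise as (BC − XY)/BC — the
BC scaling follows the printed formula even though it is asymmetric; it
absorbs participant-level amplitude differences.  Elements with zero BC
power are flagged invalid and excluded.  Statistics run on the
linear-scale index (dB is presentation-only).  The index is cluster-tested
against zero within each segment window; significant-cluster mean power
per trial (read from the dB cubes, which the RSA already holds in memory)
is regressed on the matched window similarity via the MVNIG model.

## The synthetic-EEG generator

What it emulates: pink (1/f) background noise; per-movie, per-segment
oscillatory signatures (integer-frequency components inside theta,
alpha and beta bands with movie- and participant-specific channel
amplitudes and phases) that are stable across repetitions up to a small
temporal jitter (30 ms SD) — this is exactly the structure wavelet
coherence is sensitive to; planted integration (during the BC movie's
first-Sim segments, a component whose channel × frequency profile copies
the corresponding AB movie's joint-segment signature) and planted
separation (during the shared-Sim segment, a nonnegative profile
reflected around the mean of the AB profile, hence anti-correlated with
it in pattern space); per-trial coupling strengths drawn around the
planted amplitude; and behavioral outcomes generated from those strengths
through a logistic link, including slow (> 10 s) and "guessing" responses
so the recoding filter (correct → incorrect when RT > 10 s or
confidence = guessing) has real work.

What it does not emulate: volume conduction and a head model, eye and
muscle artifacts, non-stationary noise, inter-individual anatomy, or any
perceptual structure of actual movies.  Passing recovery tests therefore
demonstrates that the analysis chain detects the statistical structure it
assumes — not that real EEG contains that structure.

Planted amplitudes are calibrated, not copied: real-data similarity
magnitudes at 36 participants give no usable anchor for a 12-participant,
8-channel simulation.  Pilot parameter-recovery runs at the desk profile
fixed integration/separation amplitudes of ±0.6 (signature-band units)
as values that are reliably detected while a fully null generator stays
silent; they are frozen in `PLANTED_DESK_EFFECTS`.

## Problem sizes and numerical choices

The default ("desk") profile — 12 participants, 6 triads, 8 channels,
100 Hz, 5 repetitions — is the package's simulation-study scale; the
"full" profile (36 participants, 24 triads, 62 channels, 500 Hz) exposes
the acquisition-scale layout through identical code paths.  Recovery and
calibration studies in the tests and the acceptance script run at desk
scale with 10–20 seeds, 200–500 permutations, and n = 600 trials for the
regression suites.

Numerical conventions collected in one place: r clipped at 1 − 10⁻⁷
before atanh; invalid values propagate as NaN and are excluded, never
zero-filled; coherence clipped to [0, 1]; permutation p-values use the
+1 convention; the exceedance comparison includes a 10⁻⁹ relative
tolerance so the observed labeling always counts against itself; all
randomness flows through explicit integer seeds, and a config hash plus
report hash make end-to-end runs bit-reproducible.

## Known limitations

- The Gaussian conjugate regression on binary accuracy is a
  linear-probability approximation; a logistic model would need a
  non-conjugate sampler, which is out of scope.
- Trial-level pooling in the evidence trace treats trials within a
  participant as exchangeable observations; their correlation (shared
  anchors, shared baselines) makes the nominal BF slightly anticonservative,
  which is why the null-calibration study (≥ 90% of null seeds windowless)
  is part of acceptance.
- Coherence smoothing parameters are assumptions (the estimator's
  bandwidth is not identifiable from the design) and are recorded in
  provenance rather than fitted.
- EDF export is not implemented (no writer dependency); the native
  HDF5+JSON container is the round-trip format, and EDF/BrainVision files
  are ingest-only.
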