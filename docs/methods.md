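# Methods

This note documents the models and procedures `mseplsc` implements, the
choices made where conventions genuinely diverge, and what the synthetic
cohorts do and do not establish about real EEG.

## Data model

A cohort has three diagnostic groups — ASD, ADHD and a control group — with
one multichannel EEG recording and one behavioral row per subject and
reasoning condition (`valid` / `invalid`). The montage is the 14-channel
10–20-derived consumer headset layout, in the canonical order AF3, F7, F3,
FC5, T7, P7, O1, O2, P8, T8, FC6, F4, F8, AF4, sampled at 128 Hz. Signals
are taken as already band-passed at acquisition; the package validates but
never filters or resamples. Behavioral measures per subject/condition are
age (years), the SAM (Self-Assessment Manikin) 9-point integer ratings of
valence, arousal and dominance, and a 0–100 % confidence self-report.

## Multiscale sample entropy

For a series `x_1..x_N`, the coarse-grained series at scale τ is the
sequence of non-overlapping window means of width τ (length ⌊N/τ⌋; the
remainder is discarded). Sample entropy is

    SampEn(m, r) = −ln(A / B)

where B counts pairs of distinct length-m templates whose Chebyshev
distance is strictly below r, A is the same count at length m+1, and both
counts run over the same N−m template start positions, so A/B is the
conditional probability that an m-point match extends one point further.
Self-matches are excluded. Defaults are m = 2, r = 0.15·sd, τ = 1..20; the
per-subject, per-channel analysis feature is the mean of the curve over all
scales.

Conventions that needed a decision:

* **Distance and inequality.** Chebyshev (max-norm) with strict `< r`, the
  standard SampEn convention.
* **Tolerance per scale** (`r_mode="per_scale"`, the default): r is
  recomputed from each coarse-grained series' own standard deviation. This
  makes the entropy exactly invariant to affine rescaling of the signal at
  every scale. The consequence — verified by a test — is that white noise
  has a *flat* multiscale curve under this convention, because
  coarse-grained white noise is again white noise. The classic picture in
  which white-noise entropy decays across scales while 1/f noise stays flat
  belongs to the original convention that fixes r from the raw series once;
  that convention is available as `r_mode="scale1"` and is the one used by
  the curve-shape tests.
* **Undefined values.** When no template pair matches (A = 0 or B = 0) the
  entropy is returned as NaN, an explicit undefined marker. The feature
  matrix rejects any subject with an undefined scale (no imputation). A
  zero-variance signal is an error, since r would be 0.
* **Performance.** The pair count sorts templates by their first coordinate
  and scans only the candidate window within r on that coordinate
  (box-assisted counting). Counts are bit-identical to a full O(N²) scan,
  which exists independently in the test suite as the oracle; at N = 60,000
  a scale-1 evaluation takes well under a second.

## Behavior PLSC

Let X (subjects × 14 channels) hold the scale-averaged entropies of one
condition and Y (subjects × 3) the behavioral block in the fixed column
order age, emotional state (mean of the SAM dimensions; subset
configurable), confidence. Within each group the columns of X and Y are
centered and scaled to unit sum of squares, so the per-group cross-product

    R_n = Z_Y,nᵀ Z_X,n        (3 × 14, Pearson correlations)

is a correlation block. Blocks are stacked group-major — rows ordered
(ASD-age, ASD-emotional-state, ASD-confidence, ADHD-age, …) — into the
9 × 14 matrix R, decomposed by thin SVD R = U Δ Vᵀ. Columns of V are brain
saliences (channel weights), rows of U behavior saliences per
group-measure. Brain scores are L_X = Z_X V; behavior scores are computed
per group with that group's U block, L_Y,n = Z_Y,n U_n, and concatenated.
With a single group L_Xᵀ L_Y = Δ exactly; with stacked groups the identity
holds per block only, which is why the group-wise projection is used.

Numerical conventions: singular values below 1e−12·δ₁ are dropped;
the SVD sign indeterminacy is fixed by making each V column's
largest-magnitude entry positive; explained variance per component is
100·δ_l²/Σδ², which is exact bookkeeping because Σδ² = ‖R‖²_F.

### Permutation inference

The global association index is the inertia I = Σ δ_l (sum of singular
values; a Σδ² variant is available). The test shuffles the rows of X,
recomputes normalization, rebuilds R, and records the null inertia;
p = (1 + #{I_perm ≥ I_obs}) / (n_perm + 1). The default scope permutes
within each group block, which preserves the stacked-block structure (and
commutes with within-group normalization, enabling a fast path); a global
scope that shuffles across groups is provided as an alternative reading of
"permuting the rows of X". Default n_perm = 10,000.

## Seed PLSC and connectivity graphs

The seed analysis removes the seed channels (default F3/F4, left/right
DLPFC proxies) from X and uses them as the second block: R_seed is
(3 groups × 2 seeds) × 12 and its entries are within-group correlations
between each seed's complexity and every remaining channel's — a primitive
functional-connectivity map. Its rank is at most 6 in the default design.
An edge list (group, seed, channel, weight) is emitted for entries with
|w| above a display threshold (default 0.3), signs retained.

For graph summarization the channels × (group, seed) connectivity matrix is
condensed to a weighted undirected graph: W[i,j] is the Pearson correlation
of channel i's and j's connectivity profiles, diagonal zeroed. Thresholding
is either absolute (|w| ≥ t, default t = 0.20) or proportional (top
fraction of edges by |w|, ties included); the two are genuinely different
rules that the source material conflates, so the run manifest records which
was used. Metrics on the thresholded graph: degree (retained edges per
node), strength (Σ|w|), density (retained / possible edges), and
betweenness centrality computed on 1/|w| edge distances and normalized by
(n−1)(n−2)/2 — the standard brain-connectivity conventions. Negative
weights contribute through |w| to distances and strength; signs survive
only in the edge list and weight matrix. A hemisphere summary partitions
every (seed, channel) edge into same- vs different-hemisphere cells (odd
suffix = left, even = right) and reports both signed and absolute-value
means, because neither convention alone reproduces every qualitative
comparison published for such tables.

## Mixed-design degrees of freedom

For the channels (a = 14) × condition (b = 2) × group (g = 3, s = 63
subjects) mixed design, the sphericity-assumed dfs are design-determined:
group (g−1, s−g); channels (a−1, (a−1)(s−g)); channels×group
((a−1)(g−1), same error); condition (b−1, (b−1)(s−g)); and so on for the
interactions. The calculator reproduces the published table's 13/780 and
26 dfs and satisfies the budget Σ df = a·b·s − 1. The F statistics
themselves, sphericity corrections, effect sizes and post-hoc tests are
deliberately out of scope: they depend on the unavailable original
recordings, while the dfs do not.

## Synthetic cohorts

Each channel is a weighted mixture of unit-variance white noise, pink
(1/f amplitude-shaped) noise, and an 8 Hz sinusoid with random phase
(weights non-negative, summing to 1; signal scaled to ±20 µV). 8 Hz is
chosen inside the alpha band so that the period is exactly 16 samples at
128 Hz, making the oscillation genuinely periodic in discrete time. The
default mixing profile is pink-dominated with white-noise bumps on FC6/AF4
(ASD), F4/O1 (ADHD) and F3/O1 (CONTROL), giving each group a
high-complexity signature consistent with the group-by-channel contrasts
the pipeline is meant to resolve.

Behavior is planted on the *realized* features: the generator computes each
subject's scale-averaged entropies with the configured MSE parameters,
projects them onto a loading vector (default concentrated on FC6/AF4),
standardizes the projection across the cohort per condition, and maps it
affinely onto the SAM scale (5 + 1.5·z, rounded and clipped to 1–9) and the
confidence scale (50 + 15·z, clipped to 0–100), adding independent Gaussian
noise of `behavior_noise_sd` (default 0.5) per measure. Ages are normal,
truncated below at 18 years, with group means/SDs 31.2 ± 10.52,
28.65 ± 8.75 and 28.05 ± 6.152. A zero loading makes behavior independent
of the brain block — the null case for calibration; a one-hot loading with
low noise is the recovery case. Every subject/condition owns an RNG stream
keyed by (master seed, group index, subject index, condition), so resizing
one group never changes another subject's data, and equal seeds give
bit-identical datasets.

What the generator does *not* emulate: volume conduction and inter-channel
correlation (channels are independent given the profile), non-stationarity,
artifacts (blinks, line noise), realistic spectra beyond the three-component
mixture, and any sex structure. Passing recovery/calibration tests
therefore shows that the analysis chain recovers planted structure of this
kind at these sample sizes — not that it would behave identically on real
recordings, where channel correlations in particular would concentrate
variance on fewer components (the published seed analyses have a first
component near 98 % of variance; independent synthetic channels sit much
lower).

## Problem sizes used in tests

The test and acceptance workloads run reduced designs chosen to exercise
every code path at seconds-to-minutes scale: unit cohorts of 3 subjects per
group with 2,000 samples and τ ≤ 4; recovery studies of 100 cohorts at 10
subjects per group, 4,000 samples, τ ≤ 5, one-hot loading, noise sd 0.1;
calibration over 200 null replicates with 199 permutations at 10 subjects
per group. The study-scale defaults (21/21/21, 60,000 samples, τ = 20,
10,000 permutations) remain the package defaults.

## Known limitations

* EDF support is the minimal standard 16-bit profile (one recording per
  file, no annotations); physical ranges are per-channel min/max, so the
  quantization step varies by channel.
* The permutation test permutes X rows only (the published procedure);
  permuting Y instead is equivalent in distribution but not implemented.
* Betweenness ties at equal path length depend on floating-point equality;
  with continuous weights ties have measure zero, and the test oracle uses
  a small tolerance when identifying equal-length paths.
* The behavior block has only three columns, so the behavior-PLSC rank cap
  (9 = 3 groups × 3 measures) keeps every component; component-wise
  inference beyond the global inertia test is not implemented.
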