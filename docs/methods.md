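# Methods

This note documents the models behind `soundportraits`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical decisions that shape the results.

## 1. Synthetic corpus

Each stimulus is additive synthesis with explicit parameters: a harmonic
series at a C-octave fundamental (C1–C8, twelve-tone equal temperament,
A4 = 440 Hz), partial amplitudes following a spectral slope in dB/octave,
white noise mixed at a fixed noise-to-harmonic RMS ratio, optional
sinusoidal amplitude modulation, and a family-dependent envelope: linear
attack then a sustained plateau for blown/bowed families, or an exponential
decay (τ = duration/3) for plucked/struck families (harp, guitar,
keyboards). Harmonics above Nyquist are dropped; waveforms are
deterministic given the per-stimulus seed.

Family priors (slope, noise, attack and harmonic-count ranges, technique
lists) are qualitative caricatures — brass is shallow-sloped with fast
attacks, *sul ponticello* strings and multiphonics are noisy, *tremolo* and
*flatterzunge* add amplitude modulation. They are **our own inventions**,
chosen so the corpus spans the acoustic dimensions the analysis uses; they
are not estimates of any real sample library's distributions. The default
corpus mixes seven instrument families in the proportions of a 520-sound
orchestral corpus (140 strings, 172 woodwinds, 102 brass, 67 keyboards,
16 harp, 9 guitar, 14 accordion), scaled to the configured size.

Loudness equalization implements ITU-R BS.1770 integrated loudness
(K-weighting as two biquads whose analog prototypes are pre-warped to any
sample rate; 400 ms blocks at 75 % overlap; −70 LUFS absolute and −10 LU
relative gates). The target level is −23 LUFS, the EBU R-128 reference,
since no other target was specified; it is configurable. The meter
reproduces the published reference point (0 dBFS ~1 kHz sine → −3.01 LKFS)
within 0.1 LU. If normalization would clip, the whole corpus is scaled
down by one common factor so relative loudness is preserved, with a
warning.

Defaults: 44.1 kHz mono for standalone corpus export; the simulation
pipeline runs at 16 kHz with 0.5–3 s durations, which keeps every acoustic
feature well-defined while holding a full study to desk scale. All
analysis code is sample-rate agnostic.

## 2. Trial designs

Per rater and concept the corpus is partitioned into ⌈N/k⌉ trials of k = 4
(a final trial of N mod k ≥ 2 is permitted and flagged). Within the
configurable uniqueness scope — default: one group × concept, the unit on
which scores are computed — no unordered pair of stimuli may co-occur in
two non-retest trials. The builder is randomized greedy backtracking:
trials are seeded with the stimulus that already participates in the most
used pairs (a cheap most-constrained-first heuristic), partners are drawn
randomly among compatible candidates, dead ends backtrack, and the whole
build restarts from a fresh sub-seed after a bounded node budget. This
finds resolvable designs even at the exact feasibility bound
(5 raters × 16 stimuli uses all C(16,2) = 120 pairs) and builds
8 × 520-stimulus plans in under a second.

Retest trials re-present a random sample of earlier trials (fresh
within-trial order) at random positions in the second half of the
sequence, always after their source; they are exempt from the pair
constraint and excluded from scoring. The default retest count is 10 % of
trials, the ratio of the reference design (13 retests per 130 trials).

## 3. Rater model

A rater holds, per concept, a weight vector over named latent attributes —
the ground-truth synthesis parameters (log2 F0, spectral slope, noise
level, AM depth, log10 attack) plus a derived `centroid_proxy`, the
closed-form energy-weighted mean frequency of the generating harmonic
series. Attributes are z-scored over the corpus. On each trial the rater
perceives uᵢ = w·zᵢ + ε, ε ~ Normal(0, noise_sd), independently per
stimulus per trial (a Thurstonian model; Gaussian rather than Gumbel noise
because it makes the choice probabilities transparent). Best = argmax,
worst = argmin, ties broken toward the lowest stimulus id. Noise draws are
keyed on (rater seed, concept, trial index), so a judgment is independent
of simulation order.

Groups draw raters around a shared mean weight vector with Gaussian
dispersion (default SD 0.15 per weight). The three preset groups share
qualitatively sensible concept definitions (brightness = spectral centroid
for engineers, pitch-plus-low-noise for non-experts; warmth/roundness =
low centroid and pitch; roughness = noise and AM) and differ mainly in
judgment noise (0.3 / 0.5 / 0.8 × the group's mean utility SD). These are
demonstration presets, not fits to any population. Noise is parameterized
as a *fraction of utility SD* so "moderate noise" means the same thing for
any weight vector.

## 4. Tournament scoring

One best/worst choice on a k-tuple determines 2k−3 duels. Scoring is a
Rescorla–Wagner / Elo hybrid on the logistic of score differences:
p̂ = σ(s_w − s_l), δ = 1 − p̂, s_w += αδ, s_l −= αδ. The update is
symmetric (zero-sum), so the mean score is conserved and only differences
matter (translation invariance is tested at 1e−9). Defaults α = 0.05,
50 epochs, epoch-level shuffling, initial score 0: bounded per-duel
updates, order-robustness through shuffled epochs, and doubling the epoch
count moves fewer than 1 % of ranked pairs. The original scoring
algorithm's constants are not public; this variant is declared, not
claimed identical. Raw scores feed all downstream analyses; a min–max
normalized companion is exported alongside. Sequential updating is
order-dependent at O(α²): two items with identical duel patterns may
differ by ~1e−4 in score, which is why exact symmetry is not asserted.

**What the duel graph can and cannot determine.** With 8 raters, k = 4 and
pair-uniqueness at N = 100, the 1,000 deduced duels determine (through
transitivity) only ~73 % of the 4,950 stimulus pairs, so *no* scorer can
recover a latent total order exactly at that scale; Rescorla–Wagner scores
reach Kendall τ ≈ 0.90 and Spearman ≈ 0.98 against the latent utilities,
and τ = 1 exactly when the closure is complete (which the tests verify on
small corpora where it is). Under moderate noise (0.5 × utility SD) the
N = 100 recovery stays at Spearman ≥ 0.9 — the operational sense in which
eight raters yield robust scores.

**Compliance and the 50 % null.** Compliance compares a rater's duels with
the group score ordering; ties in group scores are dropped from the
denominator as uninformative (rare with raw RW scores). Within the study
pipeline the group table includes the rater's own judgments, as the
metric's original description implies. For the *null calibration*,
however, the random responder is evaluated against scores built from the
informative raters only: because each pair is presented exactly once, the
responder's own duel would be the only direct evidence about its pair, and
including it inflates the null from 50 % to ≈ 62 % (for the count-based
scorer as much as for Rescorla–Wagner — it is a property of
self-evaluation under pair-uniqueness, not of the learning rule). Against
an independent reference the measured null sits within half a percentage
point of 50 % over 50-seed replicate sets. `random_responder_compliance(include_self=True)` exposes the other
convention.

## 5. Consistency statistics

Retest agreement compares the pairs determined in *both* passes of a
repeated trial (intersection of the two 5-pair duel sets; 4–5 of the 6
pairs, depending on how the choices overlap) and reports the fraction with
the same winner. The alternative convention — count undetermined pairs as
disagreements — was considered and rejected as conflating indecision with
inconsistency.

The test battery wraps scipy.stats: Kruskal–Wallis H (tie-corrected, χ²
p-value), Mann–Whitney U (exact enumeration when n₁+n₂ ≤ 12 and tie-free,
else normal approximation with tie/continuity corrections; U is the first
sample's statistic, so complete separation gives U = n₁n₂), Wilcoxon
signed-rank (zeros dropped; exact for ≤ 12 non-zero tie-free differences),
Friedman Q (tie-corrected; the all-tied table returns the degenerate
Q = 0, p = 1), and Bonferroni adjustment min(1, p·m). The test suite
verifies the exact p-values against exhaustive labeling/sign-pattern
enumeration and the H and Q statistics against independent formula
implementations over entire small permutation distributions; note that the
χ² *p-values* for H and Q are approximations and visibly differ from the
exact permutation p at 3 × 3 scale — a property of the tests themselves,
not an implementation artifact.

## 6. Acoustic features

STFT descriptors use 25 ms windows with 10 ms hops; frames more than 60 dB
below the loudest frame are excluded, and each descriptor is summarized as
median and IQR. F0 and HNR come from long frames (100 ms, 25 ms hop): the
unbiased-normalized autocorrelation (rectangular window; the biased FFT
estimate would deflate the peak at long lags) is searched for local maxima
in the 25–4500 Hz period range with a 0.01-per-octave lag penalty against
subharmonics and parabolic interpolation of both lag and height; frames
with peak r ≥ 0.5 count as voiced, F0 = median over voiced frames (NaN if
none — corpus extraction substitutes the search floor and logs it), and
HNR = median of 10·log10(r/(1−r)). At a 16 kHz analysis rate the C7/C8
periods span < 8 samples and subharmonic errors appear; the pitch-grid
validation therefore runs at 44.1 kHz.

MPS roughness is the mean power of the 2-D FFT of the mean-removed
log-magnitude spectrogram within 30–150 Hz temporal modulation (both
signs, all spectral-modulation rows). The spectrogram uses a **10 ms**
window and 2.5 ms hop: the hop keeps the temporal-modulation Nyquist
(200 Hz) above the band, and the short window keeps the analysis mainlobe
(~±200 Hz) from attenuating envelope ripple *inside* the band — with a
25 ms window the 70 Hz ripple is smeared and the depth–roughness relation
degrades measurably. Empty spectrogram bins are floored 80 dB below the
peak so numerical noise cannot dominate the transform; digital silence
returns exactly 0.

Attack features read a 10 ms RMS envelope (lightly smoothed): attack =
10 %→90 % rise before the peak (floored at one envelope frame), slope =
0.8/rise on the max-normalized envelope, log-attack-time = log10(rise),
temporal centroid = energy-weighted mean time.

Meta features are one-hot family and technique indicators. Multicollinearity
pruning is greedy: while any acoustic pair exceeds |r| = 0.9, drop the
member with the larger mean |r| to the other acoustic columns; meta columns
are exempt; every removal is logged. The full acoustic superset (5 spectral
descriptors × {median, IQR} + F0, HNR, 3 attack features, MPS roughness =
16 columns) is extracted and pruning reduces it per-corpus rather than
hard-coding a final list.

## 7. Portrait models

Per group × concept, scores are regressed on the pruned features with
XGBoost (300 trees, depth 4, learning rate 0.05, subsample 0.8, fixed
seed — modest capacity for a few hundred rows; one default set for all
cells) in a shuffled five-fold split; accuracy is R² between held-out
predictions and scores.

Shapley attributions are computed by a float64 implementation of
path-dependent TreeSHAP over the dumped trees (thresholds re-rounded
through float32 so branch decisions match the booster bit-for-bit). Each
stimulus is attributed once, on the fold where it was held out. The local
accuracy identity — base value plus a row's contributions equals the
traversal prediction — holds to ~1e−14 here; the booster's native
float32 `pred_contribs` agrees to ~1e−6 and serves as an independent
cross-check in the tests, alongside a brute-force subset-enumeration
Shapley oracle on tiny trees. Global importance is mean |φ| per feature;
the reported direction is the sign of the correlation between feature
values and their contributions. Portraits are the top-5 features by
importance.

## 8. Concept relations

Pearson correlations between concept score tables (p from the t
distribution, df = n−2). Steiger's (1980) Z compares two dependent
correlations via Fisher-z transforms with the pooled-correlation
covariance term; both the overlapping (shared variable, one cross
correlation) and non-overlapping (four cross correlations) variants are
implemented, and the caller chooses. When all cross correlations vanish
the statistic reduces exactly to the classical two-independent-samples
Fisher-z test, which the suite checks in closed form, plus a Monte-Carlo
type-I calibration (≈ 5 % rejections under H₀ at n = 500). The rendered
result reports Z(n−1) in text while computing the SE from n. The pipeline
runs all within-group shared-variable comparisons by default.

The consistency–accuracy coupling is the Pearson correlation between mean
compliance and mean cross-validated R² over the group × concept grid (12
cells in the default study); in noise-graded simulations it is reliably
positive, mirroring the qualitative finding that better-agreeing
populations are better modeled.

## 9. Reproducibility and scale

Every stage derives its seed as CRC32(master seed, stage label, entity
ids) < 2³¹, so stages can be re-run in isolation and a config reruns
byte-identically (the suite compares artifact bytes across runs). The
default study — 100 stimuli, 3 groups × 8 raters × 4 concepts — runs in
about half a minute on one core; the problem sizes in the tests (520-sound
designs, 100-stimulus recovery runs, 2,000-replicate null simulations,
50-seed calibrations) were chosen so the full suite completes in a few
minutes while still exercising every stage at meaningful scale.

## 10. What passing tests do and do not show

The simulation validates the *pipeline*, not human psychoacoustics: the
synthetic raters are linear-utility automata with Gaussian noise, the
latent attributes are the true synthesis parameters, and the corpus lacks
room acoustics, dynamics-dependent spectra beyond a slope offset,
inharmonicity, vibrato, and recording chain effects. Group presets are
illustrative; nothing here estimates real engineers or conductors.
Consequently: recovery results bound what the *method* can extract under
known ground truth, consistency orderings confirm the metrics' sensitivity
to noise, and portraits confirm the attribution machinery — none of this
transfers numerical values to real listener data.
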