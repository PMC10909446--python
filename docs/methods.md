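# Methods

This note documents the statistical procedures, the generative model behind
the synthetic data, the numerical conventions, and the design choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Design and conventions

The package analyzes a 2 (reward: high/low) × 2 (list composition:
mixed/pure) free-recall design: 9 blocks (1 practice + 8 experimental) of 16
pictures each, 144 distinct stimuli per subject; experimental blocks split
4 mixed / 2 pure-high / 2 pure-low. Serial positions, output positions and
blocks are 1-based. Time is in milliseconds relative to stimulus onset;
analysis windows are inclusive-start / exclusive-end. EEG epochs span
−2000…+3000 ms at 500 Hz (2500 samples), voltages in µV stored as
little-endian float32. The practice block is stored but excluded from all
statistics: the analyses concern the experimental lists only.

Intrusions and repetitions are stored in the recall log but flagged, and all
statistics use correct recalls only; "first recall" means the first
*correct* recall of a list. This is one reading of how hand-coded free
recall protocols are usually scored; the alternative (counting an intrusion
as occupying output position 1) would only relabel positions and cannot
change which item is the first correct recall.

## Recall-dynamics statistics

**Recall proportion** per subject × cell divides correct recalls by items
studied in that cell (32 per cell: 4 mixed lists contribute 8 high + 8 low
each; 2 pure lists contribute 16 each).

**Probability of first recall (PFR)** is the fraction of a subject's mixed
lists whose first correct recall is high-reward; lists without correct
recalls do not contribute.

**Organization scores** use the percentile-rank ("clustering factor")
formulation: at each transition between consecutive correct recalls, every
studied, not-yet-recalled item is a candidate; the score is the rank of the
actually-recalled item among candidates (ties counted half), under
|serial lag| for the temporal metric or reward mismatch for the reward
metric. Transitions with a single candidate are skipped. Scores lie in
[0, 1] with expectation 0.5 under a uniformly random output order (verified
by simulation in the test suite). Transitions are **pooled within subject
across lists** before averaging rather than averaged per list first: short
lists contribute few transitions and per-list means would be noisy; the
choice is internal to one function and easy to change. Reward organization
is computed on mixed lists only — in pure lists every transition is an
all-tie and the score is constant 0.5.

## Permutation nulls and scalar tests

Because high-reward items are recalled more often, PFR and reward
clustering are biased upward even under order-random recall. The chance
level is estimated per subject by permuting the output order of the
recalled items within each mixed list uniformly (recalled set fixed;
default 10,000 permutations) and recomputing the statistic; the observed
value is compared to the per-subject permuted mean with a one-sample
Wilcoxon signed-rank test. Pairing each subject with their own permuted
mean is one reading of "comparing observed to permuted data"; testing all
subjects against the group-level permuted mean is available via
`compare_observed_to_null(..., target="group")`.

The **Wilcoxon** statistic V is the sum of ranks of positive differences
(zeros dropped, average ranks for ties). The two-sided p is exact — the
full 2ⁿ sign-assignment distribution, computed by dynamic programming —
when n ≤ 25 and the ranks are untied, otherwise a normal approximation with
the standard tie-correction term and a 0.5 continuity correction. The exact
path is cross-checked against brute-force enumeration and scipy in the
tests.

The **one-way repeated-measures ANOVA** for temporal organization by list
type uses the standard within-subject partition, F = MS_condition /
MS_(condition×subject), with partial η² = SS_c/(SS_c + SS_error) and no
sphericity correction (cross-checked against pingouin).

The 2 × 2 recall interaction is assessed nonparametrically: the per-subject
statistic (mixed_high − mixed_low) − (pure_high − pure_low) is compared to
a null built from independent random sign flips per subject, two-sided,
with the +1 Monte-Carlo correction. This is a deliberately simple
distribution-free stand-in for a mixed-effects model, which is out of scope
here.

**Power analysis.** A partial η² is converted to a paired-contrast effect
size dz = √(η²/(1−η²)) and the two-sided noncentral-t power equation is
solved continuously in n. The default rounds the continuous solution to the
nearest integer — the convention of the common R power calculators, whose
reported (fractional) n users round; `conservative=True` returns the
smallest integer n whose achieved power actually reaches the target, which
can be one larger when the continuous solution sits just below a .x5
boundary. The modeled design is a two-level within-subject contrast; the
original effect's exact design is rarely recoverable from a reported η²
alone, and this conversion is stated so the assumption is explicit.

## Spectral analysis

All spectral estimates share one scaling convention: with taper w over an
N-sample window, amplitude at frequency f is a = 2|Σ wₙxₙe^(−i2πfn/fs)|/Σwₙ
(taper-gain compensated, single-sided; no doubling at DC/Nyquist), and
power is a²/2 except at DC and Nyquist where it is a² — so a sinusoid of
amplitude A at a bin center yields bin power A²/2, doubling amplitude
quadruples power, and the rectangular-window single-sided power sums to the
signal's mean square (Parseval; asserted in the tests to 1e−8).

The focal ssVEP is the amplitude at electrode Oz averaged over the 14 and
15 Hz bins ("between 14 and 15 Hz" read as inclusive of both bin centers at
the 1 Hz resolution of the 1 s window) of the Hann-tapered spectrum of the
1000–2000 ms window, after −500…0 ms baseline correction. The
time–frequency decomposition uses Hann-tapered sliding windows of five
cycles per frequency (4–30 Hz, 1 Hz steps, 50 ms time steps); time points
whose window would leave the epoch are marked missing. Trial power is
averaged within (subject, condition) *before* dB conversion,
10·log₁₀(P/P̄_baseline) with the −700…−200 ms baseline computed per
channel × frequency within each condition; per-trial dB is available as an
option. The pre-stimulus baseline ends at −200 ms so that five-cycle
windows centered in the baseline do not overlap post-stimulus flicker
activity.

The ssVEP peak finder averages the dB power over the stimulation band and
all groups, takes the maximal (channel, time) cell, and expands a
contiguous time window over points within 3 dB of the peak; ties break
toward the lowest channel index, then the earliest window.

**Band-stop filtering** for ERP analysis uses a symmetric (zero-phase)
multiband windowed-sinc kernel, Hamming window, 1651 taps at 500 Hz
(≈1 Hz transition width), with the nominal 14–15 and 28–29 Hz stopbands
widened by 0.25 Hz at each edge so the flicker line at 85/6 ≈ 14.17 Hz sits
past the transition region: measured attenuation there exceeds 26 dB on a
2 s tone segment while 5 and 40 Hz tones pass within 0.1 dB. Epoch edges
are reflect-padded by half the kernel. ERPs are then baseline-corrected
(−200…0 ms) and averaged per (subject, condition).

## Cluster-based permutation test

Channel adjacency comes from sensor coordinates: an edge where the
Euclidean (chord) distance is at most 1.5× the median nearest-neighbor
distance (symmetrized k-nearest-neighbors is available). Sample-level
paired t values are thresholded two-tailed at α = .05 for df = n−1;
suprathreshold samples of equal sign are joined into connected components
under spatiotemporal adjacency (same channel ± one time step, or
neighboring channels at the same time step, implemented as sparse-graph
connected components). "Including at least two electrodes" is read as:
clusters whose channel span is a single electrode are discarded (this
differs from FieldTrip's `minnbchan`, which constrains each sample's
neighborhood; the ambiguity is noted here deliberately). Cluster mass is
the summed t.

The null distribution flips the sign of each subject's difference map with
probability ½ per permutation (subject-level sign flips — the standard
exchangeability argument for within-subject designs; permuting trial-level
condition labels before averaging is a different, costlier scheme not
implemented here), recording the maximal positive and minimal negative
cluster mass. Each observed cluster's p is the +1-corrected proportion of
permutation extrema at least as extreme in its own tail; significance is
declared at .025 per tail. The observed statistic is effectively included
in its own null, so p > 0 always. Zero-variance samples get t clamped to
±10⁹ (sign of the mean difference) so clustering stays defined.

For the global ssVEP test the features are dB time–frequency values
averaged over 14–15 Hz at the 50 ms grid points within 0–2000 ms; for the
ERP test, voltage samples 0–2000 ms at the full 500 Hz resolution. The 2×2
contrasts are: main effects as means of two cells against the other two;
the interaction as the pair (mixed_high − mixed_low) vs (pure_high −
pure_low); and within-list simple effects.

## Synthetic-data generative model

**Recall.** Each studied item is recalled independently with probability
p_low (+ boost_mixed for high-reward items in mixed lists, + boost_pure in
pure lists). The output order of the recalled set is sampled sequentially:
the first item with weight ∝ exp(β_first·1[high]) in mixed lists (uniform
in pure lists), each subsequent item with weight
∝ exp(β_reward·1[same reward as previous] − β_temporal·|serial lag|/16).
This softmax is the simplest process whose three weights independently tune
the three behavioral statistics (PFR, reward clustering, temporal
clustering); it is **not** a retrieved-context model and makes no claim
about mechanism. Defaults: p_low = 0.35 (a typical free-recall level for
picture lists), boost_mixed = 0.20, boost_pure = 0 (the hypothesized
mixed-list-only reward benefit; the reference behavioral results are
reported only graphically, so the defaults target the qualitative pattern,
not exact means), β_first = 1.0, β_reward = 0.6, β_temporal = 1.5 (chosen
a priori to place PFR, reward clustering and temporal clustering in the
empirically typical ranges while keeping the permutation tests' targets
detectable at n = 43).

**EEG.** Each trial is independent per-channel 1/f^χ noise (χ = 1,
frequency-domain shaping, 10 µV SD — small enough that the ±100 µV
amplitude rejection removes well under 5% of trials) plus (i) a flicker
response: sin(2π·85/6·t) for t ∈ [0, 2047 ms] with a raised-cosine envelope
reaching maximum at 1000 ms, an occipital Gaussian spatial profile centered
on an Oz-like channel, and per-condition amplitudes (default 3.5 µV low /
2.8 µV high reward — the hypothesized *reduction* for high reward,
preserved in both list types; the 0.8 ratio and absolute level were fixed
so a 29-trial average separates the conditions within single subjects);
and (ii) a late slow wave: a raised-cosine-edged 590–1450 ms window over
centroparietal (LPP-like) and frontal (FSW-like) channel groups, default
3 µV in the mixed-high condition only. A per-subject lognormal gain
(σ = 0.2) supplies between-subject amplitude variability. The flicker
frequency is exactly 85/6 Hz — the printed 14.17 Hz is this ratio (an 85 Hz
monitor refresh divided by 6) rounded — so spectral leakage behaves as in
the experiment. Channel positions are a Fibonacci lattice on the upper
unit hemisphere with Oz-, CPz- and Fz-like channels designated by angular
proximity to anatomical anchor directions.

**What the generator does not emulate:** volume conduction and channel
covariance, ocular/muscle artifacts, non-stationary noise, serial-position
effects in recall, intrusions and repetitions, and any dependence between a
subject's behavior and their EEG. Passing recovery tests therefore shows
that the *pipeline* detects effects of the injected form at realistic sizes
— not that the generator reproduces real EEG.

## Problem sizes and numerics

The test suite and the acceptance script run the full study at 43
behavioral subjects (the design's target sample) and a reduced EEG arm of
16 subjects × 32 channels with 1000-permutation cluster tests;
type-I calibration uses 200 replicates at 20 subjects, a 16-channel
layout and 1000 permutations. These sizes keep a complete validation run
in minutes on one core while leaving the calibration and recovery margins
comfortable; all sizes are parameters, and the full-scale montage
(113 channels, 5000 permutations) runs unchanged.

Monte-Carlo p-values always use the (+1)/(n+1) correction and mandatory
seeds; the permutation schedule is reproducible from the seed. Degenerate
inputs fail loudly: all-zero Wilcoxon differences, missing ANOVA cells,
zero baseline power, and epoch/kernel mismatches raise errors rather than
returning silent NaNs.

## Known limitations

- Widely used implementations of the clustering-factor family (e.g. the
  EMBAM toolbox) differ in whether transition scores are averaged per list
  or pooled across lists, and FFT toolboxes differ in taper-gain scaling;
  published analyses rarely state which variant they used. This package
  fixes and documents its own choices above, so cross-implementation
  comparisons should expect small systematic differences.
- The Wilcoxon normal approximation is used whenever ranks are tied, even
  at small n (an exact tied-rank enumeration would be straightforward but
  is not needed at the package's operating sizes).
- The cluster test controls the familywise rate at the cluster level only;
  the spatial/temporal extent of a significant cluster is descriptive, and
  the reported onsets/offsets should not be read as sample-level inference.
- The mixed-effects models sometimes applied to such designs (GLMM/LMM,
  Bayesian ANOVA) are intentionally out of scope; the sign-flip interaction
  test is the package's distribution-free replacement.
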