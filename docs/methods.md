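# Methods

## The data model

A subject contributes two recording series. Series 1 is always the
control condition (Vaseline cream site, pre-conditioning-stimulus scan,
or constant-temperature offset control); series 2 carries the
modulation (placebo cream site, concurrent muscle-pain conditioning
stimulus, or the T1/T2/T3 offset sequence). Ratings are continuous
0–100 VAS samples every 0.5 s across eight stimulus blocks separated by
non-painful interstimulus intervals (ISI): 15 s blocks / 15 s ISIs for
placebo and CPM (including the ~2.5 s thermode ramps at 4 °C/s), 14.4 s
blocks / 14.4 s ISIs for offset, whose block is partitioned into
T1 = 4 s at the calibrated moderate temperature, T2 = 4 s at +1 °C and
T3 = 6.4 s back at moderate.

### Windowing

All statistics consume per-block means. Placebo/CPM use the full block
(ramps included — ratings over each whole pain period are averaged).
Offset compares the mean over T3 in series 2 against the mean over the
last 6.4 s of each block in series 1, the duration-matched control
window. Windows are half-open `[start, end)` so the T1/T2/T3 windows
tile the block with no overlap or double counting; a sample on a
boundary belongs to the later window.

One numerical subtlety: the offset block period (28.8 s) is not a
multiple of the 0.5 s sampling interval, so the sampling grid's phase
drifts by 0.3 s per block. T1 and T2 always contain 8 samples; T3 (and
the control tail) contain 13 samples in most blocks and 12 in the two
blocks whose phase puts the first sample 0.4 s into the window. The
expected count per window is derived from the grid and asserted; a
trace with missing in-window samples is rejected, never imputed.
Boundary membership uses a 1e-9 s tolerance so float rounding of block
start times (k x 28.8) cannot flip a sample across a window edge.

No smoothing, detrending or outlier rejection is applied to traces.

## The classifier

`classify_subject` draws B bootstrap means (means of 8 draws with
replacement) independently from each series, pairs them by replicate
index, and uses the two tail proportions of the paired difference as
one-tailed p-values (defaults B = 10,000, alpha = 0.05). Design
choices, in decreasing order of consequence:

* **Two independent resampling streams, paired by index** — rather than
  permutation of pooled values — because each series is resampled "with
  replacement" separately. The paired difference's null distribution is
  then the convolution of the two bootstrap mean laws.
* **Ties count toward both tails**, making `p_inhibit + p_facilitate
  >= 1` an invariant and nonresponder the degenerate-case label (two
  identical constant series give p = 1 on both sides). The two
  significant labels are mutually exclusive for any alpha < 0.5.
* **Plain tail proportions** (no +1 continuity correction): the
  granularity cost at B = 10,000 is quantified by the exact oracle.
* **Per-subject RNG streams** keyed by (seed, CRC32 of subject id), so
  results are order-independent and adding a subject to a cohort never
  changes another subject's label.

### The exact enumeration oracle

`exact_bootstrap_p` computes the same two tail masses exactly: each
series' bootstrap mean law has support on the C(15,7) = 6435 multisets
of 8 draws from 8 values, with multinomial weights 8!/(prod m_i!)/8^8.
Sorting one side's means and accumulating weights gives
P(diff >= 0) and P(diff <= 0) in O(S log S) for S = 6435, with a
relative 1e-9 tolerance for float ties between resampled means. The
oracle swaps its two outputs exactly when the series are swapped; the
Monte-Carlo classifier satisfies the same symmetry only within
Monte-Carlo tolerance, because the two arguments consume different
stream positions.

### Calibration

On exchangeable series (no true effect) the nominal two-tail rejection
rate is 2 x alpha = 10%. The bootstrap-of-means test on n = 8 blocks is
measurably **liberal**: with Gaussian block means the measured rate is
~13–15% depending on noise shape. This is a property of the procedure
itself (the exact oracle reproduces the same rate on the same
subjects to within fractions of a percentage point), not Monte-Carlo
error. The test suite asserts MC-vs-exact agreement within 2
percentage points on 2,000 null subjects and stability across seeds;
users should interpret the label "nonresponder" with this mild
anti-conservatism in mind.

## The synthetic cohort generator

Emulates the statistical structure the analysis assumes, not the
physiology. Per subject and series, the latent in-block level is
`baseline + delta[series 2 only] + N(0, block_noise_sd)` per block,
plus `N(0, within_block_sd)` per sample, clamped to [0, 100]; ISI
ratings decay linearly to zero over 5 s (ISI temperature is
non-painful; no analysed window overlaps the ISI, so the decay shape is
immaterial and tested as such). For offset series 2, T1 sits at
baseline, T2 at baseline + 15 VAS (the +1 °C period rates higher; the
value never enters any analysed window), and T3 at baseline + delta.

A block mean over m in-window samples therefore has variance
`block_noise_sd^2 + within_block_sd^2 / m` before clamping; the
variance-decomposition test checks exactly this. Defaults are chosen at
published magnitudes: class mix 48/34/18%, inhibitor delta
N(−12.4, 4.8), facilitator N(+13.3, 7.0), between-block SD ~5,
within-block jitter SD 3 (a value not pinned by any published summary;
it adds sample-level roughness while contributing only 0.3 VAS points
to block-mean SD at m = 30), baselines near the calibrated moderate
target of 40–50 VAS, thermode temperatures on the 44–48.5 °C grid in
0.5 °C steps.

Class allocation is stratified (largest-remainder rounding), so a
100-subject cohort at mix 0.49/0.34/0.17 contains exactly 49/34/17
subjects; draws use one stream per subject (stable sub-seeding), so
cohorts are reproducible byte-for-byte and extensible without
perturbation.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: habituation/sensitisation drift
across blocks, serial correlation of ratings within a block (samples
are conditionally i.i.d. given the block level), slider kinematics and
reporting lag, non-Gaussian rating noise, and any dependence of
modulation magnitude on baseline. The calibration figures above are
therefore conditional on roughly Gaussian block-mean noise.

## Cohort statistics

* Paired effects: Cohen's D = |mean|/SD and t = mean/(SD/sqrt(n)) of
  within-subject differences, SD with n−1, two-sided p (the one-tailed
  rule applies only to classification). Zero-SD vectors return a
  flagged degenerate result.
* Percent change is computed per subject then summarised as
  mean ± SEM (not the ratio of group means).
* Two-proportion z: pooled variance, two-sided; degenerate pooled
  proportion 0 or 1 returns (z = 0, p = 1) by contract.
* Normality gate: Lilliefors-style KS (parameters estimated from the
  sample, statsmodels critical values); any rejecting or degenerate
  group routes the contrast to Mann–Whitney (exact enumeration for
  n <= 20, asymptotic with tie correction above).
* Bonferroni family m = 3: the three pairwise contrasts among the
  response classes per measure, capped at 1.
* ANOVA: one-way fixed effects; post hoc pooled-variance Student's
  t-tests, uncorrected, only when the main effect has p < 0.05. The
  choice of pooled over Welch t is deliberate and switchable at the
  call site by the test router.

## Problem sizes

Default experiment sizes — 2,000 null subjects for calibration, 50
pairs for oracle agreement, 300 subjects for mix recovery, B = 10,000
everywhere — were fixed up front as the smallest sizes at which the
binomial error bars are decisively narrower than the effects being
checked; each runs in seconds to tens of seconds on one core.

## Known limitations

* The classifier's anti-conservatism under the null (above) is
  reported, not corrected; a studentised or calibrated variant is out
  of scope because the aim is a faithful implementation of the
  procedure as practised.
* Percent change requires a strictly positive control mean; subjects
  rating the control series at 0 throughout are rejected rather than
  given an arbitrary value.
* The ingest path expects the package's own long-format schema
  (subject_id, series, time_s, vas) on the canonical 0.5 s grid;
  irregular sampling is rejected rather than resampled.
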