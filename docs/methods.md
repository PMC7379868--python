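# Methods

`nirspace` implements a complete two-class fNIRS brain-computer-interface
(BCI) analysis — mental arithmetic vs. idle — from raw optical density to a
statistically tested classifier comparison, together with a synthetic
session generator so the whole chain is verifiable without any recording.

## Signal model and preprocessing

A continuous-wave fNIRS device measures optical-density changes
ΔOD(λ, t) at three wavelengths λ ∈ {780, 805, 830} nm on 16 channels at
13.3 Hz.  Concentration changes of reduced and oxygenated hemoglobin (in
mM·cm, i.e. concentration × path length) follow from the modified
Beer–Lambert law as a fixed linear map per sample:

    [ΔHbR]   [ 1.8545  −0.2394  −1.0947] [ΔOD₇₈₀]
    [ΔHbO] = [−1.4887   0.5970   1.4847] [ΔOD₈₀₅]
                                         [ΔOD₈₃₀]

The coefficient rows are ordered (HbR, HbO) and the columns
(780, 805, 830) nm; the round-trip test against the generator's forward
model would fail loudly on any transposition.

The continuous chromophore series is band-pass filtered with a 6th-order
Butterworth design at 0.01–0.09 Hz applied forward and backward
(`sosfiltfilt`), i.e. zero-phase with an effective squared magnitude
response.  Filtering precedes segmentation: a 0.01 Hz cutoff has no
meaning on a 16 s epoch.  Epochs span −1…15 s around each task onset
(nearest-sample onset mapping; fixed length `round(16 × 13.3) = 213`
samples so trials stack), and are baseline-corrected by subtracting the
per-trial/channel/chromophore mean over −1…0 s.  Intervals are half-open
`[start, end)` throughout, so adjacent windows never share a sample
despite the non-integer sampling rate.

## Features

Two temporal features are computed per trial, chromophore, channel and
window on the 0–15 s segment: the windowed mean amplitude (AVG) and the
windowed slope (SLP).  SLP is the ordinary-least-squares slope of value
against time; the cruder `(last − first)/Δt` variant is available behind
`slope_method="endpoints"`.  Four window schemes tile 0–15 s: one 15 s
window (TYPE 1), three 5 s (TYPE 2), five 3 s (TYPE 3), fifteen 1 s
(TYPE 4).  Dimensionality is the product

    D = n_type × n_chrm × n_ch × n_win,

e.g. D = 1 × 2 × 16 × 15 = 480 (a 32 × 15 layout) for a single feature at
TYPE 4 — roughly 8.9 features per training trial under 10-fold
partitioning of 60 trials.  Columns are ordered feature-major, then
chromophore, channel, window, and carry full provenance descriptors, so a
subset index always denotes the same feature.

## Classifiers

*Strong learners* use all D features: a linear-kernel soft-margin SVM with
unit cost on z-standardized features (standardization fitted on training
rows only; zero-variance features keep unit scale), and an LDA on raw
features.  *The random-subspace ensemble* draws N (default 100) subsets of
M feature indices — uniform without replacement within a subset,
independent across learners — trains one LDA weak learner per subset, and
predicts by majority vote; ties at even learner counts are broken by a
seeded coin flip.  Candidate subset sizes form a ladder
`{c−4, c−2, c, c+2, c+4} ∩ [1, D]` centred at `c = ⌊√D + 0.5⌋` (c = 7 for
D = 50, c = 22 for D = 480).  The published description prints the centre
rule without the radical, but its own worked example (centre 7 at D = 50)
and the reported per-participant M values (18–35 for D of 480–960) are
consistent only with the square-root reading, which we therefore adopt as
a typo correction.

All LDA fits use a pooled within-class covariance with a small ridge,
`1e−6 × mean(diag)`, injected through a covariance-estimator shim.  This
keeps the D ≥ n strong-LDA case numerically defined while preserving its
characteristic small-sample degradation — regularizing it away would
erase the very phenomenon the ensemble is meant to fix.

## Evaluation and the corrected t statistic

Classifiers are compared on identical partitions: R = 10 repetitions of
stratified K = 10-fold cross-validation (stratification guarantees both
classes in every training split of a 30/30 session; 54 training / 6 test
trials per fold).  All fitting, including standardization and subset
drawing, happens inside the training fold.  With paired fold losses
`d_{r,k} = err_A(r,k) − err_B(r,k)`:

    E(d)  = mean over all r,k of d_{r,k}
    S²    = (1/RK) Σ_{r,k} (d_{r,k} − E(d))²
    t     = E(d) / √(S²/(df+1)),   df = 10

with a two-sided p-value from Student's t with df = 10.  The deliberately
small df compensates for the dependence between folds that share training
data; the statistic errs on the conservative side.  The printed source
equation omits the radical typographically; the √ reading follows the
corrected-resampled-t literature it cites.  Per-repetition means and
variances (E(d_r), σ_r², E(σ²)) are reported alongside.  Degenerate
cases: all-zero differences give t = 0, p = 1; zero variance with nonzero
mean gives t = ±∞, p = 0 with a warning.

Accuracy-vs-learner-count curves reuse the N fitted weak learners per fold
(majority vote of the first n), so the curve at n = N coincides with the
full ensemble.  Per-n p-values are Benjamini–Hochberg FDR-adjusted at
q = 0.05 across the learner-count grid; a naive paired t-test across all
R·K fold pairs is available (`test="paired"`) but the corrected statistic
is the default.  The ladder search reports the best M by mean CV accuracy
(matching the original report-best-over-ladder analysis and therefore
slightly optimistic); nesting it inside an outer CV is the unbiased
alternative and is left to the caller.

## Synthetic sessions

The generator emulates the block-design paradigm: 30 mental-arithmetic and
30 idle trials in a seeded random order, 10 s task periods, rest drawn
uniformly from 24–26 s per trial, 30 s lead-in.  A seeded random half of
the channels is "responsive": during mental-arithmetic trials they carry a
canonical double-gamma hemodynamic response (peak 6 s, undershoot 16 s,
ratio 1/6) convolved with the 10 s task boxcar, scaled to a peak ΔHbO of
0.05 mM·cm and ΔHbR of −0.02 mM·cm, with 20 % per-trial gain jitter.
Idle trials evoke nothing.  Every channel additionally carries cardiac
(~1.0 Hz, 0.03), respiratory (~0.3 Hz, 0.02) and Mayer-wave (~0.1 Hz,
0.015) oscillations, a linear drift (≤0.05 over the session), and white
noise (0.01 per sample); HbR nuisance amplitudes are scaled by 0.3.
Oscillation phases follow a random walk (0.4 rad/√s), giving the finite
coherence time of real rhythms — a session-long pure tone at 0.1 Hz would
alias the ~35 s trial spacing into an artificial class cue.  Ground truth
is generated in chromophore space and projected to ΔOD with the
Moore–Penrose right inverse of the conversion matrix, so the analysis
conversion recovers it to numerical precision without inventing extinction
coefficients.

Two structural choices deserve emphasis.  First, class order is
randomized, not alternated: with slow in-band noise, strict alternation
makes every temporal neighbour an opposite-class trial and pushes
cross-validated null accuracy systematically *below* chance, violating
the requirement that a session with no evoked response be
class-exchangeable.  Second, the default amplitudes put a full-SNR
session well above the 90 % accuracy mark; human sessions typically sit
lower (peak ΔHbO around 0.005 mM·cm in this model reproduces mid-80 %
ensemble accuracies with the high-dimensional LDA falling towards the
70 % usability threshold, as `examples/03` shows).  The generator does
not model photon transport, motion artifacts (deliberately: the emulated
recordings were stationary and uncorrected), channel cross-talk, or
serially dependent trial difficulty — so passing tests demonstrate the
pipeline's statistical machinery, not performance on any particular human
cohort.

## Numerical and design notes

- Determinism: every random choice (rest durations, label order,
  responsive subset, noise, fold shuffles, subset draws, tie breaks)
  flows from named integer seeds; a master seed fans out to stage seeds
  via `SeedSequence([master, stage_index])` reduced below 2³¹.
- Filtering requires the series to exceed three times the filter's edge
  extension; shorter inputs raise a dedicated error rather than returning
  transient-dominated output.
- Epoch/window membership uses nearest-sample onset rounding and
  half-open intervals; two sessions differing by an integer-sample shift
  segment identically.
- The Type-I calibration test pairs two ensembles that differ only in a
  fold-fixed subset draw: exchangeable by construction, yet each replicate
  carries a draw-conditional performance difference — the regime where
  the corrected test is least conservative.  Weakly-differing pairs
  (e.g. LDA vs. SVM on null features) reject at well under 1 %,
  consistent with the statistic's known conservatism.
- Scaled-down problem sizes in tests (fewer repetitions or trials where a
  property does not need the full 10 × 10 design) are the package's own
  choices for fast, deterministic suites; the full-size defaults match
  the emulated study throughout the library.

## Known limitations

The original study's participant-level accuracies are properties of its
18-subject recordings and are not reproduced here; synthetic sessions
verify contracts and trends, not human effect sizes.  The report-best-M
mode shares the original analysis' optimism; use nested selection for
unbiased estimates.  SNIRF support covers the minimal layout the package
writes (single data block, per-channel source/detector pairs); exotic
probe geometries are out of scope.
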