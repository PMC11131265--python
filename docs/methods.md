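# Methods

This note records the models, conventions and numerical choices behind
circaflow, what the synthetic generators do and do not emulate, and the known
limitations.

## Rhythm detection model

A gene's expression over circadian time is modelled as
`y(t) = M·(1 + a·cos(2π(t − φ)/T))` with mesor `M` (TPM), relative amplitude
`a = A/M` (dimensionless), acrophase `φ` (CT hours in [0, 24)) and period
`T = 24 h`. Two-cycle records (CT0–CT44, 4-h steps) are fitted un-folded at
period 24 so cycle-to-cycle consistency contributes to the fit.

Three detectors give independent evidence:

1. **Cosinor.** Linear regression on `[1, cos ωt, sin ωt]`; amplitude
   `√(a² + b²)`, acrophase from `atan2(b, a)`, p from the F-test of the two
   harmonic terms (df 2, n − 3). A constant series returns amplitude 0 and
   p = 1 rather than an error. This detector also supplies the phase estimate
   used by the circular statistics, because its acrophase is a continuous
   maximum-likelihood-style quantity rather than a grid value.
2. **Rank/template.** The statistic is the maximum Kendall τ_b between the
   series and cosine reference waveforms with peak phases every 2 h (an
   optional asymmetry parameter warps the rise/fall fractions; the default
   bank is symmetric). The p-value is empirical over permutations of the time
   labels, count-corrected as `(1 + #{perm ≥ obs})/(n_perm + 1)` so it can
   never be 0; `n_perm ≥ 999` is enforced. Because τ depends only on rank
   orders, the permutation distribution of the statistic is pivotal for any
   tie-free series: one seeded null sample is drawn per call and shared by
   all tie-free genes (genes with tied values get their own permutations).
   This makes the per-gene cost independent of `n_perm` precision and is
   exactly equivalent in distribution to per-gene permutation for continuous
   data.
3. **AR-spectral.** The series is detrended by intercept + slope, where the
   slope is estimated jointly with a 24-h harmonic — on a two-cycle record a
   plain linear fit absorbs part of the oscillation (measured distortion up
   to ~23% of amplitude on a pure cosine), which biases everything
   downstream. The AR model is fitted by the modified-covariance
   (forward–backward least-squares) estimator with AIC order selection,
   order ≤ n/3 and order 0 (white noise) allowed; this estimator was chosen
   because Yule–Walker mislocates the spectral pole of a 12-point noiseless
   cosine by ~2 h and Burg by 0.3–1.3 h, while forward–backward least
   squares recovers it to < 0.1 h. The candidate period is the spectral peak
   on a 0.1-h grid inside 20–28 h when that peak is interior, else 24 h; the
   p-value is the cosinor F-test at the candidate period.

Per detector, q-values are BH-adjusted over the tested gene universe (the
filtered background: mean TPM ≥ 1). The consensus call is a pure function of
the q triple; the default rule is the intersection ("all") at q < 0.4, which
favours specificity, with "any" and "majority" available. The threshold-sweep
table (counts of calls per threshold per method and rule) is how a user picks
the threshold for their data.

**Normalized amplitude.** Values below 1 TPM are raised to 1 before a cosinor
fit, and amplitude/mesor of that fit is reported. The floor prevents genes
whose troughs sit near zero from reporting enormous relative amplitudes that
would dominate amplitude comparisons.

## Calibration properties and their limits

Cosinor and AR-spectral p-values are continuous and KS-uniform on null data.
The rank/template empirical p is *valid* (P(p ≤ α) ≤ α) but discrete: with 12
samples on a 4-h grid the max-τ statistic takes ~58 distinct values with
atoms of up to ~5% probability mass, so its null p-values have ~0.05-wide
gaps in their support. Consequences: a KS test against the continuous uniform
sits near its own critical value at n = 1000 genes and rejects in a sizeable
fraction of seeds, and the realized rejection rate at nominal 0.05 falls
below 0.05 (conservative, roughly 0.035–0.05 depending on where an atom
boundary lands). This is intrinsic to rank statistics at this design size,
not a coding artifact; the binomial-validity check is the meaningful
error-control property for this detector.

## Chi-square periodogram and lesion verification

Minute counts are summed into 6-min columns (bounding the number of fold
columns B); for each trial period of B columns the Sokolove–Bushell statistic
`Q_p = N·Var_pop(column means)/Var_pop(all) = K·Σ_h(M_h − M̄)²/s²` is
compared with the χ²(B − 1) quantile at 1 − α (α = 10⁻⁴). The peak is taken
within the circadian range 20–28 h and its excess over the significance line
(0 when below it) is the record's rhythmicity score. A tested record passes
lesion verification when its excess is *strictly* below 10% of the average
control excess ("below 10%" is read as strict). At least 3 full cycles of the
longest tested period are required; a zero-variance record is an error, not a
pass.

## Phase clustering and circular statistics

Profiles are z-scored per gene across the 12 time points (constant genes are
an error). K-means uses Euclidean distance on z-profiles, k = 6 and 50 seeded
restarts (defaults); clusters are relabelled 1..k by ascending centroid
acrophase so output is stable across runs. The amplitude class of a cluster
is "high" when the median member floor-normalized amplitude exceeds the upper
tercile of all clustered genes (configurable cut) — the tercile is a declared
convention, since amplitude classes are qualitative. The Rayleigh vector uses
`p ≈ exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n))`, accurate for the n in play
here (tens to thousands).

## Enrichment and group tests

ORA p is the exact hypergeometric upper tail `P(X ≥ k)` of the study/term
overlap within the background; fold enrichment is
`(k/|study|)/(|term ∩ bg|/|bg|)`; terms with empty background intersection
are skipped; q is BH over tested terms. Genes outside the background never
affect the result (membership is intersected with the background first).
The day–night statistic divides each gene by its own mean over all its
samples and takes `|mean(day) − mean(night)|`; for 12-time-point designs the
default day samples are CT8 and CT32 and night samples CT20 and CT44 — the
sampled analogues of ZT7/ZT18 averaged over both cycles, chosen so the
two-time-point knockout design and the full time courses are comparable on
the same scale. Dunn's post-hoc z-tests use pooled midranks with the standard
tie correction and BH adjustment across pairs (the adjustment choice is a
convention; the omnibus Kruskal–Wallis p is reported alongside).

## Bioluminescence pipeline

*Cosmic rays* are single-frame, single-pixel events; detection thresholds the
second temporal difference `x[t] − (x[t−1] + x[t+1])/2` at 5 robust SDs
(1.4826·MAD over pixels with temporal variation). The second difference is
slope-invariant, so spikes riding the steep flank of a high-amplitude
oscillation are still caught; detected pixels are replaced by the mean of
their temporal neighbours, and the operation is idempotent on clean stacks.

*Tessellation* clips a square grid of `cell_size` pixels to the mask; cells
holding less than half a cell's pixels are merged into their largest kept
neighbour (or dropped/kept, configurable); a mask smaller than one cell
becomes a single ROI.

*Preconditioning* subtracts a centred running mean (window 48 h, forced to an
odd frame count so a linear trend is removed exactly) and applies a 3-frame
centred running median. The trend is evaluated only where the full window
fits and held at the nearest full-window value near the edges; a shrinking
window would subtract part of the oscillation itself from the first and last
half-window. The median denoiser clips sampled extrema of a 24-h/1-h-sampled
cosine by up to `1 − cos(2π/24) ≈ 3.4%`; period and phase are unaffected, but
amplitudes carry this small systematic attenuation — tests budget 5% for it.

*Fitting* profiles a grid of (period 18–35 h step 1 h) × (damping 0, 0.01,
0.02, 0.05 h⁻¹) where the remaining parameters are linear, then refines the
best start by bounded trust-region least squares with `d ∈ [0, 0.5]` and `T`
in bounds. Amplitude is `√(a² + b²) ≥ 0` by construction; phase is hours
since recording start, mod 24. A fit whose period lands at a bound is
flagged and excluded by the gate unless explicitly allowed. R² is computed
against the preconditioned trace; the reported "mesor" of an ROI is the mean
of its raw trace (the average luminescence level), since the preconditioned
trace is zero-mean by construction.

*Gating* keeps `R² > 0.97` (strict) with an interior period. White-noise
traces reach at most R² ≈ 0.1–0.5 across the multistart grid, far from the
gate. Group summaries exclude values beyond 3 SD within a group before
Kruskal–Wallis/Dunn testing, and phases are summarized by the Rayleigh
vector; the spatial table (centroid, phase, amplitude) supports phase maps.

## Synthetic data: what it emulates, what it does not

The transcriptome generator draws log-normal baselines (default
ln TPM ~ N(2, 1.5²)), marks a fraction of genes rhythmic, gives them cosine
profiles with relative amplitudes uniform on a configurable range (default
0.1–1.0; the empirical amplitude distribution of real rhythmic genes is
unknown, so this is a declared free parameter) and peak phases from a
two-component von Mises mixture centred at CT12 and CT20 (weights 0.6/0.4,
κ = 4) — the bimodal early-night/late-night phase structure typical of
strongly clock-driven tissue. Noise is multiplicative log-normal with mean
one (`exp(σZ − σ²/2)`, default σ = 0.1), reproducing TPM heteroskedasticity
without modelling read counts. The lesion-like condition multiplies true
amplitudes by a collapse factor (default 0.2) with everything else held
identical under the same seed; the knockout-like condition samples only
ZT7/ZT18. One replicate per time point and two cycles, as in the design the
package targets; replicates are available but off by default.

Not emulated: gene–gene correlation, count-level (Poisson/NB) noise,
batch effects, asymmetric or non-sinusoidal waveforms, and ultradian
periods. Detector power measured on these simulations is therefore an upper
bound relative to real tissue, where waveform distortion and correlated
noise reduce it; the error-control (null) properties transfer more directly.

The activity generator is a square-wave-modulated Poisson process (active
half at the nominal rate, quiescent half at 10%) or homogeneous Poisson for
the lesioned case; it does not emulate ultradian bouts or wheel-running
autocorrelation. The bioluminescence generator assigns one ground-truth cell
per grid square with damped-cosine emission on a polynomial trend, Gaussian
camera noise, and Poisson cosmic rays on interior frames (uniform 10–25× the
noise SD, respecting the ≥ 5× floor); it does not model photon shot noise,
PSF blur between cells, or focus drift.

## Numerical conventions and degenerate inputs

Seeds are mandatory for every stochastic operation; identical config + seed
is bit-identical. Constant series: cosinor returns amplitude 0/p = 1, profile
normalization raises, the periodogram raises, Kruskal–Wallis on an
all-identical pooled sample returns p = 1. Phases are reported in [0, 24);
circular means use the resultant-vector argument. BH is applied per detector
over the filtered background. Time labels accept both CT and ZT prefixes and
are stored as hours; the distinction is metadata only. Text outputs use '.'
decimals, UTF-8 and Unix newlines so manifests can checksum them.

## Problem sizes used in the shipped checks

The shipped test suite and `scripts/acceptance.py` run at desk scale, chosen
to exercise every property with comfortable statistical margins: null
calibration on 20 × 1,000-gene matrices, recovery on 10 × 1,000-gene
matrices, 100 periodogram records of 7 days, and 32 × 32-pixel/120-frame
image stacks (64 ROIs; ~50 stacks for the synchrony sweep). A full-size
analysis (≈ 20k genes, ≈ 5,000 ROIs) uses the same code paths and scales
linearly in genes and ROIs.

## Known limitations

* The rank/template empirical p is discrete at 12 time points (see above);
  downstream BH on it is valid but conservative.
* The third-detector role is filled by the fixed-period cosinor; it is not a
  learned detector and will differ from neural-network scores on non-
  sinusoidal waveforms.
* The damped-cosine fit assumes a single oscillatory component; explants with
  period lability over the recording are summarized by an effective period.
* Tessellation is geometric (squares), not a segmentation of actual cells;
  "approximately cell-sized" is the operative phrase.
* The medium/high amplitude class boundary is a tercile convention, not a
  biological threshold.
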