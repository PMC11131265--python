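# circaflow

Circadian analysis of tissue-level transcriptomes and single-ROI
bioluminescence recordings, built for the classic lesion-study design: a
two-day transcriptome time course sampled every 4 h in constant darkness
(CT0–CT44, one sample per time point), locomotor activity records that verify
whether the central pacemaker (the suprachiasmatic nucleus, SCN) was ablated,
and five-day bioluminescence movies of cultured explants imaged hourly at
approximately single-cell resolution.

The package is aimed at chronobiologists who need the full desk-side pipeline:
calling rhythmic genes with several independent detectors, choosing a
significance threshold by a sweep, clustering rhythmic genes by peak phase,
testing gene-set over-representation, and quantifying per-cell rhythm
parameters and their synchrony in image stacks. Every stage has a matching
synthetic-data generator with known ground truth, so the whole pipeline is
testable without any external download.

## Methods at a glance

**Rhythm detection.** Three detectors score every gene of the *filtered
background* (genes with mean TPM ≥ 1):

* *cosinor* — harmonic regression `y(t) = M + A·cos(2π(t − φ)/T)` at fixed
  `T = 24 h`, fitted linearly via cos/sin covariates; p from the F-test of the
  joint cos/sin terms. The acrophase `φ` is the phase estimate used downstream.
* *rank_template* — maximum Kendall τ_b between the gene's values and a bank
  of cosine reference waveforms (phases every 2 h), with an empirical
  permutation p-value `p = (1 + #{perm ≥ obs})/(n_perm + 1)`.
* *ar_spectral* — trend-aware detrending, an autoregressive spectral estimate
  (modified-covariance AR, AIC order selection) whose peak in the 20–28 h
  window picks the candidate period, then harmonic regression at that period.

Each detector's p-values are Benjamini–Hochberg adjusted; a gene is called
rhythmic when all three q-values fall below the threshold (default `q < 0.4`,
chosen via `threshold_sweep`; "any"/"majority" rules are available).
Normalized amplitude is amplitude/mesor of a cosinor fit after flooring the
series at 1 TPM.

**Phase structure.** Rhythmic genes are z-scored per gene and partitioned by
K-means (k = 6, 50 seeded restarts); each cluster reports the acrophase of its
centroid and a medium/high amplitude class. Phase populations are summarized
by the Rayleigh vector `R = |n⁻¹ Σ exp(i·2πφ_g/24)|` with the standard
Rayleigh test approximation.

**Group statistics.** Hypergeometric over-representation of a study set
against the filtered background (BH over terms), the per-gene normalized
|day − night| statistic for comparing designs with different time grids, and
Mann–Whitney, Wilcoxon signed-rank, and Kruskal–Wallis with Dunn's post-hoc
(BH across pairs).

**Activity.** The Sokolove–Bushell chi-square periodogram
`Q_p = N·Var(column means)/Var(all)` on 6-min columns with the significance
line at `P < 10⁻⁴`, and the lesion-verification rule: a record counts as
arrhythmic when its circadian peak excess is below 10% of the average control
peak excess.

**Bioluminescence.** Cosmic rays are removed by thresholding the second
temporal difference; the explant mask is tessellated into cell-sized square
ROIs; each mean-intensity trace is detrended (48-h running mean) and denoised
(3-frame median); a damped cosine
`y(t) = M + A·e^{−dt}·cos(2π(t − φ)/T)` with `T ∈ [18, 35] h` is fitted by
multistart nonlinear least squares; ROIs with `R² > 0.97` and an interior
period are gated as rhythmic and summarized spatially and per group.

## Worked example

```
circaflow simulate-transcriptome --seed 7 --n-genes 800 --frac-rhythmic 0.25 --out-dir .
circaflow detect --matrix expression.tsv --seed 7 --out-dir det
circaflow cluster --matrix expression.tsv --rhythmic det/consensus.tsv --seed 7 --out-dir clu
circaflow simulate-activity --seed 7 --out activity.csv
circaflow periodogram --activity activity.csv --out periodogram.csv
circaflow simulate-biolum --seed 7 --out-dir .
circaflow biolum-analyze --stack stack.tif --out-dir roi
```

prints

```
wrote 800 genes x 12 time points to expression.tsv
232 rhythmic genes of 726 at q<0.4 (rule=all)
232 genes into 6 clusters (peaks at 3.9, 9.9, 12.5, 15.3, 19.3, 22.0 h)
wrote 10080 minute bins to activity.csv
peak 24.00 h, excess 1234.3
wrote 120-frame stack to stack.tif
44/64 ROIs pass R^2>0.97 (68.8%)
```

Reading the numbers: of 800 simulated genes (200 truly rhythmic), 726 survive
the mean-TPM ≥ 1 background filter and 232 pass all three detectors at
q < 0.4 — the 200 true positives plus the false-positive margin the permissive
0.4 threshold allows. The six cluster peaks are the centroid acrophases in CT
hours. The activity record peaks at exactly 24 h with a chi-square statistic
1234 units above the P < 10⁻⁴ line — this peak excess is the reference a
lesioned animal's record is compared against. In the image stack, 44 of 64
cell-sized ROIs pass the R² > 0.97 damped-cosine gate, matching the simulated
rhythmic fraction.

Every subcommand writes its tables (TSV/CSV/JSON) plus a `manifest.json` with
config, input checksums and row counts, so runs are reproducible
bit-for-bit given the same seed.

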