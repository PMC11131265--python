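"""Rhythmicity detection for circadian expression time series and activity records.

Three independent per-gene detectors (harmonic-regression cosinor, rank/template
permutation test, autoregressive-spectral), Benjamini-Hochberg FDR per detector,
a consensus call over the per-method q values, plus the Sokolove-Bushell
chi-square periodogram and the lesion-verification criterion for locomotor
activity records.

Phase convention: circadian-time hours in [0, 24), the peak time of the fitted
waveform.  Two-cycle series (e.g. CT0..CT44) are fitted un-folded at a 24 h
period.  Normalized amplitude is amplitude/mesor of a cosinor fit after raising
every value below 1 TPM to 1 (the "floor-to-1" convention), which prevents very
low-expressed genes from reporting huge relative amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "CosineFit",
    "ActivityRecord",
    "PeriodogramResult",
    "cosinor_fit",
    "detect_cosinor",
    "detect_rank_template",
    "detect_ar_spectral",
    "bh_fdr",
    "consensus_call",
    "venn_counts",
    "threshold_sweep",
    "relative_amplitude",
    "chi_square_periodogram",
    "lesion_check",
]

DETECTOR_COLUMNS = ["gene_id", "method", "p_value", "q_value",
                    "period_est", "phase_est", "amp_est"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x time-points TPM matrix.

    ``times`` are CT/ZT hours, strictly increasing; ``values`` is a
    (n_genes, n_times) non-negative array.
    """

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), self.times.size):
            raise ValueError("values shape does not match gene_ids x times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("TPM values must be finite and non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def filtered_background(self, min_mean_tpm: float = 1.0) -> "ExpressionMatrix":
        """Genes with mean TPM >= 1 across samples (the detection/enrichment universe)."""
        keep = self.values.mean(axis=1) >= min_mean_tpm
        return ExpressionMatrix([g for g, k in zip(self.gene_ids, keep) if k],
                                self.times, self.values[keep])

    def subset(self, gene_ids) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.times, self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=[f"CT{t:g}" for t in self.times])


@dataclass
class CosineFit:
    """Parameters of a (possibly damped) cosine fit.

    y(t) = mesor + amplitude * exp(-damping_rate * t) * cos(2*pi*(t - phase_h)/period_h)
    """

    mesor: float
    amplitude: float
    period_h: float
    phase_h: float
    r2: float
    p_value: float = float("nan")
    damping_rate: float = 0.0
    at_period_bound: bool = False


@dataclass
class ActivityRecord:
    """Minute-binned locomotor activity counts."""

    counts: np.ndarray
    bin_minutes: float = 1.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("activity counts must be non-negative")

    @property
    def duration_h(self) -> float:
        return self.counts.size * self.bin_minutes / 60.0


@dataclass
class PeriodogramResult:
    periods: np.ndarray
    qp: np.ndarray
    sig_line: np.ndarray
    alpha: float
    peak_period: float
    peak_excess: float
    circadian_range: tuple[float, float] = (20.0, 28.0)


# ---------------------------------------------------------------------------
# cosinor (harmonic regression) — the fixed-period third detector
# ---------------------------------------------------------------------------

def _cosinor_design(times: np.ndarray, period_h: float) -> np.ndarray:
    w = 2.0 * np.pi / period_h
    return np.column_stack([np.ones_like(times), np.cos(w * times), np.sin(w * times)])


def cosinor_fit(times, values, period_h: float = 24.0) -> CosineFit:
    """Least-squares cosinor fit at a fixed period with an F-test of rhythmicity.

    Fits ``y = M + a*cos(wt) + b*sin(wt)`` by linear regression; amplitude is
    ``hypot(a, b)``, acrophase is the peak time in ``[0, period_h)``, and the
    p-value is the F-test of the joint cos/sin terms against an intercept-only
    model.  A constant series returns amplitude 0 and p = 1.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("times and values must have equal length")
    if t.size < 4:
        raise ValueError("cosinor fit needs at least 4 time points")
    if period_h <= 0:
        raise ValueError("period_h must be positive")

    X = _cosinor_design(t, period_h)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))

    if sst <= 1e-300:  # constant series: nothing to explain
        return CosineFit(mesor=float(y.mean()), amplitude=0.0, period_h=period_h,
                         phase_h=0.0, r2=0.0, p_value=1.0)

    mesor = float(beta[0])
    amplitude = float(np.hypot(beta[1], beta[2]))
    phase = float((np.arctan2(beta[2], beta[1]) * period_h / (2.0 * np.pi)) % period_h)
    r2 = 1.0 - sse / sst
    dfe = t.size - 3
    if sse <= 1e-300 * sst:
        p = 0.0
    else:
        f = ((sst - sse) / 2.0) / (sse / dfe)
        p = float(stats.f.sf(f, 2, dfe))
    return CosineFit(mesor=mesor, amplitude=amplitude, period_h=period_h,
                     phase_h=phase, r2=float(r2), p_value=p)


def _vectorized_cosinor(times: np.ndarray, Y: np.ndarray, period_h: float):
    """Cosinor fit of every row of Y at once.

    Returns (mesor, amplitude, phase in [0, period), p_value, r2) arrays.
    """
    n = times.size
    X = _cosinor_design(times, period_h)
    beta = np.linalg.lstsq(X, Y.T, rcond=None)[0]        # (3, G)
    fitted = (X @ beta).T
    sse = np.sum((Y - fitted) ** 2, axis=1)
    sst = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)

    mesor = beta[0]
    amplitude = np.hypot(beta[1], beta[2])
    phase = (np.arctan2(beta[2], beta[1]) * period_h / (2.0 * np.pi)) % period_h

    dfe = n - 3
    const = sst <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((sst - sse) / 2.0) / (sse / dfe)
        p = stats.f.sf(f, 2, dfe)
        r2 = 1.0 - sse / np.where(const, 1.0, sst)
    p = np.where(const, 1.0, np.where(sse <= 1e-300 * np.maximum(sst, 1e-300), 0.0, p))
    amplitude = np.where(const, 0.0, amplitude)
    phase = np.where(const, 0.0, phase)
    r2 = np.where(const, 0.0, r2)
    return mesor, amplitude, phase, p, r2


def relative_amplitude(values, times=None, floor: float = 1.0,
                       period_h: float = 24.0) -> float:
    """Floor-normalized relative amplitude (amplitude/mesor).

    Values below ``floor`` (1 TPM by default) are raised to the floor before the
    cosinor fit, so the relative amplitude of barely-expressed genes is not
    inflated by division with a near-zero mesor.
    """
    y = np.maximum(np.asarray(values, dtype=float), floor)
    if times is None:
        times = np.arange(y.size) * 4.0
    fit = cosinor_fit(times, y, period_h=period_h)
    if fit.amplitude == 0.0 or fit.mesor <= 0:
        return 0.0
    return fit.amplitude / fit.mesor


def _relative_amplitudes(times: np.ndarray, Y: np.ndarray, floor: float = 1.0,
                         period_h: float = 24.0) -> np.ndarray:
    Yf = np.maximum(Y, floor)
    mesor, amplitude, _, _, _ = _vectorized_cosinor(times, Yf, period_h)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = amplitude / mesor
    return np.where((amplitude <= 0) | (mesor <= 0), 0.0, rel)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# detector 1: fixed-period cosinor over a matrix
# ---------------------------------------------------------------------------

def detect_cosinor(matrix: ExpressionMatrix, period_h: float = 24.0) -> pd.DataFrame:
    """Per-gene cosinor F-test at a fixed 24 h period.

    The acrophase of this detector is the phase estimate used downstream (the
    per-gene peak time in CT hours).
    """
    if matrix.n_genes == 0:
        raise ValueError("empty expression matrix")
    if matrix.times.size < 4:
        raise ValueError("need at least 4 time points")
    _, _, phase, p, _ = _vectorized_cosinor(matrix.times, matrix.values, period_h)
    amp = _relative_amplitudes(matrix.times, matrix.values, period_h=period_h)
    return pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "method": "cosinor",
        "p_value": p,
        "q_value": bh_fdr(p),
        "period_est": period_h,
        "phase_est": phase % 24.0,
        "amp_est": amp,
    })


# ---------------------------------------------------------------------------
# detector 2: rank/template permutation test (eJTK-style)
# ---------------------------------------------------------------------------

def _templates(times: np.ndarray, phase_step_h: float = 2.0,
               period_h: float = 24.0,
               asymmetries: tuple[float, ...] = (0.5,)) -> tuple[np.ndarray, np.ndarray]:
    """Cosine reference waveforms with phases on a grid, optionally asymmetric.

    An asymmetry ``f`` makes the waveform rise over a fraction ``f`` of the
    cycle and fall over ``1 - f`` (``f = 0.5`` is the symmetric cosine).
    Returns (templates, phases) with templates of shape (K, n_times).
    """
    phases = np.arange(0.0, period_h, phase_step_h)
    rows, phase_of_row = [], []
    for f in asymmetries:
        if not 0.0 < f < 1.0:
            raise ValueError("asymmetry fraction must lie in (0, 1)")
        for ph in phases:
            u = ((times - ph) % period_h) / period_h
            # warp cycle position so the descending half occupies (1 - f)
            g = np.where(u < (1.0 - f), 0.5 * u / (1.0 - f),
                         0.5 + 0.5 * (u - (1.0 - f)) / f)
            rows.append(np.cos(2.0 * np.pi * g))
            phase_of_row.append(ph)
    return np.asarray(rows), np.asarray(phase_of_row)


def _pair_signs(V: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray) -> np.ndarray:
    return np.sign(V[:, idx_i] - V[:, idx_j])


def _max_tau(values: np.ndarray, tmpl_signs: np.ndarray, tmpl_untied: np.ndarray,
             idx_i: np.ndarray, idx_j: np.ndarray):
    """Max Kendall tau-b of each row of ``values`` against the template bank."""
    s = _pair_signs(values, idx_i, idx_j)                 # (G, P)
    untied = (s != 0).sum(axis=1).astype(float)           # P - ties per series
    num = s @ tmpl_signs.T                                # (G, K)
    den = np.sqrt(np.outer(untied, tmpl_untied))
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(den > 0, num / den, 0.0)
    best = np.argmax(tau, axis=1)
    return tau[np.arange(tau.shape[0]), best], best


def detect_rank_template(matrix: ExpressionMatrix, n_perm: int = 999,
                         seed: int = 0, phase_step_h: float = 2.0,
                         asymmetries: tuple[float, ...] = (0.5,)) -> pd.DataFrame:
    """Nonparametric rank-concordance detector with a permutation p-value.

    The statistic is the maximum Kendall tau-b between a gene's values and a
    bank of cosine reference waveforms (period 24 h, phases every 2 h).  The
    empirical p is ``(1 + #{permuted >= observed}) / (n_perm + 1)`` where
    permutations shuffle the time labels.  Because the statistic is rank-based,
    its permutation distribution for a tie-free series depends only on the rank
    order — a single seeded null sample therefore serves every tie-free gene;
    genes with tied values get their own permutations.
    """
    if matrix.n_genes == 0:
        raise ValueError("empty expression matrix")
    n = matrix.times.size
    if n < 8:
        raise ValueError("rank-template detection needs at least 8 time points")
    if n_perm < 999:
        raise ValueError("n_perm must be at least 999")

    idx_i, idx_j = map(np.asarray, zip(*combinations(range(n), 2)))
    tmpl, tmpl_phase = _templates(matrix.times, phase_step_h=phase_step_h,
                                  asymmetries=asymmetries)
    tmpl_signs = _pair_signs(tmpl, idx_i, idx_j)
    tmpl_untied = (tmpl_signs != 0).sum(axis=1).astype(float)

    Y = matrix.values
    stat, best = _max_tau(Y, tmpl_signs, tmpl_untied, idx_i, idx_j)

    rng = np.random.default_rng(seed)
    # shared pivotal null for tie-free series: permuted time labels of any
    # tie-free series give the same max-tau distribution as a random rank order
    perms = np.argsort(rng.random((n_perm, n)), axis=1).astype(float)
    null_stat, _ = _max_tau(perms, tmpl_signs, tmpl_untied, idx_i, idx_j)
    null_sorted = np.sort(null_stat)

    has_ties = np.array([np.unique(row).size < n for row in Y])
    # number of permuted stats >= observed, via the sorted shared null
    ge = n_perm - np.searchsorted(null_sorted, stat - 1e-12, side="left")
    p = (1.0 + ge) / (n_perm + 1.0)

    for g in np.nonzero(has_ties)[0]:  # per-gene null when ranks are not unique
        row = Y[g]
        perm_vals = np.array([row[pi] for pi in
                              (rng.permutation(n) for _ in range(n_perm))])
        ns, _ = _max_tau(perm_vals, tmpl_signs, tmpl_untied, idx_i, idx_j)
        p[g] = (1.0 + np.sum(ns >= stat[g] - 1e-12)) / (n_perm + 1.0)

    amp = _relative_amplitudes(matrix.times, Y)
    return pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "method": "rank_template",
        "p_value": p,
        "q_value": bh_fdr(p),
        "period_est": 24.0,
        "phase_est": tmpl_phase[best] % 24.0,
        "amp_est": amp,
    })


def max_template_tau(values, times, phase_step_h: float = 2.0,
                     asymmetries: tuple[float, ...] = (0.5,)):
    """Observed statistic of the rank/template detector for one series."""
    t = np.asarray(times, dtype=float)
    idx_i, idx_j = map(np.asarray, zip(*combinations(range(t.size), 2)))
    tmpl, tmpl_phase = _templates(t, phase_step_h=phase_step_h, asymmetries=asymmetries)
    ts = _pair_signs(tmpl, idx_i, idx_j)
    tu = (ts != 0).sum(axis=1).astype(float)
    stat, best = _max_tau(np.asarray(values, dtype=float)[None, :], ts, tu, idx_i, idx_j)
    return float(stat[0]), float(tmpl_phase[best[0]])


# ---------------------------------------------------------------------------
# detector 3: autoregressive-spectral period estimate + harmonic regression
# ---------------------------------------------------------------------------

def _ar_fit_aic(y: np.ndarray, max_order: int):
    """Forward-backward least-squares AR fit with AIC order selection.

    The modified-covariance estimator (unconstrained forward+backward
    prediction-error least squares) locates spectral poles far better than
    Yule-Walker or Burg on the short (12-point) records this detector sees;
    order 0 (flat spectrum) is allowed and wins on white noise.
    """
    n = y.size
    var0 = float(np.dot(y, y) / n)
    if var0 <= 0:
        return np.array([]), 0.0
    best = (n * np.log(max(var0, 1e-300)), np.array([]), var0)  # order 0
    for p in range(1, max_order + 1):
        rows = [y[i - 1::-1][:p] for i in range(p, n)]          # forward
        rows += [y[i + 1: i + 1 + p] for i in range(n - p)]     # backward
        rhs = np.concatenate([y[p:], y[: n - p]])
        A = np.asarray(rows)
        phi, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        sigma2 = float(np.mean((rhs - A @ phi) ** 2))
        if not np.isfinite(sigma2) or sigma2 < 0:
            continue
        aic = n * np.log(max(sigma2, 1e-300)) + 2.0 * p
        if aic < best[0]:
            best = (aic, phi, sigma2)
    return best[1], best[2]


def _ar_spectrum(phi: np.ndarray, sigma2: float, freqs: np.ndarray) -> np.ndarray:
    """AR spectral density at frequencies in cycles per sample."""
    if phi.size == 0:
        return np.full(freqs.size, sigma2)
    k = np.arange(1, phi.size + 1)
    z = 1.0 - np.exp(-2j * np.pi * np.outer(freqs, k)) @ phi
    return sigma2 / np.abs(z) ** 2


def detect_ar_spectral(matrix: ExpressionMatrix,
                       period_window: tuple[float, float] = (20.0, 28.0),
                       period_step_h: float = 0.1) -> pd.DataFrame:
    """AR-spectral detector (ARSER-style): detrend, AR spectrum, harmonic fit.

    Each gene is linearly detrended (the slope is estimated jointly with a
    24 h harmonic so a circadian oscillation does not leak into the trend on a
    two-cycle record); an autoregressive model (Burg, order by AIC, capped at
    n/3) provides a spectral density whose peak inside ``period_window``
    selects the candidate period (falling back to 24 h when there is no
    interior peak); the p-value is the cosinor F-test at that period.
    Requires evenly spaced times.
    """
    if matrix.n_genes == 0:
        raise ValueError("empty expression matrix")
    t = matrix.times
    if t.size < 10:
        raise ValueError("AR-spectral detection needs at least 10 time points")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0]):
        raise ValueError("AR-spectral detection requires evenly spaced times")
    dt = float(dt[0])

    periods = np.arange(period_window[0], period_window[1] + 1e-9, period_step_h)
    freqs = dt / periods  # cycles per sample
    max_order = max(1, t.size // 3)
    w24 = 2.0 * np.pi / 24.0
    trend_X = np.column_stack([np.ones_like(t), t,
                               np.cos(w24 * t), np.sin(w24 * t)])

    cand = np.empty(matrix.n_genes)
    for g in range(matrix.n_genes):
        y = matrix.values[g]
        coef, *_ = np.linalg.lstsq(trend_X, y, rcond=None)
        resid = y - trend_X[:, :2] @ coef[:2]  # remove intercept+slope only
        if np.var(resid) <= 1e-300:
            cand[g] = 24.0
            continue
        phi, sigma2 = _ar_fit_aic(resid, max_order)
        psd = _ar_spectrum(phi, sigma2, freqs)
        k = int(np.argmax(psd))
        cand[g] = periods[k] if 0 < k < periods.size - 1 else 24.0

    p = np.empty(matrix.n_genes)
    phase = np.empty(matrix.n_genes)
    for g in range(matrix.n_genes):
        fit = cosinor_fit(t, matrix.values[g], period_h=cand[g])
        p[g] = fit.p_value
        phase[g] = fit.phase_h % 24.0

    amp = _relative_amplitudes(t, matrix.values)
    return pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "method": "ar_spectral",
        "p_value": p,
        "q_value": bh_fdr(p),
        "period_est": cand,
        "phase_est": phase,
        "amp_est": amp,
    })


# ---------------------------------------------------------------------------
# consensus and threshold sweep
# ---------------------------------------------------------------------------

_RULES = {
    "all": lambda hits: hits.all(axis=1),
    "any": lambda hits: hits.any(axis=1),
    "majority": lambda hits: hits.sum(axis=1) * 2 > hits.shape[1],
}


def _q_table(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-method q values aligned on a shared gene universe."""
    if not results:
        raise ValueError("no detector results given")
    tables = {}
    universe = None
    for method, df in results.items():
        s = df.set_index("gene_id")["q_value"]
        if universe is None:
            universe = set(s.index)
        elif set(s.index) != universe:
            raise ValueError("detector results cover different gene sets")
        tables[method] = s
    first = next(iter(results.values()))
    return pd.DataFrame(tables).loc[first["gene_id"].tolist()]


def consensus_call(results: dict[str, pd.DataFrame], q_threshold: float = 0.4,
                   rule: str = "all") -> pd.DataFrame:
    """Combine per-method q values into a single rhythmic call.

    ``rule`` is "all" (intersection of methods, the default, which minimizes
    low-amplitude false positives), "any" (union) or "majority".
    """
    if rule not in _RULES:
        raise ValueError(f"unknown rule {rule!r}")
    qs = _q_table(results)
    hits = qs.values < q_threshold
    out = qs.reset_index().rename(columns={"index": "gene_id"})
    out.columns = ["gene_id"] + [f"q_{m}" for m in qs.columns]
    out["rhythmic"] = _RULES[rule](hits)
    out.attrs["rule"] = rule
    out.attrs["q_threshold"] = q_threshold
    return out


def venn_counts(results: dict[str, pd.DataFrame], q_threshold: float = 0.4) -> dict:
    """Counts of genes per method combination at a q threshold (Venn regions)."""
    qs = _q_table(results)
    hits = qs < q_threshold
    counts: dict[frozenset, int] = {}
    for _, row in hits.iterrows():
        key = frozenset(m for m in qs.columns if row[m])
        counts[key] = counts.get(key, 0) + 1
    return {"+".join(sorted(k)) if k else "none": v for k, v in counts.items()}


def threshold_sweep(results: dict[str, pd.DataFrame], q_grid) -> pd.DataFrame:
    """Number of rhythmic genes per method and consensus rule along a q grid."""
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.size == 0:
        raise ValueError("empty threshold grid")
    if np.any((q_grid <= 0) | (q_grid > 1)):
        raise ValueError("thresholds must lie in (0, 1]")
    qs = _q_table(results)
    rows = []
    for thr in q_grid:
        hits = qs.values < thr
        for j, m in enumerate(qs.columns):
            rows.append({"q_threshold": thr, "method": m,
                         "n_rhythmic": int(hits[:, j].sum())})
        for rule, fn in _RULES.items():
            rows.append({"q_threshold": thr, "method": f"consensus_{rule}",
                         "n_rhythmic": int(fn(hits).sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chi-square periodogram and lesion verification
# ---------------------------------------------------------------------------

def chi_square_periodogram(activity: ActivityRecord, period_grid_h=(16.0, 32.0),
                           alpha: float = 1e-4, column_minutes: float = 6.0,
                           circadian_range: tuple[float, float] = (20.0, 28.0),
                           ) -> PeriodogramResult:
    """Sokolove-Bushell chi-square periodogram of an activity record.

    Counts are aggregated into ``column_minutes`` columns; for each trial
    period of B columns the series is folded and
    ``Qp = N * Var(column means) / Var(all samples)`` (population variances;
    equivalently K * sum_h (M_h - M.)^2 / s^2 with K rows per fold) is
    compared with the chi-square critical value at ``1 - alpha`` with
    ``B - 1`` df, which is Qp's approximate null distribution.  The peak is
    reported within the circadian range and its excess over the significance
    line (0 when not significant).
    """
    agg = int(round(column_minutes / activity.bin_minutes))
    if agg < 1:
        raise ValueError("column width smaller than activity bin")
    x = activity.counts
    n_cols = x.size // agg
    x = x[: n_cols * agg].reshape(n_cols, agg).sum(axis=1)
    if np.var(x) <= 0:
        raise ValueError("zero-variance activity record: statistic undefined")

    col_h = column_minutes / 60.0
    b_lo = int(np.ceil(period_grid_h[0] / col_h))
    b_hi = int(np.floor(period_grid_h[1] / col_h))
    if n_cols < 3 * b_hi:
        raise ValueError("need at least 3 full cycles of the longest tested period")

    periods, qp, sig = [], [], []
    grand_var = np.var(x)
    for B in range(b_lo, b_hi + 1):
        n_use = (n_cols // B) * B
        folded = x[:n_use].reshape(-1, B)
        col_means = folded.mean(axis=0)
        q = n_use * np.var(col_means) / grand_var
        periods.append(B * col_h)
        qp.append(q)
        sig.append(stats.chi2.ppf(1.0 - alpha, B - 1))
    periods, qp, sig = map(np.asarray, (periods, qp, sig))

    in_range = (periods >= circadian_range[0]) & (periods <= circadian_range[1])
    if not in_range.any():
        raise ValueError("period grid does not cover the circadian range")
    k = np.nonzero(in_range)[0][np.argmax(qp[in_range])]
    excess = max(float(qp[k] - sig[k]), 0.0)
    return PeriodogramResult(periods=periods, qp=qp, sig_line=sig, alpha=alpha,
                             peak_period=float(periods[k]), peak_excess=excess,
                             circadian_range=circadian_range)


def lesion_check(test: PeriodogramResult, control_peak_excess_avg: float) -> bool:
    """Arrhythmicity verification: peak excess strictly below 10% of control.

    Returns True when the tested record qualifies as arrhythmic (SCN-lesion
    verified), i.e. its significant periodogram peak excess in the circadian
    range is below 10% of the average control peak excess.
    """
    if control_peak_excess_avg <= 0:
        raise ValueError("control average peak excess must be positive")
    return test.peak_excess < 0.10 * control_peak_excess_avg
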