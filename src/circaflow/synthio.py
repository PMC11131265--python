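"""Synthetic inputs with known ground truth for every pipeline stage.

Generates circadian expression matrices (two-day, 4-h sampling), minute-binned
locomotor activity, bioluminescence image stacks with cell-sized rhythmic
regions, and flat gene-set collections.  Every generator takes an explicit seed
and is bit-reproducible.

The transcriptome generator emulates the statistical structure of a bulk TPM
time course: log-normal baseline expression, a rhythmic fraction with cosine
profiles whose peak phases follow a bimodal circular mixture centred near CT12
and CT20, multiplicative log-normal noise (mean-one, so the marginal mean of a
gene equals its deterministic profile), and three condition designs — a
control-like series, a lesion-like series in which all true amplitudes are
multiplied by a collapse factor, and a knockout-like design sampled at only
two time points (ZT7 and ZT18).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rhythmdet import ActivityRecord, ExpressionMatrix

__all__ = [
    "SimConfig",
    "BiolumSimConfig",
    "TranscriptomeTruth",
    "GeneSetCollection",
    "ImageStack",
    "gen_transcriptome",
    "gen_activity",
    "gen_biolum_stack",
    "gen_gene_sets",
]

DEFAULT_TIMEPOINTS = tuple(float(t) for t in range(0, 48, 4))   # CT0..CT44
KO_TIMEPOINTS = (7.0, 18.0)                                     # ZT7, ZT18


# ---------------------------------------------------------------------------
# configs and truth records
# ---------------------------------------------------------------------------

@dataclass
class TranscriptomeTruth:
    gene_id: str
    is_rhythmic: bool
    baseline: float
    rel_amplitude: float
    phase_ct: float
    period_h: float
    noise_sigma: float


@dataclass
class SimConfig:
    """Transcriptome simulation parameters.

    The defaults mirror the study design: 12 samples every 4 h over two
    circadian cycles, one replicate per time point.  ``phase_mixture`` is a
    two-component von Mises mixture (centres in CT hours, concentrations,
    weight of the first component); the defaults put most peaks near CT12 with
    a secondary mode near CT20.  ``condition`` is "control", "lesion"
    (amplitudes multiplied by ``collapse_factor``) or "ko_two_timepoint"
    (samples only at ZT7 and ZT18).
    """

    n_genes: int = 1000
    frac_rhythmic: float = 0.2
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    phase_centers_ct: tuple[float, float] = (12.0, 20.0)
    phase_kappas: tuple[float, float] = (4.0, 4.0)
    phase_weight_first: float = 0.6
    amplitude_range: tuple[float, float] = (0.1, 1.0)
    baseline_lognormal: tuple[float, float] = (2.0, 1.5)    # (mu, sigma) of ln TPM
    noise_sigma: float = 0.1
    period_h: float = 24.0
    condition: str = "control"
    collapse_factor: float = 0.2
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_rhythmic <= 1.0:
            raise ValueError("frac_rhythmic must lie in [0, 1]")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size == 0:
            raise ValueError("timepoints must be non-empty")
        if np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.condition not in ("control", "lesion", "ko_two_timepoint"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class BiolumSimConfig:
    """Bioluminescence stack simulation parameters.

    One ground-truth cell occupies each ``cell_size`` square inside the mask;
    rhythmic cells emit a damped cosine on top of a polynomial trend, with
    phases drawn from a von Mises distribution of concentration
    ``phase_concentration`` (lower = more desynchronised tissue).  Cosmic rays
    are single-pixel, single-frame positive spikes at a Poisson rate per frame.
    """

    grid_shape: tuple[int, int] = (32, 32)
    mask: np.ndarray | None = None          # default: full grid
    cell_size: int = 4
    frac_rhythmic_rois: float = 0.6
    period_range_h: tuple[float, float] = (22.0, 26.0)
    damping_rate: float = 0.01              # 1/h
    trend: tuple[float, ...] = (200.0, -0.5)  # polynomial in t (low->high order)
    mesor_range: tuple[float, float] = (300.0, 600.0)
    amplitude_range: tuple[float, float] = (100.0, 300.0)
    noise_sd: float = 5.0
    cosmic_ray_rate: float = 0.5            # events per frame over the stack
    n_frames: int = 120
    frame_interval_h: float = 1.0
    phase_center_h: float = 12.0
    phase_concentration: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if not self.mask.any():
                raise ValueError("mask must be non-empty")
            if self.cell_size > max(self.mask.shape):
                raise ValueError("cell_size larger than mask")


@dataclass
class ImageStack:
    """T x H x W stack of non-negative intensities."""

    frames: np.ndarray
    frame_interval_h: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 3:
            raise ValueError("stack must be T x H x W with T >= 3")

    @property
    def times_h(self) -> np.ndarray:
        return self.t0 + np.arange(self.frames.shape[0]) * self.frame_interval_h


@dataclass
class GeneSetCollection:
    """Flat term -> member mapping with optional term names."""

    sets: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term: str) -> set[str]:
        return self.sets[term]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def _sample_phases(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    comp = rng.random(n) >= cfg.phase_weight_first
    centers = np.asarray(cfg.phase_centers_ct)[comp.astype(int)]
    kappas = np.asarray(cfg.phase_kappas)[comp.astype(int)]
    ang = rng.vonmises(centers * 2.0 * np.pi / 24.0, kappas)
    return (ang * 24.0 / (2.0 * np.pi)) % 24.0


def gen_transcriptome(cfg: SimConfig) -> tuple[ExpressionMatrix, list[TranscriptomeTruth]]:
    """Simulate a TPM matrix plus its per-gene ground truth.

    Rhythmic gene g has expectation
    ``baseline * (1 + rel_amplitude * cos(2*pi*(t - phase_ct)/period_h))``
    with multiplicative mean-one log-normal noise; arrhythmic genes are
    constant-mean with the same noise.
    """
    rng = np.random.default_rng(cfg.seed)
    times = np.asarray(KO_TIMEPOINTS if cfg.condition == "ko_two_timepoint"
                       else cfg.timepoints, dtype=float)
    if cfg.replicates > 1:
        times = np.sort(np.tile(times, cfg.replicates) +
                        1e-6 * np.arange(times.size * cfg.replicates))

    n = cfg.n_genes
    n_rhythmic = int(round(cfg.frac_rhythmic * n))
    is_rhythmic = np.zeros(n, dtype=bool)
    is_rhythmic[rng.choice(n, size=n_rhythmic, replace=False)] = True

    mu, sig = cfg.baseline_lognormal
    baseline = np.exp(rng.normal(mu, sig, size=n))
    amp = np.where(is_rhythmic,
                   rng.uniform(*cfg.amplitude_range, size=n), 0.0)
    if cfg.condition == "lesion":
        amp = amp * cfg.collapse_factor
    phase = np.where(is_rhythmic, _sample_phases(rng, n, cfg), 0.0)

    profile = 1.0 + amp[:, None] * np.cos(
        2.0 * np.pi * (times[None, :] - phase[:, None]) / cfg.period_h)
    mean = baseline[:, None] * profile
    if cfg.noise_sigma > 0:
        noise = np.exp(rng.normal(-0.5 * cfg.noise_sigma ** 2, cfg.noise_sigma,
                                  size=mean.shape))
    else:
        noise = 1.0
    values = np.maximum(mean * noise, 0.0)

    gene_ids = [f"gene{g:05d}" for g in range(n)]
    truth = [TranscriptomeTruth(gene_id=gene_ids[g], is_rhythmic=bool(is_rhythmic[g]),
                                baseline=float(baseline[g]),
                                rel_amplitude=float(amp[g]),
                                phase_ct=float(phase[g]) if is_rhythmic[g] else 0.0,
                                period_h=cfg.period_h,
                                noise_sigma=cfg.noise_sigma)
             for g in range(n)]
    return ExpressionMatrix(gene_ids, times, values), truth


def truth_frame(truth: list[TranscriptomeTruth]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truth])


# ---------------------------------------------------------------------------
# locomotor activity
# ---------------------------------------------------------------------------

def gen_activity(days: int, period_h: float | None = 24.0,
                 counts_per_min: float = 5.0, quiescent_fraction: float = 0.1,
                 seed: int = 0) -> ActivityRecord:
    """Minute-binned Poisson activity counts.

    With a period, the rate follows a square wave — active half of the cycle at
    ``counts_per_min``, quiescent half at ``quiescent_fraction`` of it (a
    nocturnal rodent's consolidated activity bout).  Without a period the
    record is homogeneous Poisson, the arrhythmic (SCN-lesioned) pattern.
    """
    if days < 3:
        raise ValueError("need at least 3 days of activity")
    if counts_per_min <= 0:
        raise ValueError("counts_per_min must be positive")
    rng = np.random.default_rng(seed)
    minutes = np.arange(days * 24 * 60)
    if period_h is None:
        rate = np.full(minutes.size, counts_per_min)
    else:
        phase = (minutes / 60.0) % period_h
        rate = np.where(phase < period_h / 2.0, counts_per_min,
                        counts_per_min * quiescent_fraction)
    return ActivityRecord(counts=rng.poisson(rate).astype(float), bin_minutes=1.0)


# ---------------------------------------------------------------------------
# bioluminescence stacks
# ---------------------------------------------------------------------------

def gen_biolum_stack(cfg: BiolumSimConfig) -> tuple[ImageStack, pd.DataFrame]:
    """Simulate a bioluminescence stack plus a per-cell/spike truth table.

    Returns the stack and a truth DataFrame with one row per ground-truth cell
    (columns: cell_id, row0, col0, rows, cols, is_rhythmic, mesor, amplitude,
    period_h, phase_h, damping_rate) whose ``attrs['cosmic_rays']`` holds the
    injected spike log (frame, row, col, magnitude).
    """
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.grid_shape
    mask = (np.ones((H, W), dtype=bool) if cfg.mask is None else cfg.mask)
    if mask.shape != (H, W):
        raise ValueError("mask shape must equal grid_shape")
    if not mask.any():
        raise ValueError("mask must be non-empty")

    t = np.arange(cfg.n_frames) * cfg.frame_interval_h
    trend = np.polynomial.polynomial.polyval(t, np.asarray(cfg.trend))
    stack = np.zeros((cfg.n_frames, H, W))

    cells = []
    cs = cfg.cell_size
    for r0 in range(0, H, cs):
        for c0 in range(0, W, cs):
            sub = mask[r0: r0 + cs, c0: c0 + cs]
            if not sub.any():
                continue
            rhythmic = rng.random() < cfg.frac_rhythmic_rois
            mesor = rng.uniform(*cfg.mesor_range)
            if rhythmic:
                amplitude = rng.uniform(*cfg.amplitude_range)
                period = rng.uniform(*cfg.period_range_h)
                ang = rng.vonmises(cfg.phase_center_h * 2 * np.pi / 24.0,
                                   cfg.phase_concentration)
                phase = (ang * 24.0 / (2 * np.pi)) % 24.0
                signal = mesor + amplitude * np.exp(-cfg.damping_rate * t) * \
                    np.cos(2 * np.pi * (t - phase) / period)
            else:
                amplitude, period, phase = 0.0, np.nan, np.nan
                signal = np.full(cfg.n_frames, mesor)
            signal = signal + trend
            block = stack[:, r0: r0 + cs, c0: c0 + cs]
            block[:, sub] = signal[:, None]
            cells.append({"cell_id": f"cell_{r0}_{c0}", "row0": r0, "col0": c0,
                          "rows": sub.shape[0], "cols": sub.shape[1],
                          "is_rhythmic": rhythmic, "mesor": mesor,
                          "amplitude": amplitude, "period_h": period,
                          "phase_h": phase, "damping_rate": cfg.damping_rate})

    if cfg.noise_sd > 0:
        stack = stack + rng.normal(0.0, cfg.noise_sd, size=stack.shape)
    stack[:, ~mask] = 0.0
    stack = np.maximum(stack, 0.0)

    spikes = []
    if cfg.cosmic_ray_rate > 0:
        mask_idx = np.flatnonzero(mask)
        # spikes only on interior frames so both temporal neighbours exist
        for frame in range(1, cfg.n_frames - 1):
            for _ in range(rng.poisson(cfg.cosmic_ray_rate)):
                flat = int(rng.choice(mask_idx))
                r, c = divmod(flat, W)
                floor_mag = 5.0 * cfg.noise_sd if cfg.noise_sd > 0 else 50.0
                mag = rng.uniform(2.0, 5.0) * floor_mag
                stack[frame, r, c] += mag
                spikes.append({"frame": frame, "row": r, "col": c, "magnitude": mag})

    truth = pd.DataFrame(cells)
    truth.attrs["cosmic_rays"] = pd.DataFrame(
        spikes, columns=["frame", "row", "col", "magnitude"])
    return ImageStack(frames=stack, frame_interval_h=cfg.frame_interval_h), truth


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def gen_gene_sets(n_terms: int, sizes, background,
                  enriched_term_spec: dict | None = None,
                  seed: int = 0) -> GeneSetCollection:
    """Random flat gene sets sampled from a background universe.

    ``enriched_term_spec`` may designate one term to be enriched in a study
    set: ``{"term": "term0000", "study": <gene set>, "overlap": k}`` forces
    exactly ``k`` of that term's members to come from the study set.
    """
    background = list(background)
    if not background:
        raise ValueError("background must be non-empty")
    sizes = list(np.broadcast_to(np.asarray(sizes), (n_terms,)))
    if any(s > len(background) for s in sizes):
        raise ValueError("term size exceeds background size")
    rng = np.random.default_rng(seed)

    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for i in range(n_terms):
        term = f"term{i:04d}"
        sets[term] = set(rng.choice(background, size=int(sizes[i]), replace=False))
        names[term] = f"synthetic term {i}"

    if enriched_term_spec is not None:
        term = enriched_term_spec["term"]
        study = list(enriched_term_spec["study"])
        k = int(enriched_term_spec["overlap"])
        size = len(sets[term])
        if k > size or k > len(study):
            raise ValueError("requested overlap exceeds term or study size")
        inside = rng.choice(study, size=k, replace=False)
        outside_pool = [g for g in background if g not in set(study)]
        outside = rng.choice(outside_pool, size=size - k, replace=False)
        sets[term] = set(inside) | set(outside)
    return GeneSetCollection(sets=sets, names=names)
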