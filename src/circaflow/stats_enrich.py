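"""Enrichment and group-difference statistics.

Hypergeometric over-representation analysis of a study gene set against a
filtered background with BH-FDR over terms; the per-gene normalized day-night
difference statistic used to compare sampling designs with different time
grids; and the nonparametric group tests (Mann-Whitney U, Wilcoxon
signed-rank, Kruskal-Wallis with Dunn's post-hoc, BH-adjusted across pairs).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .rhythmdet import ExpressionMatrix, bh_fdr
from .synthio import GeneSetCollection

__all__ = [
    "hypergeom_ora",
    "day_night_stat",
    "compare_groups",
    "dunn_posthoc",
]

# nearest sampled analogs of ZT7 (day) and ZT18 (night) on the CT0..CT44 grid,
# averaged across the two recorded cycles
DEFAULT_DAY_TIMES = (8.0, 32.0)
DEFAULT_NIGHT_TIMES = (20.0, 44.0)


def hypergeom_ora(study, collection: GeneSetCollection, background) -> pd.DataFrame:
    """Over-representation of each term in a study set against a background.

    p is the upper-tail hypergeometric probability of observing at least the
    seen overlap when drawing ``|study|`` genes from ``|background|`` of which
    ``|term & background|`` belong to the term; q is BH over the tested terms.
    Terms with no background intersection are skipped.
    """
    study = set(study)
    background = set(background)
    if not background:
        raise ValueError("background must be non-empty")
    if not study:
        raise ValueError("study set must be non-empty")
    if not study <= background:
        raise ValueError("study set must be a subset of the background")

    N, n = len(background), len(study)
    rows = []
    for term, members in collection.items():
        K = len(members & background)
        if K == 0:
            continue
        k = len(members & study)
        expected = n * K / N
        fold = (k / n) / (K / N)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term,
                     "name": collection.names.get(term, term),
                     "overlap": k, "term_in_background": K,
                     "expected": expected, "fold_enrichment": fold,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term_id", "name", "overlap",
                                      "term_in_background", "expected",
                                      "fold_enrichment", "p"])
    out["q"] = bh_fdr(out["p"].values) if len(out) else []
    return out


def day_night_stat(matrix: ExpressionMatrix, day_times=DEFAULT_DAY_TIMES,
                   night_times=DEFAULT_NIGHT_TIMES,
                   genes=None) -> pd.DataFrame:
    """Absolute normalized day-night difference per gene.

    Each gene's values are divided by the gene's mean over all its samples
    (scale-free, so designs with different time grids are comparable), then
    d = |mean(day values) - mean(night values)|.
    """
    day_times = np.asarray(day_times, dtype=float)
    night_times = np.asarray(night_times, dtype=float)
    if day_times.size == 0 or night_times.size == 0:
        raise ValueError("day and night selections must be non-empty")
    day_idx = _time_indices(matrix.times, day_times)
    night_idx = _time_indices(matrix.times, night_times)

    sub = matrix if genes is None else matrix.subset(genes)
    mean_all = sub.values.mean(axis=1)
    if np.any(mean_all <= 0):
        raise ValueError("cannot normalize genes with zero mean expression")
    norm = sub.values / mean_all[:, None]
    d = np.abs(norm[:, day_idx].mean(axis=1) - norm[:, night_idx].mean(axis=1))
    return pd.DataFrame({"gene_id": sub.gene_ids, "d_value": d})


def _time_indices(times: np.ndarray, wanted: np.ndarray) -> np.ndarray:
    idx = []
    for w in wanted:
        hits = np.nonzero(np.isclose(times, w))[0]
        if hits.size == 0:
            raise ValueError(f"time point {w} not present in matrix")
        idx.append(hits[0])
    return np.asarray(idx)


def compare_groups(groups: dict[str, np.ndarray], test: str = "mann_whitney"):
    """Two-sided nonparametric comparison of sample groups.

    ``mann_whitney`` and ``wilcoxon_signed_rank`` need exactly two groups
    (paired and of equal length for Wilcoxon); ``kruskal_dunn`` accepts two or
    more and returns the omnibus Kruskal-Wallis result together with Dunn's
    pairwise z tests, BH-adjusted across pairs.  Ties are handled by midranks.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size == 0 for a in arrays.values()):
        raise ValueError("empty group")

    if test == "mann_whitney":
        if len(arrays) != 2:
            raise ValueError("Mann-Whitney needs exactly 2 groups")
        a, b = arrays.values()
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return {"test": test, "statistic": float(stat), "p": float(p)}

    if test == "wilcoxon_signed_rank":
        if len(arrays) != 2:
            raise ValueError("Wilcoxon signed-rank needs exactly 2 paired groups")
        a, b = arrays.values()
        if a.size != b.size:
            raise ValueError("paired groups must have equal length")
        if np.allclose(a, b):
            return {"test": test, "statistic": 0.0, "p": 1.0}
        stat, p = stats.wilcoxon(a, b, alternative="two-sided")
        return {"test": test, "statistic": float(stat), "p": float(p)}

    if test == "kruskal_dunn":
        if len(arrays) < 2:
            raise ValueError("Kruskal-Wallis needs at least 2 groups")
        pooled = np.concatenate(list(arrays.values()))
        if np.all(pooled == pooled[0]):  # degenerate: nothing to rank
            return {"test": test, "statistic": 0.0, "p": 1.0,
                    "dunn": dunn_posthoc(arrays)}
        stat, p = stats.kruskal(*arrays.values())
        return {"test": test, "statistic": float(stat), "p": float(p),
                "dunn": dunn_posthoc(arrays)}

    raise ValueError(f"unknown test {test!r}")


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled midranks, BH-adjusted across pairs."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    sizes = np.array([groups[g].size for g in names])
    ranks = stats.rankdata(pooled)
    N = pooled.size

    # tie correction over the pooled sample
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (N - 1))

    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array([ranks[bounds[i]: bounds[i + 1]].mean()
                           for i in range(len(names))])

    rows = []
    for i, j in combinations(range(len(names)), 2):
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": names[i], "group_b": names[j],
                     "z": float(z), "p": float(min(p, 1.0))})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_fdr(out["p"].values) if len(out) else []
    return out
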