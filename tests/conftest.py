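import numpy as np
import pytest

import circaflow as cf


@pytest.fixture
def ct_times():
    """The two-day, 4-h sampling grid (CT0..CT44)."""
    return np.arange(0.0, 48.0, 4.0)


@pytest.fixture
def small_matrix(ct_times):
    """Three genes: a clean rhythmic cosine, a constant, and a noisy flat gene."""
    rng = np.random.default_rng(7)
    rows = np.vstack([
        10.0 + 3.0 * np.cos(2 * np.pi * (ct_times - 8.0) / 24.0),
        np.full(ct_times.size, 5.0),
        np.abs(rng.normal(20.0, 1.0, ct_times.size)),
    ])
    return cf.ExpressionMatrix(["rhythmic", "flat", "noisy"], ct_times, rows)


@pytest.fixture
def null_matrix():
    """1,000 arrhythmic genes with log-normal noise."""
    cfg = cf.SimConfig(n_genes=1000, frac_rhythmic=0.0, noise_sigma=0.2, seed=11)
    matrix, _ = cf.gen_transcriptome(cfg)
    return matrix


@pytest.fixture
def rhythmic_mix():
    """Config + data with 20% rhythmic genes under the study's sampling design."""
    cfg = cf.SimConfig(n_genes=600, frac_rhythmic=0.2,
                       amplitude_range=(0.3, 1.0), noise_sigma=0.1, seed=5)
    matrix, truth = cf.gen_transcriptome(cfg)
    return cfg, matrix, truth
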