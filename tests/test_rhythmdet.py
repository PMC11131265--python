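"""Detectors, FDR, consensus, periodogram: exactness, oracles, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import circaflow as cf
from circaflow.rhythmdet import max_template_tau, venn_counts
from oracles import (bh_step_up, circular_mae_h, grid_search_cosinor_sse,
                     kendall_tau_b)


class TestCosinorFit:
    def test_noiseless_cosine_recovered_exactly(self, ct_times):
        y = 10.0 + 3.0 * np.cos(2 * np.pi * (ct_times - 8.0) / 24.0)
        fit = cf.cosinor_fit(ct_times, y)
        assert fit.mesor == pytest.approx(10.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(3.0, abs=1e-9)
        assert fit.phase_h == pytest.approx(8.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_has_zero_amplitude_and_p_one(self, ct_times):
        fit = cf.cosinor_fit(ct_times, np.full(ct_times.size, 5.0))
        assert fit.amplitude == 0.0
        assert fit.p_value == 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cf.cosinor_fit([0, 8, 16], [1, 2, 3])

    def test_matches_grid_search_oracle_on_random_instances(self, ct_times):
        rng = np.random.default_rng(0)
        for _ in range(50):
            mesor = rng.uniform(1, 50)
            amp = rng.uniform(0, 10)
            phase = rng.uniform(0, 24)
            y = mesor + amp * np.cos(2 * np.pi * (ct_times - phase) / 24.0) \
                + rng.normal(0, 1.0, ct_times.size)
            fit = cf.cosinor_fit(ct_times, y)
            fitted = fit.mesor + fit.amplitude * np.cos(
                2 * np.pi * (ct_times - fit.phase_h) / 24.0)
            sse = np.sum((y - fitted) ** 2)
            assert sse - grid_search_cosinor_sse(ct_times, y) < 1e-6


class TestRelativeAmplitude:
    def test_below_floor_series_has_zero_amplitude(self, ct_times):
        assert cf.relative_amplitude(np.full(12, 0.3), ct_times) == 0.0

    def test_floor_is_noop_above_one(self, ct_times):
        y = 10.0 + 3.0 * np.cos(2 * np.pi * (ct_times - 4.0) / 24.0)
        assert cf.relative_amplitude(y, ct_times) == pytest.approx(0.3, abs=1e-9)

    def test_series_crossing_floor_equals_fit_on_hand_floored_vector(self, ct_times):
        y = 2.1 + 1.9 * np.cos(2 * np.pi * (ct_times - 10.0) / 24.0)  # 0.2..4.0
        floored = np.maximum(y, 1.0)
        fit = cf.cosinor_fit(ct_times, floored)
        assert cf.relative_amplitude(y, ct_times) == pytest.approx(
            fit.amplitude / fit.mesor, abs=1e-12)


class TestBhFdr:
    def test_hand_computed_example(self):
        assert np.allclose(cf.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert cf.bh_fdr([1.0]) == pytest.approx([1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_matches_independent_step_up(self, ps):
        assert np.allclose(cf.bh_fdr(ps), bh_step_up(ps), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cf.bh_fdr([0.5, 1.2])


class TestDetectCosinor:
    def test_all_constant_matrix_yields_no_calls(self, ct_times):
        m = cf.ExpressionMatrix(["a", "b"], ct_times,
                                np.vstack([np.full(12, 3.0), np.full(12, 9.0)]))
        res = cf.detect_cosinor(m)
        assert (res.p_value == 1.0).all()
        assert (res.q_value >= 1.0 - 1e-12).all()

    def test_single_rhythmic_gene_has_smallest_p(self, small_matrix):
        res = cf.detect_cosinor(small_matrix)
        assert res.loc[res.p_value.idxmin(), "gene_id"] == "rhythmic"

    def test_q_matches_brute_force_bh(self, rhythmic_mix):
        _, matrix, _ = rhythmic_mix
        res = cf.detect_cosinor(matrix.filtered_background())
        assert np.allclose(res.q_value, bh_step_up(res.p_value.values))


class TestRankTemplate:
    def test_observed_tau_equals_pairwise_oracle(self, ct_times):
        rng = np.random.default_rng(1)
        from circaflow.rhythmdet import _templates
        tmpl, phases = _templates(ct_times)
        for series in [np.arange(12.0),                      # monotone
                       rng.normal(10, 3, 12)]:
            stat, best_phase = max_template_tau(series, ct_times)
            taus = [kendall_tau_b(series, tm) for tm in tmpl]
            assert stat == pytest.approx(max(taus), abs=1e-12)
            assert best_phase == phases[int(np.argmax(taus))]

    def test_template_gene_attains_minimum_p(self, ct_times):
        y = 100.0 + 50.0 * np.cos(2 * np.pi * (ct_times - 6.0) / 24.0)
        filler = np.abs(np.random.default_rng(2).normal(10, 2, (19, 12)))
        m = cf.ExpressionMatrix([f"g{i}" for i in range(20)], ct_times,
                                np.vstack([y, filler]))
        res = cf.detect_rank_template(m, n_perm=999, seed=0)
        assert res.p_value.iloc[0] == pytest.approx(1.0 / 1000.0)
        assert res.phase_est.iloc[0] == pytest.approx(6.0)

    def test_null_rejection_rate_is_valid_and_not_degenerate(self):
        # empirical p-values are valid (P(p <= a) <= a) but discrete: the
        # max-tau statistic on 12 points has ~5% atoms, so the rejection rate
        # sits at-or-below the nominal level rather than exactly on it
        cfg = cf.SimConfig(n_genes=2000, frac_rhythmic=0.0, noise_sigma=0.2,
                           seed=21)
        m, _ = cf.gen_transcriptome(cfg)
        res = cf.detect_rank_template(m, n_perm=999, seed=33)
        hits = int((res.p_value < 0.05).sum())
        hi = stats.binom.ppf(0.995, 2000, 0.05)
        assert 0.01 * 2000 <= hits <= hi

    def test_too_few_points_and_permutations_rejected(self):
        m = cf.ExpressionMatrix(["a"], np.arange(0.0, 24.0, 4.0),
                                np.arange(6.0)[None, :])
        with pytest.raises(ValueError):
            cf.detect_rank_template(m, n_perm=999, seed=0)
        m12 = cf.ExpressionMatrix(["a"], np.arange(0.0, 48.0, 4.0),
                                  np.arange(12.0)[None, :])
        with pytest.raises(ValueError):
            cf.detect_rank_template(m12, n_perm=100, seed=0)


class TestArSpectral:
    def test_noiseless_cosine_period_recovered(self, ct_times):
        y = 10.0 + 3.0 * np.cos(2 * np.pi * ct_times / 24.0)
        m = cf.ExpressionMatrix(["a"], ct_times, y[None, :])
        res = cf.detect_ar_spectral(m)
        assert abs(res.period_est.iloc[0] - 24.0) <= 0.5
        assert res.p_value.iloc[0] < 1e-6

    def test_period_recovered_under_linear_trend(self, ct_times):
        rng = np.random.default_rng(3)
        amp = 3.0
        y = 10.0 + amp * np.cos(2 * np.pi * (ct_times - 6.0) / 24.0) \
            + (amp / 24.0) * ct_times + rng.normal(0, 0.1, 12)
        m = cf.ExpressionMatrix(["a"], ct_times, np.maximum(y, 0)[None, :])
        res = cf.detect_ar_spectral(m)
        assert abs(res.period_est.iloc[0] - 24.0) <= 1.0

    def test_uneven_spacing_rejected(self):
        times = np.array([0.0, 4, 8, 12, 16, 20, 24, 28, 32, 40])
        m = cf.ExpressionMatrix(["a"], times, np.ones(10)[None, :])
        with pytest.raises(ValueError):
            cf.detect_ar_spectral(m)


class TestConsensus:
    def _results(self, qs):
        genes = [f"g{i}" for i in range(len(next(iter(qs.values()))))]
        return {m: pd.DataFrame({"gene_id": genes, "method": m,
                                 "p_value": v, "q_value": v,
                                 "period_est": 24.0, "phase_est": 0.0,
                                 "amp_est": 1.0})
                for m, v in qs.items()}

    def test_all_rule_at_default_threshold(self):
        res = self._results({"a": [0.30], "b": [0.20], "c": [0.39]})
        assert cf.consensus_call(res, 0.4, "all").rhythmic.iloc[0]

    def test_rules_differ_when_one_method_misses(self):
        res = self._results({"a": [0.30], "b": [0.50], "c": [0.10]})
        assert not cf.consensus_call(res, 0.4, "all").rhythmic.iloc[0]
        assert cf.consensus_call(res, 0.4, "any").rhythmic.iloc[0]
        assert cf.consensus_call(res, 0.4, "majority").rhythmic.iloc[0]

    def test_zero_threshold_calls_nothing(self):
        res = self._results({"a": [0.0001, 0.2], "b": [0.001, 0.3],
                             "c": [0.0005, 0.1]})
        for rule in ("all", "any", "majority"):
            assert not cf.consensus_call(res, 0.0, rule).rhythmic.any()

    def test_mismatched_gene_sets_rejected(self):
        res = self._results({"a": [0.1], "b": [0.1]})
        res["b"] = res["b"].assign(gene_id=["other"])
        with pytest.raises(ValueError):
            cf.consensus_call(res)

    def test_venn_counts_partition_the_universe(self):
        res = self._results({"a": [0.1, 0.5, 0.1], "b": [0.1, 0.1, 0.5]})
        counts = venn_counts(res, 0.4)
        assert sum(counts.values()) == 3
        assert counts["a+b"] == 1


class TestThresholdSweep:
    def test_counts_monotone_and_saturate(self, rhythmic_mix):
        _, matrix, _ = rhythmic_mix
        fb = matrix.filtered_background()
        res = {"cosinor": cf.detect_cosinor(fb),
               "ar": cf.detect_ar_spectral(fb)}
        sweep = cf.threshold_sweep(res, [0.05, 0.1, 0.2, 0.4, 1.0])
        for method, grp in sweep.groupby("method"):
            counts = grp.sort_values("q_threshold").n_rhythmic.values
            assert (np.diff(counts) >= 0).all()
        top = sweep[(sweep.q_threshold == 1.0)
                    & (sweep.method == "consensus_any")]
        assert top.n_rhythmic.iloc[0] == fb.n_genes

    def test_empty_or_invalid_grid_rejected(self, small_matrix):
        res = {"cosinor": cf.detect_cosinor(small_matrix)}
        with pytest.raises(ValueError):
            cf.threshold_sweep(res, [])
        with pytest.raises(ValueError):
            cf.threshold_sweep(res, [0.0, 0.5])

    def test_strong_rhythmic_subset_recovered_at_strict_threshold(self):
        cfg = cf.SimConfig(n_genes=1000, frac_rhythmic=0.1,
                           amplitude_range=(0.5, 1.0), noise_sigma=0.05, seed=17)
        matrix, truth = cf.gen_transcriptome(cfg)
        res = {"cosinor": cf.detect_cosinor(matrix)}
        sweep = cf.threshold_sweep(res, [0.05])
        n = sweep[sweep.method == "cosinor"].n_rhythmic.iloc[0]
        n_true = sum(t.is_rhythmic for t in truth)
        assert n_true <= n <= n_true + 0.05 * (1000 - n_true) + 3 * np.sqrt(
            0.05 * (1000 - n_true))


class TestPhaseRecovery:
    def test_cosinor_phase_circular_mae_below_one_hour(self):
        cfg = cf.SimConfig(n_genes=400, frac_rhythmic=0.5,
                           amplitude_range=(0.5, 1.0), noise_sigma=0.05, seed=23)
        matrix, truth = cf.gen_transcriptome(cfg)
        res = cf.detect_cosinor(matrix).set_index("gene_id")
        rhythmic = [t for t in truth if t.is_rhythmic]
        est = [res.loc[t.gene_id, "phase_est"] for t in rhythmic]
        assert circular_mae_h(est, [t.phase_ct for t in rhythmic]) < 1.0


class TestPeriodogram:
    def test_square_wave_peak_at_24h_above_significance(self):
        rec = cf.gen_activity(days=7, period_h=24.0, counts_per_min=10.0, seed=0)
        res = cf.chi_square_periodogram(rec)
        assert abs(res.peak_period - 24.0) <= 0.1  # one 6-min column
        assert res.peak_excess > 0

    def test_scale_invariance(self):
        rec = cf.gen_activity(days=7, period_h=24.0, seed=5)
        doubled = cf.ActivityRecord(rec.counts * 2.0)
        r1 = cf.chi_square_periodogram(rec)
        r2 = cf.chi_square_periodogram(doubled)
        assert np.allclose(r1.qp, r2.qp)

    def test_zero_variance_rejected(self):
        rec = cf.ActivityRecord(np.full(7 * 24 * 60, 3.0))
        with pytest.raises(ValueError):
            cf.chi_square_periodogram(rec)

    def test_poisson_activity_rarely_significant(self):
        crossings = 0
        for seed in range(25):
            rec = cf.gen_activity(days=7, period_h=None, counts_per_min=5.0,
                                  seed=seed)
            res = cf.chi_square_periodogram(rec)
            crossings += res.peak_excess > 0
        assert crossings <= 2


class TestLesionCheck:
    def test_ten_percent_criterion(self):
        base = cf.PeriodogramResult(np.array([24.0]), np.array([1.0]),
                                    np.array([1.0]), 1e-4, 24.0, 0.0)
        low = cf.PeriodogramResult(np.array([24.0]), np.array([1.0]),
                                   np.array([1.0]), 1e-4, 24.0, 5.0)
        mid = cf.PeriodogramResult(np.array([24.0]), np.array([1.0]),
                                   np.array([1.0]), 1e-4, 24.0, 10.0)
        high = cf.PeriodogramResult(np.array([24.0]), np.array([1.0]),
                                    np.array([1.0]), 1e-4, 24.0, 50.0)
        assert cf.lesion_check(low, 100.0)            # 5% of control
        assert not cf.lesion_check(mid, 100.0)        # exactly 10%: strict
        assert not cf.lesion_check(high, 100.0)
        with pytest.raises(ValueError):
            cf.lesion_check(base, 0.0)
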