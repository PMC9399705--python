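import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hesdyn import (
    LatticeSpec,
    ModelParams,
    SimConfig,
    analyze_spatial,
    extract_spatial_signals,
    fisher_g_pvalue,
    fisher_g_test,
    generate_signal,
    kymograph,
    mean_significant_period,
    occurrence,
    power_spectrum,
    simulate,
    white_noise_batch,
)
from hesdyn.model import Trajectory
from hesdyn.spatial import _periodogram


def _toy_trajectory(p, n_rows, n_cols):
    times = np.arange(p.shape[0], dtype=float)
    return Trajectory(spec=LatticeSpec(n_rows, n_cols), times_min=times,
                      m=np.zeros_like(p), p=p)


class TestSignalExtraction:
    def test_1d_one_signal_per_time_point(self, short_sim):
        signals, meta = extract_spatial_signals(short_sim)
        assert signals.shape == (len(short_sim.times_min), 26)
        assert (meta["column"] == 1).all()

    def test_2d_signal_count_is_k_times_j_minus_1(self):
        K, I, J = 100, 26, 6
        p = np.random.default_rng(0).random((K, I, J))
        signals, meta = extract_spatial_signals(_toy_trajectory(p, I, J))
        assert signals.shape == (K * (J - 1), I)
        assert sorted(meta["column"].unique()) == [2, 3, 4, 5, 6]

    def test_2d_even_rows_average_straddling_cells(self):
        p = np.zeros((1, 4, 3))
        p[0, :, 1] = [10, 20, 30, 40]
        p[0, :, 0] = [0, 60, 0, 80]
        signals, meta = extract_spatial_signals(_toy_trajectory(p, 4, 3))
        col2 = signals[meta["column"] == 2][0]
        # 1-based odd rows (index 0, 2) take the cell itself; even rows
        # average with the cell one column left
        assert col2.tolist() == [10, 40, 30, 60]

    def test_constant_lattice_gives_constant_signals(self):
        p = np.full((5, 8, 4), 7.0)
        signals, _ = extract_spatial_signals(_toy_trajectory(p, 8, 4))
        assert np.allclose(signals, 7.0)


class TestPowerSpectrum:
    def test_single_cosine_concentrates_power(self):
        x = np.cos(2 * np.pi * 6 * np.arange(24) / 24)
        res = power_spectrum(x)
        assert res.power.argmax() == 5  # bin k=6
        assert res.peak_period == pytest.approx(4.0)
        assert res.power[5] / res.power.sum() > 0.999

    def test_constant_signal_degenerate(self):
        res = power_spectrum(np.full(16, 3.0))
        assert res.degenerate and res.p_val == 1.0 and res.g == 0.0

    def test_two_equal_cosines_share_power(self):
        x = np.arange(24)
        sig = (np.cos(2 * np.pi * 3 * x / 24) + np.cos(2 * np.pi * 6 * x / 24))
        res = power_spectrum(sig)
        assert res.power[2] == pytest.approx(res.power[5], rel=1e-9)

    def test_parseval_band_total(self, rng):
        x = rng.normal(size=26)
        res = power_spectrum(x)
        xc = x - x.mean()
        assert res.power.sum() == pytest.approx(26 * np.sum(xc**2), rel=1e-9)

    def test_pure_alternating_signal_peaks_at_nyquist(self):
        x = np.tile([1.0, -1.0], 13)
        res = power_spectrum(x)
        assert res.peak_period == pytest.approx(2.0)
        assert res.p_val < 1e-6


class TestFisherG:
    def test_uniform_spectrum_gives_inverse_n(self):
        g, p = fisher_g_test(np.ones(13))
        assert g == pytest.approx(1 / 13)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_single_bin_spectrum(self):
        powers = np.zeros(13)
        powers[4] = 5.0
        g, p = fisher_g_test(powers)
        assert g == 1.0 and p == 0.0

    def test_all_zero_spectrum_flagged(self):
        g, p = fisher_g_test(np.zeros(8))
        assert (g, p) == (0.0, 1.0)

    def test_pvalue_monotone_in_g(self):
        gs = np.linspace(0.12, 0.99, 50)
        ps = fisher_g_pvalue(gs, 13)
        assert np.all(np.diff(ps) < 0)

    def test_exact_formula_matches_empirical_null_quantiles(self):
        """Exact tail probabilities vs Monte-Carlo at N = 13 ordinates."""
        rng = np.random.default_rng(99)
        pw = _periodogram(white_noise_batch(4000, 26, rng))
        g = pw.max(axis=1) / pw.sum(axis=1)
        for q in (0.5, 0.9):
            g_q = np.quantile(g, q)
            p_exact = fisher_g_pvalue(g_q, 13)
            se = np.sqrt(q * (1 - q) / 4000)
            assert abs(p_exact - (1 - q)) < 4 * se + 0.02


class TestSummaries:
    def test_occurrence_extremes(self):
        assert occurrence([0.001, 0.01]) == 1.0
        assert occurrence([0.5, 0.9]) == 0.0

    def test_mean_significant_period_arithmetic(self):
        df = pd.DataFrame({
            "p_val": [0.01, 0.04, 0.02, 0.5],
            "period_cells": [4.0, 4.0, 3.71, 26.0],
        })
        assert mean_significant_period(df) == pytest.approx(3.903, abs=1e-3)

    def test_mean_significant_period_missing(self):
        df = pd.DataFrame({"p_val": [0.5], "period_cells": [4.0]})
        assert np.isnan(mean_significant_period(df))

    def test_synthetic_period_four_recovered(self, rng):
        sigs = np.stack([
            generate_signal("mixed", 24, period=4.0, amplitude=3.0,
                            noise_sd=0.5, rng=rng)
            for _ in range(50)
        ])
        pw = _periodogram(sigs)
        k_peak = pw.argmax(axis=1) + 1
        assert np.median(24 / k_peak) == pytest.approx(4.0)


def test_analyze_spatial_matches_per_signal_path(short_sim):
    table = analyze_spatial(short_sim, last_h=20.0)
    signals, _ = extract_spatial_signals(short_sim, last_h=20.0)
    for i in (0, len(table) // 2, len(table) - 1):
        res = power_spectrum(signals[i])
        assert table["g"].iloc[i] == pytest.approx(res.g)
        assert table["p_val"].iloc[i] == pytest.approx(res.p_val)


def test_kymograph_shape(short_sim):
    mat, times = kymograph(short_sim, column=1, last_h=30.0)
    assert mat.shape == (26, len(times))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_g_within_bounds_on_random_signals(seed):
    x = np.random.default_rng(seed).normal(size=26)
    res = power_spectrum(x)
    assert 1 / 13 < res.g <= 1.0
    assert 0.0 <= res.p_val <= 1.0
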