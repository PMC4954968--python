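"""Unit and property tests for ADC and T1 parametric-map fitting."""

import numpy as np
import pytest

from renofib.mapping import (
    FLAG_LL_CORRECTION_INVALID,
    DiffusionSeries,
    InversionSeries,
    fit_adc_map,
    fit_t1_map,
)
from renofib.synthetic import DEFAULT_B_VALUES, DEFAULT_TIS, rician

B = np.asarray(DEFAULT_B_VALUES)
TIS = np.asarray(DEFAULT_TIS)


def _pixel_series(b, s0, adc):
    """Single-pixel diffusion series from the mono-exponential model."""
    sig = s0 * np.exp(-b * adc * 1e-6)
    return DiffusionSeries(sig.reshape(-1, 1, 1), b)


def _adc_grid_oracle(signals, b, s0_grid, adc_grid):
    """Brute-force SSE minimisation over an (S0, ADC) grid.

    Uses the quadratic-in-S0 decomposition of the SSE so the full grid is
    evaluated exactly without materialising the (S0, ADC, b) cube.
    """
    e = np.exp(-np.outer(b, adc_grid * 1e-6))  # (nb, n_adc)
    a1 = signals @ e  # sum_b S_b * E
    a2 = np.sum(e * e, axis=0)
    const = float(np.sum(signals**2))
    best = (np.inf, None, None)
    for i, s0 in enumerate(s0_grid):
        sse = const - 2 * s0 * a1 + s0 * s0 * a2
        j = int(np.argmin(sse))
        if sse[j] < best[0]:
            best = (float(sse[j]), float(s0), float(adc_grid[j]))
    return best[1], best[2]


class TestFitAdc:
    @pytest.mark.parametrize("method", ["loglinear", "nonlinear"])
    def test_noiseless_recovery_is_exact(self, method):
        series = _pixel_series(B, 100.0, 2000.0)
        adc_map, s0_map = fit_adc_map(series, method=method)
        assert adc_map.values[0, 0] == pytest.approx(2000.0, rel=1e-9)
        assert s0_map.values[0, 0] == pytest.approx(100.0, rel=1e-9)
        assert adc_map.units == "1e-6 mm^2/s"

    @pytest.mark.parametrize("method", ["loglinear", "nonlinear"])
    def test_constant_signal_gives_zero_decay(self, method):
        series = _pixel_series(B, 50.0, 0.0)
        adc_map, s0_map = fit_adc_map(series, method=method)
        assert adc_map.values[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert s0_map.values[0, 0] == pytest.approx(50.0)

    def test_nonlinear_matches_grid_search_oracle_single_pixel(self):
        rng = np.random.default_rng(7)
        clean = 100.0 * np.exp(-B * 2000.0 * 1e-6)
        noisy = rician(clean, 2.0, rng)
        series = DiffusionSeries(noisy.reshape(-1, 1, 1), B)
        adc_map, s0_map = fit_adc_map(series, method="nonlinear")
        s0_grid = np.arange(50.0, 150.0 + 1e-9, 0.01)
        adc_grid = np.arange(0.0, 4000.0 + 1e-9, 1.0)
        s0_o, adc_o = _adc_grid_oracle(noisy, B, s0_grid, adc_grid)
        assert abs(s0_map.values[0, 0] - s0_o) <= 0.01 + 1e-12
        assert abs(adc_map.values[0, 0] - adc_o) <= 1.0 + 1e-12

    def test_nonlinear_agrees_with_oracle_on_seeded_pixels(self):
        """>=99% of 100 noisy pixels land within one (coarser) grid step."""
        rng = np.random.default_rng(42)
        s0_grid = np.arange(50.0, 150.0 + 1e-9, 0.05)
        adc_grid = np.arange(500.0, 3500.0 + 1e-9, 5.0)
        hits = 0
        for _ in range(100):
            true_adc = rng.uniform(1000.0, 3000.0)
            clean = 100.0 * np.exp(-B * true_adc * 1e-6)
            noisy = rician(clean, 2.0, rng)
            series = DiffusionSeries(noisy.reshape(-1, 1, 1), B)
            adc_map, s0_map = fit_adc_map(series, method="nonlinear")
            s0_o, adc_o = _adc_grid_oracle(noisy, B, s0_grid, adc_grid)
            if abs(adc_map.values[0, 0] - adc_o) <= 5.0 + 1e-9 and abs(
                s0_map.values[0, 0] - s0_o
            ) <= 0.05 + 1e-9:
                hits += 1
        assert hits >= 99

    def test_pixels_with_nonpositive_signal_marked_invalid_loglinear(self):
        sig = 100.0 * np.exp(-B * 2000.0 * 1e-6)
        stack = np.stack([sig, sig], axis=-1).reshape(len(B), 1, 2)
        stack[3, 0, 1] = 0.0  # one pixel loses a sample
        adc_map, _ = fit_adc_map(DiffusionSeries(stack, B), method="loglinear")
        assert adc_map.mask[0, 0] and not adc_map.mask[0, 1]

    def test_all_zero_series_yields_empty_mask(self):
        series = DiffusionSeries(np.zeros((len(B), 2, 2)), B)
        adc_map, _ = fit_adc_map(series, method="loglinear")
        assert not adc_map.mask.any()

    def test_fewer_than_two_positive_signals_invalid_not_exception(self):
        stack = np.zeros((len(B), 1, 1))
        stack[0, 0, 0] = 50.0  # only one positive sample
        adc_map, _ = fit_adc_map(DiffusionSeries(stack, B), method="nonlinear")
        assert not adc_map.mask[0, 0]

    def test_monotonicity_in_true_adc(self):
        """Higher true ADC decays faster and fits higher, strictly."""
        adcs = np.array([1000.0, 1500.0, 2000.0, 2500.0])
        fitted = []
        for adc in adcs:
            sig = 100.0 * np.exp(-B * adc * 1e-6)
            assert np.all(np.diff(sig[1:]) < 0)
            series = _pixel_series(B, 100.0, adc)
            amap, _ = fit_adc_map(series, method="nonlinear")
            fitted.append(amap.values[0, 0])
        assert np.all(np.diff(fitted) > 0)
        # larger ADC gives strictly lower signal at every b > 0
        s_lo = 100.0 * np.exp(-B[1:] * 1000.0 * 1e-6)
        s_hi = 100.0 * np.exp(-B[1:] * 2500.0 * 1e-6)
        assert np.all(s_hi < s_lo)

    @pytest.mark.parametrize("method", ["loglinear", "nonlinear"])
    def test_noise_robustness_median_within_2pct(self, method):
        """Rician sigma at 2% of S0: median over 10k pixels near truth."""
        rng = np.random.default_rng(2024)
        n = 10_000
        clean = (100.0 * np.exp(-B * 2000.0 * 1e-6))[:, None] * np.ones((1, n))
        noisy = rician(clean, 2.0, rng).reshape(len(B), 1, n)
        adc_map, _ = fit_adc_map(DiffusionSeries(noisy, B), method=method)
        med = np.median(adc_map.values[0, adc_map.mask[0]])
        assert med == pytest.approx(2000.0, rel=0.02)


def _ir_pixel(ti, signed):
    return InversionSeries(np.asarray(signed).reshape(-1, 1, 1), ti)


def _t1_sign_grid_oracle(ti, mags, t1s_grid):
    """Brute force over all 2^n sign assignments x T1* grid, (A, B) by lstsq."""
    n = len(ti)
    best = (np.inf, None, None, None)
    for bits in range(2**n):
        signs = np.array([1.0 if bits & (1 << i) else -1.0 for i in range(n)])
        y = signs * mags
        for t1s in t1s_grid:
            x = np.stack([np.ones(n), -np.exp(-ti / t1s)], axis=1)
            coef, res, *_ = np.linalg.lstsq(x, y, rcond=None)
            sse = float(np.sum((y - x @ coef) ** 2))
            if sse < best[0]:
                best = (sse, coef[0], coef[1], t1s)
    return best[1], best[2], best[3]


class TestFitT1:
    def test_correction_identity_when_b_is_2a(self):
        """A=100, B=200, T1*=600: Look-Locker correction is the identity."""
        ti = TIS
        signed = 100.0 - 200.0 * np.exp(-ti / 600.0)
        t1_map = fit_t1_map(_ir_pixel(ti, np.abs(signed)))
        assert t1_map.values[0, 0] == pytest.approx(600.0, rel=1e-6)

    def test_magnitude_self_consistency(self):
        """Magnitude data from A=80, B=150, T1*=900 refits its generators."""
        ti = TIS
        signed = 80.0 - 150.0 * np.exp(-ti / 900.0)
        t1_map = fit_t1_map(_ir_pixel(ti, np.abs(signed)))
        expected = 900.0 * (150.0 / 80.0 - 1.0)
        assert t1_map.values[0, 0] == pytest.approx(expected, rel=1e-6)

    def test_polarity_ambiguity_matches_sign_pattern_oracle(self):
        """First sample near the signal null: exhaustive-sign oracle agrees."""
        ti = TIS
        # null at TI = T1* ln(B/A) = 700*ln(2) ~ 485; put a sample next to it
        ti_amb = np.sort(np.concatenate([ti, [490.0]]))
        rng = np.random.default_rng(3)
        signed = 90.0 - 180.0 * np.exp(-ti_amb / 700.0)
        mags = np.abs(signed + rng.normal(0, 1.0, len(ti_amb)))
        t1_map = fit_t1_map(_ir_pixel(ti_amb, mags))
        grid = np.arange(300.0, 1500.0 + 1e-9, 2.0)
        a_o, b_o, t1s_o = _t1_sign_grid_oracle(ti_amb, mags, grid)
        fitted_t1 = t1_map.values[0, 0]
        oracle_t1 = t1s_o * (b_o / a_o - 1.0)
        # one grid step of T1* maps to a comparable step of corrected T1
        assert abs(fitted_t1 - oracle_t1) <= 2.0 * (b_o / a_o - 1.0) + 1e-6

    def test_noiseless_phantom_recovery(self, noiseless_ir):
        series, labels, truth = noiseless_ir
        t1_map = fit_t1_map(series, labels > 0)
        for _, row in truth.iterrows():
            vals = t1_map.values[labels == row["label"]]
            np.testing.assert_allclose(vals, row["t1_true"], rtol=1e-6)

    def test_flagged_when_correction_nonphysical(self):
        """B/A <= 1 reports T1* with the quality flag, not a failure."""
        ti = TIS
        signed = 100.0 - 80.0 * np.exp(-ti / 600.0)  # B < A: no inversion null
        t1_map = fit_t1_map(_ir_pixel(ti, np.abs(signed)))
        assert t1_map.mask[0, 0]
        assert t1_map.flags[0, 0] == FLAG_LL_CORRECTION_INVALID
        assert t1_map.values[0, 0] == pytest.approx(600.0, rel=1e-3)

    def test_needs_three_distinct_tis(self):
        with pytest.raises(ValueError):
            InversionSeries(np.zeros((3, 1, 1)), [100.0, 100.0, 300.0])


class TestSeriesValidation:
    def test_b_values_sorted_on_construction(self):
        s = DiffusionSeries(np.ones((3, 2, 2)), [300.0, 0.0, 150.0])
        assert list(s.b_values) == [0.0, 150.0, 300.0]

    def test_duplicate_b_values_rejected(self):
        with pytest.raises(ValueError):
            DiffusionSeries(np.ones((3, 2, 2)), [0.0, 150.0, 150.0])

    def test_mask_shape_mismatch_rejected(self):
        s = DiffusionSeries(np.ones((3, 2, 2)), [0.0, 150.0, 300.0])
        with pytest.raises(ValueError):
            fit_adc_map(s, np.ones((3, 3), dtype=bool))
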