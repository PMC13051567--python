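"""Resampling, smoothing, derivative and correlation-curve behaviour."""

import numpy as np
import pytest

from anthospec.containers import SpectraSet
from anthospec.preprocess import (bandwise_correlation, derivative,
                                  pearson_with_p, resample, savgol_smooth)


def spectra_from(values, wl, kind="raw"):
    values = np.atleast_2d(values)
    n = values.shape[0]
    return SpectraSet(np.asarray(wl, dtype=float), values,
                      [f"s{i}" for i in range(n)], np.full(n, 7),
                      ["2-4"] * n, kind)


class TestResample:
    def test_standard_grid_band_count(self):
        wl = np.arange(325.0, 1076.0)
        s = spectra_from(np.full((1, wl.size), 0.5), wl)
        out = resample(s, 2.5)
        assert out.n_bands == 301          # (1075-325)/2.5 + 1
        assert out.wavelengths_nm[0] == 325.0
        assert out.wavelengths_nm[-1] == 1075.0

    def test_idempotent_on_target_grid(self):
        wl = np.arange(325.0, 1076.0, 2.5)
        vals = np.random.default_rng(0).uniform(0, 1, (2, wl.size))
        s = spectra_from(vals, wl)
        out = resample(s, 2.5)
        np.testing.assert_allclose(out.values, vals, atol=1e-12)

    def test_affine_spectra_reproduced_exactly(self):
        wl = np.arange(325.0, 1076.0)
        line = 1e-4 * wl + 0.05
        out = resample(spectra_from(line, wl), 2.5)
        np.testing.assert_allclose(out.values[0],
                                   1e-4 * out.wavelengths_nm + 0.05,
                                   rtol=1e-12)

    def test_invalid_interval_rejected(self):
        wl = np.arange(325.0, 1076.0)
        s = spectra_from(np.full((1, wl.size), 0.5), wl)
        with pytest.raises(ValueError):
            resample(s, -1.0)

    def test_grid_outside_support_rejected(self):
        wl = np.arange(400.0, 900.0)
        s = spectra_from(np.full((1, wl.size), 0.5), wl)
        with pytest.raises(ValueError, match="support"):
            resample(s, 2.5)

    def test_requires_raw_kind(self):
        wl = np.arange(325.0, 1076.0)
        s = spectra_from(np.full((1, wl.size), 0.5), wl, kind="smoothed")
        with pytest.raises(ValueError, match="raw"):
            resample(s, 2.5)


class TestSavgolSmooth:
    wl = np.arange(325.0, 1076.0, 2.5)

    def test_constant_unchanged(self):
        s = spectra_from(np.full((1, self.wl.size), 0.37), self.wl)
        out = savgol_smooth(s, 11, 3)
        np.testing.assert_allclose(out.values, 0.37, atol=1e-12)
        assert out.kind == "smoothed"

    def test_cubic_reproduced_at_interior(self):
        x = (self.wl - 700.0) / 1000.0
        cubic = 0.4 + 0.1 * x + 0.2 * x ** 2 - 0.1 * x ** 3
        out = savgol_smooth(spectra_from(cubic, self.wl), 11, 3)
        interior = slice(5, -5)
        np.testing.assert_allclose(out.values[0][interior], cubic[interior],
                                   atol=1e-10)

    def test_noise_variance_reduced(self, rng):
        noisy = np.clip(0.5 + 0.05 * rng.standard_normal(self.wl.size),
                        0, 1)
        out = savgol_smooth(spectra_from(noisy, self.wl), 11, 3)
        assert out.values[0].var() < noisy.var()

    def test_even_window_rejected(self):
        s = spectra_from(np.full((1, self.wl.size), 0.5), self.wl)
        with pytest.raises(ValueError, match="odd"):
            savgol_smooth(s, 10, 3)


class TestDerivative:
    wl = np.arange(325.0, 1076.0, 2.5)

    def smoothed(self, values):
        return spectra_from(values, self.wl, kind="smoothed")

    def test_first_derivative_of_affine(self):
        line = 1e-3 * self.wl - 0.2
        out = derivative(self.smoothed(np.clip(line, 0, 1)), 1)
        interior = (self.wl > 380) & (self.wl < 1020) & (line > 0.01) \
            & (line < 0.99)
        np.testing.assert_allclose(out.values[0][interior], 1e-3,
                                   rtol=1e-6)
        assert out.kind == "fd"

    def test_second_derivative_of_quadratic(self):
        a = 2e-7
        quad = a * (self.wl - 700.0) ** 2 + 0.1
        out = derivative(self.smoothed(quad), 2)
        interior = slice(5, -5)
        np.testing.assert_allclose(out.values[0][interior], 2 * a,
                                   rtol=1e-6)
        assert out.kind == "sd"

    def test_constant_gives_zero(self):
        out = derivative(self.smoothed(np.full(self.wl.size, 0.6)), 1)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_raw_input_is_contract_error(self):
        s = spectra_from(np.full((1, self.wl.size), 0.5), self.wl, "raw")
        with pytest.raises(ValueError, match="smoothed"):
            derivative(s, 1)

    def test_unsupported_order_rejected(self):
        with pytest.raises(ValueError):
            derivative(self.smoothed(np.full(self.wl.size, 0.5)), 3)

    def test_linearity(self, rng):
        x = np.clip(0.5 + 0.1 * rng.standard_normal(self.wl.size), 0, 1)
        y = np.clip(0.5 + 0.1 * rng.standard_normal(self.wl.size), 0, 1)
        a, b = 0.3, 0.6
        combo = np.clip(a * x + b * y, 0, 1)
        d = lambda v: derivative(self.smoothed(v), 1).values[0]
        np.testing.assert_allclose(d(combo), a * d(x) + b * d(y),
                                   atol=1e-10)


class TestBandwiseCorrelation:
    def test_perfect_positive_and_negative(self):
        ant = np.array([100.0, 300.0, 500.0, 800.0, 1100.0])
        vals = np.column_stack([ant / 2000.0, 0.9 - ant / 2000.0])
        s = spectra_from(vals, [500.0, 502.5])
        bc = bandwise_correlation(s, ant)
        assert bc.r[0] == pytest.approx(1.0)
        assert bc.r[1] == pytest.approx(-1.0)
        assert bc.p_value[0] < 1e-6

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 7.0])
        # independent textbook formula
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        r, _ = pearson_with_p(x, y)
        assert r == pytest.approx(expected, rel=1e-12)
        s = spectra_from((x / 10.0)[None, :].T.reshape(3, 1), [600.0])
        bc = bandwise_correlation(s, y)
        assert bc.r[0] == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_band_is_nan(self):
        ant = np.array([1.0, 2.0, 3.0, 4.0])
        vals = np.column_stack([np.full(4, 0.5), ant / 10.0])
        bc = bandwise_correlation(spectra_from(vals, [500.0, 505.0]), ant)
        assert np.isnan(bc.r[0])
        assert bc.r[1] == pytest.approx(1.0)

    def test_sample_count_mismatch_rejected(self):
        s = spectra_from(np.full((3, 2), 0.5), [500.0, 505.0])
        with pytest.raises(ValueError):
            bandwise_correlation(s, np.arange(4.0))


class TestDerivativeAdvantage:
    def test_fd_beats_raw_at_planted_band(self, default_preprocessed,
                                          default_dataset):
        """With realistic baseline drift, the first-derivative correlation
        at the planted red-edge window exceeds the raw-spectrum one."""
        params, _, _ = default_dataset
        kinds, table = default_preprocessed
        lo, hi = params.informative_window
        wl = kinds["raw"].wavelengths_nm
        win = (wl >= lo) & (wl <= hi)
        r_raw = bandwise_correlation(kinds["raw"], table.ant).r
        r_fd = bandwise_correlation(kinds["fd"], table.ant).r
        assert (np.nanmax(np.abs(r_fd[win]))
                > np.nanmax(np.abs(r_raw[win])))
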