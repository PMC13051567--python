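"""Spectral preprocessing: resampling, smoothing, derivatives, correlation.

The fixed pipeline order is resample -> Savitzky-Golay smooth ->
derivative; each step records the spectrum kind on its output and refuses
inputs of the wrong kind, so e.g. differentiating a raw (unsmoothed)
spectrum is a contract error rather than a silent quality loss.

Derivatives use the Savitzky-Golay derivative filter (one local
least-squares fit yields the smoothed derivative directly) and are
expressed per nm / per nm^2, so values are independent of the band
spacing.  Band-wise Pearson correlation against anthocyanin concentration
produces the correlation curves used to read off pigment-sensitive
regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import SpectraSet

__all__ = [
    "SpectralResampler", "SavitzkyGolaySmoother", "SavitzkyGolayDerivative",
    "BandCorrelation", "resample", "savgol_smooth", "derivative",
    "bandwise_correlation", "preprocess_pipeline",
]


class SpectralResampler(BaseEstimator, TransformerMixin):
    """Linear interpolation of spectra onto a regular wavelength grid.

    Linear interpolation is monotone and overshoot-free, which keeps
    resampled reflectance inside [0, 1].  The target grid is the
    arithmetic sequence ``start, start+interval, ..., stop``.
    """

    def __init__(self, interval_nm: float = 2.5, start_nm: float = 325.0,
                 stop_nm: float = 1075.0):
        self.interval_nm = interval_nm
        self.start_nm = start_nm
        self.stop_nm = stop_nm

    def fit(self, wavelengths_nm, y=None):
        if self.interval_nm <= 0:
            raise ValueError("interval_nm must be > 0")
        wl = np.asarray(wavelengths_nm, dtype=float)
        n_out = int(round((self.stop_nm - self.start_nm) / self.interval_nm))
        target = self.start_nm + self.interval_nm * np.arange(n_out + 1)
        if target[0] < wl[0] - 1e-9 or target[-1] > wl[-1] + 1e-9:
            raise ValueError(
                f"target grid [{target[0]:g}, {target[-1]:g}] nm outside "
                f"source support [{wl[0]:g}, {wl[-1]:g}] nm"
            )
        self.wavelengths_in_ = wl
        self.wavelengths_out_ = target
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([
            np.interp(self.wavelengths_out_, self.wavelengths_in_, row)
            for row in X
        ])


class SavitzkyGolaySmoother(BaseEstimator, TransformerMixin):
    """Per-sample Savitzky-Golay least-squares polynomial smoothing.

    Edge bands are handled by scipy's asymmetric polynomial fit
    (``mode="interp"``); :attr:`edge_bands_` records how many bands at
    each end fall inside a truncated window so downstream stages can
    optionally exclude them.
    """

    def __init__(self, window: int = 11, polyorder: int = 3):
        self.window = window
        self.polyorder = polyorder

    def fit(self, X=None, y=None):
        if self.window % 2 == 0:
            raise ValueError("Savitzky-Golay window must be odd")
        if self.window <= self.polyorder:
            raise ValueError("window must exceed polyorder")
        self.edge_bands_ = self.window // 2
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] < self.window:
            raise ValueError("window wider than the number of bands")
        return savgol_filter(X, self.window, self.polyorder, axis=1,
                             mode="interp")


class SavitzkyGolayDerivative(BaseEstimator, TransformerMixin):
    """Savitzky-Golay derivative filter, per nm (order 1) or nm^2 (order 2)."""

    def __init__(self, order: int = 1, window: int = 11, polyorder: int = 3,
                 delta_nm: float = 2.5):
        self.order = order
        self.window = window
        self.polyorder = polyorder
        self.delta_nm = delta_nm

    def fit(self, X=None, y=None):
        if self.order not in (1, 2):
            raise ValueError("derivative order must be 1 or 2")
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("window must be odd and exceed polyorder")
        if self.polyorder < self.order:
            raise ValueError("polyorder must be >= derivative order")
        self.edge_bands_ = self.window // 2
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return savgol_filter(X, self.window, self.polyorder, axis=1,
                             deriv=self.order, delta=self.delta_nm,
                             mode="interp")


# -- SpectraSet-level wrappers ---------------------------------------------

def resample(s: SpectraSet, interval_nm: float = 2.5,
             start_nm: float = 325.0, stop_nm: float = 1075.0) -> SpectraSet:
    """Resample a raw SpectraSet onto the regular ``interval_nm`` grid."""
    if s.kind != "raw":
        raise ValueError(f"resample expects a raw spectrum, got {s.kind!r}")
    tr = SpectralResampler(interval_nm, start_nm, stop_nm).fit(
        s.wavelengths_nm)
    vals = np.clip(tr.transform(s.values), 0.0, 1.0)
    return s.with_values(vals, "raw", tr.wavelengths_out_)


def savgol_smooth(s: SpectraSet, window: int = 11,
                  polyorder: int = 3) -> SpectraSet:
    """Smooth a raw SpectraSet; output kind is ``smoothed``.

    The local polynomial fit can undershoot slightly below 0 next to
    dark bands (reflectance pinned near zero); excursions within a small
    tolerance (0.02) are nudged back into [0, 1], anything larger
    indicates bad inputs and is rejected.
    """
    if s.kind != "raw":
        raise ValueError(f"savgol_smooth expects a raw spectrum, got "
                         f"{s.kind!r}")
    tr = SavitzkyGolaySmoother(window, polyorder).fit()
    vals = tr.transform(s.values)
    if vals.size and (vals.min() < -0.02 or vals.max() > 1.02):
        raise ValueError("smoothing produced reflectance far outside [0, 1]")
    return s.with_values(np.clip(vals, 0.0, 1.0), "smoothed")


def derivative(s: SpectraSet, order: int = 1, window: int = 11,
               polyorder: int = 3) -> SpectraSet:
    """Differentiate a smoothed SpectraSet; kind becomes ``fd`` or ``sd``."""
    if s.kind != "smoothed":
        raise ValueError(
            f"derivative expects a smoothed spectrum (pipeline order is "
            f"resample -> smooth -> derivative), got {s.kind!r}"
        )
    step = float(np.median(np.diff(s.wavelengths_nm)))
    tr = SavitzkyGolayDerivative(order, window, polyorder, step).fit()
    return s.with_values(tr.transform(s.values), "fd" if order == 1 else "sd")


def preprocess_pipeline(s: SpectraSet, interval_nm: float = 2.5,
                        window: int = 11, polyorder: int = 3
                        ) -> dict[str, SpectraSet]:
    """Run the fixed chain and return all intermediate kinds.

    Returns a dict with keys ``raw`` (resampled), ``smoothed``, ``fd``,
    ``sd``.
    """
    res = resample(s, interval_nm)
    sm = savgol_smooth(res, window, polyorder)
    return {
        "raw": res,
        "smoothed": sm,
        "fd": derivative(sm, 1, window, polyorder),
        "sd": derivative(sm, 2, window, polyorder),
    }


# -- band-wise correlation --------------------------------------------------

@dataclass(frozen=True)
class BandCorrelation:
    """Per-band Pearson correlation with anthocyanin concentration.

    Bands with zero variance have ``r`` and ``p_value`` set to NaN
    (undefined, not zero).  ``p_bonferroni`` is the Bonferroni-adjusted
    p-value added for transparency; the per-band flags use the unadjusted
    values, matching common practice for correlation curves.
    """

    wavelengths_nm: np.ndarray
    r: np.ndarray
    p_value: np.ndarray
    significant_05: np.ndarray
    significant_01: np.ndarray
    p_bonferroni: np.ndarray

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "wavelength_nm": self.wavelengths_nm, "r": self.r,
            "p_value": self.p_value, "significant_05": self.significant_05,
            "significant_01": self.significant_01,
            "p_bonferroni": self.p_bonferroni,
        })


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided t-test p-value; NaN on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bandwise_correlation(s: SpectraSet, ant: np.ndarray) -> BandCorrelation:
    """Pearson correlation of every band against concentration."""
    ant = np.asarray(ant, dtype=float)
    if ant.shape[0] != s.n_samples:
        raise ValueError("sample count mismatch between spectra and ant")
    if s.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    X = s.values
    n = X.shape[0]
    xm = X - X.mean(axis=0)
    ym = ant - ant.mean()
    sx = np.sqrt((xm ** 2).sum(axis=0))
    sy = np.sqrt((ym ** 2).sum())
    valid = (sx > 0) & (sy > 0)
    r = np.full(X.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r[valid] = (xm[:, valid] * ym[:, None]).sum(axis=0) / (sx[valid] * sy)
    r = np.clip(r, -1.0, 1.0)
    p = np.full_like(r, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r ** 2))
    p[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), df=n - 2)
    p = np.clip(p, 0.0, 1.0)
    p_bonf = np.clip(p * np.sum(valid), 0.0, 1.0)
    return BandCorrelation(
        wavelengths_nm=s.wavelengths_nm, r=r, p_value=p,
        significant_05=p < 0.05, significant_01=p < 0.01,
        p_bonferroni=p_bonf,
    )
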