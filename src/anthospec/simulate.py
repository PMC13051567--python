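"""Synthetic leaf spectra and wet-chemistry tables.

The generator emulates the statistical structure of a riparian-poplar leaf
survey: five sampling months (June-October) crossed with five
groundwater-depth classes, leaf anthocyanin rising from June into
mid-summer and falling by October, and 325-1075 nm reflectance whose blue
region brightens and red region darkens as anthocyanin accumulates, with
the red edge shifting shortward under pigment stress and a near-infrared
plateau around 0.62-0.66.

The pigment-to-reflectance map is deliberately phenomenological — a smooth
baseline plus Gaussian absorption/backscatter terms and a sigmoid red edge
whose depths and position depend linearly on anthocyanin — not a
radiative-transfer model.  It reproduces the correlation sign structure
the analysis relies on (positive in the blue ~430-500 nm, negative in the
red ~600-680 nm, strong derivative signal around the red edge) without
claiming biophysical fidelity.

Wet chemistry is simulated by inversion: the planted concentration is
converted to the absorbance at 537 nm that the colorimetric formula would
produce given plausible chlorophyll-channel absorbances, then measurement
noise is added, so pushing the absorbances back through the quantification
formulas recovers the planted value exactly at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GROUNDWATER_GROUPS, SampleTable, SpectraSet
from .quantify import (A537_COEF, A647_COEF, A663_COEF, DEFAULT_M_ANT,
                       quantify)

__all__ = ["GeneratorParams", "sample_anthocyanin", "simulate_reflectance",
           "simulate_absorbances", "generate_dataset"]

MONTHS = (6, 7, 8, 9, 10)


def _gauss(x, center, width):
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class GeneratorParams:
    """Defaults define the emulated survey; every field is overridable.

    Seasonal means (mg m^-2) rise from June to an August peak and fall by
    October; groundwater classes shift the mean by +80 mg m^-2 per metre
    class of depth (deeper water table = stronger drought stress = more
    anthocyanin).  Concentrations are clamped to the observed survey range
    [0.9, 1477.3] mg m^-2.
    """

    n_per_cell: int = 12
    #: native wavelength grid: 325..1075 nm at 1 nm (751 bands)
    grid_start_nm: float = 325.0
    grid_stop_nm: float = 1075.0
    grid_step_nm: float = 1.0
    #: seasonal anthocyanin means per month (mg m^-2)
    month_mean: dict = field(default_factory=lambda: {
        6: 350.0, 7: 680.0, 8: 760.0, 9: 560.0, 10: 300.0})
    #: additive offset per groundwater class, centred on "4-6"
    group_offset_step: float = 80.0
    cell_sd: float = 170.0
    ant_clamp: tuple = (0.9, 1477.3)

    # -- pigment-to-reflectance mapping ------------------------------------
    vis_base: float = 0.10          #: visible floor reflectance
    green_amp: float = 0.10         #: green bump amplitude (550 nm)
    green_center: float = 550.0
    green_width: float = 35.0
    nir_amp: float = 0.54           #: red-edge sigmoid amplitude; NIR
    #: plateau = vis_base + nir_amp = 0.64, inside the observed 0.58-0.67
    rededge_center: float = 716.0   #: red-edge inflection at zero pigment
    rededge_shift: float = 10.0     #: shortward shift (nm) across ant range
    rededge_width: float = 9.0
    water_dip_amp: float = 0.02     #: shallow 970 nm water feature
    water_dip_center: float = 970.0
    water_dip_width: float = 25.0
    blue_amp: float = 0.05          #: anthocyanin backscatter gain, blue
    blue_center: float = 465.0
    blue_width: float = 40.0
    red_amp: float = 0.11           #: anthocyanin absorption depth, red
    red_center: float = 640.0
    red_width: float = 45.0
    #: sd of a chlorophyll-like nuisance absorption depth at 670 nm,
    #: independent of anthocyanin (biological scatter)
    chl_nuisance_sd: float = 0.015
    chl_center: float = 670.0
    chl_width: float = 25.0

    # -- noise --------------------------------------------------------------
    additive_sd: float = 0.004      #: spectrally-correlated additive noise
    additive_corr_nm: float = 5.0   #: Gaussian correlation length of noise
    multiplicative_sd: float = 0.01  #: per-spectrum gain jitter
    #: per-spectrum baseline drift: constant offset and linear tilt
    #: (scattering/illumination variation, the classic motivation for
    #: derivative preprocessing — derivatives remove it, raw spectra keep it)
    baseline_offset_sd: float = 0.015
    baseline_tilt_sd: float = 0.015  #: tilt amplitude across the full range
    absorbance_sd: float = 0.01     #: colorimeter measurement noise

    # -- leaf morphology / assay constants ----------------------------------
    leaf_area_mean: float = 0.0025  #: m^2
    leaf_area_cv: float = 0.15
    fresh_weight_mean: float = 0.6  #: g
    fresh_weight_cv: float = 0.15
    volume_ml: float = 10.0
    m_ant: float = DEFAULT_M_ANT

    #: wavelength window (nm) where the generator plants its strongest
    #: signal (the anthocyanin-driven red-edge shift); selector-recovery
    #: checks assert against this window
    informative_window: tuple = (685.0, 735.0)

    def wavelengths(self) -> np.ndarray:
        n = int(round((self.grid_stop_nm - self.grid_start_nm)
                      / self.grid_step_nm)) + 1
        return self.grid_start_nm + self.grid_step_nm * np.arange(n)

    def group_offset(self, group: str) -> float:
        idx = GROUNDWATER_GROUPS.index(group)
        return (idx - 2) * self.group_offset_step


def sample_anthocyanin(month: int, group: str, n: int,
                       rng: np.random.Generator,
                       params: GeneratorParams | None = None) -> np.ndarray:
    """Draw ``n`` concentrations (mg m^-2) for one (month, group) cell."""
    params = params or GeneratorParams()
    if month not in params.month_mean:
        raise ValueError(f"unknown month {month!r}; expected one of "
                         f"{sorted(params.month_mean)}")
    if group not in GROUNDWATER_GROUPS:
        raise ValueError(f"unknown groundwater group {group!r}")
    if n < 0:
        raise ValueError("n must be >= 0")
    mean = params.month_mean[month] + params.group_offset(group)
    draws = mean + params.cell_sd * rng.standard_normal(n)
    return np.clip(draws, *params.ant_clamp)


def _clean_reflectance(ant: float, params: GeneratorParams,
                       chl_depth: float = 0.0) -> np.ndarray:
    """Deterministic pigment-to-reflectance map on the native grid."""
    wl = params.wavelengths()
    ant_n = np.clip(ant / params.ant_clamp[1], 0.0, 1.0)
    center = params.rededge_center - params.rededge_shift * ant_n
    r = (params.vis_base
         + params.green_amp * _gauss(wl, params.green_center,
                                     params.green_width)
         + params.nir_amp * _sigmoid((wl - center) / params.rededge_width)
         - params.water_dip_amp * _gauss(wl, params.water_dip_center,
                                         params.water_dip_width)
         + params.blue_amp * ant_n * _gauss(wl, params.blue_center,
                                            params.blue_width)
         - params.red_amp * ant_n * _gauss(wl, params.red_center,
                                           params.red_width)
         - chl_depth * _gauss(wl, params.chl_center, params.chl_width))
    return np.clip(r, 0.0, 1.0)


def _correlated_noise(n_bands: int, sd: float, corr_nm: float,
                      step_nm: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth additive noise: white noise filtered with a Gaussian kernel
    of unit L2 norm, so the marginal sd stays ``sd``."""
    if sd == 0.0:
        return np.zeros(n_bands)
    half = max(1, int(round(4 * corr_nm / step_nm)))
    x = np.arange(-half, half + 1) * step_nm
    kernel = _gauss(x, 0.0, corr_nm)
    kernel /= np.linalg.norm(kernel)
    white = rng.standard_normal(n_bands + 2 * half)
    return sd * np.convolve(white, kernel, mode="valid")


def simulate_reflectance(ant: float, rng: np.random.Generator | None = None,
                         params: GeneratorParams | None = None) -> np.ndarray:
    """One reflectance spectrum on the native grid for concentration ``ant``.

    With ``rng=None`` the map is fully deterministic (no nuisance
    chlorophyll scatter, no instrument noise); all values lie in [0, 1].
    """
    params = params or GeneratorParams()
    if ant < 0:
        ant = 0.0
    if rng is None:
        return _clean_reflectance(ant, params)
    chl = params.chl_nuisance_sd * rng.standard_normal()
    r = _clean_reflectance(ant, params, chl_depth=chl)
    gain = 1.0 + params.multiplicative_sd * rng.standard_normal()
    wl = params.wavelengths()
    span = wl[-1] - wl[0]
    drift = (params.baseline_offset_sd * rng.standard_normal()
             + params.baseline_tilt_sd * rng.standard_normal()
             * (wl - wl.mean()) / span)
    r = gain * r + drift + _correlated_noise(
        r.size, params.additive_sd, params.additive_corr_nm,
        params.grid_step_nm, rng)
    return np.clip(r, 0.0, 1.0)


def simulate_absorbances(ant: float, S: float, W_F: float, V: float,
                         M_Ant: float, rng: np.random.Generator | None = None,
                         params: GeneratorParams | None = None):
    """Colorimetric absorbances consistent with a planted concentration.

    Inverts the quantification chain: because fresh weight cancels, the
    anthocyanin amount per unit solution volume is
    ``C_Ant = 1000 * S * ant / (V * M_Ant)``; chlorophyll-channel
    absorbances (A647, A663) take plausible extract values that decline
    with anthocyanin (senescing leaves lose chlorophyll), and A537 is
    solved from the colorimetric formula.  With ``rng=None`` the forward
    quantification recovers ``ant`` to floating-point precision.

    Returns ``(A537, A647, A663, A470)``; A470 is a carotenoid-region
    nuisance value unused by any downstream formula.
    """
    params = params or GeneratorParams()
    if min(S, W_F, V, M_Ant) <= 0:
        raise ValueError("S, W_F, V and M_Ant must be > 0")
    ant = max(float(ant), 0.0)
    ant_n = np.clip(ant / params.ant_clamp[1], 0.0, 1.0)
    c_ant = 1000.0 * S * ant / (V * M_Ant)
    chl_factor = 1.1 - 0.5 * ant_n
    a647 = 0.8 * chl_factor
    a663 = 1.5 * chl_factor
    a537 = (c_ant + A647_COEF * a647 + A663_COEF * a663) / A537_COEF
    a470 = 0.5 * chl_factor
    if rng is not None and params.absorbance_sd > 0:
        noise = params.absorbance_sd * rng.standard_normal(4)
        a537, a647, a663, a470 = (max(v + e, 0.0) for v, e in
                                  zip((a537, a647, a663, a470), noise))
    return float(a537), float(a647), float(a663), float(a470)


def generate_dataset(params: GeneratorParams | None = None, seed: int = 0,
                     return_truth: bool = False):
    """Generate a full synthetic survey: raw spectra + sample table.

    Deterministic given ``seed``.  Every (month, group) cell holds
    ``params.n_per_cell`` samples; spectra and table share sample ids.
    The table's ``Ant`` column is the *measured* concentration (quantified
    from noisy absorbances), while spectra are driven by the planted true
    value; with ``return_truth=True`` the planted vector is also returned.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    wl = params.wavelengths()

    rows, spectra, ids, months, groups, truth = [], [], [], [], [], []
    for month in MONTHS:
        for group in GROUNDWATER_GROUPS:
            ant_cell = sample_anthocyanin(month, group, params.n_per_cell,
                                          rng, params)
            for k, ant in enumerate(ant_cell):
                sid = f"m{month:02d}_g{group}_{k:03d}"
                S = params.leaf_area_mean * (
                    1.0 + params.leaf_area_cv * rng.standard_normal())
                S = max(S, 0.2 * params.leaf_area_mean)
                W_F = params.fresh_weight_mean * (
                    1.0 + params.fresh_weight_cv * rng.standard_normal())
                W_F = max(W_F, 0.2 * params.fresh_weight_mean)
                a537, a647, a663, a470 = simulate_absorbances(
                    ant, S, W_F, params.volume_ml, params.m_ant, rng, params)
                measured = quantify(S, W_F, a537, a647, a663,
                                    params.volume_ml, params.m_ant).Ant
                spectra.append(simulate_reflectance(ant, rng, params))
                rows.append({
                    "sample_id": sid, "S": S, "W_F": W_F,
                    "A470": a470, "A537": a537, "A647": a647, "A663": a663,
                    "V": params.volume_ml, "M_Ant": params.m_ant,
                    "Ant": float(measured), "month": month, "group": group,
                })
                ids.append(sid)
                months.append(month)
                groups.append(group)
                truth.append(ant)

    spectra_set = SpectraSet(wl, np.vstack(spectra), ids, months, groups,
                             kind="raw")
    table = SampleTable(pd.DataFrame(rows))
    if return_truth:
        return spectra_set, table, np.asarray(truth)
    return spectra_set, table
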