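"""Two-band vegetation indices over ordered band pairs.

Four index families are evaluated over *ordered* pairs (i, j), i != j, of
selected bands — the orientation matters because two of the families are
not antisymmetric and ranking keeps both orientations:

* ARI  = 1/Ri - 1/Rj            (anthocyanin reflectance index)
* CI   = (Ri - Rj)/Rj           (composite index)
* DVI  = Ri - Rj                (difference vegetation index)
* NARI = (1/Ri - 1/Rj)/(1/Ri + 1/Rj)  ==  (Rj - Ri)/(Rj + Ri)

On derivative spectra the band values can be arbitrarily close to zero,
so every reciprocal/ratio family carries a validity mask (|denominator|
< eps masks the sample, it is never zero-filled); pairs with more than
20 % masked samples are excluded from ranking.  Pair correlations against
anthocyanin concentration are ranked by |r| and the top-k pairs per
family assemble the modelling feature matrix (4 families x top-10 = 40
columns in the default configuration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SpectraSet

__all__ = ["INDEX_FAMILIES", "compute_index", "PairCorrelationMap",
           "pair_correlation_map", "top_k_pairs", "build_feature_matrix",
           "FeatureMatrix"]

log = logging.getLogger(__name__)

DEFAULT_EPS = 1e-8
#: maximum fraction of masked samples before a pair is dropped from ranking
MAX_MASKED_FRACTION = 0.20


def _ari(ri, rj, eps):
    mask = (np.abs(ri) < eps) | (np.abs(rj) < eps)
    out = np.where(mask, np.nan, 1.0 / np.where(mask, 1.0, ri)
                   - 1.0 / np.where(mask, 1.0, rj))
    return out


def _ci(ri, rj, eps):
    mask = np.abs(rj) < eps
    return np.where(mask, np.nan, (ri - rj) / np.where(mask, 1.0, rj))


def _dvi(ri, rj, eps):
    return ri - rj


def _nari(ri, rj, eps):
    denom = rj + ri
    mask = (np.abs(ri) < eps) | (np.abs(rj) < eps) | (np.abs(denom) < eps)
    return np.where(mask, np.nan,
                    (rj - ri) / np.where(mask, 1.0, denom))


INDEX_FAMILIES = {"ARI": _ari, "CI": _ci, "DVI": _dvi, "NARI": _nari}


def compute_index(family: str, r_i, r_j, eps: float = DEFAULT_EPS
                  ) -> np.ndarray:
    """Element-wise index values; invalid samples come back as NaN.

    ``r_i``/``r_j`` are per-sample band values (reflectance or derivative)
    at the two bands of the ordered pair.
    """
    if family not in INDEX_FAMILIES:
        raise ValueError(f"unknown index family {family!r}; expected one "
                         f"of {sorted(INDEX_FAMILIES)}")
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    try:
        np.broadcast_shapes(r_i.shape, r_j.shape)
    except ValueError:
        raise ValueError("band vectors must have compatible shapes") from None
    with np.errstate(divide="ignore", invalid="ignore"):
        return INDEX_FAMILIES[family](r_i, r_j, eps)


@dataclass(frozen=True)
class PairCorrelationMap:
    """Ordered-pair correlation map for one index family.

    ``r[a, b]`` is the Pearson correlation of family(band a, band b) with
    concentration; the diagonal is NaN and excluded.  ``valid[a, b]`` is
    False where the pair was dropped (too many masked samples or undefined
    variance).  ``top_k`` lists ``(i_nm, j_nm, r)`` sorted by |r|
    descending, ties broken by (lower i_nm, lower j_nm).
    """

    family: str
    bands_nm: np.ndarray
    r: np.ndarray
    valid: np.ndarray
    top_k: tuple

    @property
    def n_pairs(self) -> int:
        m = self.bands_nm.size
        return m * (m - 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.bands_nm,
                            columns=self.bands_nm)


def pair_correlation_map(s: SpectraSet, ant, family: str,
                         eps: float = DEFAULT_EPS, k: int = 10
                         ) -> PairCorrelationMap:
    """Correlate every ordered band pair's index with concentration."""
    ant = np.asarray(ant, dtype=float)
    if ant.shape[0] != s.n_samples:
        raise ValueError("sample count mismatch")
    if s.n_bands < 2:
        raise ValueError("need at least 2 selected bands")
    if s.n_samples < 3:
        raise ValueError("need at least 3 samples")
    m = s.n_bands
    n = s.n_samples
    r = np.full((m, m), np.nan)
    valid = np.zeros((m, m), dtype=bool)
    X = s.values
    y = ant
    # one vectorised sweep per i-band: index values of (i, all j) at once,
    # Pearson with pairwise exclusion of masked samples
    for a in range(m):
        V = compute_index(family, X[:, [a]], X, eps)      # (n, m)
        mask = np.isfinite(V)
        mask[:, a] = False
        c = mask.sum(axis=0)
        ok = c >= max(3, int(np.ceil((1.0 - MAX_MASKED_FRACTION) * n)))
        if not ok.any():
            continue
        V0 = np.where(mask, V, 0.0)
        Ym = np.where(mask, y[:, None], 0.0)
        sv, svv = V0.sum(0), (V0 * V0).sum(0)
        sy, syy = Ym.sum(0), (Ym * Ym).sum(0)
        svy = (V0 * Ym).sum(0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = svy - sv * sy / np.maximum(c, 1)
            var_v = svv - sv * sv / np.maximum(c, 1)
            var_y = syy - sy * sy / np.maximum(c, 1)
            rr = cov / np.sqrt(var_v * var_y)
        good = ok & np.isfinite(rr) & (var_v > 0) & (var_y > 0)
        r[a, good] = np.clip(rr[good], -1.0, 1.0)
        valid[a, good] = True
    if valid.sum() < 2:
        raise ValueError(
            f"fewer than 2 valid ordered pairs for family {family}")
    pairs = []
    for a in range(m):
        for b in range(m):
            if valid[a, b]:
                pairs.append((float(s.wavelengths_nm[a]),
                              float(s.wavelengths_nm[b]), float(r[a, b])))
    pairs.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    return PairCorrelationMap(family=family, bands_nm=s.wavelengths_nm,
                              r=r, valid=valid, top_k=tuple(pairs[:k]))


def top_k_pairs(cmap: PairCorrelationMap, k: int) -> tuple:
    """Re-rank a map's valid pairs and return the k strongest by |r|."""
    if k < 1:
        raise ValueError("k must be >= 1")
    m = cmap.bands_nm.size
    pairs = [
        (float(cmap.bands_nm[a]), float(cmap.bands_nm[b]),
         float(cmap.r[a, b]))
        for a in range(m) for b in range(m) if cmap.valid[a, b]
    ]
    if not pairs:
        raise ValueError("empty pair-correlation map")
    pairs.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    if len(pairs) < k:
        log.warning("only %d valid pairs available for k=%d", len(pairs), k)
    return tuple(pairs[:k])


@dataclass(frozen=True)
class FeatureMatrix:
    """Modelling features: one column per (family, i_nm, j_nm) pair."""

    values: np.ndarray           #: (n_samples, 4k), imputed (no NaN)
    columns: tuple               #: dicts: family, i_nm, j_nm, r, n_imputed
    sample_ids: tuple

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        names = [f"{c['family']}({c['i_nm']:g},{c['j_nm']:g})"
                 for c in self.columns]
        return pd.DataFrame(self.values, columns=names,
                            index=list(self.sample_ids))


def build_feature_matrix(s: SpectraSet, ant, k: int = 10,
                         families=("ARI", "CI", "DVI", "NARI"),
                         eps: float = DEFAULT_EPS) -> FeatureMatrix:
    """Assemble the modelling matrix from the top-k pairs of each family.

    ``s`` must already be restricted to the selected bands of one
    (derivative kind, selector) combination.  Column order is family
    order x rank, so with the four default families and k = 10 the matrix
    has 40 columns.  Residual masked samples within a retained pair
    (at most 20 %) are imputed with the column median of the valid
    samples; the count is recorded per column.
    """
    wl = s.wavelengths_nm
    cols, values = [], []
    for family in families:
        cmap = pair_correlation_map(s, ant, family, eps=eps, k=k)
        top = cmap.top_k
        if not top:
            raise ValueError(f"family {family} produced no valid pairs")
        for (i_nm, j_nm, r) in top:
            a = int(np.argmin(np.abs(wl - i_nm)))
            b = int(np.argmin(np.abs(wl - j_nm)))
            v = compute_index(family, s.values[:, a], s.values[:, b], eps)
            bad = ~np.isfinite(v)
            if bad.any():
                v = v.copy()
                v[bad] = np.nanmedian(v)
            cols.append({"family": family, "i_nm": i_nm, "j_nm": j_nm,
                         "r": r, "n_imputed": int(bad.sum())})
            values.append(v)
    return FeatureMatrix(values=np.column_stack(values), columns=tuple(cols),
                         sample_ids=s.sample_ids)
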