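"""Core data containers for leaf spectroscopy workflows.

Two containers carry all data through the pipeline: :class:`SpectraSet`
(a sample x wavelength reflectance or derivative matrix with per-sample
metadata) and :class:`SampleTable` (per-sample wet-chemistry measurements).
Both are validated on construction and round-trip losslessly through plain
CSV, so every intermediate artifact is diffable and re-readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "SampleTable",
    "SpectraFormatError",
    "SpectraValidationError",
    "read_spectra",
    "write_spectra",
    "read_sample_table",
    "write_sample_table",
    "SPECTRUM_KINDS",
    "GROUNDWATER_GROUPS",
]

#: Spectrum kinds: raw reflectance, Savitzky-Golay smoothed reflectance,
#: first derivative (per nm), second derivative (per nm^2).
SPECTRUM_KINDS = ("raw", "smoothed", "fd", "sd")

#: Groundwater-depth classes (m below surface) used to stratify sampling.
GROUNDWATER_GROUPS = ("0-2", "2-4", "4-6", "6-8", "8-10")

#: Float format preserving full float64 precision on write.
_FLOAT_FMT = "%.17g"


class SpectraFormatError(ValueError):
    """A spectra/sample file does not parse into the expected schema."""


class SpectraValidationError(ValueError):
    """Parsed data violates a container invariant."""


def _as_1d(x, name: str, n: int | None = None, dtype=None) -> np.ndarray:
    arr = np.asarray(x) if dtype is None else np.asarray(x, dtype=dtype)
    if arr.ndim != 1:
        raise SpectraValidationError(f"{name} must be one-dimensional")
    if n is not None and arr.shape[0] != n:
        raise SpectraValidationError(
            f"{name} has length {arr.shape[0]}, expected {n}"
        )
    return arr


@dataclass(frozen=True)
class SpectraSet:
    """Wavelength grid plus a sample x band matrix with sample metadata.

    Parameters
    ----------
    wavelengths_nm : array of float, strictly increasing band centres (nm).
    values : (n_samples, n_bands) matrix.  Unitless reflectance for kinds
        ``raw``/``smoothed`` (must lie in [0, 1]); per-nm or per-nm^2 for
        the derivative kinds ``fd``/``sd``.
    sample_ids : unique sample labels.
    month : sampling month per sample, integers 6-10.
    group : groundwater-depth class per sample (one of
        :data:`GROUNDWATER_GROUPS`).
    kind : one of :data:`SPECTRUM_KINDS`.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    sample_ids: tuple[str, ...]
    month: np.ndarray
    group: tuple[str, ...]
    kind: str = "raw"

    def __post_init__(self) -> None:
        wl = _as_1d(self.wavelengths_nm, "wavelengths_nm", dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise SpectraValidationError("values must be a 2-D matrix")
        n, p = vals.shape
        if p != wl.shape[0]:
            raise SpectraValidationError(
                f"values has {p} bands but {wl.shape[0]} wavelengths given"
            )
        if wl.shape[0] and np.any(np.diff(wl) <= 0):
            raise SpectraValidationError(
                "wavelengths must be strictly increasing"
            )
        ids = tuple(str(s) for s in self.sample_ids)
        if len(ids) != n:
            raise SpectraValidationError(
                f"{len(ids)} sample_ids for {n} spectra"
            )
        if len(set(ids)) != len(ids):
            raise SpectraValidationError("sample_ids must be unique")
        month = _as_1d(self.month, "month", n, dtype=int)
        if month.size and not np.all((month >= 6) & (month <= 10)):
            raise SpectraValidationError("month entries must lie in 6..10")
        grp = tuple(str(g) for g in self.group)
        if len(grp) != n:
            raise SpectraValidationError(f"{len(grp)} group labels for {n} spectra")
        bad = sorted(set(grp) - set(GROUNDWATER_GROUPS))
        if bad:
            raise SpectraValidationError(f"unknown groundwater groups: {bad}")
        if self.kind not in SPECTRUM_KINDS:
            raise SpectraValidationError(
                f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}"
            )
        if not np.all(np.isfinite(vals)):
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise SpectraValidationError(
                f"non-finite value at sample {ids[i]!r}, band {wl[j]:g} nm"
            )
        if self.kind in ("raw", "smoothed") and vals.size:
            if vals.min() < 0.0 or vals.max() > 1.0:
                i, j = np.argwhere((vals < 0) | (vals > 1))[0]
                raise SpectraValidationError(
                    f"{self.kind} reflectance outside [0, 1] at sample "
                    f"{ids[i]!r}, band {wl[j]:g} nm (value {vals[i, j]:g})"
                )
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "month", month)
        object.__setattr__(self, "group", grp)

    # -- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, kind: str,
                    wavelengths_nm: np.ndarray | None = None) -> "SpectraSet":
        """Return a copy carrying new values (and optionally a new grid)."""
        wl = self.wavelengths_nm if wavelengths_nm is None else wavelengths_nm
        return SpectraSet(wl, values, self.sample_ids, self.month,
                          self.group, kind)

    def select_bands(self, indices: Sequence[int]) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return self.with_values(self.values[:, idx], self.kind,
                                self.wavelengths_nm[idx])

    def equals(self, other: "SpectraSet", rtol: float = 0.0,
               atol: float = 0.0) -> bool:
        return (
            self.kind == other.kind
            and self.sample_ids == other.sample_ids
            and self.group == other.group
            and np.array_equal(self.month, other.month)
            and np.allclose(self.wavelengths_nm, other.wavelengths_nm,
                            rtol=rtol, atol=atol)
            and np.allclose(self.values, other.values, rtol=rtol, atol=atol)
        )


#: Columns a sample table must carry, in canonical order.
_SAMPLE_COLUMNS = [
    "sample_id", "S", "W_F", "A470", "A537", "A647", "A663",
    "V", "M_Ant", "Ant", "month", "group",
]


@dataclass(frozen=True)
class SampleTable:
    """Per-sample wet-chemistry table.

    Columns: ``sample_id``; leaf area ``S`` (m^2); fresh weight ``W_F`` (g);
    absorbances ``A470``/``A537``/``A647``/``A663`` (unitless, >= 0);
    colorimetry volume ``V`` (mL); anthocyanin molecular mass ``M_Ant``
    (g mol^-1); anthocyanin concentration ``Ant`` (mg m^-2); ``month``;
    groundwater ``group``.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise SpectraFormatError(f"sample table missing columns: {missing}")
        df = df[_SAMPLE_COLUMNS].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            raise SpectraValidationError("duplicate sample_id in sample table")
        for col in ("S", "W_F", "V", "M_Ant"):
            vals = pd.to_numeric(df[col])
            if not np.all(np.isfinite(vals)) or (vals <= 0).any():
                bad = df.loc[~(vals > 0), "sample_id"].tolist()
                raise SpectraValidationError(
                    f"{col} must be finite and > 0 (violated by {bad})"
                )
            df[col] = vals.astype(float)
        for col in ("A470", "A537", "A647", "A663"):
            vals = pd.to_numeric(df[col]).astype(float)
            if not np.all(np.isfinite(vals)) or (vals < 0).any():
                raise SpectraValidationError(f"{col} must be finite and >= 0")
            df[col] = vals
        ant = pd.to_numeric(df["Ant"]).astype(float)
        if not np.all(np.isfinite(ant)):
            raise SpectraValidationError("Ant must be finite")
        df["Ant"] = ant
        df["month"] = pd.to_numeric(df["month"]).astype(int)
        if len(df) and not df["month"].between(6, 10).all():
            raise SpectraValidationError("month entries must lie in 6..10")
        df["group"] = df["group"].astype(str)
        bad = sorted(set(df["group"]) - set(GROUNDWATER_GROUPS))
        if bad:
            raise SpectraValidationError(f"unknown groundwater groups: {bad}")
        df = df.reset_index(drop=True)
        object.__setattr__(self, "data", df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data["sample_id"])

    @property
    def ant(self) -> np.ndarray:
        """Anthocyanin concentrations (mg m^-2) as a vector."""
        return self.data["Ant"].to_numpy()

    def subset(self, mask) -> "SampleTable":
        return SampleTable(self.data.loc[mask].reset_index(drop=True))

    def equals(self, other: "SampleTable") -> bool:
        return self.data.equals(other.data)


# -- CSV I/O ---------------------------------------------------------------
# Dialect: plain UTF-8 CSV, "." decimal separator; spectra files put the
# wavelength (nm) in each column header; month/group travel as optional
# metadata columns so a single file is a complete fixture.

def write_spectra(s: SpectraSet, path) -> Path:
    """Write a :class:`SpectraSet` to CSV; inverse of :func:`read_spectra`."""
    path = Path(path)
    df = pd.DataFrame(s.values, columns=[_FLOAT_FMT % w
                                         for w in s.wavelengths_nm])
    df.insert(0, "sample_id", list(s.sample_ids))
    df["month"] = s.month
    df["group"] = list(s.group)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_spectra(path, kind: str = "raw") -> SpectraSet:
    """Read a spectra CSV written by :func:`write_spectra`.

    The first column must be ``sample_id``; remaining numeric headers are
    band centres in nm; optional trailing ``month``/``group`` columns carry
    metadata (defaults: month 6, group "0-2").
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"sample_id": str},
                     float_precision="round_trip")
    if df.columns[0] != "sample_id" if len(df.columns) else True:
        raise SpectraFormatError(
            f"{path}: first column must be 'sample_id', got "
            f"{df.columns[0] if len(df.columns) else 'nothing'!r}"
        )
    meta_cols = [c for c in ("month", "group") if c in df.columns]
    band_cols = [c for c in df.columns[1:] if c not in ("month", "group")]
    try:
        wavelengths = np.array([float(c) for c in band_cols])
    except ValueError as exc:
        raise SpectraFormatError(
            f"{path}: band column headers must parse as wavelengths in "
            f"nm ({exc})"
        ) from None
    values = df[band_cols].to_numpy(dtype=float)
    month = (df["month"].to_numpy(dtype=int) if "month" in meta_cols
             else np.full(len(df), 6, dtype=int))
    group = (list(df["group"].astype(str)) if "group" in meta_cols
             else ["0-2"] * len(df))
    finite = np.isfinite(values).all(axis=1)
    if not finite.all():
        dropped = df.loc[~finite, "sample_id"].tolist()
        raise SpectraValidationError(
            f"{path}: non-finite values in rows {dropped}"
        )
    return SpectraSet(wavelengths, values, list(df["sample_id"]),
                      month, group, kind)


def write_sample_table(t: SampleTable, path) -> Path:
    path = Path(path)
    t.data.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_sample_table(path) -> SampleTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str},
                     float_precision="round_trip")
    return SampleTable(df)
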