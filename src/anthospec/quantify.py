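"""Wet-chemistry anthocyanin quantification and sample screening.

Anthocyanin concentration per unit leaf area is derived from colorimetric
absorbances in three steps:

* specific leaf weight  ``SLW = S / W_F``  (m^2 g^-1),
* anthocyanin amount per unit solution volume (umol mL^-1)
  ``C_Ant = 0.08173*A537 - 0.00697*A647 - 0.002228*A663``,
* concentration per unit leaf area (mg m^-2)
  ``Ant = C_Ant * V * M_Ant / (1000 * W_F * SLW)``.

Because ``SLW = S / W_F``, the fresh weight cancels and
``Ant = C_Ant * V * M_Ant / (1000 * S)`` — concentration depends on fresh
weight only through the specific leaf weight.

Screening removes per-(month, group) outliers and reports a Shapiro-Wilk
normality check on the retained concentrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import SampleTable

__all__ = [
    "A537_COEF", "A647_COEF", "A663_COEF", "DEFAULT_M_ANT",
    "QuantResult", "ScreeningReport",
    "specific_leaf_weight", "anthocyanin_in_solution",
    "anthocyanin_per_area", "quantify", "quantify_table", "screen_samples",
]

log = logging.getLogger(__name__)

#: Colorimetric coefficients (umol mL^-1 per absorbance unit) at 537, 647
#: and 663 nm; the 647/663 terms correct for chlorophyll interference.
A537_COEF = 0.08173
A647_COEF = 0.00697
A663_COEF = 0.002228

#: Default anthocyanin molecular mass (g mol^-1): cyanidin-3-glucoside
#: equivalent, the conventional reference anthocyanin. Config-overridable.
DEFAULT_M_ANT = 449.2


@dataclass(frozen=True)
class QuantResult:
    """Quantification outputs for one sample."""

    SLW: float      #: specific leaf weight, m^2 g^-1
    C_Ant: float    #: anthocyanin per unit solution volume, umol mL^-1
    Ant: float      #: anthocyanin concentration, mg m^-2


def specific_leaf_weight(S, W_F):
    """Specific leaf weight ``S / W_F`` (m^2 g^-1); inputs must be > 0."""
    S = np.asarray(S, dtype=float)
    W_F = np.asarray(W_F, dtype=float)
    if np.any(S <= 0) or np.any(W_F <= 0):
        raise ValueError("leaf area S and fresh weight W_F must be > 0")
    return S / W_F


def anthocyanin_in_solution(A537, A647, A663):
    """Anthocyanin amount per unit solution volume (umol mL^-1).

    May be mathematically negative when A537 is small relative to the
    chlorophyll channels; negative values are returned as-is and flagged
    in the log rather than clipped.
    """
    A537, A647, A663 = (np.asarray(a, dtype=float) for a in (A537, A647, A663))
    if np.any(A537 < 0) or np.any(A647 < 0) or np.any(A663 < 0):
        raise ValueError("absorbances must be >= 0")
    c = A537_COEF * A537 - A647_COEF * A647 - A663_COEF * A663
    n_neg = int(np.sum(np.asarray(c) < 0))
    if n_neg:
        log.warning("anthocyanin_in_solution: %d negative C_Ant value(s) "
                    "(kept, not clipped)", n_neg)
    return c


def anthocyanin_per_area(C_Ant, V, M_Ant, W_F, SLW):
    """Anthocyanin concentration per unit leaf area (mg m^-2)."""
    C_Ant = np.asarray(C_Ant, dtype=float)
    V, M_Ant, W_F, SLW = (np.asarray(x, dtype=float)
                          for x in (V, M_Ant, W_F, SLW))
    if np.any(V <= 0) or np.any(M_Ant <= 0) or np.any(W_F <= 0) \
            or np.any(SLW <= 0):
        raise ValueError("V, M_Ant, W_F and SLW must all be > 0")
    return C_Ant * V * M_Ant / (1000.0 * W_F * SLW)


def quantify(S, W_F, A537, A647, A663, V, M_Ant=DEFAULT_M_ANT) -> QuantResult:
    """Full quantification for one sample (or vectorised inputs)."""
    slw = specific_leaf_weight(S, W_F)
    c_ant = anthocyanin_in_solution(A537, A647, A663)
    ant = anthocyanin_per_area(c_ant, V, M_Ant, W_F, slw)
    return QuantResult(SLW=slw, C_Ant=c_ant, Ant=ant)


def quantify_table(table: SampleTable) -> SampleTable:
    """Recompute the ``Ant`` column of a sample table from its absorbances."""
    df = table.data.copy()
    res = quantify(df["S"].to_numpy(), df["W_F"].to_numpy(),
                   df["A537"].to_numpy(), df["A647"].to_numpy(),
                   df["A663"].to_numpy(), df["V"].to_numpy(),
                   df["M_Ant"].to_numpy())
    df["Ant"] = res.Ant
    return SampleTable(df)


@dataclass(frozen=True)
class ScreeningReport:
    """Outcome of outlier screening + normality check."""

    rule: str
    removed_ids: tuple[str, ...]
    n_before: int
    n_after: int
    shapiro_statistic: float | None
    shapiro_p_value: float | None
    zero_variance: bool

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "removed_ids": list(self.removed_ids),
            "n_before": self.n_before,
            "n_after": self.n_after,
            "shapiro_statistic": self.shapiro_statistic,
            "shapiro_p_value": self.shapiro_p_value,
            "zero_variance": self.zero_variance,
        }


def screen_samples(table: SampleTable, n_sd: float = 3.0,
                   by_cell: bool = True) -> tuple[SampleTable, ScreeningReport]:
    """Remove concentration outliers and report a normality check.

    A sample is an outlier when its ``Ant`` lies outside mean +- ``n_sd``
    standard deviations, computed within each (month, group) cell when
    ``by_cell`` (cells with fewer than 3 samples are never trimmed) or
    globally otherwise.  Trimming is iterated to a fixed point, which makes
    the operation idempotent.  A Shapiro-Wilk test on the retained
    concentrations is reported for information only; it does not drop
    samples.
    """
    if len(table) == 0:
        raise ValueError("cannot screen an empty sample table")
    df = table.data
    ant = df["Ant"].to_numpy()
    keep = np.ones(len(df), dtype=bool)

    def _one_pass(keep: np.ndarray) -> np.ndarray:
        new = keep.copy()
        if by_cell:
            for _, idx in df.groupby(["month", "group"]).groups.items():
                idx = np.asarray(idx)
                idx = idx[keep[idx]]
                if idx.size < 3:
                    continue
                cell = ant[idx]
                mu, sd = cell.mean(), cell.std(ddof=1)
                if sd > 0:
                    new[idx] = np.abs(cell - mu) <= n_sd * sd
        else:
            idx = np.flatnonzero(keep)
            if idx.size >= 3:
                mu, sd = ant[idx].mean(), ant[idx].std(ddof=1)
                if sd > 0:
                    new[idx] = np.abs(ant[idx] - mu) <= n_sd * sd
        return new

    while True:
        new = _one_pass(keep)
        if not new.any():
            raise ValueError(
                "screening removed every sample (degenerate dataset)")
        if np.array_equal(new, keep):
            break
        keep = new
    removed = tuple(df.loc[~keep, "sample_id"])
    kept = table.subset(keep)

    kept_ant = kept.ant
    zero_var = bool(kept_ant.size < 3 or np.ptp(kept_ant) == 0)
    if zero_var:
        stat = p = None
    else:
        res = stats.shapiro(kept_ant)
        stat, p = float(res.statistic), float(res.pvalue)
    scope = "per (month, group) cell" if by_cell else "global"
    report = ScreeningReport(
        rule=f"remove |Ant - mean| > {n_sd:g} sd, {scope}",
        removed_ids=removed, n_before=len(table), n_after=len(kept),
        shapiro_statistic=stat, shapiro_p_value=p, zero_variance=zero_var,
    )
    log.info("screen_samples: kept %d / %d (%s)", len(kept), len(table),
             report.rule)
    return kept, report
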