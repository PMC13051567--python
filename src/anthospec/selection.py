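"""Wavelength selection: CARS, SFLA and RFECV over a shared PLS engine.

All three selectors score candidate band subsets by K-fold RMSECV of a
PLS1 model and return the subset minimising it, as a
:class:`SelectionResult`.  They follow the sklearn selector protocol
(``fit(X, y)``, ``get_support()``, ``transform(X)``), take explicit seeds,
and are deterministic per seed.

* **CARS** (competitive adaptive reweighted sampling): Monte-Carlo PLS
  fits on random calibration subsets weight each band by its normalised
  absolute regression coefficient; an exponentially decreasing retention
  schedule prunes low-weight bands, followed by weighted resampling with
  replacement; the iteration subset with minimum RMSECV wins.
* **SFLA** (shuffled frog leaping): a memetic search over fixed-size band
  subsets ("frogs"); per-band selection probabilities derived from the
  final population rank bands, and a nested backward sweep over that
  ranking picks the minimum-RMSECV prefix.
* **RFECV**: backward elimination of the band with the smallest absolute
  PLS1 coefficient, recording RMSECV at every subset size; the size with
  the minimum wins.

Tie-breaking everywhere: equal weights/probabilities prefer the lower
wavelength; equal RMSECV prefers the earlier (larger-subset or
earlier-iteration) candidate via strict ``<`` comparisons.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .config import CARSConfig, RFECVConfig, SFLAConfig
from .pls import PLS1, rmsecv

__all__ = ["SelectionResult", "CARSSelector", "SFLASelector",
           "RFECVSelector", "make_selector"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one wavelength-selection run."""

    method: str
    selected_wavelengths_nm: np.ndarray   #: sorted ascending
    selected_indices: np.ndarray          #: indices into the input grid
    rmsecv_trace: np.ndarray              #: RMSECV per iteration/subset size
    best_rmsecv: float
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        idx = np.asarray(self.selected_indices, dtype=int)
        wl = np.asarray(self.selected_wavelengths_nm, dtype=float)
        if idx.size == 0:
            raise ValueError("selection result must be non-empty")
        order = np.argsort(wl)
        object.__setattr__(self, "selected_wavelengths_nm", wl[order])
        object.__setattr__(self, "selected_indices", idx[order])
        object.__setattr__(self, "rmsecv_trace",
                           np.asarray(self.rmsecv_trace, dtype=float))

    @property
    def n_selected(self) -> int:
        return self.selected_indices.size

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "method": self.method,
            "selected_wavelengths_nm": self.selected_wavelengths_nm.tolist(),
            "selected_indices": self.selected_indices.tolist(),
            "rmsecv_trace": self.rmsecv_trace.tolist(),
            "best_rmsecv": self.best_rmsecv,
            "seed": self.seed,
            "config": self.config,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(
            method=d["method"],
            selected_wavelengths_nm=np.asarray(d["selected_wavelengths_nm"]),
            selected_indices=np.asarray(d["selected_indices"]),
            rmsecv_trace=np.asarray(d["rmsecv_trace"]),
            best_rmsecv=d["best_rmsecv"], seed=d["seed"], config=d["config"],
        )


class _BaseSelector(BaseEstimator):
    """Shared sklearn-style surface for the three selectors."""

    method: str = ""

    def __init__(self, wavelengths_nm=None, seed: int = 0):
        self.wavelengths_nm = wavelengths_nm
        self.seed = seed

    # subclasses implement _select(X, y, wl, rng) -> SelectionResult

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different sample counts")
        wl = (np.arange(X.shape[1], dtype=float)
              if self.wavelengths_nm is None
              else np.asarray(self.wavelengths_nm, dtype=float))
        if wl.shape[0] != X.shape[1]:
            raise ValueError("wavelengths_nm length must match n_bands")
        rng = np.random.default_rng(self.seed)
        self.selection_result_ = self._select(X, y, wl, rng)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.selection_result_.selected_indices] = True
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self, indices: bool = False):
        return (np.flatnonzero(self.support_) if indices else self.support_)

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)


def _sub_seed(rng: np.random.Generator) -> int:
    """Draw a deterministic 31-bit sub-seed for a nested RMSECV call."""
    return int(rng.integers(0, 2 ** 31 - 1))


def _tie_break_order(weights: np.ndarray) -> np.ndarray:
    """Indices ordered by decreasing weight; ties -> lower index (hence
    lower wavelength, since bands are stored in ascending order)."""
    return np.lexsort((np.arange(weights.size), -weights))


class CARSSelector(_BaseSelector):
    """Competitive adaptive reweighted sampling.

    Over ``n_mc_runs`` iterations, each fits PLS1 on a random
    ``calib_fraction`` of samples restricted to the currently retained
    bands and weights each band by its normalised |coefficient|.  The
    retention ratio follows the exponential schedule
    ``r_i = a * exp(-k * i)`` with ``a = (p/2)^(1/(N-1))`` and
    ``k = ln(p/2)/(N-1)``, so all ``p`` bands survive the first iteration
    and exactly 2 the last.  After deterministic truncation to the top
    ``ceil(r_i * p)`` bands, adaptive reweighted sampling draws that many
    bands with replacement in proportion to weight and keeps the union.
    """

    method = "CARS"

    def __init__(self, wavelengths_nm=None, seed: int = 0,
                 config: CARSConfig | None = None):
        super().__init__(wavelengths_nm, seed)
        self.config = config

    @staticmethod
    def retention_ratio(i: int, n_runs: int, p: int) -> float:
        """Fraction of the p bands retained at iteration i (1-based)."""
        if n_runs < 2:
            raise ValueError("need at least 2 Monte-Carlo runs")
        a = (p / 2.0) ** (1.0 / (n_runs - 1))
        k = np.log(p / 2.0) / (n_runs - 1)
        return float(a * np.exp(-k * i))

    def _select(self, X, y, wl, rng) -> SelectionResult:
        cfg = self.config or CARSConfig()
        n, p = X.shape
        if p < 3:
            raise ValueError("CARS needs at least 3 bands")
        N = cfg.n_mc_runs
        retained = np.arange(p)
        trace, subsets = [], []
        n_calib = max(2, int(round(cfg.calib_fraction * n)))
        for i in range(1, N + 1):
            calib = rng.choice(n, size=n_calib, replace=False)
            model = PLS1(n_components=min(cfg.max_components, retained.size),
                         scale=True).fit(X[np.ix_(calib, retained)], y[calib])
            w = np.abs(model.coef_)
            w = w / w.sum() if w.sum() > 0 else np.full(w.size, 1.0 / w.size)

            keep = int(np.ceil(self.retention_ratio(i, N, p) * p))
            keep = min(keep, retained.size)
            order = _tie_break_order(w)
            retained_local = np.sort(order[:keep])
            w_kept = w[retained_local]
            # adaptive reweighted sampling: weighted draws w. replacement
            probs = w_kept / w_kept.sum()
            draws = rng.choice(retained_local.size, size=retained_local.size,
                               replace=True, p=probs)
            survivors = np.unique(draws)
            retained = retained[retained_local[survivors]]
            if retained.size < 2:
                warnings.warn("CARS retained fewer than 2 bands before the "
                              "schedule ended; stopping early")
                break
            res = rmsecv(X[:, retained], y, cfg.max_components, cfg.folds,
                         seed=_sub_seed(rng))
            trace.append(res.rmsecv)
            subsets.append(retained.copy())
        if not subsets:
            raise RuntimeError("CARS produced no candidate subsets")
        best = int(np.argmin(trace))
        sel = subsets[best]
        return SelectionResult(
            method=self.method, selected_wavelengths_nm=wl[sel],
            selected_indices=sel, rmsecv_trace=np.asarray(trace),
            best_rmsecv=float(trace[best]), seed=self.seed,
            config=vars(cfg),
        )


class SFLASelector(_BaseSelector):
    """Shuffled frog leaping adapted to wavelength selection.

    Frogs are band subsets of fixed cardinality; fitness is -RMSECV.
    Each global iteration partitions the ranked population round-robin
    into memeplexes; within each, the worst frog repeatedly tries moves
    (adopt bands from the memeplex best, then from the global best, then
    random restart).  Final per-band selection probabilities are
    fitness-rank-weighted membership frequencies; bands are ranked by
    probability and a nested backward sweep (drop the least probable
    first) returns the minimum-RMSECV prefix.
    """

    method = "SFLA"

    def __init__(self, wavelengths_nm=None, seed: int = 0,
                 config: SFLAConfig | None = None):
        super().__init__(wavelengths_nm, seed)
        self.config = config

    def _fitness(self, X, y, frog, cfg, rng) -> float:
        res = rmsecv(X[:, np.sort(frog)], y, cfg.max_components, cfg.folds,
                     seed=self._cv_seed)
        return -res.rmsecv

    def _select(self, X, y, wl, rng) -> SelectionResult:
        cfg = self.config or SFLAConfig()
        n, p = X.shape
        card = min(cfg.frog_cardinality, p - 1)
        if card < 1:
            raise ValueError("frog cardinality must be >= 1 and < n_bands")
        if cfg.n_frogs % cfg.n_memeplexes:
            raise ValueError("n_frogs must be divisible by n_memeplexes")
        # one fixed CV seed per run: frog comparisons share fold noise
        self._cv_seed = _sub_seed(rng)

        frogs = [rng.choice(p, size=card, replace=False)
                 for _ in range(cfg.n_frogs)]
        fits = np.array([self._fitness(X, y, f, cfg, rng) for f in frogs])
        best_trace = []

        def global_best():
            return int(np.argmax(fits))

        for _ in range(cfg.global_iters):
            order = np.argsort(-fits)            # shuffle: rank, then deal
            meme = [order[m::cfg.n_memeplexes] for m in range(cfg.n_memeplexes)]
            for members in meme:
                for _ in range(cfg.local_steps):
                    worst = members[int(np.argmin(fits[members]))]
                    local_best = members[int(np.argmax(fits[members]))]
                    moved = False
                    for guide in (local_best, global_best()):
                        cand = self._leap(frogs[worst], frogs[guide], p, rng)
                        f = self._fitness(X, y, cand, cfg, rng)
                        if f > fits[worst]:
                            frogs[worst], fits[worst] = cand, f
                            moved = True
                            break
                    if not moved and worst != global_best():
                        # random restart (the incumbent best is protected)
                        cand = rng.choice(p, size=card, replace=False)
                        frogs[worst] = cand
                        fits[worst] = self._fitness(X, y, cand, cfg, rng)
            if len({tuple(np.sort(f)) for f in frogs}) == 1:
                warnings.warn("SFLA population collapsed to one frog; "
                              "randomly restarting all but the best")
                keep = global_best()
                for j in range(cfg.n_frogs):
                    if j != keep:
                        frogs[j] = rng.choice(p, size=card, replace=False)
                        fits[j] = self._fitness(X, y, frogs[j], cfg, rng)
            best_trace.append(-fits.max() if not best_trace
                              else min(best_trace[-1], -fits.max()))

        #: best population RMSECV per global iteration (elitist bookkeeping:
        #: non-increasing by construction)
        self.fitness_trace_ = np.asarray(best_trace)

        # selection probability: fitness-rank-weighted membership frequency
        ranks = np.empty(cfg.n_frogs)
        ranks[np.argsort(fits)] = np.arange(1, cfg.n_frogs + 1)  # best = max
        prob = np.zeros(p)
        for f, r in zip(frogs, ranks):
            prob[f] += r
        prob /= prob.sum() if prob.sum() > 0 else 1.0

        band_order = _tie_break_order(prob)       # most probable first
        sweep_seed = self._cv_seed
        trace, subsets = [], []
        for size in range(p, 1, -1):
            sub = np.sort(band_order[:size])
            res = rmsecv(X[:, sub], y, cfg.max_components, cfg.folds,
                         seed=sweep_seed)
            trace.append(res.rmsecv)
            subsets.append(sub)
        best = int(np.argmin(trace))
        sel = subsets[best]
        return SelectionResult(
            method=self.method, selected_wavelengths_nm=wl[sel],
            selected_indices=sel, rmsecv_trace=np.asarray(trace),
            best_rmsecv=float(trace[best]), seed=self.seed,
            config=vars(cfg),
        )

    @staticmethod
    def _leap(worst: np.ndarray, guide: np.ndarray, p: int,
              rng: np.random.Generator) -> np.ndarray:
        """Move the worst frog toward a guide: replace a random fraction of
        its bands with bands from the guide, keeping cardinality fixed."""
        card = worst.size
        novel = np.setdiff1d(guide, worst)
        if novel.size == 0:
            return worst.copy()
        n_swap = rng.integers(1, min(novel.size, card) + 1)
        take = rng.choice(novel, size=n_swap, replace=False)
        drop = rng.choice(card, size=n_swap, replace=False)
        cand = worst.copy()
        cand[drop] = take
        return cand


class RFECVSelector(_BaseSelector):
    """Recursive feature elimination with cross-validation.

    At each step the band with the smallest absolute PLS1 regression
    coefficient (on autoscaled predictors, so magnitudes are comparable)
    is eliminated; RMSECV is recorded at every visited subset size and
    the minimising size wins.  With ``step=1`` the trace has
    ``p - min_bands + 1`` entries.
    """

    method = "RFECV"

    def __init__(self, wavelengths_nm=None, seed: int = 0,
                 config: RFECVConfig | None = None):
        super().__init__(wavelengths_nm, seed)
        self.config = config

    def _select(self, X, y, wl, rng) -> SelectionResult:
        cfg = self.config or RFECVConfig()
        n, p = X.shape
        if cfg.min_bands < 1:
            raise ValueError("min_bands must be >= 1")
        if n < cfg.folds:
            raise ValueError("need at least as many samples as folds")
        cv_seed = _sub_seed(rng)
        retained = np.arange(p)
        trace, subsets = [], []
        while True:
            res = rmsecv(X[:, retained], y, cfg.max_components, cfg.folds,
                         seed=cv_seed)
            trace.append(res.rmsecv)
            subsets.append(retained.copy())
            if retained.size <= cfg.min_bands:
                break
            model = PLS1(n_components=min(cfg.max_components, retained.size),
                         scale=True).fit(X[:, retained], y)
            # |coefficient| on the autoscaled predictors
            w = np.abs(model.coef_ * model.x_std_)
            n_drop = min(cfg.step, retained.size - cfg.min_bands)
            order = _tie_break_order(w)           # decreasing importance
            keep_local = np.sort(order[:retained.size - n_drop])
            retained = retained[keep_local]
        best = int(np.argmin(trace))
        sel = subsets[best]
        return SelectionResult(
            method=self.method, selected_wavelengths_nm=wl[sel],
            selected_indices=sel, rmsecv_trace=np.asarray(trace),
            best_rmsecv=float(trace[best]), seed=self.seed,
            config=vars(cfg),
        )


def make_selector(method: str, wavelengths_nm=None, seed: int = 0,
                  config=None) -> _BaseSelector:
    """Factory keyed by method name ('cars' | 'sfla' | 'rfecv')."""
    table = {"cars": CARSSelector, "sfla": SFLASelector,
             "rfecv": RFECVSelector}
    key = method.lower()
    if key not in table:
        raise ValueError(f"unknown selection method {method!r}; "
                         f"expected one of {sorted(table)}")
    return table[key](wavelengths_nm=wavelengths_nm, seed=seed, config=config)
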