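"""Stratified splitting, SVM regression and R2/RMSE/RPD evaluation.

The modelling protocol: concentrations are sorted into five equal-width
intervals and each interval is split 7:3 into calibration and validation
(largest-remainder rounding keeps the global calibration count at
``round(ratio * n)``).  Models are scored with

* R2   = 1 - SS_res / SS_tot   (sum-of-squares form, not squared Pearson),
* RMSE = sqrt(mean squared error), in the units of the response,
* RPD  = SD(measured) / RMSE,  with the sample standard deviation
  (ddof = 1) by default.

RPD interpretation bands: >= 1.4 usable, 1.8-2 good, >= 2 very good
(usable for high-precision prediction).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .pls import kfold_indices

__all__ = [
    "SplitResult", "stratified_split", "r_squared", "rmse", "rpd",
    "rpd_class", "SVMRegressorCV", "ModelReport", "evaluate_predictions",
    "run_model_grid", "reports_to_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitResult:
    """A calibration/validation partition with stratum bookkeeping."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    stratum: np.ndarray       #: stratum id per sample (post-merging)
    seed: int

    def __post_init__(self):
        tr = np.asarray(self.train_idx, dtype=int)
        va = np.asarray(self.val_idx, dtype=int)
        if np.intersect1d(tr, va).size:
            raise ValueError("train and validation indices overlap")
        object.__setattr__(self, "train_idx", np.sort(tr))
        object.__setattr__(self, "val_idx", np.sort(va))
        object.__setattr__(self, "stratum",
                           np.asarray(self.stratum, dtype=int))

    @property
    def n(self) -> int:
        return self.train_idx.size + self.val_idx.size

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "train_idx": self.train_idx.tolist(),
            "val_idx": self.val_idx.tolist(),
            "stratum": self.stratum.tolist(),
            "seed": self.seed,
        }))
        return path

    @classmethod
    def from_json(cls, path) -> "SplitResult":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["train_idx"]), np.asarray(d["val_idx"]),
                   np.asarray(d["stratum"]), d["seed"])


def stratified_split(ant, ratio: float = 0.7, n_strata: int = 5,
                     seed: int = 0) -> SplitResult:
    """Equal-width concentration strata, split ``ratio`` : 1-ratio each.

    Per-stratum calibration counts use largest-remainder rounding so that
    the global calibration size is exactly ``round(ratio * n)``; empty
    strata are merged into their lower neighbour with a warning.  The
    draw within each stratum is without replacement and deterministic per
    seed.
    """
    ant = np.asarray(ant, dtype=float)
    n = ant.size
    if n < n_strata:
        raise ValueError("need at least n_strata samples")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly in (0, 1)")
    edges = np.linspace(ant.min(), ant.max(), n_strata + 1)
    stratum = np.clip(np.digitize(ant, edges[1:-1], right=False),
                      0, n_strata - 1)
    # merge empty strata downward so ids stay contiguous in occupancy
    occupied = [s for s in range(n_strata) if np.any(stratum == s)]
    if len(occupied) < n_strata:
        warnings.warn(f"{n_strata - len(occupied)} empty stratum(s) merged "
                      "into neighbours")
    remap = {s: i for i, s in enumerate(occupied)}
    stratum = np.array([remap[s] for s in stratum])

    n_train_total = int(round(ratio * n))
    if n_train_total in (0, n):
        raise ValueError("split ratio leaves one side empty")
    sizes = np.bincount(stratum)
    quota = ratio * sizes
    base = np.floor(quota).astype(int)
    base = np.minimum(base, sizes)  # safety
    short = n_train_total - base.sum()
    # largest fractional remainder first; ties -> lower stratum id
    order = np.lexsort((np.arange(sizes.size), -(quota - base)))
    for s in order:
        if short <= 0:
            break
        if base[s] < sizes[s]:
            base[s] += 1
            short -= 1
    rng = np.random.default_rng(seed)
    train, val = [], []
    for s, n_tr in enumerate(base):
        members = np.flatnonzero(stratum == s)
        picked = rng.choice(members, size=n_tr, replace=False)
        train.extend(picked)
        val.extend(np.setdiff1d(members, picked))
    return SplitResult(np.asarray(train), np.asarray(val), stratum, seed)


# -- metrics ----------------------------------------------------------------

def r_squared(y, y_hat) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    if y.size != y_hat.size:
        raise ValueError("length mismatch")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero variance in measured values")
    return 1.0 - float(((y - y_hat) ** 2).sum()) / ss_tot


def rmse(y, y_hat) -> float:
    """Root mean square error, in the units of ``y``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0 or y.size != y_hat.size:
        raise ValueError("inputs must be non-empty and of equal length")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def rpd(y_measured, rmse_value: float, ddof: int = 1) -> float:
    """Relative prediction deviation SD / RMSE (sample SD by default)."""
    y = np.asarray(y_measured, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 measured values")
    if rmse_value < 0:
        raise ValueError("rmse must be >= 0")
    if rmse_value == 0:
        log.warning("RPD with zero RMSE reported as +inf")
        return float("inf")
    return float(y.std(ddof=ddof) / rmse_value)


def rpd_class(value: float) -> str:
    """Qualitative RPD band: >=2 very good, 1.8-2 good, >=1.4 usable."""
    if value >= 2.0:
        return "very good"
    if value >= 1.8:
        return "good"
    if value >= 1.4:
        return "usable"
    return "unreliable"


# -- SVM --------------------------------------------------------------------

class SVMRegressorCV(BaseEstimator, RegressorMixin):
    """RBF-kernel support vector regression with grid-searched (C, gamma,
    epsilon).

    Features and target are standardised on training statistics only;
    epsilon candidates are expressed as fractions of sd(y).  The grid is
    scored by K-fold RMSE with deterministic folds; ties prefer the
    earlier grid point (grids are iterated smallest-C first).
    """

    def __init__(self, log2_C=tuple(range(-1, 10)),
                 log2_gamma=tuple(range(-7, 4)),
                 epsilon_frac=(0.01, 0.1, 0.5), folds: int = 5,
                 seed: int = 0):
        self.log2_C = log2_C
        self.log2_gamma = log2_gamma
        self.epsilon_frac = epsilon_frac
        self.folds = folds
        self.seed = seed

    def _make(self, C, gamma, eps_std):
        return SVR(kernel="rbf", C=C, gamma=gamma, epsilon=eps_std)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if np.ptp(y) == 0:
            raise ValueError("constant target: SVR-CV undefined")
        n = X.shape[0]
        if n < self.folds:
            raise ValueError("need at least `folds` training samples")
        folds = kfold_indices(n, self.folds, self.seed)
        grid = [(2.0 ** lc, 2.0 ** lg, ef)
                for lc in self.log2_C for lg in self.log2_gamma
                for ef in self.epsilon_frac]
        best = None
        for C, gamma, ef in grid:
            sq = 0.0
            for test in folds:
                train = np.setdiff1d(np.arange(n), test)
                xs = StandardScaler().fit(X[train])
                ys = StandardScaler().fit(y[train, None])
                model = self._make(C, gamma, ef).fit(
                    xs.transform(X[train]),
                    ys.transform(y[train, None]).ravel())
                pred = ys.inverse_transform(
                    model.predict(xs.transform(X[test]))[:, None]).ravel()
                sq += float(((pred - y[test]) ** 2).sum())
            score = np.sqrt(sq / n)
            if best is None or score < best[0]:
                best = (score, C, gamma, ef)
        self.cv_rmse_, C, gamma, ef = best
        self.best_params_ = {"C": C, "gamma": gamma, "epsilon_frac": ef}
        self.x_scaler_ = StandardScaler().fit(X)
        self.y_scaler_ = StandardScaler().fit(y[:, None])
        self.model_ = self._make(C, gamma, ef).fit(
            self.x_scaler_.transform(X),
            self.y_scaler_.transform(y[:, None]).ravel())
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        z = self.model_.predict(self.x_scaler_.transform(X))
        return self.y_scaler_.inverse_transform(z[:, None]).ravel()


# -- model grid -------------------------------------------------------------

@dataclass(frozen=True)
class ModelReport:
    """Calibration/validation metrics for one (derivative, selector,
    learner) combination."""

    derivative: str
    selector: str
    learner: str
    r2_c: float
    rmse_c: float
    rpd_c: float
    r2_v: float
    rmse_v: float
    rpd_v: float
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def model_id(self) -> str:
        return f"{self.derivative}-{self.selector}-{self.learner}"

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id, "derivative": self.derivative,
            "selector": self.selector, "learner": self.learner,
            "r2_c": self.r2_c, "rmse_c": self.rmse_c, "rpd_c": self.rpd_c,
            "r2_v": self.r2_v, "rmse_v": self.rmse_v, "rpd_v": self.rpd_v,
            "rpd_v_class": rpd_class(self.rpd_v),
            "hyperparameters": self.hyperparameters, "seed": self.seed,
        }


def evaluate_predictions(y_train, yhat_train, y_val, yhat_val,
                         ddof: int = 1) -> dict:
    """The six standard metrics from calibration + validation predictions."""
    rmse_c = rmse(y_train, yhat_train)
    rmse_v = rmse(y_val, yhat_val)
    return {
        "r2_c": r_squared(y_train, yhat_train), "rmse_c": rmse_c,
        "rpd_c": rpd(y_train, rmse_c, ddof),
        "r2_v": r_squared(y_val, yhat_val), "rmse_v": rmse_v,
        "rpd_v": rpd(y_val, rmse_v, ddof),
    }


def run_model_grid(features: dict, ant, split: SplitResult,
                   learners: dict | None = None, seed: int = 0
                   ) -> list[ModelReport]:
    """Fit every (derivative, selector) x learner combination.

    Parameters
    ----------
    features : mapping ``(derivative, selector) -> (n, p) array`` (or an
        object with a ``values`` attribute); the standard grid is
        {fd, sd} x {CARS, SFLA, RFECV}, giving 12 models with the two
        default learners.
    ant : measured concentrations, length n.
    split : calibration/validation partition.
    learners : mapping learner name -> estimator factory ``f(seed) ->
        estimator``; defaults to SVM and the 1D-CNN.
    """
    from .cnn import CNN1DRegressor
    if learners is None:
        learners = {
            "SVM": lambda s: SVMRegressorCV(seed=s),
            "1D-CNN": lambda s: CNN1DRegressor(seed=s),
        }
    ant = np.asarray(ant, dtype=float)
    reports = []
    rng = np.random.default_rng(seed)
    for (deriv, sel), mat in sorted(features.items()):
        X = np.asarray(getattr(mat, "values", mat), dtype=float)
        if X.shape[0] != ant.size:
            raise ValueError(f"feature matrix {deriv}-{sel} has "
                             f"{X.shape[0]} rows for {ant.size} samples")
        for name, factory in learners.items():
            sub = int(rng.integers(0, 2 ** 31 - 1))
            model = factory(sub)
            model.fit(X[split.train_idx], ant[split.train_idx])
            m = evaluate_predictions(
                ant[split.train_idx], model.predict(X[split.train_idx]),
                ant[split.val_idx], model.predict(X[split.val_idx]))
            hp = getattr(model, "best_params_", {})
            reports.append(ModelReport(derivative=deriv, selector=sel,
                                       learner=name, seed=sub,
                                       hyperparameters=dict(hp), **m))
            log.info("%s: R2_v=%.3f RMSE_v=%.2f RPD_v=%.2f",
                     reports[-1].model_id, m["r2_v"], m["rmse_v"],
                     m["rpd_v"])
    return reports


def reports_to_frame(reports: list[ModelReport]) -> pd.DataFrame:
    """Model-grid summary table (one row per model, best flagged).

    Best = highest validation R2, ties broken by higher RPD_v then lower
    RMSE_v.
    """
    df = pd.DataFrame([r.to_dict() for r in reports])
    key = df[["r2_v", "rpd_v", "rmse_v"]].copy()
    key["rmse_v"] = -key["rmse_v"]
    best = key.apply(tuple, axis=1).idxmax()
    df["best"] = False
    df.loc[best, "best"] = True
    return df
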