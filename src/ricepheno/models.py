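"""Growth/biomass model families, scoring and cross-validation.

Six candidate families describe the relation between a projected-area
predictor and a response (dry weight, or time for trajectory trends):

* linear        y = p x + q
* quadratic     y = p x^2 + q x + r
* exponential   y = p exp(q x)
* power         y = p x^q                     (requires x > 0)
* gaussian      y = A exp(-(x - mu)^2 / (2 sigma^2))
* sine          y = A sin(B x + C) + D        ("triangular sine")

Polynomial families are fit by ordinary least squares; the rest by
nonlinear least squares. Initialisation: exponential and power from a
log-linearised regression, gaussian from (max, argmax, range/4), sine
amplitude/offset from the data range with the angular frequency taken
from the dominant FFT bin of the detrended response. Non-convergence
triggers up to five seeded random restarts and then a *flagged* failure
result rather than an exception.

Fit quality is reported as R^2, MAPE (percent), RMSE and MAE, following
common practice in phenotyping-platform calibration studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

FAMILIES = ("linear", "quadratic", "exponential", "power", "gaussian", "sine")

_N_RESTARTS = 5


def _linear(x, p, q):
    return p * x + q


def _quadratic(x, p, q, r):
    return p * x**2 + q * x + r


def _exponential(x, p, q):
    return p * np.exp(q * x)


def _power(x, p, q):
    return p * np.power(x, q)


def _gaussian(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _sine(x, a, b, c, d):
    return a * np.sin(b * x + c) + d


_FUNCS = {
    "linear": _linear,
    "quadratic": _quadratic,
    "exponential": _exponential,
    "power": _power,
    "gaussian": _gaussian,
    "sine": _sine,
}

_N_PARAMS = {"linear": 2, "quadratic": 3, "exponential": 2, "power": 2, "gaussian": 3, "sine": 4}


@dataclass
class CVSummary:
    """Per-fold and aggregated cross-validation metrics."""

    k: int
    per_fold: list[dict[str, float]]
    mean: dict[str, float]
    sd: dict[str, float]


@dataclass
class ModelFitResult:
    """A fitted family with its four training metrics.

    ``success`` is False for a flagged non-convergent fit; such results
    carry NaN metrics and rank last in comparisons.
    """

    family: str
    params: tuple[float, ...]
    r2: float
    mape: float
    rmse: float
    mae: float
    success: bool = True
    message: str = ""
    cv: CVSummary | None = None

    def predict(self, x) -> np.ndarray:
        return _FUNCS[self.family](np.asarray(x, dtype=float), *self.params)


def score(y, yhat) -> tuple[float, float, float, float]:
    """(r2, mape, rmse, mae) between observed and predicted values.

    r2 = 1 - SSres/SStot; MAPE is in percent and requires all y != 0;
    a constant y makes r2 undefined and raises.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-D arrays of equal length")
    if len(y) < 2:
        raise ValueError("need at least 2 observations to score")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0:
        raise ValueError("constant y: R^2 is undefined (zero total sum of squares)")
    zeros = np.nonzero(y == 0)[0]
    if len(zeros):
        raise ValueError(f"MAPE undefined: y is zero at index {int(zeros[0])}")
    resid = y - yhat
    r2 = 1.0 - float(np.sum(resid**2)) / sstot
    mape = float(np.mean(np.abs(resid / y)) * 100.0)
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    return r2, mape, rmse, mae


def _metrics_tolerant(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float, float]:
    """Like :func:`score` but NaN-tolerant for degenerate cases.

    Used internally on training/held-out data where zero responses or a
    constant fold are legal: MAPE averages over nonzero y, r2 is NaN for
    a constant y.
    """
    resid = y - yhat
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else np.nan
    nz = y != 0
    mape = float(np.mean(np.abs(resid[nz] / y[nz])) * 100.0) if nz.any() else np.nan
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    return r2, mape, rmse, mae


def _initial_guess(x: np.ndarray, y: np.ndarray, family: str) -> np.ndarray:
    if family == "exponential":
        if np.all(y > 0):
            q, logp = np.polyfit(x, np.log(y), 1)
            return np.array([np.exp(logp), q])
        return np.array([y.mean() if y.mean() != 0 else 1.0, 0.0])
    if family == "power":
        if np.all(y > 0):
            q, logp = np.polyfit(np.log(x), np.log(y), 1)
            return np.array([np.exp(logp), q])
        return np.array([1.0, 1.0])
    if family == "gaussian":
        a = float(y.max())
        mu = float(x[int(np.argmax(y))])
        sigma = float((x.max() - x.min()) / 4.0) or 1.0
        return np.array([a, mu, sigma])
    if family == "sine":
        d = float(y.mean())
        a = float((y.max() - y.min()) / 2.0) or 1.0
        yd = y - d
        # dominant FFT frequency on a uniform resampling of the detrended data
        n = max(len(x), 8)
        xi = np.linspace(x.min(), x.max(), n)
        yi = np.interp(xi, x, yd)
        freqs = np.fft.rfftfreq(n, d=(xi[1] - xi[0]))
        spec = np.abs(np.fft.rfft(yi))
        k = int(np.argmax(spec[1:])) + 1
        b = 2.0 * np.pi * freqs[k]
        if b == 0:
            b = 2.0 * np.pi / (x.max() - x.min())
        return np.array([a, b, 0.0, d])
    raise ValueError(family)


def fit_model(x, y, family: str, seed: int | None = 0) -> ModelFitResult:
    """Fit one family; metrics are computed on the training data.

    Requires n >= n_params + 1. The power family requires x > 0.
    Nonlinear fits retry from jittered starts before being flagged.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < _N_PARAMS[family] + 1:
        raise ValueError(f"{family} fit needs >= {_N_PARAMS[family] + 1} points, got {len(x)}")
    if family == "power" and np.any(x <= 0):
        raise ValueError("power model requires x > 0")

    if family == "linear":
        params = tuple(np.polyfit(x, y, 1))
    elif family == "quadratic":
        params = tuple(np.polyfit(x, y, 2))
    else:
        fn = _FUNCS[family]
        rng = np.random.default_rng(seed)
        p0 = _initial_guess(x, y, family)
        params = None
        last_err = ""
        for attempt in range(_N_RESTARTS + 1):
            start = p0 if attempt == 0 else p0 * rng.normal(1.0, 0.3, size=p0.shape) + rng.normal(
                0.0, 0.1, size=p0.shape
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(fn, x, y, p0=start, maxfev=20_000)
                if np.all(np.isfinite(popt)) and np.all(np.isfinite(fn(x, *popt))):
                    params = tuple(popt)
                    break
            except (RuntimeError, ValueError, TypeError) as e:  # pragma: no cover - rare
                last_err = str(e)
        if params is None:
            return ModelFitResult(
                family, (), np.nan, np.nan, np.nan, np.nan, success=False,
                message=f"non-convergence after {_N_RESTARTS} restarts: {last_err}",
            )
    yhat = _FUNCS[family](x, *params)
    r2, mape, rmse, mae = _metrics_tolerant(y, yhat)
    return ModelFitResult(family, tuple(float(p) for p in params), r2, mape, rmse, mae)


def compare_models(x, y, families=FAMILIES, seed: int | None = 0, cv_k: int | None = None) -> list[ModelFitResult]:
    """Fit several families and rank by R^2 (ties by lower RMSE).

    Failed fits rank last and stay flagged. With ``cv_k`` set, each
    successful fit also carries a k-fold CV summary.
    """
    families = tuple(families)
    if len(families) < 1:
        raise ValueError("at least one family required")
    results = []
    for i, fam in enumerate(families):
        try:
            res = fit_model(x, y, fam, seed=None if seed is None else seed + i)
        except ValueError:
            res = ModelFitResult(fam, (), np.nan, np.nan, np.nan, np.nan, success=False, message="domain error")
        if res.success and cv_k:
            try:
                res.cv = cross_validate(x, y, fam, k=cv_k, seed=seed)
            except ValueError:
                res.cv = None
        results.append(res)
    if all(not r.success for r in results):
        raise RuntimeError("all model fits failed")

    def key(r: ModelFitResult):
        return (
            not r.success,
            not np.isfinite(r.r2),
            -(r.r2 if np.isfinite(r.r2) else -np.inf),
            r.rmse if np.isfinite(r.rmse) else np.inf,
        )

    return sorted(results, key=key)


def cross_validate(x, y, family: str, k: int = 5, seed: int | None = 0) -> CVSummary:
    """Seeded k-fold cross-validation of one family.

    Points are randomly partitioned into k near-equal folds (every
    point held out exactly once); the model is fit on the remaining
    folds and scored on the held-out one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    per_fold = []
    for i, hold in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[hold] = False
        res = fit_model(x[mask], y[mask], family, seed=None if seed is None else seed + 1 + i)
        if not res.success:
            per_fold.append({"r2": np.nan, "mape": np.nan, "rmse": np.nan, "mae": np.nan})
            continue
        r2, mape, rmse, mae = _metrics_tolerant(y[hold], res.predict(x[hold]))
        per_fold.append({"r2": r2, "mape": mape, "rmse": rmse, "mae": mae})
    keys = ("r2", "mape", "rmse", "mae")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mean = {kk: float(np.nanmean([f[kk] for f in per_fold])) for kk in keys}
        sd = {kk: float(np.nanstd([f[kk] for f in per_fold], ddof=1)) for kk in keys}
    return CVSummary(k=k, per_fold=per_fold, mean=mean, sd=sd)
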