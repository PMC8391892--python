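"""PLSR and PCR calibration with leave-one-out cross-validation.

Both methods regress a concentration vector y (% v/v, 0-100) on a
spectral matrix X (samples x points) through a k-dimensional latent
basis of the mean-centered data:

* PLSR (PLS1, NIPALS): factor a extracts the unit weight vector
  ``w_a ~ X^T y`` (maximal covariance with y), scores ``t_a = X w_a``,
  X-loading ``p_a = X^T t_a / t_a^T t_a`` and y-loading
  ``q_a = y^T t_a / t_a^T t_a``; X and y are deflated by the rank-one
  score contribution before the next factor.  For a univariate y the
  weight extraction is closed-form, no inner iteration is needed.
  Coefficients: ``b = W (P^T W)^-1 q``.
* PCR: SVD of centered X; y is regressed on the first k principal
  scores (columns ordered by decreasing singular value, sign fixed so
  the largest-magnitude loading element is positive).

Model quality follows the standard cross-validation metric set:
``PRESS = sum (yhat_i - y_i)^2`` over the leave-one-out predictions,
``SECV = sqrt(PRESS / n)``, ``bias = |mean residual|``, R^2 the squared
Pearson correlation of actual and predicted, and the calibration line
``yhat = slope * y + intercept`` fitted by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import FoldError

__all__ = [
    "CalibrationSet",
    "RegressionModel",
    "CrossValidationResult",
    "fit_plsr",
    "fit_pcr",
    "predict",
    "cv_metrics",
    "secv_from_press",
    "loo_cross_validate",
    "select_factors",
]


@dataclass
class CalibrationSet:
    """Preprocessed spectra (X) with reference concentrations (y, % v/v)."""

    X: np.ndarray
    y: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D samples x points matrix")
        n = self.X.shape[0]
        if self.y.shape != (n,):
            raise ValueError("y must align with the rows of X")
        if n < 3:
            raise ValueError("need at least 3 calibration samples")
        if np.unique(self.y).size < 2:
            raise ValueError("y must span at least 2 distinct values")
        if not self.sample_ids:
            self.sample_ids = [f"sample{i}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise ValueError("sample_ids must align with the rows of X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class RegressionModel:
    """Fitted PLSR or PCR artifact mapping centered spectra to centered y."""

    method: str
    k: int
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray
    basis: dict = field(default_factory=dict)


@dataclass
class CrossValidationResult:
    """Leave-one-out predictions plus the cross-validation metric set."""

    y_actual: np.ndarray
    y_predicted: np.ndarray
    press: float
    secv: float
    bias: float
    r2: float
    slope: float
    intercept: float
    k: int
    n: int


def _check_k(n: int, p: int, k: int, max_n_minus: int = 1) -> None:
    kmax = min(n - max_n_minus, p)
    if not 1 <= k <= kmax:
        raise ValueError(f"k={k} outside valid range 1..{kmax} for n={n}, p={p}")


def fit_plsr(X: np.ndarray, y: np.ndarray, k: int) -> RegressionModel:
    """NIPALS PLS1 on mean-centered data.

    Extraction stops early if the residual covariance vanishes (data rank
    exhausted); remaining factors then contribute nothing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    _check_k(n, p, k)
    if np.unique(y).size < 2:
        raise ValueError("y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    scale = max(np.linalg.norm(Xc) * np.linalg.norm(yc), 1.0)

    W = np.zeros((p, k))
    P = np.zeros((p, k))
    Q = np.zeros(k)
    extracted = 0
    for a in range(k):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-13 * scale:
            break  # rank exhausted
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 0.0:
            break
        pl = Xc.T @ t / tt
        q = float(yc @ t) / tt
        Xc -= np.outer(t, pl)
        yc = yc - q * t
        W[:, a], P[:, a], Q[a] = w, pl, q
        extracted += 1

    if extracted == 0:
        coef = np.zeros(p)
    else:
        Wk, Pk, Qk = W[:, :extracted], P[:, :extracted], Q[:extracted]
        coef = Wk @ np.linalg.solve(Pk.T @ Wk, Qk)
    return RegressionModel(
        method="PLSR",
        k=k,
        x_mean=x_mean,
        y_mean=y_mean,
        coefficients=coef,
        basis={"weights": W[:, :extracted], "loadings": P[:, :extracted],
               "y_loadings": Q[:extracted], "extracted": extracted},
    )


def fit_pcr(X: np.ndarray, y: np.ndarray, k: int) -> RegressionModel:
    """Principal component regression on the first k centered-X components."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    _check_k(n, p, k)
    if np.unique(y).size < 2:
        raise ValueError("y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| element of each component positive
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    gamma = np.zeros(k)
    tol = 1e-12 * (s[0] if s.size else 0.0)
    used = 0
    for j in range(min(k, s.size)):
        if s[j] <= tol:
            break
        t = U[:, j] * s[j]
        gamma[j] = float(t @ yc) / (s[j] ** 2)
        used += 1
    coef = Vt[:used].T @ gamma[:used] if used else np.zeros(p)
    return RegressionModel(
        method="PCR",
        k=k,
        x_mean=x_mean,
        y_mean=y_mean,
        coefficients=coef,
        basis={"loadings": Vt[:used].T, "singular_values": s[:used],
               "extracted": used},
    )


def predict(model: RegressionModel, X_new: np.ndarray) -> np.ndarray:
    """``yhat = y_mean + (X_new - x_mean) b``; no clipping to [0, 100]."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.coefficients.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects "
            f"{model.coefficients.size}"
        )
    return model.y_mean + (X_new - model.x_mean) @ model.coefficients


def secv_from_press(press: float, n: int) -> float:
    """Standard error of cross-validation, SECV = sqrt(PRESS / n)."""
    if press < 0 or n <= 0:
        raise ValueError("press must be >= 0 and n > 0")
    return float(np.sqrt(press / n))


def cv_metrics(
    y_actual: np.ndarray, y_predicted: np.ndarray, k: int = 0
) -> CrossValidationResult:
    """Assemble the metric set from actual and (cross-validated) predictions."""
    y = np.asarray(y_actual, dtype=float)
    yhat = np.asarray(y_predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y_actual and y_predicted must be equal-length vectors")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples for cross-validation metrics")
    residuals = yhat - y
    press = float(residuals @ residuals)
    secv = secv_from_press(press, n)
    bias = float(abs(residuals.mean()))
    if np.std(y) == 0.0 or np.std(yhat) == 0.0:
        raise ValueError("r2 undefined: zero variance in actual or predicted values")
    r = float(np.corrcoef(y, yhat)[0, 1])
    slope, intercept = np.polyfit(y, yhat, 1)
    return CrossValidationResult(
        y_actual=y,
        y_predicted=yhat,
        press=press,
        secv=secv,
        bias=bias,
        r2=r * r,
        slope=float(slope),
        intercept=float(intercept),
        k=int(k),
        n=n,
    )


_FITTERS = {"PLSR": fit_plsr, "PCR": fit_pcr}


def loo_cross_validate(
    calset: CalibrationSet, method: str, k: int
) -> CrossValidationResult:
    """Leave-one-out CV: refit (including re-centering) within each fold."""
    method = method.upper()
    if method not in _FITTERS:
        raise ValueError(f"method must be one of {sorted(_FITTERS)}, got {method!r}")
    _check_k(calset.n, calset.p, k, max_n_minus=2)
    fit = _FITTERS[method]
    predictions = np.empty(calset.n)
    for i in range(calset.n):
        mask = np.ones(calset.n, dtype=bool)
        mask[i] = False
        y_train = calset.y[mask]
        if np.unique(y_train).size < 2:
            raise FoldError(
                f"fold leaving out {calset.sample_ids[i]!r} has zero y variance"
            )
        model = fit(calset.X[mask], y_train, k)
        predictions[i] = predict(model, calset.X[i:i + 1])[0]
    return cv_metrics(calset.y, predictions, k=k)


def select_factors(calset: CalibrationSet, method: str, k_max: int) -> int:
    """Smallest k minimizing leave-one-out PRESS (ties go to smaller k)."""
    _check_k(calset.n, calset.p, k_max, max_n_minus=2)
    best_k, best_press = 1, np.inf
    for k in range(1, k_max + 1):
        press = loo_cross_validate(calset, method, k).press
        if press < best_press:
            best_k, best_press = k, press
    return best_k
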