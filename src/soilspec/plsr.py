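"""PLS1 regression with cross-validated component selection and the
R^2 / RMSE / RPD evaluation used in soil chemometrics.

The fit itself is the standard single-response partial least squares solution
on mean-centered data (delegated to scikit-learn's ``PLSRegression`` with
scaling off); coefficients are stored back in original predictor units so a
model is just ``y_hat = X @ coef + intercept``.

Evaluation conventions:

* RCV^2 / RMSEC — leave-one-out cross-validation on the calibration set,
* RP^2 / RMSEP — prediction on the held-out validation set, R^2 = 1 - SSE/SST,
* RPD — SD of observed concentrations divided by RMSEP; by default the
  calibration-set SD (configurable to the validation SD).  RPD < 1.4 is a
  poor model, 1.4-2.0 average, > 2.0 good; boundary values fall to the lower
  class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

__all__ = ["PLSRModel", "EvaluationReport", "fit_plsr", "predict",
           "select_components", "loo_predictions", "evaluate", "classify_rpd"]


@dataclass
class PLSRModel:
    n_components: int
    coefficients: np.ndarray
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    training_ids: list | None = None


@dataclass
class EvaluationReport:
    rcv2: float
    rmsec: float
    rp2: float
    rmsep: float
    rpd: float
    rpd_class: str
    n_components: int = 0


def _validate_xy(X, y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("undefined (NaN/inf) entries are not allowed in the fit")
    return X, y


def fit_plsr(X, y, n_components: int, ids=None) -> PLSRModel:
    """Fit a PLS1 model with the given number of latent components."""
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if not 1 <= n_components <= min(p, n - 1):
        raise ValueError(
            f"n_components must lie in [1, min(n_features, n_samples-1)] = "
            f"[1, {min(p, n - 1)}]"
        )
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all predictors are constant (rank 0)")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    coef = np.ravel(np.asarray(pls.coef_))
    if coef.size != p:  # older/newer sklearn transpose conventions
        coef = np.ravel(np.asarray(pls.coef_).T)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    intercept = y_mean - float(x_mean @ coef)
    return PLSRModel(
        n_components=int(n_components),
        coefficients=coef,
        intercept=intercept,
        x_mean=x_mean,
        y_mean=y_mean,
        training_ids=list(ids) if ids is not None else None,
    )


def predict(model: PLSRModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.empty(0)
    X = np.atleast_2d(X)
    if X.shape[1] != model.coefficients.size:
        raise ValueError(
            f"feature-count mismatch: model expects {model.coefficients.size}, got {X.shape[1]}"
        )
    return X @ model.coefficients + model.intercept


def loo_predictions(X, y, n_components: int) -> np.ndarray:
    """Leave-one-out predictions, refitting the PLS model per fold."""
    X, y = _validate_xy(X, y)
    n = X.shape[0]
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        c = min(n_components, min(X.shape[1], n - 2))
        m = fit_plsr(X[mask], y[mask], c)
        out[i] = predict(m, X[[i]])[0]
    return out


def select_components(X, y, max_components: int, folds: str = "loo") -> int:
    """Component count minimizing cross-validated RMSE (ties -> fewer)."""
    X, y = _validate_xy(X, y)
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    if folds != "loo":
        raise ValueError("only leave-one-out selection is implemented")
    cap = min(max_components, X.shape[1], X.shape[0] - 1)
    best_c, best_rmse = 1, np.inf
    for c in range(1, cap + 1):
        pred = loo_predictions(X, y, c)
        rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        if rmse < best_rmse - 1e-12:
            best_c, best_rmse = c, rmse
    return best_c


def classify_rpd(rpd: float) -> str:
    """Reliability class of an RPD value (boundaries fall to the lower class)."""
    if not np.isfinite(rpd) or rpd <= 0:
        raise ValueError("RPD must be a positive finite number")
    if rpd <= 1.4:
        return "poor"
    if rpd <= 2.0:
        return "average"
    return "good"


def evaluate(model: PLSRModel, Xc, yc, Xv, yv,
             rpd_denominator: str = "calibration_sd") -> EvaluationReport:
    """Calibration (LOO) and validation metrics for one fitted model.

    RMSEP = 0 (perfect validation predictions) yields RPD = NaN with the
    class flagged ``perfect``.
    """
    Xc, yc = _validate_xy(Xc, yc)
    Xv, yv = _validate_xy(Xv, yv)
    if rpd_denominator not in ("calibration_sd", "validation_sd"):
        raise ValueError(f"unknown rpd_denominator {rpd_denominator!r}")

    cv_pred = loo_predictions(Xc, yc, model.n_components)
    rmsec = float(np.sqrt(np.mean((cv_pred - yc) ** 2)))
    rcv2 = 1.0 - float(np.sum((cv_pred - yc) ** 2) / np.sum((yc - yc.mean()) ** 2))

    pv = predict(model, Xv)
    rmsep = float(np.sqrt(np.mean((pv - yv) ** 2)))
    rp2 = 1.0 - float(np.sum((pv - yv) ** 2) / np.sum((yv - yv.mean()) ** 2))

    sd = float(yc.std(ddof=1) if rpd_denominator == "calibration_sd" else yv.std(ddof=1))
    if rmsep == 0:
        rpd, rpd_class = float("nan"), "perfect"
    else:
        rpd = sd / rmsep
        rpd_class = classify_rpd(rpd)
    return EvaluationReport(
        rcv2=rcv2,
        rmsec=rmsec,
        rp2=rp2,
        rmsep=rmsep,
        rpd=rpd,
        rpd_class=rpd_class,
        n_components=model.n_components,
    )
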