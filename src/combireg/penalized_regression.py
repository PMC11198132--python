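"""Elastic-net logistic and linear regression with cross-validated lambda.

The regularisation path runs from lambda_max (empty model) down to
``ratio * lambda_max`` on a log scale; coefficients along the path are
obtained by warm-started coordinate descent (see :mod:`combireg._descent`
for the exact objective scaling). Lambda is selected by k-fold
cross-validation, minimising the pooled held-out logistic deviance
(binomial) or mean squared error (gaussian), with ties broken toward the
larger, more regularised lambda.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from combireg import _descent
from combireg.data_model import StandardisationState

FAMILIES = ("binomial", "gaussian")

#: path-solver stopping rule (per lambda): relative objective change below this
CD_TOL = 1e-7
#: tighter tolerance for single-lambda fits, which are compared to
#: closed-form oracles in the tests
FIT_TOL = 1e-12
#: maximum coordinate-descent passes per lambda
CD_MAX_PASSES = 100_000

#: guard so the fit at lambda_max is empty despite floating-point roundoff
_LAMBDA_MAX_INFLATION = 1e-10
#: effective alpha used for the closed-form lambda_max when alpha == 0
_RIDGE_ALPHA_FLOOR = 1e-3


@dataclass
class RegularisedFit:
    """One penalised GLM fit: path, CV losses, selected lambda, coefficients.

    ``cv_loss`` holds the mean-per-sample cross-validated loss (logistic
    deviance for binomial, MSE for gaussian) at each path value.
    ``oof_predictions`` are the held-out predictions at ``lambda_selected``
    (probabilities for binomial, values for gaussian). Deserialised models
    carry only the coefficient fields; path/CV fields may then be ``None``.
    """

    family: str
    alpha: float
    intercept: float
    slopes: np.ndarray
    lambda_selected: float
    lambda_sequence: Optional[np.ndarray] = None
    cv_loss: Optional[np.ndarray] = None
    oof_predictions: Optional[np.ndarray] = None
    fold_assignment: Optional[np.ndarray] = None

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.slopes))

    def linear_predictor(self, Xstd: np.ndarray) -> np.ndarray:
        return self.intercept + Xstd @ self.slopes


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")


def _check_binomial_target(target: np.ndarray) -> None:
    if not np.isin(target, (0, 1)).all():
        raise ValueError("binomial target must contain only 0 and 1")
    if target.min() == target.max():
        raise ValueError("binomial target is single-class")


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def lambda_path(
    Xstd: np.ndarray,
    target: np.ndarray,
    family: str,
    alpha: float,
    n_lambda: int = 100,
    min_ratio: Optional[float] = None,
) -> np.ndarray:
    """Decreasing log-spaced lambda sequence from the empty to the full model.

    ``lambda_max`` is the smallest penalty at which every slope is zero:
    ``max_j |<x_j, t - tbar>| / (n * alpha)``, with ``alpha`` floored at
    0.001 so the ridge path stays finite. ``min_ratio`` defaults to 0.01
    when p > n and 0.0001 otherwise.
    """
    _check_family(family)
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    Xstd = np.asarray(Xstd, dtype=float)
    target = np.asarray(target, dtype=float)
    if not (np.all(np.isfinite(Xstd)) and np.all(np.isfinite(target))):
        raise ValueError("non-finite values in fitting data")
    n, p = Xstd.shape
    if family == "binomial":
        _check_binomial_target(target)
    centred = target - target.mean()
    lam_max = np.max(np.abs(Xstd.T @ centred)) / (n * max(alpha, _RIDGE_ALPHA_FLOOR))
    lam_max *= 1.0 + _LAMBDA_MAX_INFLATION
    if lam_max <= 0.0:
        lam_max = 1.0  # degenerate target; arbitrary positive scale
    if min_ratio is None:
        min_ratio = 0.01 if p > n else 1e-4
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


def _solve_path(
    Xstd: np.ndarray,
    target: np.ndarray,
    family: str,
    alpha: float,
    lambdas: np.ndarray,
    tol: float = CD_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    Xstd = np.ascontiguousarray(Xstd, dtype=float)
    target = np.ascontiguousarray(target, dtype=float)
    if not (np.all(np.isfinite(Xstd)) and np.all(np.isfinite(target))):
        raise ValueError("non-finite values in fitting data")
    lambdas = np.ascontiguousarray(lambdas, dtype=float)
    if family == "binomial":
        _check_binomial_target(target)
        return _descent.binomial_path(Xstd, target, lambdas, alpha, tol, CD_MAX_PASSES)
    return _descent.gaussian_path(Xstd, target, lambdas, alpha, tol, CD_MAX_PASSES)


def fit_penalised(
    Xstd: np.ndarray,
    target: np.ndarray,
    family: str,
    alpha: float,
    lam: float,
    warm_path: bool = True,
) -> tuple[float, np.ndarray]:
    """Minimise the penalised loss at a single lambda.

    With ``warm_path`` the solver descends a short path from the empty model
    down to ``lam``, which speeds up and stabilises small-lambda solutions.
    """
    _check_family(family)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    Xstd = np.asarray(Xstd, dtype=float)
    target = np.asarray(target, dtype=float)
    if warm_path:
        start = lambda_path(Xstd, target, family, alpha, n_lambda=3)[0]
        if lam >= start:
            lambdas = np.array([lam])
        else:
            lambdas = np.append(np.geomspace(start, max(lam, 1e-12), 8)[:-1], lam)
    else:
        lambdas = np.array([lam])
    intercepts, coefs = _solve_path(Xstd, target, family, alpha, lambdas, tol=FIT_TOL)
    return float(intercepts[-1]), coefs[-1].copy()


def make_stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Assign samples to k folds, balanced within each label value."""
    labels = np.asarray(labels)
    n = labels.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError("more folds than samples")
    assignment = np.empty(n, dtype=np.int64)
    offset = 0
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        idx = rng.permutation(idx)
        folds = (np.arange(idx.shape[0]) + offset) % k
        assignment[idx] = folds
        offset += idx.shape[0]
    return assignment


def _pooled_cv_loss(
    preds: np.ndarray, target: np.ndarray, family: str, clip: float = 1e-5
) -> np.ndarray:
    """Mean held-out loss per lambda, pooled over all folds."""
    if family == "binomial":
        p = np.clip(preds, clip, 1.0 - clip)
        ll = target[:, None] * np.log(p) + (1.0 - target[:, None]) * np.log(1.0 - p)
        return -2.0 * ll.mean(axis=0)
    return ((preds - target[:, None]) ** 2).mean(axis=0)


def cross_validate_lambda(
    Xstd: np.ndarray,
    target: np.ndarray,
    family: str,
    alpha: float,
    fold_assignment: np.ndarray,
    n_lambda: int = 100,
) -> RegularisedFit:
    """Select lambda by k-fold CV and refit on all samples.

    The lambda sequence is built once from the full data and shared across
    folds. For each lambda, held-out predictions from all folds are pooled
    into one loss estimate; the selected lambda is the largest one attaining
    the minimum. Final coefficients come from a warm-started refit on all
    samples at the selected lambda.
    """
    _check_family(family)
    Xstd = np.asarray(Xstd, dtype=float)
    target = np.asarray(target, dtype=float)
    fold_assignment = np.asarray(fold_assignment, dtype=np.int64)
    n = Xstd.shape[0]
    if fold_assignment.shape[0] != n:
        raise ValueError("fold_assignment must cover all samples")
    folds = np.unique(fold_assignment)
    if folds.shape[0] < 2:
        raise ValueError("need at least 2 folds")
    lambdas = lambda_path(Xstd, target, family, alpha, n_lambda=n_lambda)
    preds = np.empty((n, lambdas.shape[0]))
    for f in folds:
        test = fold_assignment == f
        train = ~test
        if family == "binomial" and target[train].min() == target[train].max():
            raise ValueError(f"training folds excluding fold {f} are single-class")
        intercepts, coefs = _solve_path(Xstd[train], target[train], family, alpha, lambdas)
        eta = intercepts[None, :] + Xstd[test] @ coefs.T
        preds[test] = _sigmoid(eta) if family == "binomial" else eta
    cv_loss = _pooled_cv_loss(preds, target, family)
    best = int(np.argmin(cv_loss))  # first minimum = largest lambda (ties)
    intercepts, coefs = _solve_path(Xstd, target, family, alpha, lambdas[: best + 1])
    return RegularisedFit(
        family=family,
        alpha=alpha,
        intercept=float(intercepts[best]),
        slopes=coefs[best].copy(),
        lambda_selected=float(lambdas[best]),
        lambda_sequence=lambdas,
        cv_loss=cv_loss,
        oof_predictions=preds[:, best].copy(),
        fold_assignment=fold_assignment,
    )


def predict_glm(
    fit: RegularisedFit, Xnew: np.ndarray, state: Optional[StandardisationState] = None
) -> np.ndarray:
    """Predicted probabilities (binomial) or values (gaussian) for new data.

    ``Xnew`` is on the original feature scale when ``state`` is given, and
    already standardised otherwise.
    """
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim == 1:
        Xnew = Xnew[None, :]
    Xstd = state.transform(Xnew) if state is not None else Xnew
    if Xstd.shape[1] != fit.slopes.shape[0]:
        raise ValueError(
            f"expected {fit.slopes.shape[0]} columns after preprocessing, "
            f"got {Xstd.shape[1]}"
        )
    eta = fit.linear_predictor(Xstd)
    return _sigmoid(eta) if fit.family == "binomial" else eta


def original_scale_coefficients(
    fit: RegularisedFit, state: StandardisationState
) -> tuple[float, np.ndarray]:
    """Back-transform standardised-scale coefficients to the original scale.

    Dropped (constant) columns get a zero slope; their contribution is part
    of the intercept.
    """
    keep = state.retained_columns
    slopes = np.zeros(state.n_features_in)
    slopes[keep] = fit.slopes / state.sds[keep]
    intercept = fit.intercept - float(np.dot(slopes[keep], state.means[keep]))
    return intercept, slopes


def coefficient_table(
    fit: RegularisedFit,
    state: StandardisationState,
    feature_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-feature coefficients on the standardised and original scales."""
    p = state.n_features_in
    if feature_names is None:
        feature_names = [f"x{j + 1}" for j in range(p)]
    std_slopes = np.zeros(p)
    std_slopes[state.retained_columns] = fit.slopes
    _, orig_slopes = original_scale_coefficients(fit, state)
    return pd.DataFrame(
        {
            "feature": list(feature_names),
            "coefficient_standardised": std_slopes,
            "coefficient_original": orig_slopes,
        }
    )
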