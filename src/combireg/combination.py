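"""Calibrate linear predictions through a Gaussian CDF and blend them with
logistic probabilities.

The combined probability for sample i is

    p_i = (1 - pi) * zhat_i + pi * Phi(yhat_i | mu=c, sigma2),

where zhat comes from penalised logistic regression on the binary outcome,
yhat from penalised linear regression on the numeric outcome, and Phi is
the Gaussian CDF centred at the dichotomisation threshold c. The weight pi
and variance sigma2 are tuned by minimising the combined logistic deviance
over a (pi, sigma) grid, evaluated on out-of-fold predictions so the tuning
is not biased by in-sample overfit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from combireg._version import __version__
from combireg.data_model import LabelledDataset, StandardisationState, standardise
from combireg.penalized_regression import (
    RegularisedFit,
    cross_validate_lambda,
    make_stratified_folds,
    predict_glm,
)

#: default clipping applied to probabilities before logarithms
CLIP_EPSILON = 1e-5

#: keep CDF output strictly inside (0, 1) without affecting deviances,
#: which clip harder anyway
_CDF_EPS = 1e-16

DEFAULT_PI_STEP = 0.02
DEFAULT_SIGMA_POINTS = 20
DEFAULT_SIGMA_SPAN = (0.05, 5.0)  # multiples of sd(y)


def calibrate(yhat: np.ndarray, c: float, sigma2: float) -> np.ndarray:
    """Map predicted values to probabilities via the Gaussian CDF.

    Returns P(Y > c)-style probabilities: 0.5 exactly at ``yhat == c``,
    monotone increasing in ``yhat``, diverging to 0/1 as ``sigma2`` shrinks
    and converging to 0.5 as it grows.
    """
    if not (np.isfinite(sigma2) and sigma2 > 0):
        raise ValueError("sigma2 must be a positive finite number")
    yhat = np.asarray(yhat, dtype=float)
    out = norm.cdf((yhat - c) / np.sqrt(sigma2))
    return np.clip(out, _CDF_EPS, 1.0 - _CDF_EPS)


def combine(zhat: np.ndarray, yhat_calibrated: np.ndarray, pi: float) -> np.ndarray:
    """Convex combination of logistic and calibrated-linear probabilities."""
    zhat = np.asarray(zhat, dtype=float)
    yhat_calibrated = np.asarray(yhat_calibrated, dtype=float)
    if zhat.shape != yhat_calibrated.shape:
        raise ValueError("probability vectors must have the same length")
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    if zhat.size and (zhat.min() < 0.0 or zhat.max() > 1.0):
        raise ValueError("zhat must contain probabilities in [0, 1]")
    return (1.0 - pi) * zhat + pi * yhat_calibrated


def combined_deviance(
    z: np.ndarray,
    phat: np.ndarray,
    clip_epsilon: float = CLIP_EPSILON,
    mean: bool = False,
) -> float:
    """Logistic deviance of combined probabilities against observed classes.

    ``mean=False`` gives the -2*sum form, ``mean=True`` the per-sample mean
    (the two differ by a factor n). Probabilities are clipped into
    ``[clip_epsilon, 1 - clip_epsilon]`` before taking logarithms.
    """
    z = np.asarray(z, dtype=float)
    p = np.clip(np.asarray(phat, dtype=float), clip_epsilon, 1.0 - clip_epsilon)
    ll = z * np.log(p) + (1.0 - z) * np.log(1.0 - p)
    return float(-2.0 * (ll.mean() if mean else ll.sum()))


@dataclass
class CombinationParams:
    """Weight pi, calibration variance sigma2, and the threshold c."""

    pi: float
    sigma2: float
    c: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")


@dataclass
class LossSurface:
    """Combined deviance over the (pi, sigma) tuning grid."""

    pi_grid: np.ndarray
    sigma_grid: np.ndarray  # standard deviations
    loss: np.ndarray  # shape (len(pi_grid), len(sigma_grid)), -2*sum form
    argmin: tuple[float, float]  # (pi, sigma)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loss,
            index=pd.Index(self.pi_grid, name="pi"),
            columns=pd.Index(self.sigma_grid, name="sigma"),
        )


def default_pi_grid() -> np.ndarray:
    n = int(round(1.0 / DEFAULT_PI_STEP)) + 1
    return np.linspace(0.0, 1.0, n)


def default_sigma_grid(y_scale: float) -> np.ndarray:
    """Log-spaced standard deviations spanning 0.05 to 5 times ``y_scale``."""
    if not (np.isfinite(y_scale) and y_scale > 0):
        y_scale = 1.0
    lo, hi = DEFAULT_SIGMA_SPAN
    return np.geomspace(lo * y_scale, hi * y_scale, DEFAULT_SIGMA_POINTS)


def estimate_pi_sigma(
    z: np.ndarray,
    zhat_oof: np.ndarray,
    yhat_oof: np.ndarray,
    c: float,
    pi_grid: Optional[np.ndarray] = None,
    sigma_grid: Optional[np.ndarray] = None,
    clip_epsilon: float = CLIP_EPSILON,
) -> tuple[CombinationParams, LossSurface]:
    """Grid-minimise the combined deviance over (pi, sigma).

    Inputs should be out-of-fold predictions. The default grid contains both
    endpoints pi=0 and pi=1, so the achieved loss never exceeds the
    logistic-only loss nor the best calibrated-linear-only loss on the
    tuning vectors. Ties are broken toward smaller pi, then larger sigma.
    """
    z = np.asarray(z, dtype=float)
    if z.min() == z.max():
        raise ValueError("single-class z: cannot tune the combination")
    zhat_oof = np.asarray(zhat_oof, dtype=float)
    yhat_oof = np.asarray(yhat_oof, dtype=float)
    if pi_grid is None:
        pi_grid = default_pi_grid()
    pi_grid = np.asarray(pi_grid, dtype=float)
    if sigma_grid is None:
        sigma_grid = default_sigma_grid(float(np.std(yhat_oof, ddof=1)))
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if np.any(sigma_grid <= 0):
        raise ValueError("sigma_grid must be positive")

    # (n, S) calibrated probabilities, one column per sigma
    phi = norm.cdf((yhat_oof[:, None] - c) / sigma_grid[None, :])
    loss = np.empty((pi_grid.shape[0], sigma_grid.shape[0]))
    for a, pi in enumerate(pi_grid):
        p = np.clip(
            (1.0 - pi) * zhat_oof[:, None] + pi * phi,
            clip_epsilon,
            1.0 - clip_epsilon,
        )
        ll = z[:, None] * np.log(p) + (1.0 - z[:, None]) * np.log(1.0 - p)
        loss[a] = -2.0 * ll.sum(axis=0)

    best = loss.min()
    rows, cols = np.nonzero(loss == best)
    a = rows.min()  # smallest pi
    s = cols[rows == a].max()  # then largest sigma
    params = CombinationParams(
        pi=float(pi_grid[a]), sigma2=float(sigma_grid[s] ** 2), c=float(c)
    )
    surface = LossSurface(
        pi_grid=pi_grid,
        sigma_grid=sigma_grid,
        loss=loss,
        argmin=(float(pi_grid[a]), float(sigma_grid[s])),
    )
    return params, surface


@dataclass
class CombinedModel:
    """The deployable predictor: two penalised fits plus combination state.

    ``direction`` controls which side of the threshold is the positive
    class; with ``direction="le"`` the calibration CDF is mirrored so that
    larger predicted values imply smaller class-1 probabilities.
    """

    logistic_fit: RegularisedFit
    linear_fit: RegularisedFit
    params: CombinationParams
    standardisation: StandardisationState
    clip_epsilon: float = CLIP_EPSILON
    direction: str = "gt"
    feature_names: Optional[Sequence[str]] = None
    version: str = field(default=__version__)

    def _oriented(self, yhat: np.ndarray) -> np.ndarray:
        """Mirror predicted values for le-direction thresholds."""
        if self.direction == "le":
            return 2.0 * self.params.c - yhat
        return yhat

    def predict_parts(self, Xnew: np.ndarray) -> pd.DataFrame:
        """All intermediate quantities: zhat, yhat, Phi(yhat), phat."""
        Xnew = np.asarray(Xnew, dtype=float)
        if Xnew.ndim == 1:
            Xnew = Xnew[None, :]
        zhat = predict_glm(self.logistic_fit, Xnew, self.standardisation)
        yhat = predict_glm(self.linear_fit, Xnew, self.standardisation)
        phi = calibrate(self._oriented(yhat), self.params.c, self.params.sigma2)
        phat = np.clip(
            combine(zhat, phi, self.params.pi),
            self.clip_epsilon,
            1.0 - self.clip_epsilon,
        )
        return pd.DataFrame({"zhat": zhat, "yhat": yhat, "phi": phi, "phat": phat})

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        """Combined predicted probabilities, clipped into [eps, 1 - eps]."""
        return self.predict_parts(Xnew)["phat"].to_numpy()

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        def sparse(fit: RegularisedFit) -> dict:
            names = self._slope_names()
            return {names[j]: fit.slopes[j] for j in np.flatnonzero(fit.slopes)}

        state = self.standardisation
        return {
            "format": "combireg-model",
            "version": self.version,
            "direction": self.direction,
            "clip_epsilon": self.clip_epsilon,
            "pi": self.params.pi,
            "sigma2": self.params.sigma2,
            "c": self.params.c,
            "alpha": self.logistic_fit.alpha,
            "logistic": {
                "intercept": self.logistic_fit.intercept,
                "lambda": self.logistic_fit.lambda_selected,
                "slopes": sparse(self.logistic_fit),
            },
            "linear": {
                "intercept": self.linear_fit.intercept,
                "lambda": self.linear_fit.lambda_selected,
                "slopes": sparse(self.linear_fit),
            },
            "standardisation": {
                "feature_names": self._feature_names(),
                "means": state.means.tolist(),
                "sds": state.sds.tolist(),
                "dropped_columns": state.dropped_columns.tolist(),
            },
        }

    def _feature_names(self) -> list[str]:
        if self.feature_names is not None:
            return list(self.feature_names)
        return [f"x{j + 1}" for j in range(self.standardisation.n_features_in)]

    def _slope_names(self) -> list[str]:
        names = self._feature_names()
        return [names[j] for j in self.standardisation.retained_columns]

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, doc: dict) -> "CombinedModel":
        state = StandardisationState(
            means=np.asarray(doc["standardisation"]["means"], dtype=float),
            sds=np.asarray(doc["standardisation"]["sds"], dtype=float),
            dropped_columns=np.asarray(
                doc["standardisation"]["dropped_columns"], dtype=np.int64
            ),
        )
        names = doc["standardisation"]["feature_names"]
        retained = [names[j] for j in state.retained_columns]
        index = {name: j for j, name in enumerate(retained)}

        def dense(branch: dict) -> np.ndarray:
            slopes = np.zeros(len(retained))
            for name, value in branch["slopes"].items():
                slopes[index[name]] = value
            return slopes

        alpha = doc["alpha"]

        def fit(branch: dict, family: str) -> RegularisedFit:
            return RegularisedFit(
                family=family,
                alpha=alpha,
                intercept=float(branch["intercept"]),
                slopes=dense(branch),
                lambda_selected=float(branch["lambda"]),
            )

        return cls(
            logistic_fit=fit(doc["logistic"], "binomial"),
            linear_fit=fit(doc["linear"], "gaussian"),
            params=CombinationParams(
                pi=float(doc["pi"]), sigma2=float(doc["sigma2"]), c=float(doc["c"])
            ),
            standardisation=state,
            clip_epsilon=float(doc["clip_epsilon"]),
            direction=doc["direction"],
            feature_names=names,
            version=doc["version"],
        )

    @classmethod
    def load(cls, path: str) -> "CombinedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def predict_combined(model: CombinedModel, Xnew: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`CombinedModel.predict`."""
    return model.predict(Xnew)


def _cv_stage(
    dataset: LabelledDataset,
    alpha: float,
    k: int,
    seed: int,
    n_lambda: int = 100,
) -> tuple[StandardisationState, RegularisedFit, RegularisedFit]:
    """Shared first stage: standardise, build folds, run both CV fits.

    The same stratified fold assignment is used for the logistic and the
    linear fit so their out-of-fold predictions are comparable.
    """
    dataset.require_both_classes()
    if dataset.n < 2 * k:
        raise ValueError("need at least 2*k samples for k-fold tuning")
    Xstd, state = standardise(dataset.X)
    rng = np.random.default_rng(seed)
    folds = make_stratified_folds(dataset.z, k, rng)
    logistic_fit = cross_validate_lambda(Xstd, dataset.z, "binomial", alpha, folds, n_lambda)
    linear_fit = cross_validate_lambda(Xstd, dataset.y, "gaussian", alpha, folds, n_lambda)
    return state, logistic_fit, linear_fit


def _combine_stage(
    dataset: LabelledDataset,
    state: StandardisationState,
    logistic_fit: RegularisedFit,
    linear_fit: RegularisedFit,
    pi: Optional[float],
    pi_grid: Optional[np.ndarray],
    sigma_grid: Optional[np.ndarray],
    clip_epsilon: float,
) -> tuple[CombinedModel, LossSurface]:
    if sigma_grid is None:
        sigma_grid = default_sigma_grid(float(np.std(dataset.y, ddof=1)))
    if pi is not None:
        pi_grid = np.array([float(pi)])
    yhat_oof = linear_fit.oof_predictions
    if dataset.direction == "le":
        yhat_oof = 2.0 * dataset.c - yhat_oof
    params, surface = estimate_pi_sigma(
        dataset.z,
        logistic_fit.oof_predictions,
        yhat_oof,
        dataset.c,
        pi_grid=pi_grid,
        sigma_grid=sigma_grid,
        clip_epsilon=clip_epsilon,
    )
    model = CombinedModel(
        logistic_fit=logistic_fit,
        linear_fit=linear_fit,
        params=params,
        standardisation=state,
        clip_epsilon=clip_epsilon,
        direction=dataset.direction,
        feature_names=dataset.feature_names,
    )
    return model, surface


def fit_combined(
    dataset: LabelledDataset,
    alpha: float = 1.0,
    k: int = 10,
    seed: int = 0,
    pi: Optional[float] = None,
    pi_grid: Optional[np.ndarray] = None,
    sigma_grid: Optional[np.ndarray] = None,
    clip_epsilon: float = CLIP_EPSILON,
    n_lambda: int = 100,
    return_surface: bool = False,
):
    """Two-stage fit: penalised GLMs first, then the combination weights.

    Stage one tunes lambda for the logistic fit (on z) and the linear fit
    (on y) with shared stratified folds; stage two tunes (pi, sigma2) by
    grid search on the out-of-fold predictions at the selected lambdas.
    Fixing ``pi=0`` or ``pi=1`` yields the logistic-only and
    calibrated-linear-only special cases. Deterministic given ``seed``.
    """
    state, logistic_fit, linear_fit = _cv_stage(dataset, alpha, k, seed, n_lambda)
    model, surface = _combine_stage(
        dataset, state, logistic_fit, linear_fit, pi, pi_grid, sigma_grid, clip_epsilon
    )
    return (model, surface) if return_surface else model


VARIANTS = ("logistic", "combined", "calibrated_linear")


def fit_variant_models(
    dataset: LabelledDataset,
    alpha: float = 1.0,
    k: int = 10,
    seed: int = 0,
    clip_epsilon: float = CLIP_EPSILON,
    n_lambda: int = 100,
) -> dict[str, CombinedModel]:
    """Fit all three comparators from one shared pair of CV fits.

    "logistic" fixes pi=0, "calibrated_linear" fixes pi=1 (sigma tuned on
    the same out-of-fold values), and "combined" tunes both parameters.
    """
    state, logistic_fit, linear_fit = _cv_stage(dataset, alpha, k, seed, n_lambda)
    out = {}
    for name, pi in (("logistic", 0.0), ("combined", None), ("calibrated_linear", 1.0)):
        out[name], _ = _combine_stage(
            dataset, state, logistic_fit, linear_fit, pi, None, None, clip_epsilon
        )
    return out


def combined_fitter(alpha: float = 1.0, pi: Optional[float] = None):
    """Factory returning a ``fitter(dataset, k, seed) -> CombinedModel``.

    Used by the evaluation protocols, which need interchangeable model
    constructors sharing a common call signature.
    """

    def fitter(dataset: LabelledDataset, k: int, seed: int) -> CombinedModel:
        return fit_combined(dataset, alpha=alpha, k=k, seed=seed, pi=pi)

    return fitter
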