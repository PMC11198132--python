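"""Synthetic data generators and the hold-out comparison study.

Features are standard Gaussian; effects come from a Bernoulli-Gaussian
mixture (a fraction ``sparsity`` of features carry standard-normal
effects); the numeric outcome is built from the linear predictor
eta = X beta and noise eps in one of four ways:

* ``standard``:       y = eta + eps
* ``latent_binary``:  y = -2 + eps if eta < 0 else +2 + eps
* ``asymmetric``:     y = -|eta + eps| if eta < 0 else (eta + eps)^2
* ``outliers``:       y = eta + eps, shifted by -1.5*max|eta| or
                      +1.5*max|eta| with probability 2.5% each

The threshold is 0 and z = I[y > 0] throughout. The hold-out study fits
logistic-only, calibrated-linear-only and combined regression on n0
training samples, measures mean out-of-sample deviance on n1 test samples,
and compares models with one-sided Wilcoxon signed-rank tests at a
Bonferroni-adjusted level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from combireg._stats import one_sided_wilcoxon_less
from combireg.combination import CLIP_EPSILON, VARIANTS, combined_deviance, fit_variant_models
from combireg.data_model import LabelledDataset

logger = logging.getLogger(__name__)

EXAMPLES = ("standard", "latent_binary", "asymmetric", "outliers")

_OUTLIER_RATE = 0.025  # each tail
_OUTLIER_SHIFT = 1.5  # multiples of the infinity norm of eta
_LATENT_OFFSET = 2.0


@dataclass
class SimulationSpec:
    """Configuration of one data-generating run."""

    example: str
    n0: int = 100
    n1: int = 10_000
    p: int = 500
    sparsity: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.example not in EXAMPLES:
            raise ValueError(
                f"unknown example {self.example!r}; valid names: {', '.join(EXAMPLES)}"
            )
        if self.n0 < 10 or self.n1 < 1 or self.p < 1:
            raise ValueError("need n0 >= 10, n1 >= 1, p >= 1")
        if not 0.0 < self.sparsity < 1.0:
            raise ValueError("sparsity must lie strictly between 0 and 1")


def simulate_effects(p: int, sparsity: float, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli-Gaussian effects: zero w.p. 1 - sparsity, else N(0, 1)."""
    if p < 1:
        raise ValueError("p must be positive")
    if not 0.0 < sparsity < 1.0:
        raise ValueError("sparsity must lie strictly between 0 and 1")
    active = rng.binomial(1, sparsity, size=p)
    return active * rng.standard_normal(p)


@dataclass
class SimulatedData:
    """Train/test split plus the true effects; iterates as a 3-tuple."""

    train: LabelledDataset
    test: LabelledDataset
    beta: np.ndarray
    n_outliers: int = 0

    def __iter__(self):
        return iter((self.train, self.test, self.beta))


def _outcomes(
    example: str, eta: np.ndarray, eps: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    if example == "standard":
        return eta + eps, 0
    if example == "latent_binary":
        # eta == 0 (measure zero) goes to the positive branch
        return np.where(eta < 0, -_LATENT_OFFSET, _LATENT_OFFSET) + eps, 0
    if example == "asymmetric":
        s = eta + eps
        return np.where(eta < 0, -np.abs(s), s**2), 0
    # outliers: shift is scaled by the infinity norm over the full eta vector
    y = eta + eps
    shift = _OUTLIER_SHIFT * np.max(np.abs(eta))
    u = rng.random(eta.shape[0])
    y = y - shift * (u < _OUTLIER_RATE) + shift * (u >= 1.0 - _OUTLIER_RATE)
    n_outliers = int(np.sum((u < _OUTLIER_RATE) | (u >= 1.0 - _OUTLIER_RATE)))
    return y, n_outliers


def simulate_dataset(spec: SimulationSpec) -> SimulatedData:
    """Generate one train/test pair from the chosen data-generating process.

    A single feature matrix of n0 + n1 rows and one effect vector are drawn;
    the first n0 rows become the training set. Threshold 0, direction gt.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n0 + spec.n1
    X = rng.standard_normal((n, spec.p))
    beta = simulate_effects(spec.p, spec.sparsity, rng)
    eta = X @ beta
    eps = rng.standard_normal(n)
    y, n_outliers = _outcomes(spec.example, eta, eps, rng)
    train = LabelledDataset(X=X[: spec.n0], y=y[: spec.n0], c=0.0, direction="gt")
    test = LabelledDataset(X=X[spec.n0 :], y=y[spec.n0 :], c=0.0, direction="gt")
    return SimulatedData(train=train, test=test, beta=beta, n_outliers=n_outliers)


COMPARISONS = (
    ("combined", "logistic"),
    ("combined", "calibrated_linear"),
)


@dataclass
class StudyResult:
    """Per-repetition out-of-sample deviances and Wilcoxon comparisons."""

    examples: tuple[str, ...]
    reps: int
    deviances: dict[str, np.ndarray]  # example -> (reps, 3), columns = VARIANTS
    p_values: pd.DataFrame  # example, comparison, p_value, significant
    bonferroni_level: float
    seed: int = 0
    redraws: dict[str, int] = field(default_factory=dict)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for example in self.examples:
            dev = self.deviances[example]
            for rep in range(dev.shape[0]):
                for m, model in enumerate(VARIANTS):
                    rows.append(
                        {
                            "example": example,
                            "repetition": rep,
                            "model": model,
                            "deviance": dev[rep, m],
                        }
                    )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        return self.p_values.copy()


def _fit_and_score(
    train: LabelledDataset,
    test: LabelledDataset,
    alpha: float,
    k: int,
    seed: int,
) -> np.ndarray:
    models = fit_variant_models(train, alpha=alpha, k=k, seed=seed)
    out = np.empty(len(VARIANTS))
    for m, name in enumerate(VARIANTS):
        phat = models[name].predict(test.X)
        out[m] = combined_deviance(test.z, phat, clip_epsilon=CLIP_EPSILON, mean=True)
    return out


def run_holdout_study(
    examples: Sequence[str] = EXAMPLES,
    reps: int = 100,
    n0: int = 100,
    n1: int = 10_000,
    p: int = 500,
    sparsity: float = 0.05,
    alpha: float = 1.0,
    k: int = 10,
    seed: int = 0,
) -> StudyResult:
    """Repeat the hold-out comparison and test model differences.

    For each example and repetition, the three comparators are fit on the
    training half (sharing penalised fits and folds) and scored by mean
    logistic deviance on the test half. One-sided Wilcoxon signed-rank
    tests ask whether combined regression has lower deviance than each
    endpoint model; significance uses the Bonferroni-adjusted level
    0.05 / (2 * number of examples). Repetitions whose training outcome is
    single-class are redrawn with an advanced seed (counted in
    ``redraws``).
    """
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    examples = tuple(examples)
    for example in examples:
        if example not in EXAMPLES:
            raise ValueError(f"unknown example {example!r}")
    root = np.random.SeedSequence(seed)
    example_seeds = root.spawn(len(examples))
    deviances: dict[str, np.ndarray] = {}
    redraws: dict[str, int] = {}
    for e, example in enumerate(examples):
        rep_seeds = example_seeds[e].spawn(reps)
        dev = np.empty((reps, len(VARIANTS)))
        n_redraw = 0
        for rep in range(reps):
            words = rep_seeds[rep].generate_state(12, dtype=np.uint32)
            attempt = 0
            while True:
                spec = SimulationSpec(
                    example=example,
                    n0=n0,
                    n1=n1,
                    p=p,
                    sparsity=sparsity,
                    seed=int(words[2 * attempt]),
                )
                data = simulate_dataset(spec)
                if data.train.has_both_classes():
                    break
                n_redraw += 1
                attempt += 1
                logger.info(
                    "example %s rep %d: single-class training outcome, redrawing",
                    example,
                    rep,
                )
                if attempt >= 5:
                    raise RuntimeError("repeated single-class training draws")
            dev[rep] = _fit_and_score(
                data.train, data.test, alpha=alpha, k=k, seed=int(words[11])
            )
            logger.debug(
                "example %s rep %d deviances %s", example, rep, np.round(dev[rep], 4)
            )
        deviances[example] = dev
        redraws[example] = n_redraw
        logger.info(
            "example %s: mean deviances %s",
            example,
            dict(zip(VARIANTS, np.round(dev.mean(axis=0), 4))),
        )
    level = 0.05 / (2 * len(examples))
    rows = []
    for example in examples:
        dev = deviances[example]
        for model_a, model_b in COMPARISONS:
            a = dev[:, VARIANTS.index(model_a)]
            b = dev[:, VARIANTS.index(model_b)]
            pval = one_sided_wilcoxon_less(a, b)
            rows.append(
                {
                    "example": example,
                    "comparison": f"{model_a}<{model_b}",
                    "p_value": pval,
                    "significant": pval <= level,
                }
            )
    p_values = pd.DataFrame(rows)
    return StudyResult(
        examples=examples,
        reps=reps,
        deviances=deviances,
        p_values=p_values,
        bonferroni_level=level,
        seed=seed,
        redraws=redraws,
    )
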