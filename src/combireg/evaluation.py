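"""Performance metrics and significance-testing protocols.

Two protocols are provided for comparing predictors of a dichotomised
outcome on one dataset:

* a multi-split test: repeated stratified 80/20 splits, a one-sided
  Wilcoxon signed-rank test on paired squared deviance residuals per
  split, and the median of the per-split p-values as the reported
  significance;
* nested cross-validation: shared stratified outer folds, each fitter
  tuned internally on the outer-training part, metrics computed on the
  pooled out-of-fold test predictions.

Fitters are callables ``fitter(dataset, k, seed) -> model`` where the model
exposes ``predict(X) -> probabilities``; see
:func:`combireg.combination.combined_fitter`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from combireg._stats import lower_median, one_sided_wilcoxon_less
from combireg.combination import CLIP_EPSILON
from combireg.data_model import LabelledDataset
from combireg.penalized_regression import make_stratified_folds

logger = logging.getLogger(__name__)

Fitter = Callable[[LabelledDataset, int, int], object]


def squared_deviance_residuals(
    z: np.ndarray, phat: np.ndarray, clip_epsilon: float = CLIP_EPSILON
) -> np.ndarray:
    """Per-sample deviance contributions; their mean is the mean-form deviance."""
    z = np.asarray(z, dtype=float)
    p = np.clip(np.asarray(phat, dtype=float), clip_epsilon, 1.0 - clip_epsilon)
    return -2.0 * (z * np.log(p) + (1.0 - z) * np.log(1.0 - p))


@dataclass
class ClassificationMetrics:
    """Misclassification at the 0.5 cut-off plus ranking metrics.

    ``auroc``/``auprc`` are ``None`` (undefined, not zero) when only one
    class is present.
    """

    misclassification: float
    auroc: Optional[float]
    auprc: Optional[float]


def classification_metrics(z: np.ndarray, phat: np.ndarray) -> ClassificationMetrics:
    """Misclassification (predict class 1 when phat > 0.5), AUROC, AUPRC."""
    z = np.asarray(z, dtype=float)
    phat = np.asarray(phat, dtype=float)
    misclass = float(np.mean((phat > 0.5).astype(float) != z))
    if z.min() == z.max():
        return ClassificationMetrics(misclass, None, None)
    return ClassificationMetrics(
        misclassification=misclass,
        auroc=float(roc_auc_score(z, phat)),
        auprc=float(average_precision_score(z, phat)),
    )


def _stratified_split(
    z: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx = []
    test_idx = []
    for value in np.unique(z):
        idx = rng.permutation(np.flatnonzero(z == value))
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


@dataclass
class MultiSplitResult:
    median_p: float
    p_values: np.ndarray


def multi_split_test(
    dataset: LabelledDataset,
    fitter_a: Fitter,
    fitter_b: Fitter,
    n_splits: int = 50,
    train_frac: float = 0.8,
    seed: int = 0,
    k: int = 10,
    clip_epsilon: float = CLIP_EPSILON,
) -> MultiSplitResult:
    """Median p-value over repeated splits for H1: model b beats model a.

    Each split trains both fitters on a stratified ``train_frac`` portion
    and compares their test-set squared deviance residuals pairwise with a
    one-sided Wilcoxon signed-rank test (b lower). Splits are stratified by
    z; degenerate splits are redrawn with an advanced seed. If every paired
    difference in a split is zero the split's p-value is 1. The reported
    median is the lower median for an even number of splits.
    """
    dataset.require_both_classes()
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    root = np.random.SeedSequence(seed)
    split_seeds = root.spawn(n_splits)
    p_values = np.empty(n_splits)
    for s in range(n_splits):
        words = split_seeds[s].generate_state(8, dtype=np.uint32)
        for attempt in range(5):
            rng = np.random.default_rng(int(words[attempt]))
            train_idx, test_idx = _stratified_split(dataset.z, train_frac, rng)
            train = dataset.subset(train_idx)
            test = dataset.subset(test_idx)
            if train.has_both_classes() and test_idx.size >= 2:
                break
            logger.info("split %d attempt %d degenerate, redrawing", s, attempt)
        else:
            raise RuntimeError("could not draw a non-degenerate split")
        fit_seed = int(words[7])
        model_a = fitter_a(train, k, fit_seed)
        model_b = fitter_b(train, k, fit_seed)
        res_a = squared_deviance_residuals(test.z, model_a.predict(test.X), clip_epsilon)
        res_b = squared_deviance_residuals(test.z, model_b.predict(test.X), clip_epsilon)
        p_values[s] = one_sided_wilcoxon_less(res_b, res_a)
    return MultiSplitResult(median_p=lower_median(p_values), p_values=p_values)


@dataclass
class EvaluationReport:
    """Pooled nested-CV metrics per model plus pairwise deviance changes."""

    per_model: dict[str, dict]
    reference: str
    pct_change_deviance: dict[str, float]
    outer_k: int
    inner_k: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "outer_k": self.outer_k,
            "inner_k": self.inner_k,
            "seed": self.seed,
            "per_model": self.per_model,
            "pct_change_deviance": self.pct_change_deviance,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    def __str__(self) -> str:
        lines = [
            f"{'model':<20}{'deviance':>12}{'misclass':>10}{'auroc':>8}{'auprc':>8}{'change%':>10}"
        ]
        for name, metrics in self.per_model.items():
            change = self.pct_change_deviance.get(name)
            lines.append(
                f"{name:<20}"
                f"{metrics['deviance_mean']:>12.4f}"
                f"{metrics['misclassification']:>10.3f}"
                + "".join(
                    f"{metrics[key]:>8.3f}" if metrics[key] is not None else f"{'NA':>8}"
                    for key in ("auroc", "auprc")
                )
                + (f"{change:>10.2f}" if change is not None else f"{'-':>10}")
            )
        return "\n".join(lines)


def nested_cv_compare(
    dataset: LabelledDataset,
    fitters: Mapping[str, Fitter],
    outer_k: int = 5,
    inner_k: int = 10,
    seed: int = 0,
    clip_epsilon: float = CLIP_EPSILON,
) -> EvaluationReport:
    """Nested cross-validation with shared folds across fitters.

    The outer loop provides unbiased test predictions (each sample is held
    out exactly once); the inner loop, run by each fitter on the outer
    training part with the same seed, does the tuning. The percentage
    change in pooled deviance is reported relative to the first fitter:
    ``100 * (D_model - D_reference) / D_reference`` (negative = better).
    """
    dataset.require_both_classes()
    if dataset.n < 2 * outer_k:
        raise ValueError("need at least 2*outer_k samples")
    names = list(fitters)
    if not names:
        raise ValueError("no fitters given")
    root = np.random.SeedSequence(seed)
    fold_rng = np.random.default_rng(root.spawn(1)[0])
    assignment = make_stratified_folds(dataset.z, outer_k, fold_rng)
    fit_seeds = [int(w) for w in root.generate_state(outer_k, dtype=np.uint32)]
    pooled = {name: np.empty(dataset.n) for name in names}
    for f in range(outer_k):
        test = assignment == f
        train_ds = dataset.subset(np.flatnonzero(~test))
        train_ds.require_both_classes()
        Xtest = dataset.X[test]
        for name in names:
            model = fitters[name](train_ds, inner_k, fit_seeds[f])
            pooled[name][test] = model.predict(Xtest)
    per_model = {}
    for name in names:
        residuals = squared_deviance_residuals(dataset.z, pooled[name], clip_epsilon)
        metrics = classification_metrics(dataset.z, pooled[name])
        per_model[name] = {
            "deviance_mean": float(residuals.mean()),
            "deviance_sum": float(residuals.sum()),
            "misclassification": metrics.misclassification,
            "auroc": metrics.auroc,
            "auprc": metrics.auprc,
        }
    reference = names[0]
    ref_dev = per_model[reference]["deviance_mean"]
    pct = {
        name: 100.0 * (per_model[name]["deviance_mean"] - ref_dev) / ref_dev
        for name in names
        if name != reference
    }
    return EvaluationReport(
        per_model=per_model,
        reference=reference,
        pct_change_deviance=pct,
        outer_k=outer_k,
        inner_k=inner_k,
        seed=seed,
    )


class _InterceptModel:
    """Constant-probability predictor (training prevalence)."""

    def __init__(self, prevalence: float):
        self.prevalence = prevalence

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        Xnew = np.asarray(Xnew, dtype=float)
        n = Xnew.shape[0] if Xnew.ndim == 2 else 1
        return np.full(n, self.prevalence)


def intercept_only_fitter(dataset: LabelledDataset, k: int, seed: int) -> _InterceptModel:
    """Null fitter: predicts the training-set class-1 prevalence everywhere."""
    return _InterceptModel(float(dataset.z.mean()))
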