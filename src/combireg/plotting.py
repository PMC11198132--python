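"""Figures: study box plots, calibration curves, loss-surface heat maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from combireg.combination import LossSurface, calibrate
from combireg.simulation import VARIANTS, StudyResult


def plot_study_boxplots(result: StudyResult, path: str) -> None:
    """One panel per example: out-of-sample deviance by model."""
    n = len(result.examples)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.6), squeeze=False)
    for ax, example in zip(axes[0], result.examples):
        dev = result.deviances[example]
        ax.boxplot([dev[:, m] for m in range(len(VARIANTS))], tick_labels=VARIANTS)
        ax.plot(range(1, len(VARIANTS) + 1), dev.mean(axis=0), "k.", markersize=8)
        ax.set_title(example)
        ax.set_ylabel("out-of-sample deviance")
        ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_calibration_curve(c: float, sigma2: float, path: str, span: float = 4.0) -> None:
    """Predicted value vs calibrated probability for the fitted sigma2."""
    sigma = float(np.sqrt(sigma2))
    yhat = np.linspace(c - span * sigma, c + span * sigma, 400)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(yhat, calibrate(yhat, c, sigma2))
    ax.axvline(c, color="grey", linewidth=0.8)
    ax.axhline(0.5, color="grey", linewidth=0.8)
    ax.set_xlabel("predicted value")
    ax.set_ylabel("calibrated probability")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_loss_surface(surface: LossSurface, path: str) -> None:
    """Heat map of combined deviance over the (pi, sigma) grid."""
    fig, ax = plt.subplots(figsize=(5.0, 4.0))
    mesh = ax.pcolormesh(
        surface.sigma_grid, surface.pi_grid, surface.loss, shading="nearest"
    )
    ax.set_xscale("log")
    pi_hat, sigma_hat = surface.argmin
    ax.plot([sigma_hat], [pi_hat], "wx", markersize=10)
    ax.set_xlabel("standard deviation sigma")
    ax.set_ylabel("weight pi")
    fig.colorbar(mesh, ax=ax, label="combined deviance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
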