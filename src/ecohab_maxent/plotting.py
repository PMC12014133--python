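"""Quick-look plots for fitted models and validation reports."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_couplings", "plot_calibration", "plot_cv_path",
           "plot_k_distribution"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_couplings(results, ax=None):
    """Heat map of the inferred coupling matrix J."""
    ax = _ax(ax)
    vmax = np.abs(results.J).max() or 1.0
    im = ax.imshow(results.J, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.figure.colorbar(im, ax=ax, label="$J_{ij}$")
    ax.set_xlabel("mouse")
    ax.set_ylabel("mouse")
    return ax


def plot_calibration(curve, ax=None):
    """Observed vs model-predicted in-state probability by percentile bin."""
    ax = _ax(ax)
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="unbiased")
    ax.plot(curve.pred, curve.obs, "o-", label="model")
    ax.set_xlabel("predicted in-state probability")
    ax.set_ylabel("observed frequency")
    ax.legend()
    return ax


def plot_cv_path(report, n_days=None, ax=None):
    """Train/test likelihood against the regularization strength."""
    ax = _ax(ax)
    s = report.summary()
    if n_days is not None:
        s = s[s["n_days"] == n_days]
    ax.plot(s["beta"], s["train_ll"], "o-", label="train")
    ax.plot(s["beta"], s["test_ll"], "s-", label="test")
    ax.set_xscale("symlog", linthresh=min(b for b in s["beta"] if b > 0)
                  if (s["beta"] > 0).any() else 1.0)
    ax.set_xlabel(r"regularization strength $\beta$")
    ax.set_ylabel("log-likelihood (nats / observation)")
    ax.legend()
    return ax


def plot_k_distribution(hist, model_hist=None, ax=None):
    """Probability of K mice sharing a compartment, data vs model."""
    ax = _ax(ax)
    ax.semilogy(hist.support, hist.aggregated, "o-", label="data")
    if model_hist is not None:
        ax.semilogy(model_hist.support, model_hist.aggregated, "s--",
                    label="model")
    ax.set_xlabel("K mice in the same compartment")
    ax.set_ylabel("probability")
    ax.legend()
    return ax
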