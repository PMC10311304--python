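"""Optional matplotlib views: curve fans and synergy histograms.

Never on the numeric path; every function returns a Figure.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .inference import PosteriorSamples
from .model import PriorConfig, hill_mean, sample_prior
from .synergy import SynergyReport

__all__ = ["prior_curve_fan", "posterior_curve_fan", "synergy_histograms"]


def prior_curve_fan(
    cfg: PriorConfig, doses: np.ndarray, n_curves: int = 300, seed: int = 0
):
    """Fan of expected monotherapy responses under the prior."""
    doses = np.asarray(doses, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    for p in sample_prior(cfg, "mono", n_curves, seed):
        ax.plot(doses, hill_mean(p, doses), color="C0", alpha=0.08, lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("dose")
    ax.set_ylabel("response")
    ax.set_title("prior expected dose-response curves")
    return fig


def posterior_curve_fan(
    post: PosteriorSamples, doses: np.ndarray, data=None, n_curves: int = 200
):
    """Fan of expected responses under a monotherapy posterior."""
    if post.setting != "mono":
        raise ValueError("curve fan is drawn for monotherapy posteriors")
    doses = np.asarray(doses, dtype=float)
    idx = np.linspace(0, post.n_draws - 1, min(n_curves, post.n_draws)).astype(int)
    sub = post.draws.iloc[idx]
    fig, ax = plt.subplots(figsize=(5, 4))
    for _, row in sub.iterrows():
        mu = row.E0 + (row.E1 - row.E0) / (1.0 + (row.C / doses) ** row.H)
        ax.plot(doses, mu, color="C0", alpha=0.1, lw=0.8)
    if data is not None:
        ax.plot(data.doses[:, 0], data.responses, "o", color="C3", ms=4)
    ax.set_xscale("log")
    ax.set_xlabel("dose")
    ax.set_ylabel("response")
    ax.set_title("posterior expected dose-response curves")
    return fig


def synergy_histograms(report: SynergyReport):
    """Posterior histograms of Delta-HSA and log(alpha) with their thresholds."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].hist(report.delta_hsa_samples, bins=40, color="C0")
    axes[0].axvline(0.0, color="red")
    axes[0].set_xlabel(r"$\Delta$HSA")
    axes[0].set_title(f"P(synergistic efficacy) = {report.p_synergistic_efficacy:.3f}")
    axes[1].hist(report.log_alpha_samples, bins=40, color="C1")
    axes[1].axvline(0.0, color="red")
    axes[1].set_xlabel(r"$\log\alpha$")
    axes[1].set_title(f"P(synergistic potency) = {report.p_synergistic_potency:.3f}")
    fig.tight_layout()
    return fig
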