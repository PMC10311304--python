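"""Decoupled synergy summaries from a combination posterior.

Efficacy synergy is summarized by Delta-HSA = min(E1, E2) - E3: on the
decreasing-response scale the more effective single drug has the LOWER
maximal-effect level, so a positive value means the combination reaches a
stronger maximal effect than the best single agent. Potency synergy is
carried by the association parameter alpha (alpha > 1 = synergistic
potency). Both are computed per posterior draw, so every min/threshold is
taken inside the joint posterior, never on marginal summaries; the reported
probabilities are exact empirical fractions over the retained draws (no
kernel smoothing), with strict inequalities so ties count as
non-synergistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import PosteriorSamples
from .model import CombinationParams

__all__ = ["SynergyReport", "delta_hsa", "synergy_probabilities", "parameter_summaries"]


@dataclass
class SynergyReport:
    delta_hsa_samples: np.ndarray
    log_alpha_samples: np.ndarray
    p_synergistic_efficacy: float
    p_synergistic_potency: float
    parameter_summaries: pd.DataFrame

    @property
    def n_draws(self) -> int:
        return len(self.delta_hsa_samples)

    def to_json(self, path=None) -> dict:
        payload = {
            "p_synergistic_efficacy": self.p_synergistic_efficacy,
            "p_synergistic_potency": self.p_synergistic_potency,
            "summaries": {
                name: dict(row)
                for name, row in self.parameter_summaries.iterrows()
            },
            "n_draws": self.n_draws,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload

    def samples_to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "delta_hsa": self.delta_hsa_samples,
                "log_alpha": self.log_alpha_samples,
            }
        ).to_csv(path, index=False)


def delta_hsa(draw: CombinationParams) -> float:
    """Excess maximal effect of the combination over the better single agent."""
    return min(draw.E1, draw.E2) - draw.E3


def parameter_summaries(post: PosteriorSamples) -> pd.DataFrame:
    """Median and central 95% interval per parameter.

    IC50 parameters are summarized on the log scale and exponentiated back
    (order statistics commute with the monotone map, so this is also the
    quantile on the raw scale).
    """
    rows = {}
    for name in post.param_names:
        x = post.param(name)
        if name in ("C", "C1", "C2"):
            q = np.exp(np.quantile(np.log(x), [0.5, 0.025, 0.975]))
        else:
            q = np.quantile(x, [0.5, 0.025, 0.975])
        rows[name] = {"median": q[0], "q2.5": q[1], "q97.5": q[2]}
    return pd.DataFrame.from_dict(rows, orient="index")


def synergy_probabilities(post: PosteriorSamples) -> SynergyReport:
    """Posterior Delta-HSA and log(alpha) samples with tail probabilities.

    ``p_synergistic_efficacy`` is the fraction of draws with Delta-HSA > 0,
    ``p_synergistic_potency`` the fraction with alpha > 1.
    """
    if post.setting != "combo":
        raise ValueError("synergy summaries require a combination posterior")
    dh = np.minimum(post.param("E1"), post.param("E2")) - post.param("E3")
    log_alpha = np.log(post.param("alpha"))
    return SynergyReport(
        delta_hsa_samples=dh,
        log_alpha_samples=log_alpha,
        p_synergistic_efficacy=float(np.mean(dh > 0)),
        p_synergistic_potency=float(np.mean(log_alpha > 0)),
        parameter_summaries=parameter_summaries(post),
    )
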