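"""Seeded synthetic dose-response matrices drawn from the generative model.

Matrices follow the two screening layouts the models are designed for: a
6x6 "DREAM-shaped" matrix (1 dose-zero base cell, two 5-point monotherapy
slices, a 5x5 combination grid) and a 16-point "ALMANAC-shaped" grid (base
cell, two 3-point slices, 3x3 grid). Responses are the detailed-balance
surface mean plus i.i.d. Gaussian noise at every cell, including the base
cell. Negative simulated responses are kept - the noise model allows them;
the stricter rejection rule applies only to real-data ingestion through the
CSV loader.

Default dose grids are 5-point (or 3-point) log-spaced ladders. When the
ground truth is given explicitly the ladder is centred on the geometric mean
of the two IC50s, making identifiability controllable: an "unsaturating"
scenario (all doses well below the IC50s) reproduces the
high-Einf-uncertainty regime by design. When the truth is drawn from the
prior, a fixed ladder spanning 10^-1.5 .. 10^1.5 is used together with the
dose-derived IC50 bounds, so the generating prior and the fitting prior
coincide - the condition for exact simulation-based calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .data import DoseResponseDataset
from .model import CombinationParams, MonotherapyParams, PriorConfig, sample_prior
from .model import _combo_mean_arrays, _hill_mean_arrays

__all__ = ["ScenarioConfig", "generate_matrix", "generate_suite", "generate_mono"]

_DEFAULT_GRID_5 = tuple(np.geomspace(10**-1.5, 10**1.5, 5))
_DEFAULT_GRID_3 = tuple(np.geomspace(10**-1.0, 10**1.0, 3))


@dataclass(frozen=True)
class ScenarioConfig:
    """Specification of one synthetic-screen scenario."""

    shape: Literal["dream_6x6", "almanac_15", "custom"] = "dream_6x6"
    dose_grids: tuple[tuple[float, ...], tuple[float, ...]] | None = None
    generating_params: CombinationParams | Literal["sample_from_prior"] = (
        "sample_from_prior"
    )
    sigma_override: float | None = None
    seed: int = 0
    n_matrices: int = 1
    prior_cfg: PriorConfig | None = None
    B: float = 100.0

    def __post_init__(self) -> None:
        if self.n_matrices < 1:
            raise ValueError("n_matrices must be at least 1")
        if self.dose_grids is not None:
            for grid in self.dose_grids:
                g = np.asarray(grid, dtype=float)
                if np.any(g <= 0) or np.any(np.diff(g) <= 0):
                    raise ValueError("dose grids must be strictly positive and sorted")
        if self.sigma_override is not None and self.sigma_override < 0:
            raise ValueError("sigma_override must be non-negative")

    def grid_size(self) -> int:
        if self.shape == "dream_6x6":
            return 5
        if self.shape == "almanac_15":
            return 3
        if self.dose_grids is None:
            raise ValueError("custom shape requires explicit dose_grids")
        return len(self.dose_grids[0])

    def resolved_grids(
        self, truth: CombinationParams | None
    ) -> tuple[np.ndarray, np.ndarray]:
        if self.dose_grids is not None:
            return (
                np.asarray(self.dose_grids[0], float),
                np.asarray(self.dose_grids[1], float),
            )
        k = self.grid_size()
        base = _DEFAULT_GRID_5 if k == 5 else _DEFAULT_GRID_3
        if truth is None or self.generating_params == "sample_from_prior":
            g = np.asarray(base, float)
            return g, g
        # centre the ladder on each drug's IC50, +-1.5 decades
        g1 = truth.C1 * np.geomspace(10**-1.5, 10**1.5, k)
        g2 = truth.C2 * np.geomspace(10**-1.5, 10**1.5, k)
        return g1, g2

    def resolved_prior(self, grids: tuple[np.ndarray, np.ndarray]) -> PriorConfig:
        if self.prior_cfg is not None:
            return self.prior_cfg
        doses = np.concatenate(grids)
        return PriorConfig(
            B=self.B, delta=float(doses.min()) / 2.0, M_upper=float(doses.max()) * 10.0
        )


def _layout(grids: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Dose pairs: base cell, drug-1 slice, drug-2 slice, full grid."""
    g1, g2 = grids
    points = [(0.0, 0.0)]
    points += [(float(x1), 0.0) for x1 in g1]
    points += [(0.0, float(x2)) for x2 in g2]
    points += [(float(x1), float(x2)) for x1 in g1 for x2 in g2]
    return np.asarray(points, dtype=float)


def generate_matrix(
    cfg: ScenarioConfig, seed: int | None = None
) -> tuple[DoseResponseDataset, CombinationParams]:
    """One synthetic matrix plus its ground-truth parameters.

    Deterministic per seed (``cfg.seed`` unless overridden by ``seed``).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    grids_probe = cfg.resolved_grids(None)
    prior = cfg.resolved_prior(grids_probe)
    if cfg.generating_params == "sample_from_prior":
        truth = sample_prior(prior, "combo", 1, rng)[0]
        grids = grids_probe
    else:
        truth = cfg.generating_params
        grids = cfg.resolved_grids(truth)
    if cfg.sigma_override is not None:
        truth = CombinationParams(
            truth.E0, truth.E1, truth.E2, truth.E3,
            truth.C1, truth.C2, truth.H1, truth.H2,
            truth.alpha, max(cfg.sigma_override, 1e-300),
        )
    doses = _layout(grids)
    mu = _combo_mean_arrays(
        truth.E0, truth.E1, truth.E2, truth.E3,
        truth.C1, truth.C2, truth.H1, truth.H2,
        truth.alpha, doses[:, 0], doses[:, 1],
    )
    sigma = cfg.sigma_override if cfg.sigma_override is not None else truth.sigma
    responses = mu + rng.normal(0.0, sigma, size=mu.shape) if sigma > 0 else mu.copy()
    data = DoseResponseDataset(doses, responses, B=cfg.B, strict=False)
    return data, truth


def generate_suite(
    cfg: ScenarioConfig,
) -> list[tuple[DoseResponseDataset, CombinationParams]]:
    """``cfg.n_matrices`` independent matrices; seeds derive from ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(cfg.n_matrices)]
    return [generate_matrix(cfg, seed=s) for s in child_seeds]


def generate_mono(
    params: MonotherapyParams,
    doses: np.ndarray,
    seed: int = 0,
    B: float = 100.0,
) -> DoseResponseDataset:
    """Synthetic monotherapy vector at the given doses (noise from params.sigma)."""
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    mu = _hill_mean_arrays(params.E0, params.E1, params.C, params.H, doses)
    y = mu + rng.normal(0.0, params.sigma, size=mu.shape)
    return DoseResponseDataset(doses[:, None], y, B=B, strict=False)
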