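"""Held-out prediction and calibration evaluation.

The predictive distribution for an unseen response is the Monte-Carlo
mixture over posterior draws,

    p(y | D, x) ~= (1/M) sum_m Normal(y; mean(theta_m, x), sigma_m),

never a single Gaussian at the posterior-mean parameters. Point predictions
are posterior-predictive means; accuracy is RMSE over the held-out points
and the summary test log-likelihood is the MEAN per-point log predictive
density (per-point vectors are retained so a sum convention can be
recovered). Calibration uses the probability integral transform: the
mixture predictive CDF evaluated at each held-out observation, tested for
uniformity with a one-sample Kolmogorov-Smirnov test per combination.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .data import DoseResponseDataset
from .inference import PosteriorSamples

__all__ = [
    "TrainTestSplit",
    "EvalResult",
    "split_dream",
    "split_almanac",
    "split_fraction",
    "predictive_density",
    "log_predictive_density",
    "predict_mean",
    "pit_values",
    "ks_uniformity",
    "evaluate",
]

KS_ALPHA = 0.05


class ContaminationError(RuntimeError):
    """Posterior was not fitted on this split's training data."""


@dataclass(frozen=True)
class TrainTestSplit:
    train: DoseResponseDataset
    test: DoseResponseDataset
    strategy: str
    seed: int
    test_indices: tuple[int, ...]

    def to_json(self, path=None) -> dict:
        payload = {
            "strategy": self.strategy,
            "seed": self.seed,
            "test_indices": list(self.test_indices),
            "n_train": self.train.n_points,
            "n_test": self.test.n_points,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload


@dataclass(frozen=True)
class EvalResult:
    per_point_log_density: np.ndarray
    test_log_likelihood: float  # mean per-point log predictive density
    rmse: float
    pit_values: np.ndarray
    ks_p_value: float

    @property
    def well_calibrated(self) -> bool:
        return self.ks_p_value >= KS_ALPHA

    def to_json(self, path=None) -> dict:
        payload = {
            "rmse": self.rmse,
            "mean_log_density": self.test_log_likelihood,
            "n_test": int(len(self.pit_values)),
            "ks_p": self.ks_p_value,
            "pit": [float(v) for v in self.pit_values],
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def _build_split(
    matrix: DoseResponseDataset, test_idx: np.ndarray, strategy: str, seed: int
) -> TrainTestSplit:
    test_idx = np.sort(np.asarray(test_idx, dtype=int))
    train_idx = np.setdiff1d(np.arange(matrix.n_points), test_idx)
    return TrainTestSplit(
        train=matrix.subset(train_idx),
        test=matrix.subset(test_idx),
        strategy=strategy,
        seed=int(seed),
        test_indices=tuple(int(i) for i in test_idx),
    )


def split_dream(matrix: DoseResponseDataset, seed: int) -> TrainTestSplit:
    """Leave out 7 of the 35 non-zero-dose points of a 6x6 matrix.

    One point from each 5-point monotherapy slice plus 5 of the 25
    combination-grid points, so each monotherapy retains a held-out
    measurement. The dose-zero base point always stays in the training set.
    """
    if not matrix.is_combo:
        raise ValueError("6x6 split requires combination data")
    base = np.flatnonzero(matrix.base_mask())
    mono1 = np.flatnonzero(matrix.mono_slice_mask(0))
    mono2 = np.flatnonzero(matrix.mono_slice_mask(1))
    grid = np.flatnonzero(matrix.grid_mask())
    if not (len(base) == 1 and len(mono1) == 5 and len(mono2) == 5 and len(grid) == 25):
        raise ValueError(
            "expected a 6x6 layout: 1 base point, two 5-point monotherapy "
            f"slices and a 5x5 grid; got ({len(base)}, {len(mono1)}, "
            f"{len(mono2)}, {len(grid)})"
        )
    rng = np.random.default_rng(seed)
    test_idx = np.concatenate(
        [
            rng.choice(mono1, size=1, replace=False),
            rng.choice(mono2, size=1, replace=False),
            rng.choice(grid, size=5, replace=False),
        ]
    )
    return _build_split(matrix, test_idx, "dream_6x6", seed)


def split_almanac(matrix: DoseResponseDataset, seed: int) -> TrainTestSplit:
    """Leave out 3 of the 15 non-base points of an ALMANAC-shaped grid.

    No per-slice constraint: the matrices are too small (3 points per
    monotherapy, 9 interactions).
    """
    if not matrix.is_combo:
        raise ValueError("ALMANAC split requires combination data")
    base = np.flatnonzero(matrix.base_mask())
    nonbase = np.flatnonzero(~matrix.base_mask())
    if len(base) != 1 or len(nonbase) != 15:
        raise ValueError(
            "expected an ALMANAC layout: 1 base point + 15 non-base points "
            f"(two 3-point monotherapy slices and a 3x3 grid); got 1+{len(nonbase)}"
        )
    rng = np.random.default_rng(seed)
    test_idx = rng.choice(nonbase, size=3, replace=False)
    return _build_split(matrix, test_idx, "almanac_15", seed)


def split_fraction(
    matrix: DoseResponseDataset, test_fraction: float, seed: int
) -> TrainTestSplit:
    """Hold out a seeded random fraction of the non-base points."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    nonbase = np.flatnonzero(np.any(matrix.doses > 0, axis=1))
    n_test = max(1, int(round(test_fraction * len(nonbase))))
    if n_test >= len(nonbase):
        raise ValueError("test fraction leaves no training points")
    rng = np.random.default_rng(seed)
    test_idx = rng.permutation(nonbase)[:n_test]
    return _build_split(matrix, test_idx, "fraction", seed)


# ---------------------------------------------------------------------------
# posterior predictive quantities
# ---------------------------------------------------------------------------


def log_predictive_density(post: PosteriorSamples, x, y: float) -> float:
    """Log of the Monte-Carlo mixture density at observation ``y``."""
    mu = post.means_at(x)
    sigma = post.param("sigma")
    logs = (
        -0.5 * math.log(2.0 * math.pi)
        - np.log(sigma)
        - 0.5 * ((y - mu) / sigma) ** 2
    )
    return float(logsumexp(logs) - math.log(len(logs)))


def predictive_density(post: PosteriorSamples, x, y: float) -> float:
    """Mixture predictive density (1/M) sum_m Normal-pdf(y; mean_m, sigma_m)."""
    return math.exp(log_predictive_density(post, x, y))


def predict_mean(post: PosteriorSamples, x) -> float:
    """Posterior-predictive mean at dose vector ``x`` (noise is zero-mean)."""
    return float(np.mean(post.means_at(x)))


def pit_values(post: PosteriorSamples, test: DoseResponseDataset) -> np.ndarray:
    """Mixture predictive CDF evaluated at each held-out observation."""
    sigma = post.param("sigma")
    vals = np.empty(test.n_points)
    for i in range(test.n_points):
        mu = post.means_at(test.doses[i])
        z = (test.responses[i] - mu) / sigma
        vals[i] = np.mean(stats.norm.cdf(z))
    return vals


def ks_uniformity(pit: np.ndarray) -> float:
    """One-sample Kolmogorov-Smirnov p-value of the PIT values against U(0,1)."""
    pit = np.asarray(pit, dtype=float)
    if pit.size < 1:
        raise ValueError("need at least one PIT value")
    if np.any((pit < 0) | (pit > 1)):
        raise ValueError("PIT values must lie in [0, 1]")
    return float(stats.kstest(pit, "uniform").pvalue)


def evaluate(post: PosteriorSamples, split: TrainTestSplit) -> EvalResult:
    """RMSE, mean log predictive density and PIT/K-S calibration on the test set.

    Raises ContaminationError when the posterior was not fitted on
    ``split.train`` (checked through the training-data fingerprint).
    """
    if post.data_hash != split.train.data_hash():
        raise ContaminationError(
            "posterior data fingerprint does not match the split's training data"
        )
    test = split.test
    preds = np.array([predict_mean(post, test.doses[i]) for i in range(test.n_points)])
    rmse = float(np.sqrt(np.mean((test.responses - preds) ** 2)))
    lpd = np.array(
        [
            log_predictive_density(post, test.doses[i], test.responses[i])
            for i in range(test.n_points)
        ]
    )
    pit = pit_values(post, test)
    return EvalResult(
        per_point_log_density=lpd,
        test_log_likelihood=float(np.mean(lpd)),
        rmse=rmse,
        pit_values=pit,
        ks_p_value=ks_uniformity(pit),
    )
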