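"""Generative model: Hill mean functions, likelihoods, priors, prior sampling.

Monotherapy response at dose ``x`` follows the Hill equation

    E(x) = E0 + (E1 - E0) / (1 + (C / x)^H),

with ``E0`` the base level at dose zero, ``E1`` the maximal-effect level
(Einf), ``C`` the IC50 and ``H`` the Hill slope. The two-drug surface is the
detailed-balance form

    E(x1, x2) = (C1^H1 C2^H2 E0 + x1^H1 C2^H2 E1 + C1^H1 x2^H2 E2
                 + a x1^H1 x2^H2 E3)
              / (C1^H1 C2^H2 + x1^H1 C2^H2 + C1^H1 x2^H2 + a x1^H1 x2^H2),

where ``a`` (alpha) is the association parameter: alpha > 1 means the drugs
potentiate each other (synergistic potency). Observed responses are the mean
plus i.i.d. Gaussian noise with standard deviation sigma.

Priors: E0 ~ Normal(B, variance 0.03*B); each normalized efficacy ratio
Ei/E0 is Uniform(0,1) or Beta(0.46, 0.58); log C is Uniform(log delta,
log M); H, sigma and alpha are lognormal(0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import special

from .data import DoseResponseDataset

__all__ = [
    "MonotherapyParams",
    "CombinationParams",
    "PriorConfig",
    "hill_mean",
    "combo_mean",
    "log_likelihood_mono",
    "log_likelihood_combo",
    "log_prior_mono",
    "log_prior_combo",
    "sample_prior",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class MonotherapyParams:
    """One point in monotherapy parameter space (E0, E1, C, H, sigma)."""

    E0: float
    E1: float
    C: float
    H: float
    sigma: float

    def __post_init__(self) -> None:
        if not all(
            np.isfinite(v) for v in (self.E0, self.E1, self.C, self.H, self.sigma)
        ):
            raise ValueError("parameters must be finite")
        if self.C <= 0 or self.H <= 0 or self.sigma <= 0:
            raise ValueError("C, H and sigma must be strictly positive")
        if self.E0 <= 0 or not (0.0 <= self.E1 / self.E0 <= 1.0):
            raise ValueError("normalized maximal response E1/E0 must lie in [0, 1]")


@dataclass(frozen=True)
class CombinationParams:
    """One point in combination parameter space.

    ``E0 = E(0,0)``, ``E1 = E(inf,0)``, ``E2 = E(0,inf)``, ``E3 = E(inf,inf)``.
    """

    E0: float
    E1: float
    E2: float
    E3: float
    C1: float
    C2: float
    H1: float
    H2: float
    alpha: float
    sigma: float

    def __post_init__(self) -> None:
        vals = (
            self.E0, self.E1, self.E2, self.E3, self.C1, self.C2,
            self.H1, self.H2, self.alpha, self.sigma,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("parameters must be finite")
        if min(self.C1, self.C2, self.H1, self.H2, self.alpha, self.sigma) <= 0:
            raise ValueError("C1, C2, H1, H2, alpha and sigma must be positive")
        if self.E0 <= 0:
            raise ValueError("E0 must be positive")
        for e in (self.E1, self.E2, self.E3):
            if not 0.0 <= e / self.E0 <= 1.0:
                raise ValueError("each normalized level Ei/E0 must lie in [0, 1]")

    def drug1(self) -> MonotherapyParams:
        return MonotherapyParams(self.E0, self.E1, self.C1, self.H1, self.sigma)

    def drug2(self) -> MonotherapyParams:
        return MonotherapyParams(self.E0, self.E2, self.C2, self.H2, self.sigma)


@dataclass(frozen=True)
class PriorConfig:
    """Hyper-parameters of the prior.

    ``delta`` and ``M_upper`` bound the uniform prior on log IC50 and are
    stored on the raw dose scale. ``efficacy_prior`` selects Uniform(0,1)
    ("uniform") or Beta(beta_a, beta_b) ("beta") for each normalized
    efficacy ratio Ei/E0.
    """

    B: float = 100.0
    delta: float = 1e-10
    M_upper: float = 1e6
    efficacy_prior: Literal["uniform", "beta"] = "uniform"
    beta_a: float = 0.46
    beta_b: float = 0.58

    def __post_init__(self) -> None:
        if not (0 < self.delta < self.M_upper):
            raise ValueError("need 0 < delta < M_upper")
        if self.B <= 0 or self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("B, beta_a and beta_b must be positive")
        if self.efficacy_prior not in ("uniform", "beta"):
            raise ValueError("efficacy_prior must be 'uniform' or 'beta'")

    @property
    def e0_sd(self) -> float:
        # "variance 0.03 B" read literally: sd = sqrt(0.03 * B)
        return math.sqrt(0.03 * self.B)

    @property
    def log_c_range(self) -> float:
        return math.log(self.M_upper) - math.log(self.delta)

    def for_dataset(self, data: DoseResponseDataset) -> "PriorConfig":
        """Bounds tied to the dose range: delta below every non-zero dose, M above all."""
        delta, m = data.dose_bounds()
        return replace(self, delta=delta, M_upper=m, B=data.B)


# ---------------------------------------------------------------------------
# mean functions
# ---------------------------------------------------------------------------


def _hill_mean_arrays(E0, E1, C, H, x):
    """Vectorized Hill mean; broadcasts parameters against doses."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        g = H * (np.log(x) - np.log(C))
    # expit(g) = (x/C)^H / (1 + (x/C)^H); expit(-inf) = 0 gives E(0) = E0
    return E0 + (E1 - E0) * special.expit(g)


def _combo_mean_arrays(E0, E1, E2, E3, C1, C2, H1, H2, alpha, x1, x2):
    """Vectorized detailed-balance surface, computed on the log scale.

    The four surface weights are normalized by their maximum exponent so the
    expression never overflows even for extreme Hill slopes or dose ratios.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    with np.errstate(divide="ignore"):
        g1 = np.clip(H1 * (np.log(x1) - np.log(C1)), -745.0, 700.0)
        g2 = np.clip(H2 * (np.log(x2) - np.log(C2)), -745.0, 700.0)
    ga = g1 + g2 + np.log(alpha)
    m = np.maximum(np.maximum(0.0, g1), np.maximum(g2, ga))
    w0 = np.exp(0.0 - m)
    w1 = np.exp(g1 - m)
    w2 = np.exp(g2 - m)
    w3 = np.exp(ga - m)
    return (w0 * E0 + w1 * E1 + w2 * E2 + w3 * E3) / (w0 + w1 + w2 + w3)


def _check_doses(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("doses must be finite and non-negative")
    return x


def hill_mean(params: MonotherapyParams, x):
    """Expected monotherapy response at dose ``x`` (scalar or array).

    The zero-dose value is E0 by the limit convention; no division by zero
    occurs.
    """
    x = _check_doses(x)
    out = _hill_mean_arrays(params.E0, params.E1, params.C, params.H, x)
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def combo_mean(params: CombinationParams, x1, x2):
    """Expected combination response at doses ``(x1, x2)``."""
    x1 = _check_doses(x1)
    x2 = _check_doses(x2)
    out = _combo_mean_arrays(
        params.E0, params.E1, params.E2, params.E3,
        params.C1, params.C2, params.H1, params.H2,
        params.alpha, x1, x2,
    )
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------


def _gauss_logpdf(resid, sigma):
    return -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * (resid / sigma) ** 2


def log_likelihood_mono(params: MonotherapyParams, data: DoseResponseDataset) -> float:
    """Sum of Gaussian log-densities of the responses around the Hill mean."""
    if not data.is_mono:
        raise ValueError("expected monotherapy data (dose vectors of length 1)")
    mu = _hill_mean_arrays(params.E0, params.E1, params.C, params.H, data.doses[:, 0])
    return float(np.sum(_gauss_logpdf(data.responses - mu, params.sigma)))


def log_likelihood_combo(params: CombinationParams, data: DoseResponseDataset) -> float:
    """Sum of Gaussian log-densities around the combination surface.

    Monotherapy slice points (one zero dose) contribute through the surface's
    exact reduction to the single-drug Hill curve.
    """
    if not data.is_combo:
        raise ValueError("expected combination data (dose vectors of length 2)")
    mu = _combo_mean_arrays(
        params.E0, params.E1, params.E2, params.E3,
        params.C1, params.C2, params.H1, params.H2,
        params.alpha, data.doses[:, 0], data.doses[:, 1],
    )
    return float(np.sum(_gauss_logpdf(data.responses - mu, params.sigma)))


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


def _lognormal_logpdf(v: float) -> float:
    """lognormal(0, 1) log-density at v > 0."""
    lv = math.log(v)
    return -0.5 * _LOG_2PI - lv - 0.5 * lv * lv


def _ratio_log_density(r: float, cfg: PriorConfig) -> float:
    """Log-density of a normalized efficacy ratio under the configured prior."""
    if cfg.efficacy_prior == "uniform":
        return 0.0 if 0.0 <= r <= 1.0 else -math.inf
    if not 0.0 < r < 1.0:
        return -math.inf
    a, b = cfg.beta_a, cfg.beta_b
    return (
        (a - 1.0) * math.log(r)
        + (b - 1.0) * math.log1p(-r)
        - special.betaln(a, b)
    )


def _log_c_density(c: float, cfg: PriorConfig) -> float:
    if not cfg.delta <= c <= cfg.M_upper:
        return -math.inf
    return -math.log(cfg.log_c_range)


def log_prior_mono(params: MonotherapyParams, cfg: PriorConfig) -> float:
    """Joint log prior density in the coordinates (E0, E1, log C, H, sigma).

    The efficacy factor is the ratio prior evaluated at E1/E0 with the
    change-of-variable Jacobian 1/E0 (density with respect to E1 given E0).
    Returns -inf outside the support instead of raising.
    """
    if params.E0 <= 0:
        return -math.inf
    lp = _gauss_logpdf(params.E0 - cfg.B, cfg.e0_sd)
    r = params.E1 / params.E0
    lp += _ratio_log_density(r, cfg) - math.log(params.E0)
    lp += _log_c_density(params.C, cfg)
    lp += _lognormal_logpdf(params.H)
    lp += _lognormal_logpdf(params.sigma)
    return float(lp)


def log_prior_combo(params: CombinationParams, cfg: PriorConfig) -> float:
    """Joint log prior density in (E0, E1, E2, E3, log C1, log C2, H1, H2, alpha, sigma)."""
    if params.E0 <= 0:
        return -math.inf
    lp = _gauss_logpdf(params.E0 - cfg.B, cfg.e0_sd)
    for e in (params.E1, params.E2, params.E3):
        lp += _ratio_log_density(e / params.E0, cfg) - math.log(params.E0)
    lp += _log_c_density(params.C1, cfg)
    lp += _log_c_density(params.C2, cfg)
    lp += _lognormal_logpdf(params.H1)
    lp += _lognormal_logpdf(params.H2)
    lp += _lognormal_logpdf(params.alpha)
    lp += _lognormal_logpdf(params.sigma)
    return float(lp)


# ---------------------------------------------------------------------------
# prior sampling
# ---------------------------------------------------------------------------


def _sample_e0(rng: np.random.Generator, cfg: PriorConfig) -> float:
    # resample the (practically impossible at B=100) non-positive tail
    while True:
        e0 = rng.normal(cfg.B, cfg.e0_sd)
        if e0 > 0:
            return float(e0)


def _sample_ratio(rng: np.random.Generator, cfg: PriorConfig) -> float:
    if cfg.efficacy_prior == "uniform":
        return float(rng.uniform(0.0, 1.0))
    return float(np.clip(rng.beta(cfg.beta_a, cfg.beta_b), 1e-12, 1.0 - 1e-12))


def _sample_c(rng: np.random.Generator, cfg: PriorConfig) -> float:
    return float(np.exp(rng.uniform(math.log(cfg.delta), math.log(cfg.M_upper))))


def sample_prior(
    cfg: PriorConfig,
    setting: Literal["mono", "combo"],
    n: int,
    seed,
) -> list:
    """Draw ``n`` independent parameter points from the prior.

    ``seed`` may be an integer or a numpy Generator. Draws are deterministic
    given an integer seed, satisfy the type invariants and have finite
    log-prior.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if setting not in ("mono", "combo"):
        raise ValueError("setting must be 'mono' or 'combo'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = []
    for _ in range(n):
        e0 = _sample_e0(rng, cfg)
        if setting == "mono":
            draws.append(
                MonotherapyParams(
                    E0=e0,
                    E1=_sample_ratio(rng, cfg) * e0,
                    C=_sample_c(rng, cfg),
                    H=float(np.exp(rng.normal())),
                    sigma=float(np.exp(rng.normal())),
                )
            )
        else:
            draws.append(
                CombinationParams(
                    E0=e0,
                    E1=_sample_ratio(rng, cfg) * e0,
                    E2=_sample_ratio(rng, cfg) * e0,
                    E3=_sample_ratio(rng, cfg) * e0,
                    C1=_sample_c(rng, cfg),
                    C2=_sample_c(rng, cfg),
                    H1=float(np.exp(rng.normal())),
                    H2=float(np.exp(rng.normal())),
                    alpha=float(np.exp(rng.normal())),
                    sigma=float(np.exp(rng.normal())),
                )
            )
    return draws
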