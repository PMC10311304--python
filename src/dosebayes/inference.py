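"""Posterior sampling for the dose-response models.

Sampling runs on an unconstrained reparameterization (log for C, H, sigma
and alpha; logit for the efficacy ratios Ei/E0; identity for E0) so every
retained draw automatically satisfies the parameter-type invariants. The
backend is an affine-invariant ensemble MCMC sampler (emcee): each requested
chain is an independent walker ensemble, and the retained ensemble states
are thinned to exactly ``chains x (iterations - warmup)`` stored draws.
Convergence is summarized with rank-normalized split R-hat and effective
sample size (arviz); thresholds (R-hat < 1.05, ESS >= 100) are reported,
not enforced.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import special

from .data import DoseResponseDataset
from .model import (
    CombinationParams,
    MonotherapyParams,
    PriorConfig,
    _combo_mean_arrays,
    _hill_mean_arrays,
    sample_prior,
)

__all__ = ["McmcConfig", "PosteriorSamples", "fit", "diagnostics_report"]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)

MONO_PARAMS = ("E0", "E1", "C", "H", "sigma")
COMBO_PARAMS = ("E0", "E1", "E2", "E3", "C1", "C2", "H1", "H2", "alpha", "sigma")

RHAT_THRESHOLD = 1.05
ESS_THRESHOLD = 100.0


@dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration: 4 chains of 1000 iterations, 500 warm-up by default.

    ``thin`` is backend tuning: each retained iteration corresponds to
    ``thin`` internal ensemble steps, which buys effective sample size on
    posteriors with long flat directions (IC50 far outside the dose range)
    without changing the chain/draw bookkeeping.
    """

    iterations: int = 1000
    warmup: int = 500
    chains: int = 4
    seed: int = 0
    thin: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.warmup < self.iterations:
            raise ValueError("need 0 <= warmup < iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.thin < 1:
            raise ValueError("thin must be at least 1")

    @property
    def retained(self) -> int:
        return self.chains * (self.iterations - self.warmup)


@dataclass
class PosteriorSamples:
    """MCMC draws with chain/draw indexing plus convergence diagnostics."""

    setting: Literal["mono", "combo"]
    draws: pd.DataFrame
    prior_cfg: PriorConfig
    data_hash: str
    diagnostics: dict = field(default_factory=dict)
    mcmc_cfg: McmcConfig | None = None

    @property
    def param_names(self) -> tuple[str, ...]:
        return MONO_PARAMS if self.setting == "mono" else COMBO_PARAMS

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def n_chains(self) -> int:
        return int(self.draws["chain"].nunique())

    def param(self, name: str) -> np.ndarray:
        """All retained draws of one parameter, flattened across chains."""
        return self.draws[name].to_numpy()

    def param_points(self):
        """Iterate over draws as typed parameter objects."""
        cls = MonotherapyParams if self.setting == "mono" else CombinationParams
        cols = list(self.param_names)
        for row in self.draws[cols].itertuples(index=False):
            yield cls(*row)

    def means_at(self, x: np.ndarray) -> np.ndarray:
        """Per-draw model mean at dose vector ``x``; shape (n_draws,)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.setting == "mono":
            if x.size != 1:
                raise ValueError("monotherapy posterior expects a length-1 dose vector")
            return _hill_mean_arrays(
                self.param("E0"), self.param("E1"),
                self.param("C"), self.param("H"), x[0],
            )
        if x.size != 2:
            raise ValueError("combination posterior expects a length-2 dose vector")
        return _combo_mean_arrays(
            self.param("E0"), self.param("E1"), self.param("E2"), self.param("E3"),
            self.param("C1"), self.param("C2"), self.param("H1"), self.param("H2"),
            self.param("alpha"), x[0], x[1],
        )

    # -- serialization: columnar draws CSV + JSON sidecar --------------------

    def save(self, draws_csv, meta_json) -> None:
        self.draws.to_csv(draws_csv, index=False)
        meta = {
            "setting": self.setting,
            "data_hash": self.data_hash,
            "prior_cfg": {
                "B": self.prior_cfg.B,
                "delta": self.prior_cfg.delta,
                "M_upper": self.prior_cfg.M_upper,
                "efficacy_prior": self.prior_cfg.efficacy_prior,
                "beta_a": self.prior_cfg.beta_a,
                "beta_b": self.prior_cfg.beta_b,
            },
            "diagnostics": self.diagnostics,
            "mcmc_cfg": None
            if self.mcmc_cfg is None
            else {
                "iterations": self.mcmc_cfg.iterations,
                "warmup": self.mcmc_cfg.warmup,
                "chains": self.mcmc_cfg.chains,
                "seed": self.mcmc_cfg.seed,
                "thin": self.mcmc_cfg.thin,
            },
        }
        Path(meta_json).write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, draws_csv, meta_json) -> "PosteriorSamples":
        draws = pd.read_csv(draws_csv)
        meta = json.loads(Path(meta_json).read_text())
        mcfg = meta.get("mcmc_cfg")
        return cls(
            setting=meta["setting"],
            draws=draws,
            prior_cfg=PriorConfig(**meta["prior_cfg"]),
            data_hash=meta["data_hash"],
            diagnostics=meta.get("diagnostics", {}),
            mcmc_cfg=None if mcfg is None else McmcConfig(**mcfg),
        )


# ---------------------------------------------------------------------------
# unconstrained parameterization
# ---------------------------------------------------------------------------


def _params_to_unconstrained(p, setting: str) -> np.ndarray:
    def logit(r):
        r = min(max(r, 1e-12), 1.0 - 1e-12)
        return math.log(r) - math.log1p(-r)

    if setting == "mono":
        return np.array(
            [p.E0, logit(p.E1 / p.E0), math.log(p.C), math.log(p.H), math.log(p.sigma)]
        )
    return np.array(
        [
            p.E0,
            logit(p.E1 / p.E0), logit(p.E2 / p.E0), logit(p.E3 / p.E0),
            math.log(p.C1), math.log(p.C2),
            math.log(p.H1), math.log(p.H2),
            math.log(p.alpha), math.log(p.sigma),
        ]
    )


def _unconstrained_to_columns(u: np.ndarray, setting: str) -> dict:
    """Map an (n, ndim) unconstrained array to constrained parameter columns."""
    e0 = u[:, 0]
    if setting == "mono":
        return {
            "E0": e0,
            "E1": special.expit(u[:, 1]) * e0,
            "C": np.exp(u[:, 2]),
            "H": np.exp(u[:, 3]),
            "sigma": np.exp(u[:, 4]),
        }
    return {
        "E0": e0,
        "E1": special.expit(u[:, 1]) * e0,
        "E2": special.expit(u[:, 2]) * e0,
        "E3": special.expit(u[:, 3]) * e0,
        "C1": np.exp(u[:, 4]),
        "C2": np.exp(u[:, 5]),
        "H1": np.exp(u[:, 6]),
        "H2": np.exp(u[:, 7]),
        "alpha": np.exp(u[:, 8]),
        "sigma": np.exp(u[:, 9]),
    }


def _ratio_logprior_t(t: np.ndarray, cfg: PriorConfig) -> np.ndarray:
    """Prior log-density of a logit-transformed efficacy ratio (Jacobian included)."""
    log_r = -np.logaddexp(0.0, -t)
    log_1mr = -np.logaddexp(0.0, t)
    if cfg.efficacy_prior == "uniform":
        return log_r + log_1mr
    a, b = cfg.beta_a, cfg.beta_b
    return a * log_r + b * log_1mr - special.betaln(a, b)


def _make_log_post(data: DoseResponseDataset, cfg: PriorConfig, setting: str):
    """Vectorized unconstrained log posterior, shape (nwalkers,) -> (nwalkers,)."""
    y = data.responses
    log_delta, log_m = math.log(cfg.delta), math.log(cfg.M_upper)
    log_range = math.log(cfg.log_c_range)
    e0_sd = cfg.e0_sd
    B = cfg.B

    if setting == "mono":
        x = data.doses[:, 0]

        def log_post(u: np.ndarray) -> np.ndarray:
            u = np.atleast_2d(u)
            e0, t, v, w, s = u.T
            lp = -0.5 * ((e0 - B) / e0_sd) ** 2 - 0.5 * _LOG_2PI - math.log(e0_sd)
            lp += _ratio_logprior_t(t, cfg)
            lp += np.where((v >= log_delta) & (v <= log_m), -log_range, -np.inf)
            lp += -0.5 * (w**2 + s**2) - _LOG_2PI
            ok = np.isfinite(lp) & (e0 > 0)
            if np.any(ok):
                e1 = special.expit(t[ok]) * e0[ok]
                mu = _hill_mean_arrays(
                    e0[ok, None], e1[:, None],
                    np.exp(v[ok, None]), np.exp(w[ok, None]), x[None, :],
                )
                sig = np.exp(s[ok, None])
                ll = np.sum(
                    -0.5 * _LOG_2PI - np.log(sig) - 0.5 * ((y[None, :] - mu) / sig) ** 2,
                    axis=1,
                )
                lp[ok] += ll
            lp[~ok] = -np.inf
            return lp

        return log_post

    x1 = data.doses[:, 0]
    x2 = data.doses[:, 1]

    def log_post(u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(u)
        e0 = u[:, 0]
        t = u[:, 1:4]
        v = u[:, 4:6]
        w = u[:, 6:8]
        la = u[:, 8]
        s = u[:, 9]
        lp = -0.5 * ((e0 - B) / e0_sd) ** 2 - 0.5 * _LOG_2PI - math.log(e0_sd)
        lp += np.sum(_ratio_logprior_t(t, cfg), axis=1)
        inside = np.all((v >= log_delta) & (v <= log_m), axis=1)
        lp += np.where(inside, -2.0 * log_range, -np.inf)
        lp += -0.5 * (np.sum(w**2, axis=1) + la**2 + s**2) - 2.0 * _LOG_2PI
        ok = np.isfinite(lp) & (e0 > 0)
        if np.any(ok):
            e0k = e0[ok, None]
            r = special.expit(t[ok])
            mu = _combo_mean_arrays(
                e0k,
                r[:, 0:1] * e0k, r[:, 1:2] * e0k, r[:, 2:3] * e0k,
                np.exp(v[ok, 0:1]), np.exp(v[ok, 1:2]),
                np.exp(w[ok, 0:1]), np.exp(w[ok, 1:2]),
                np.exp(la[ok, None]),
                x1[None, :], x2[None, :],
            )
            sig = np.exp(s[ok, None])
            ll = np.sum(
                -0.5 * _LOG_2PI - np.log(sig) - 0.5 * ((y[None, :] - mu) / sig) ** 2,
                axis=1,
            )
            lp[ok] += ll
        lp[~ok] = -np.inf
        return lp

    return log_post


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit(
    data: DoseResponseDataset,
    prior_cfg: PriorConfig | None = None,
    mcmc_cfg: McmcConfig | None = None,
) -> PosteriorSamples:
    """Sample the posterior of the model matching ``data``'s dose dimension.

    When ``prior_cfg`` is omitted, the IC50 bounds are tied to the dataset's
    dose range (delta = half the smallest non-zero dose, M = 10x the largest).
    Deterministic for a fixed ``mcmc_cfg.seed`` and backend version. Results
    are returned even when diagnostics flag non-convergence; the caller
    decides.
    """
    setting = "mono" if data.is_mono else "combo"
    if prior_cfg is None:
        prior_cfg = PriorConfig(B=data.B).for_dataset(data)
    if mcmc_cfg is None:
        mcmc_cfg = McmcConfig()
    n_informative = int(np.sum(np.any(data.doses > 0, axis=1)))
    if n_informative < 2:
        warnings.warn(
            "fewer than 2 non-zero-dose points; posterior will track the prior",
            stacklevel=2,
        )

    ndim = 5 if setting == "mono" else 10
    nwalkers = 2 * ndim + 2
    log_post = _make_log_post(data, prior_cfg, setting)
    kept = mcmc_cfg.iterations - mcmc_cfg.warmup

    frames = []
    accept = []
    for c in range(mcmc_cfg.chains):
        rng = np.random.default_rng([int(mcmc_cfg.seed) % 2**31, c])
        init = np.stack(
            [
                _params_to_unconstrained(p, setting)
                for p in sample_prior(prior_cfg, setting, nwalkers, rng)
            ]
        )
        # mixing stretch with differential-evolution moves handles both the
        # well-identified posteriors and the prior-dominated ones (wide flat
        # IC50 prior, mild multimodality in Einf) better than either alone
        sampler = emcee.EnsembleSampler(
            nwalkers,
            ndim,
            log_post,
            vectorize=True,
            moves=[
                (emcee.moves.StretchMove(), 0.5),
                (emcee.moves.DEMove(), 0.3),
                (emcee.moves.DESnookerMove(), 0.2),
            ],
        )
        sampler.random_state = np.random.RandomState(
            (int(mcmc_cfg.seed) * 100003 + c + 1) % 2**31
        ).get_state()
        sampler.run_mcmc(
            init,
            mcmc_cfg.iterations * mcmc_cfg.thin,
            progress=False,
            skip_initial_state_check=True,
        )
        chain = sampler.get_chain()[mcmc_cfg.warmup * mcmc_cfg.thin :: mcmc_cfg.thin]
        # one state per post-warmup step, cycling through walkers
        steps = np.arange(kept)
        sel = chain[steps, steps % nwalkers, :]
        cols = _unconstrained_to_columns(sel, setting)
        frame = pd.DataFrame({"chain": c, "draw": steps, **cols})
        frames.append(frame)
        accept.append(float(np.mean(sampler.acceptance_fraction)))

    draws = pd.concat(frames, ignore_index=True)
    post = PosteriorSamples(
        setting=setting,
        draws=draws,
        prior_cfg=prior_cfg,
        data_hash=data.data_hash(),
        mcmc_cfg=mcmc_cfg,
    )
    post.diagnostics = diagnostics_report(post)
    post.diagnostics["mean_acceptance_fraction"] = float(np.mean(accept))
    if post.diagnostics.get("converged") is False:
        logger.warning(
            "convergence flags raised (max R-hat %.3f, min ESS %.0f); result returned",
            post.diagnostics.get("max_rhat", float("nan")),
            post.diagnostics.get("min_ess", float("nan")),
        )
    return post


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def diagnostics_report(post: PosteriorSamples) -> dict:
    """Per-parameter split R-hat and ESS recomputed from the stored draws.

    With a single chain, cross-chain R-hat is undefined and the report says
    so; ESS is still computed. The ``converged`` flag requires R-hat < 1.05
    on every parameter and ESS >= 100.
    """
    if post.n_draws == 0:
        raise ValueError("empty posterior")
    names = list(post.param_names)
    chains = sorted(post.draws["chain"].unique())
    arrays = {
        name: np.stack(
            [
                post.draws.loc[post.draws["chain"] == c, name].to_numpy()
                for c in chains
            ]
        )
        for name in names
    }
    idata = az.from_dict(posterior=arrays)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = az.ess(idata)
    report: dict = {"n_chains": len(chains), "params": {}}
    if len(chains) < 2:
        report["note"] = "insufficient chains: R-hat undefined for a single chain"
        rhat = None
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
    for name in names:
        report["params"][name] = {
            "rhat": None if rhat is None else float(rhat[name].values),
            "ess": float(ess[name].values),
        }
    ess_vals = [v["ess"] for v in report["params"].values()]
    report["min_ess"] = float(min(ess_vals))
    if rhat is None:
        report["converged"] = None
    else:
        rhat_vals = [v["rhat"] for v in report["params"].values()]
        report["max_rhat"] = float(max(rhat_vals))
        report["converged"] = bool(
            report["max_rhat"] < RHAT_THRESHOLD and report["min_ess"] >= ESS_THRESHOLD
        )
    return report
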