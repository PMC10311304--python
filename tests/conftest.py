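import numpy as np
import pandas as pd
import pytest

import dosebayes as db


@pytest.fixture(scope="session")
def fast_mcmc() -> db.McmcConfig:
    """Reduced sampler settings for unit tests (not the scientific default)."""
    return db.McmcConfig(iterations=400, warmup=200, chains=2, seed=7, thin=1)


@pytest.fixture(scope="session")
def dream_matrix():
    """One synthetic 6x6 matrix with a well-identified ground truth."""
    truth = db.CombinationParams(
        E0=100, E1=10, E2=30, E3=5, C1=1.0, C2=2.0,
        H1=1.5, H2=1.2, alpha=5.0, sigma=2.0,
    )
    cfg = db.ScenarioConfig(shape="dream_6x6", generating_params=truth, seed=21)
    data, _ = db.generate_matrix(cfg)
    return data, truth


@pytest.fixture
def build_posterior():
    """Factory for hand-built posteriors from explicit parameter draws."""

    def _build(setting: str, rows: list[dict], data_hash: str = "hand-built"):
        df = pd.DataFrame(rows)
        df.insert(0, "draw", np.arange(len(rows)))
        df.insert(0, "chain", 0)
        return db.PosteriorSamples(
            setting=setting,
            draws=df,
            prior_cfg=db.PriorConfig(),
            data_hash=data_hash,
        )

    return _build


@pytest.fixture
def mono_params() -> db.MonotherapyParams:
    return db.MonotherapyParams(E0=100.0, E1=20.0, C=0.5, H=1.0, sigma=2.0)


@pytest.fixture
def combo_params() -> db.CombinationParams:
    return db.CombinationParams(
        E0=100.0, E1=25.0, E2=40.0, E3=10.0, C1=0.8, C2=1.6,
        H1=1.3, H2=0.9, alpha=2.0, sigma=1.5,
    )
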