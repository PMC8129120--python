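import numpy as np
import pandas as pd
import pytest

from spinescale import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort shared across tests."""
    return generate_cohort(SynthConfig(), seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort (still 12 mice, fewer spines)."""
    cfg = SynthConfig(dendrites_per_mouse=(2, 3), spines_per_dendrite=(10.0, 3.0))
    return generate_cohort(cfg, seed=5)


@pytest.fixture(scope="session")
def static_config():
    """Configuration with no dynamics, no noise and no turnover."""
    return SynthConfig(
        sleep_downscale=(0.0, 0.72),
        wake_upscale=(0.0, 1.3),
        learning_boost=(0.0, 2.2),
        volatility_log_sd=0.0,
        measurement_noise_sd=0.0,
        turnover=(0.0, 0.0),
    )


def random_nd_frame(rng, n_mice=6, spines_per_mouse=40):
    """Random long-format ND frame for oracle-equivalence tests."""
    rows = []
    for m in range(n_mice):
        mouse = f"M{m:02d}"
        for s in range(spines_per_mouse):
            x_pre = rng.lognormal(0, 0.7)
            x_post = x_pre * rng.lognormal(0, 0.4)
            rows.append(
                {
                    "mouse_id": mouse,
                    "condition": "S" if m % 2 == 0 else "SD",
                    "dendrite_id": f"{mouse}_d{s % 3}",
                    "spine_id": f"{mouse}_s{s:03d}",
                    "x_pre": x_pre,
                    "x_post": x_post,
                }
            )
    df = pd.DataFrame(rows)
    df["nd"] = (df.x_post - df.x_pre) / (df.x_post + df.x_pre)
    return df
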