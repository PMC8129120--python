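"""Configuration objects for the synthetic cohort generator and pipeline runs.

The defaults describe the emulated study: 12 mice imaged at five sessions
(T-24, T-17, T0, T7, T24 hours relative to motor training), split after
training into a sleep (S) and a sleep-deprivation (SD) group of 6 mice each,
with 4-6 dendrites per mouse and on average ~27 spines per dendrite
(~1500 spines in total).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

TIMEPOINTS = ("T-24", "T-17", "T0", "T7", "T24")
#: the four between-session intervals, in chronological order
INTERVALS = tuple(zip(TIMEPOINTS[:-1], TIMEPOINTS[1:]))
CONDITIONS = ("S", "SD")

#: fraction of time spent awake in each interval, per condition.  The first
#: two intervals precede the S/SD split and are identical: a mostly-sleep
#: light-phase interval (~36% wake) and a mostly-wake interval spanning the
#: dark phase plus training.  After training, S mice sleep (~38% wake) while
#: SD mice are kept awake (~99% wake); the final 17 h interval is mixed.
DEFAULT_STATE_SCHEDULE = {
    "S": (0.363, 0.568, 0.379, 0.505),
    "SD": (0.363, 0.568, 0.987, 0.438),
}

#: index of the interval that ends at T0, i.e. contains the training session
LEARNING_INTERVAL = 1
#: index of the post-training S/SD interval (T0 -> T7)
POST_TRAINING_INTERVAL = 2


@dataclass
class PerformanceModel:
    """Linear link from a mouse's net post-training ND to its session-2
    onset speed (mean of the first 3 trials, rpm).

    ``noise_sd`` may be given explicitly; if None it is calibrated per cohort
    from ``target_r`` and the realized spread of net ND so that the expected
    mouse-level Pearson correlation equals the target.
    """

    intercept: float = 12.0
    slope: float = -40.0
    target_r: float = -0.64
    noise_sd: float | None = None


@dataclass
class SynthConfig:
    """Parameters of the synthetic longitudinal spine cohort.

    Intensities are in arbitrary units on the natural scale; all
    state-dependent dynamics are multiplicative on intensity.
    """

    n_mice_per_condition: int = 6
    dendrites_per_mouse: tuple[int, int] = (4, 6)
    #: (mean, sd) of spines per dendrite; sampled as a rounded truncated normal
    spines_per_dendrite: tuple[float, float] = (27.3, 14.2)
    #: natural-scale (mean, variance) of baseline spine SEP-GluA1
    baseline_lognormal: tuple[float, float] = (1.0, 1.0)
    #: natural-scale (mean, variance) of baseline spine dsRed2
    dsred_lognormal: tuple[float, float] = (1.0, 1.0)
    #: natural-scale (mean, variance) of baseline shaft SEP-GluA1
    shaft_sep_lognormal: tuple[float, float] = (0.8, 0.3)
    #: natural-scale (mean, variance) of baseline shaft dsRed2 (normalizer)
    shaft_dsred_lognormal: tuple[float, float] = (1.0, 0.04)
    #: target natural-scale correlation spine SEP vs spine dsRed2
    dsred_coupling: float = 0.93
    #: target natural-scale correlation spine SEP vs shaft SEP
    shaft_coupling: float = 0.18
    #: per-interval within-spine log-scale fluctuation (biological volatility);
    #: controls the within-spine across-time autocorrelation, which the
    #: emulated study does not pin down
    volatility_log_sd: float = 0.20
    state_schedule: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_STATE_SCHEDULE.items()}
    )
    #: per-mouse jitter (sd) on the scheduled wake fraction
    wake_fraction_jitter: float = 0.02
    #: (proportion, multiplicative factor < 1): sleep-driven downscaling;
    #: the per-spine event probability is proportion * (1 - wake fraction)
    sleep_downscale: tuple[float, float] = (0.25, 0.72)
    #: (proportion, multiplicative factor > 1): wake-driven upscaling;
    #: event probability is proportion * wake fraction
    wake_upscale: tuple[float, float] = (0.03, 1.30)
    #: (proportion, multiplicative factor > 1): learning-boosted ("max")
    #: spines receive this factor over the interval ending at T0
    learning_boost: tuple[float, float] = (0.135, 2.2)
    #: probability that a learning-boosted spine resists sleep downscaling
    #: after training (smart down-selection of potentiated synapses)
    learning_protection: float = 1.0
    #: additive measurement noise sd (intensity units)
    measurement_noise_sd: float = 0.02
    #: (formation probability, elimination probability) per interval
    turnover: tuple[float, float] = (0.003, 0.003)
    performance_model: PerformanceModel = field(default_factory=PerformanceModel)
    seed: int = 0

    def validate(self) -> None:
        m, v = self.baseline_lognormal
        if m <= 0 or v <= 0:
            raise ValueError("baseline log-normal mean and variance must be > 0")
        for name in ("dsred_lognormal", "shaft_sep_lognormal", "shaft_dsred_lognormal"):
            mm, vv = getattr(self, name)
            if mm <= 0 or vv <= 0:
                raise ValueError(f"{name} mean and variance must be > 0")
        for name in ("dsred_coupling", "shaft_coupling"):
            if abs(getattr(self, name)) >= 1:
                raise ValueError(f"{name} must satisfy |r| < 1")
        for name in ("sleep_downscale", "wake_upscale", "learning_boost"):
            p, f = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} proportion must be in [0, 1]")
            if f <= 0:
                raise ValueError(f"{name} factor must be > 0")
        if self.sleep_downscale[1] >= 1 and self.sleep_downscale[0] > 0:
            raise ValueError("sleep_downscale factor must be < 1")
        if self.wake_upscale[1] <= 1 and self.wake_upscale[0] > 0:
            raise ValueError("wake_upscale factor must be > 1")
        p_form, p_elim = self.turnover
        if not (0 <= p_form <= 1 and 0 <= p_elim <= 1):
            raise ValueError("turnover probabilities must be in [0, 1]")
        n_intervals = len(INTERVALS)
        if (1 - p_elim) ** n_intervals / (1 + n_intervals * p_form) < 0.95:
            raise ValueError("turnover rates imply expected persistence < 0.95")
        if self.measurement_noise_sd < 0 or self.volatility_log_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if not 0 <= self.learning_protection <= 1:
            raise ValueError("learning_protection must be in [0, 1]")
        for cond in CONDITIONS:
            sched = self.state_schedule[cond]
            if len(sched) != len(INTERVALS):
                raise ValueError("state_schedule needs one wake fraction per interval")
            if any(not 0 <= w <= 1 for w in sched):
                raise ValueError("wake fractions must lie in [0, 1]")
        lo, hi = self.dendrites_per_mouse
        if not (1 <= lo <= hi):
            raise ValueError("dendrites_per_mouse must be an increasing positive range")
        if self.spines_per_dendrite[0] <= 0 or self.spines_per_dendrite[1] < 0:
            raise ValueError("spines_per_dendrite mean must be > 0, sd >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "performance_model" in d and isinstance(d["performance_model"], dict):
            d["performance_model"] = PerformanceModel(**d["performance_model"])
        for key in (
            "dendrites_per_mouse",
            "spines_per_dendrite",
            "baseline_lognormal",
            "dsred_lognormal",
            "shaft_sep_lognormal",
            "shaft_dsred_lognormal",
            "sleep_downscale",
            "wake_upscale",
            "learning_boost",
            "turnover",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "state_schedule" in d:
            d["state_schedule"] = {k: tuple(v) for k, v in d["state_schedule"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
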