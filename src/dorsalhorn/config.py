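"""Experiment configuration: fiber bundles, network parameters, protocol settings.

The canonical input is a brief painful stimulus applied at 500 ms to a
mixed nerve bundle of 380 fast mechanoreceptor (A-beta) fibers and 820 slow
nociceptor (C) fibers (roughly one rat nerve bundle).  Every fiber fires
spontaneously at 1 Hz; conduction delays are uniform on 0-20 ms for A-beta
and 90-300 ms for C, which spreads the C volley into the broad late
response that the pain markers measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .dh_model import DHParameters
from .injury import InjuryRule
from .spike_trains import FiberPopulationConfig

__all__ = [
    "abeta_config",
    "c_config",
    "ExperimentConfig",
    "DEFAULT_DURATION_MS",
    "DEFAULT_WINDOW_MS",
]

#: Total simulated time (ms); the C response is over well before the end.
DEFAULT_DURATION_MS = 1100.0

#: Marker window (ms): wide enough to contain the whole C response even
#: when injuries delay or spread it.
DEFAULT_WINDOW_MS = (600.0, 800.0)

#: Per-fiber stimulus pulse rate (Hz) and duration (ms).  The pulse rate is
#: a calibration-bound value: it was set, together with the network
#: parameters, so that the healthy C response crosses the 25 Hz pain
#: threshold while touch (A-beta) input alone never does.
DEFAULT_STIMULUS_RATE_HZ = 150.0
DEFAULT_STIMULUS_DURATION_MS = 20.0
DEFAULT_STIMULUS_ONSET_MS = 500.0
BACKGROUND_RATE_HZ = 1.0


def abeta_config(
    stimulus_rate: float = DEFAULT_STIMULUS_RATE_HZ,
    stimulus_onset: float = DEFAULT_STIMULUS_ONSET_MS,
) -> FiberPopulationConfig:
    """The mechanoreceptor bundle: 380 fast fibers, delays 0-20 ms."""
    return FiberPopulationConfig(
        n_fibers=380,
        background_rate=BACKGROUND_RATE_HZ,
        stimulus_rate=stimulus_rate,
        stimulus_onset=stimulus_onset,
        stimulus_duration=DEFAULT_STIMULUS_DURATION_MS,
        delay_min=0.0,
        delay_max=20.0,
    )


def c_config(
    stimulus_rate: float = DEFAULT_STIMULUS_RATE_HZ,
    stimulus_onset: float = DEFAULT_STIMULUS_ONSET_MS,
) -> FiberPopulationConfig:
    """The nociceptor bundle: 820 slow fibers, delays 90-300 ms."""
    return FiberPopulationConfig(
        n_fibers=820,
        background_rate=BACKGROUND_RATE_HZ,
        stimulus_rate=stimulus_rate,
        stimulus_onset=stimulus_onset,
        stimulus_duration=DEFAULT_STIMULUS_DURATION_MS,
        delay_min=90.0,
        delay_max=300.0,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment.

    ``abeta_rule``/``c_rule`` are applied to the injured subsets of the
    respective bundles (fractions ``abeta_fraction``/``c_fraction``).
    Randomness derives entirely from ``master_seed``; realization i of any
    protocol uses the i-th child seed, so sweeps that share a master seed
    share fiber spike trains per realization index (common random numbers).
    """

    abeta: FiberPopulationConfig = field(default_factory=abeta_config)
    c: FiberPopulationConfig = field(default_factory=c_config)
    params: DHParameters = field(default_factory=DHParameters.default)
    abeta_rule: InjuryRule = field(default_factory=InjuryRule)
    c_rule: InjuryRule = field(default_factory=InjuryRule)
    abeta_fraction: float = 0.0
    c_fraction: float = 0.0
    n_realizations: int = 30
    master_seed: int = 0
    duration: float = DEFAULT_DURATION_MS
    window: tuple[float, float] = DEFAULT_WINDOW_MS
    threshold: float = 25.0
    rate_dt: float = 1.0  # ms, fiber-rate bin width
    smoothing_width: float = 5.0  # ms, Gaussian kernel sd on the fiber rates
    sim_dt: float = 0.1  # ms, Euler step

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if not (0.0 <= self.abeta_fraction <= 1.0 and 0.0 <= self.c_fraction <= 1.0):
            raise ValueError("injured fractions must lie in [0, 1]")
        if not self.window[0] < self.window[1]:
            raise ValueError("window must satisfy t0 < tf")
        if self.duration <= 0 or self.rate_dt <= 0 or self.sim_dt <= 0:
            raise ValueError("duration and step sizes must be positive")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")

    def with_(self, **changes) -> "ExperimentConfig":
        return replace(self, **changes)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        fib = lambda f: {
            "n_fibers": f.n_fibers,
            "background_rate": f.background_rate,
            "stimulus_rate": f.stimulus_rate,
            "stimulus_onset": f.stimulus_onset,
            "stimulus_duration": f.stimulus_duration,
            "delay_min": f.delay_min,
            "delay_max": f.delay_max,
        }
        return {
            "abeta": fib(self.abeta),
            "c": fib(self.c),
            "params": self.params.to_dict(),
            "abeta_rule": self.abeta_rule.to_dict(),
            "c_rule": self.c_rule.to_dict(),
            "abeta_fraction": self.abeta_fraction,
            "c_fraction": self.c_fraction,
            "n_realizations": self.n_realizations,
            "master_seed": self.master_seed,
            "duration": self.duration,
            "window": list(self.window),
            "threshold": self.threshold,
            "rate_dt": self.rate_dt,
            "smoothing_width": self.smoothing_width,
            "sim_dt": self.sim_dt,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        kwargs = {}
        if "abeta" in d:
            kwargs["abeta"] = FiberPopulationConfig(**d.pop("abeta"))
        if "c" in d:
            kwargs["c"] = FiberPopulationConfig(**d.pop("c"))
        if "params" in d:
            kwargs["params"] = DHParameters.from_dict(d.pop("params"))
        for key in ("abeta_rule", "c_rule"):
            if key in d:
                kwargs[key] = InjuryRule.from_dict(d.pop(key))
        if "window" in d:
            kwargs["window"] = tuple(d.pop("window"))
        allowed = {
            "abeta_fraction", "c_fraction", "n_realizations", "master_seed",
            "duration", "threshold", "rate_dt", "smoothing_width", "sim_dt",
        }
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def realization_seeds(self, n: int | None = None) -> list[np.random.SeedSequence]:
        """Child seed sequences, one per realization index."""
        n = self.n_realizations if n is None else n
        return np.random.SeedSequence(self.master_seed).spawn(n)
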