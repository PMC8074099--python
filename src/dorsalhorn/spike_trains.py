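"""Poisson fiber spike trains, conduction delays and population rate traces.

Afferent input to the dorsal horn is modelled as a bundle of independent
fibers, each firing as an inhomogeneous Poisson process: a low spontaneous
background rate everywhere plus a brief high-rate pulse encoding the painful
stimulus.  Each fiber has a fixed conduction delay (a property of the axon,
drawn once per realization), and the bundle is reduced to a single average
firing-rate trace that drives the network model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "SpikeTrain",
    "FiberPopulationConfig",
    "PiecewiseConstantRate",
    "RateTrace",
    "generate_fiber_spikes",
    "apply_conduction_delay",
    "sample_population_delays",
    "population_rate",
    "stimulus_rate_profile",
    "generate_population",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of a single fiber, in ms.

    Times are strictly increasing and non-negative; duplicates are not
    allowed (two spikes cannot occupy the same instant on one axon).
    """

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D sequence")
        if t.size and t[0] < 0:
            raise ValueError("spike times must be non-negative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def shifted(self, delay: float) -> "SpikeTrain":
        """Return a copy with every event time shifted by +delay ms."""
        if delay < 0:
            raise ValueError("delay must be non-negative")
        return SpikeTrain(self.times + delay)

    @classmethod
    def from_line(cls, line: str) -> "SpikeTrain":
        """Parse one whitespace-separated line of spike times (ms)."""
        return cls(np.array([float(x) for x in line.split()], dtype=float))

    def to_line(self) -> str:
        return " ".join(f"{t:.6g}" for t in self.times)


@dataclass(frozen=True)
class FiberPopulationConfig:
    """Description of one afferent fiber bundle.

    Defaults describe neither bundle in particular; the canonical
    mechanoreceptor (A-beta) and nociceptor (C) bundles are built by
    :func:`abeta_config` and :func:`c_config` in :mod:`dorsalhorn.config`.
    """

    n_fibers: int
    background_rate: float  # Hz, spontaneous firing everywhere
    stimulus_rate: float  # Hz, added on the stimulus pulse
    stimulus_onset: float  # ms
    stimulus_duration: float  # ms
    delay_min: float  # ms, conduction delay lower bound
    delay_max: float  # ms, conduction delay upper bound

    def __post_init__(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.background_rate < 0 or self.stimulus_rate < 0:
            raise ValueError("rates must be non-negative")
        if not (0 <= self.delay_min <= self.delay_max):
            raise ValueError("need 0 <= delay_min <= delay_max")
        if self.stimulus_duration <= 0:
            raise ValueError("stimulus_duration must be positive")


@dataclass(frozen=True)
class PiecewiseConstantRate:
    """Piecewise-constant rate function r(t) on [0, T], rates in Hz.

    ``edges`` has one more entry than ``rates``; r(t) = rates[i] on
    [edges[i], edges[i+1]).
    """

    edges: np.ndarray  # ms, strictly increasing, edges[0] == 0
    rates: np.ndarray  # Hz

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "rates", r)
        if e.size != r.size + 1:
            raise ValueError("edges must have len(rates)+1 entries")
        if not np.all(np.diff(e) > 0):
            raise ValueError("edges must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("rates must be non-negative")

    @property
    def duration(self) -> float:
        return float(self.edges[-1] - self.edges[0])

    def integral(self) -> float:
        """Expected spike count over the whole support (rate integral)."""
        return float(np.sum(self.rates * np.diff(self.edges)) / 1000.0)


def stimulus_rate_profile(config: FiberPopulationConfig, duration: float) -> PiecewiseConstantRate:
    """Background rate everywhere plus the stimulus pulse, clipped to [0, duration]."""
    on = config.stimulus_onset
    off = config.stimulus_onset + config.stimulus_duration
    edges = [0.0]
    rates = []
    for a, b, r in [
        (0.0, on, config.background_rate),
        (on, off, config.background_rate + config.stimulus_rate),
        (off, duration, config.background_rate),
    ]:
        a, b = max(a, 0.0), min(b, duration)
        if b > a:
            edges.append(b)
            rates.append(r)
    return PiecewiseConstantRate(np.array(edges), np.array(rates))


@dataclass(frozen=True)
class RateTrace:
    """Uniformly sampled firing rate (Hz) versus time (ms)."""

    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if np.any(v < 0):
            raise ValueError("rates must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.values.size - 1)

    def at(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the trace at times ``t`` (ms)."""
        return np.interp(t, self.times, self.values)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_ms": self.times, "rate_hz": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RateTrace":
        import pandas as pd

        df = pd.read_csv(path)
        t = df["time_ms"].to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError("rate trace needs at least two samples")
        dt = float(t[1] - t[0])
        if not np.allclose(np.diff(t), dt):
            raise ValueError("rate trace must be uniformly sampled")
        return cls(t0=float(t[0]), dt=dt, values=df["rate_hz"].to_numpy(dtype=float))


def generate_fiber_spikes(
    rate_profile: PiecewiseConstantRate,
    duration: float,
    rng: np.random.Generator | int,
) -> SpikeTrain:
    """Draw one inhomogeneous-Poisson spike train from a piecewise-constant rate.

    Sampling is exact per piece: on each constant-rate segment the count is
    Poisson with mean rate*length and event times are i.i.d. uniform.  The
    event count over any interval is therefore Poisson with mean equal to
    the integral of the rate, as required of a Poisson process.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pieces = []
    for i, r in enumerate(rate_profile.rates):
        a = max(float(rate_profile.edges[i]), 0.0)
        b = min(float(rate_profile.edges[i + 1]), duration)
        if b <= a or r == 0.0:
            continue
        n = rng.poisson(r * (b - a) / 1000.0)
        if n:
            pieces.append(rng.uniform(a, b, size=n))
    if not pieces:
        return SpikeTrain(np.empty(0))
    t = np.sort(np.concatenate(pieces))
    # collapse the (measure-zero) chance of exact ties from float draws
    if t.size > 1:
        t = t[np.concatenate(([True], np.diff(t) > 0))]
    return SpikeTrain(t)


def apply_conduction_delay(train: SpikeTrain, delay: float) -> SpikeTrain:
    """Shift every event by the fiber's conduction delay (ms)."""
    return train.shifted(delay)


def sample_population_delays(
    config: FiberPopulationConfig, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw one conduction delay per fiber, uniform on [delay_min, delay_max].

    Delays model axonal conduction time, so each fiber's delay is fixed for
    the whole realization.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if config.delay_min == config.delay_max:
        return np.full(config.n_fibers, config.delay_min, dtype=float)
    return rng.uniform(config.delay_min, config.delay_max, size=config.n_fibers)


def population_rate(
    trains: list[SpikeTrain],
    n_fibers: int,
    duration: float,
    dt: float = 1.0,
    smoothing_width: float = 5.0,
) -> RateTrace:
    """Average the bundle's spikes into a firing-rate trace (Hz).

    Spikes are binned into [t, t+dt) bins; the binned rate is
    count / (n_fibers * dt) converted to Hz, so the total spike mass is
    conserved exactly before smoothing.  A Gaussian kernel of standard
    deviation ``smoothing_width`` ms (0 disables smoothing) then produces a
    smooth drive for the rate equations.

    Spikes outside [0, duration) are dropped with a logged warning.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_bins = int(round(duration / dt))
    if abs(n_bins * dt - duration) > 1e-9 * max(duration, 1.0):
        raise ValueError("duration must be an integer multiple of dt")
    all_times = (
        np.concatenate([tr.times for tr in trains]) if trains else np.empty(0)
    )
    inside = (all_times >= 0) & (all_times < duration)
    n_out = int(all_times.size - np.count_nonzero(inside))
    if n_out:
        logger.warning("dropping %d spikes outside [0, %g) ms", n_out, duration)
    counts, _ = np.histogram(all_times[inside], bins=n_bins, range=(0.0, n_bins * dt))
    rate = counts / (n_fibers * dt * 1e-3)  # Hz
    if smoothing_width > 0:
        rate = gaussian_filter1d(rate, sigma=smoothing_width / dt, mode="reflect")
        rate = np.maximum(rate, 0.0)
    return RateTrace(t0=0.0, dt=dt, values=rate)


def generate_population(
    config: FiberPopulationConfig,
    duration: float,
    seed: np.random.SeedSequence | int,
) -> tuple[list[SpikeTrain], np.ndarray]:
    """Generate undelayed spike trains and conduction delays for one bundle.

    Per-fiber randomness comes from seed sub-streams derived from the fiber
    index, so fiber i's train is reproducible regardless of how many other
    fibers are generated.  Returns ``(trains, delays)``; delays are *not*
    applied here because injury transforms act on the undelayed trains.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    delay_ss, fibers_ss = ss.spawn(2)
    delays = sample_population_delays(config, np.random.default_rng(delay_ss))
    profile = stimulus_rate_profile(config, duration)
    trains = [
        generate_fiber_spikes(profile, duration, np.random.default_rng(child))
        for child in fibers_ss.spawn(config.n_fibers)
    ]
    return trains, delays
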