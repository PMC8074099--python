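"""Quantitative pain markers computed from a projection-neuron rate trace.

The network's pain readout is the projection-population firing rate during
the window in which the slow (C-fiber) volley reaches the dorsal horn.  Five
scalar markers summarise that response relative to the calibrated painful
firing-rate threshold (25 Hz):

* ``a_total`` — trapezoidal area under the trace over the window (Hz*ms);
* ``a_star``  — area above the threshold (Hz*ms);
* ``pi_star`` — average above-threshold rate, a_star / window length (Hz);
* ``pi_max``  — peak rate in the window (Hz);
* ``n_crossings`` — number of times the trace crosses the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spike_trains import RateTrace

__all__ = ["PainMarkers", "compute_markers", "detect_response_window", "PAIN_THRESHOLD_HZ"]

logger = logging.getLogger(__name__)

#: Firing-rate threshold (Hz) above which the projection output is painful.
PAIN_THRESHOLD_HZ = 25.0

MARKER_NAMES = ("a_total", "a_star", "pi_star", "pi_max", "n_crossings")


@dataclass(frozen=True)
class PainMarkers:
    a_total: float  # Hz*ms
    a_star: float  # Hz*ms
    pi_star: float  # Hz
    pi_max: float  # Hz
    n_crossings: int
    t0: float  # ms, window start
    tf: float  # ms, window end
    threshold: float  # Hz

    def as_dict(self) -> dict:
        return {
            "a_total": self.a_total,
            "a_star": self.a_star,
            "pi_star": self.pi_star,
            "pi_max": self.pi_max,
            "n_crossings": self.n_crossings,
            "window_t0": self.t0,
            "window_tf": self.tf,
            "threshold": self.threshold,
        }


def _window_samples(trace: RateTrace, t0: float, tf: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample points covering [t0, tf]: exact endpoints plus interior grid points."""
    times = trace.times
    inner = times[(times > t0) & (times < tf)]
    t = np.concatenate(([t0], inner, [tf]))
    return t, trace.at(t)


def compute_markers(
    trace: RateTrace,
    t0: float,
    tf: float,
    threshold: float = PAIN_THRESHOLD_HZ,
) -> PainMarkers:
    """Compute the five pain markers of a rate trace on [t0, tf].

    Areas use the trapezoidal rule on the trace's sample grid (endpoints
    interpolated linearly).  A crossing is a strict sign change of
    (trace - threshold) between consecutive samples; samples exactly at
    threshold carry the previous sign so grid coincidences do not create
    spurious crossings.
    """
    if not t0 < tf:
        raise ValueError("need t0 < tf")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if t0 < trace.t0 - 1e-9 or tf > trace.t_end + 1e-9:
        raise ValueError(
            f"window [{t0}, {tf}] outside trace span [{trace.t0}, {trace.t_end}]"
        )
    t, v = _window_samples(trace, t0, tf)
    a_total = float(np.trapezoid(v, t))
    a_star = float(np.trapezoid(np.maximum(v - threshold, 0.0), t))
    pi_max = float(np.max(v))
    pi_star = a_star / abs(tf - t0)

    sign = np.sign(v - threshold)
    # exact-threshold samples inherit the previous sign (first sample: next
    # non-zero sign, so a trace starting at threshold is not a crossing)
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    nz = np.flatnonzero(sign)
    if nz.size:
        sign[: nz[0]] = sign[nz[0]]
    n_crossings = int(np.count_nonzero(np.diff(sign[sign != 0])))

    return PainMarkers(
        a_total=a_total,
        a_star=a_star,
        pi_star=pi_star,
        pi_max=pi_max,
        n_crossings=n_crossings,
        t0=t0,
        tf=tf,
        threshold=threshold,
    )


def detect_response_window(
    trace: RateTrace,
    fixed_window: tuple[float, float] = (600.0, 800.0),
    mode: str = "fixed",
    baseline_level: float = 5.0,
    search_range: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Return the (t0, tf) window over which markers are computed.

    ``fixed`` mode passes through ``fixed_window`` (default [600, 800] ms,
    wide enough to hold the whole C response even when injuries delay or
    spread it).  ``auto`` mode returns the longest contiguous interval
    within ``search_range`` where the trace exceeds ``baseline_level`` Hz;
    if no supra-baseline interval exists it falls back to the fixed window
    with a logged warning.
    """
    if mode not in ("fixed", "auto"):
        raise ValueError("mode must be 'fixed' or 'auto'")
    if mode == "fixed":
        return fixed_window
    lo, hi = search_range if search_range is not None else fixed_window
    times = trace.times
    mask = (times >= lo) & (times <= hi) & (trace.values > baseline_level)
    if not mask.any():
        logger.warning(
            "no supra-baseline response found in [%g, %g]; using fixed window", lo, hi
        )
        return fixed_window
    idx = np.flatnonzero(mask)
    # longest contiguous run of supra-baseline samples
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    lengths = ends - starts
    best = np.argmax(lengths)
    return float(times[idx[starts[best]]]), float(times[idx[ends[best]]])
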