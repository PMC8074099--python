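"""Firing-rate model of the dorsal-horn pain-processing circuit.

Three interacting populations evolve Wilson–Cowan-type rate dynamics

    tau_X dr_X/dt = -r_X + f_X(u_X(t)),    X in {P, E, I},

where f_X is a logistic response curve bounded by the population's maximal
rate and u_X is the weighted sum of presynaptic rates:

    u_P = w_AbP * Ab(t) + g(r_P) * w_CP * C(t) + w_EP * r_E - w_IP * r_I
    u_E = w_AbE * Ab(t) + w_CE * C(t)
    u_I = w_AbI * Ab(t)

Ab(t) and C(t) are the average firing rates of the mechanoreceptor (A-beta)
and nociceptor (C) fiber bundles.  Following gate-control circuitry, the
inhibitory interneurons are driven by the fast touch fibers and are the only
inhibitory projection onto the projection neurons, so a well-timed A-beta
volley suppresses the pain output.  g(r_P) is a bounded, monotonically
increasing function of the projection rate standing in for NMDA-type
synapses from the C fibers: the more active the projection population, the
stronger the nociceptive synapse, which produces wind-up.

Integration is fixed-step explicit Euler.  E and I receive no recurrent
input, so their updates are precomputed as a linear recursion over the
whole trace; P is stepped in a scalar loop because of the g(r_P) feedback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import yaml

from .spike_trains import RateTrace

__all__ = [
    "ResponseCurve",
    "NMDAParams",
    "DHParameters",
    "IntegrationError",
    "response_curve",
    "nmda_weight",
    "simulate_dh",
]


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass(frozen=True)
class ResponseCurve:
    """Logistic response curve f(u) = max_rate / (1 + exp(-gain*(u - half_drive)))."""

    max_rate: float  # Hz
    half_drive: float  # drive at which f = max_rate / 2
    gain: float  # steepness, 1 / drive-units

    def __post_init__(self) -> None:
        if self.max_rate <= 0:
            raise ValueError("max_rate must be positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def __call__(self, u):
        x = np.clip(self.gain * (np.asarray(u, dtype=float) - self.half_drive), -500, 500)
        return self.max_rate / (1.0 + np.exp(-x))


def response_curve(input_drive, curve_params: ResponseCurve):
    """Evaluate a population response curve at the given drive."""
    return curve_params(input_drive)


@dataclass(frozen=True)
class NMDAParams:
    """Activity-dependent multiplier on the C -> P synaptic weight.

    g(r) = baseline + (saturation - baseline) * r^h / (r^h + half_rate^h),
    a Hill function of the projection rate: g(0) = baseline and
    g(inf) = saturation, monotone in between.
    """

    baseline: float = 1.0
    saturation: float = 1.0
    half_rate_hz: float = 15.0
    hill: float = 2.0

    def __post_init__(self) -> None:
        if self.baseline <= 0 or self.saturation <= 0:
            raise ValueError("baseline and saturation must be positive")
        if self.saturation < self.baseline:
            raise ValueError("saturation must be >= baseline")
        if self.half_rate_hz <= 0 or self.hill <= 0:
            raise ValueError("half_rate_hz and hill must be positive")

    def __call__(self, r_p: float) -> float:
        if r_p <= 0:
            return self.baseline
        x = (r_p / self.half_rate_hz) ** self.hill
        return self.baseline + (self.saturation - self.baseline) * x / (1.0 + x)


def nmda_weight(r_p: float, nmda_params: NMDAParams) -> float:
    """Effective multiplier on w_CP at projection rate r_p (Hz)."""
    if r_p < 0:
        raise ValueError("r_p must be non-negative")
    return nmda_params(r_p)


@dataclass(frozen=True)
class DHParameters:
    """Complete parameter set of the dorsal-horn network."""

    tau_p: float  # ms
    tau_e: float  # ms
    tau_i: float  # ms
    w_ab_p: float  # A-beta -> P
    w_ab_e: float  # A-beta -> E
    w_ab_i: float  # A-beta -> I
    w_c_p: float  # C -> P (NMDA-modulated)
    w_c_e: float  # C -> E
    w_e_p: float  # E -> P
    w_i_p: float  # I -> P, enters with negative sign
    curve_p: ResponseCurve
    curve_e: ResponseCurve
    curve_i: ResponseCurve
    nmda: NMDAParams

    def __post_init__(self) -> None:
        if min(self.tau_p, self.tau_e, self.tau_i) <= 0:
            raise ValueError("time constants must be positive")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "time_constants_ms": {"p": self.tau_p, "e": self.tau_e, "i": self.tau_i},
            "weights": {
                "ab_to_p": self.w_ab_p,
                "ab_to_e": self.w_ab_e,
                "ab_to_i": self.w_ab_i,
                "c_to_p": self.w_c_p,
                "c_to_e": self.w_c_e,
                "e_to_p": self.w_e_p,
                "i_to_p": self.w_i_p,
            },
            "response_curves": {
                k: asdict(c)
                for k, c in {"p": self.curve_p, "e": self.curve_e, "i": self.curve_i}.items()
            },
            "nmda": asdict(self.nmda),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DHParameters":
        tc = d["time_constants_ms"]
        w = d["weights"]
        rc = d["response_curves"]
        return cls(
            tau_p=float(tc["p"]),
            tau_e=float(tc["e"]),
            tau_i=float(tc["i"]),
            w_ab_p=float(w["ab_to_p"]),
            w_ab_e=float(w["ab_to_e"]),
            w_ab_i=float(w["ab_to_i"]),
            w_c_p=float(w["c_to_p"]),
            w_c_e=float(w["c_to_e"]),
            w_e_p=float(w["e_to_p"]),
            w_i_p=float(w["i_to_p"]),
            curve_p=ResponseCurve(**rc["p"]),
            curve_e=ResponseCurve(**rc["e"]),
            curve_i=ResponseCurve(**rc["i"]),
            nmda=NMDAParams(**d["nmda"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "DHParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def default(cls) -> "DHParameters":
        """The shipped default parameter set (see data/default_params.yaml)."""
        ref = resources.files("dorsalhorn") / "data" / "default_params.yaml"
        with ref.open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- fixed points --------------------------------------------------

    def resting_state(self) -> tuple[float, float, float]:
        """Fixed point with zero afferent input (r_P, r_E, r_I).

        With no afferent drive the NMDA term vanishes (C = 0), so the
        projection fixed point is closed-form given r_E and r_I.
        """
        r_e = float(self.curve_e(0.0))
        r_i = float(self.curve_i(0.0))
        r_p = float(self.curve_p(self.w_e_p * r_e - self.w_i_p * r_i))
        return r_p, r_e, r_i


def _euler_filter(drive_f: np.ndarray, alpha: float, r0: float) -> np.ndarray:
    """Explicit-Euler relaxation r[k+1] = (1-alpha) r[k] + alpha f[k] as a linear filter."""
    from scipy.signal import lfilter

    out = lfilter([0.0, alpha], [1.0, -(1.0 - alpha)], drive_f)
    decay = (1.0 - alpha) ** np.arange(1, drive_f.size + 1)
    return out + r0 * np.concatenate(([1.0], decay[:-1]))


def simulate_dh(
    abeta_rate: RateTrace,
    c_rate: RateTrace,
    params: DHParameters,
    dt: float = 0.1,
    burn_in: float = 200.0,
    nmda_mode: str = "enabled",
) -> tuple[RateTrace, RateTrace, RateTrace]:
    """Integrate the P/E/I dynamics driven by the two fiber-rate traces.

    Parameters
    ----------
    abeta_rate, c_rate
        Average fiber rates on a common uniform grid (Hz vs ms).
    dt
        Euler step in ms; must not exceed the input grid spacing.  The
        actual step divides the grid spacing exactly.
    burn_in
        Duration (ms) integrated before t0 with the inputs frozen at their
        first sample, starting from the zero-input fixed point, so the
        network enters the trace at its background steady state.
    nmda_mode
        ``"enabled"`` uses the activity-dependent multiplier g(r_P);
        ``"frozen"`` pins it at its baseline value (no wind-up).

    Returns
    -------
    (r_P, r_E, r_I) as RateTraces on the input grid.
    """
    if nmda_mode not in ("enabled", "frozen"):
        raise ValueError("nmda_mode must be 'enabled' or 'frozen'")
    if abeta_rate.values.size != c_rate.values.size or abeta_rate.dt != c_rate.dt or abeta_rate.t0 != c_rate.t0:
        raise ValueError("A-beta and C rate traces must share the same grid")
    if dt <= 0 or dt > abeta_rate.dt + 1e-12:
        raise ValueError("need 0 < dt <= input trace dt")

    grid_dt = abeta_rate.dt
    n_sub = max(1, int(round(grid_dt / dt)))
    h = grid_dt / n_sub  # actual Euler step, ms
    n_grid = abeta_rate.values.size
    n_steps = (n_grid - 1) * n_sub + 1

    t_fine = abeta_rate.t0 + h * np.arange(n_steps)
    ab = np.interp(t_fine, abeta_rate.times, abeta_rate.values)
    c = np.interp(t_fine, c_rate.times, c_rate.values)

    a_p, a_e, a_i = h / params.tau_p, h / params.tau_e, h / params.tau_i
    if max(a_p, a_e, a_i) >= 2.0:
        raise ValueError("Euler step too large for the time constants (unstable)")

    r_p0, r_e0, r_i0 = params.resting_state()

    # burn-in with inputs frozen at the first sample
    n_burn = int(round(burn_in / h))
    ab0, c0 = ab[0], c[0]
    f_e0 = float(params.curve_e(params.w_ab_e * ab0 + params.w_c_e * c0))
    f_i0 = float(params.curve_i(params.w_ab_i * ab0))
    r_e, r_i, r_p = r_e0, r_i0, r_p0
    g = params.nmda if nmda_mode == "enabled" else (lambda r: params.nmda.baseline)
    fp = params.curve_p
    w_ab_p, w_c_p, w_e_p, w_i_p = params.w_ab_p, params.w_c_p, params.w_e_p, params.w_i_p
    for _ in range(n_burn):
        u_p = w_ab_p * ab0 + g(r_p) * w_c_p * c0 + w_e_p * r_e - w_i_p * r_i
        r_p += a_p * (-r_p + float(fp(u_p)))
        r_e += a_e * (-r_e + f_e0)
        r_i += a_i * (-r_i + f_i0)

    # feedforward populations over the whole trace in one pass
    f_e = np.asarray(params.curve_e(params.w_ab_e * ab + params.w_c_e * c))
    f_i = np.asarray(params.curve_i(params.w_ab_i * ab))
    re_t = np.maximum(_euler_filter(f_e, a_e, r_e), 0.0)
    ri_t = np.maximum(_euler_filter(f_i, a_i, r_i), 0.0)
    if not (np.all(np.isfinite(re_t)) and np.all(np.isfinite(ri_t))):
        raise IntegrationError("non-finite interneuron state during integration")

    # projection population: scalar Euler loop (NMDA feedback on its own rate)
    max_p = fp.max_rate
    gain_p, half_p = fp.gain, fp.half_drive
    nmda = params.nmda
    frozen = nmda_mode == "frozen"
    base, sat, half_r, hill = nmda.baseline, nmda.saturation, nmda.half_rate_hz, nmda.hill
    rp_t = np.empty(n_steps)
    rp = r_p
    exp = math.exp
    for k in range(n_steps):
        rp_t[k] = rp
        if k == n_steps - 1:
            break
        if frozen or rp <= 0.0:
            gk = base
        else:
            x = (rp / half_r) ** hill
            gk = base + (sat - base) * x / (1.0 + x)
        u = w_ab_p * ab[k] + gk * w_c_p * c[k] + w_e_p * re_t[k] - w_i_p * ri_t[k]
        z = gain_p * (u - half_p)
        if z > 500.0:
            fu = max_p
        elif z < -500.0:
            fu = 0.0
        else:
            fu = max_p / (1.0 + exp(-z))
        rp = rp + a_p * (-rp + fu)
        if rp < 0.0:
            rp = 0.0
        if not math.isfinite(rp):
            raise IntegrationError(
                f"non-finite projection rate at step {k + 1} (t = {t_fine[k + 1]:.3f} ms)"
            )

    sel = slice(None, None, n_sub)
    t0 = abeta_rate.t0
    return (
        RateTrace(t0, grid_dt, rp_t[sel]),
        RateTrace(t0, grid_dt, re_t[sel]),
        RateTrace(t0, grid_dt, ri_t[sel]),
    )
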