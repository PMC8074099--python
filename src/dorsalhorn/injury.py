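"""Phenomenological spike-train distortions caused by axonal damage.

Focal axonal swellings and demyelination distort spike propagation rather
than silencing it outright.  Each rule here is an input/output transform on
a single fiber's spike train:

* ``evoked``      — an input spike may trigger a short burst of k extra spikes;
* ``block``       — conduction alternates periodically between total block
                    and faithful transmission (square-wave gate);
* ``refractory``  — an enlarged refractory period deletes spikes that follow
                    the previous surviving spike too closely (dead time);
* ``delay``       — all spikes are shifted later by a fixed conduction delay;
* ``total_block`` / ``none`` — the trivial limits (delete all / identity).

Injuries are assigned to a random subset of fibers and the chosen rule is
applied to each injured fiber's whole train for the realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spike_trains import SpikeTrain

__all__ = [
    "InjuryRule",
    "VARIANTS",
    "evoke_potentials",
    "intermittent_block",
    "increase_refractoriness",
    "delay_train",
    "apply_rule",
    "assign_injuries",
]

VARIANTS = ("none", "total_block", "evoked", "block", "refractory", "delay")


@dataclass(frozen=True)
class InjuryRule:
    """One injury rule and its parameters.

    Parameters irrelevant to the chosen variant are ignored.  ``omega`` is an
    angular frequency in rad/ms; the conduction gate has period 2*pi/omega ms
    with a 50% duty cycle.
    """

    variant: str = "none"
    p_evoke: float = 0.0  # per-input-spike probability of a burst (evoked)
    k_extra: int = 0  # number of extra spikes per burst (evoked)
    spacing: float = 2.0  # ms between burst spikes (evoked)
    omega: float = np.pi / 20.0  # rad/ms gate angular frequency (block)
    phase_offset: float = 0.0  # ms, gate starts passing at this time (block)
    tau: float = 0.0  # ms enlarged refractory period (refractory)
    d: float = 0.0  # ms spike-train delay (delay)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown injury variant {self.variant!r}; expected one of {VARIANTS}")
        if not 0.0 <= self.p_evoke <= 1.0:
            raise ValueError("p_evoke must lie in [0, 1]")
        if self.k_extra < 0:
            raise ValueError("k_extra must be >= 0")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.tau < 0 or self.d < 0:
            raise ValueError("tau and d must be non-negative")

    @classmethod
    def from_dict(cls, spec: dict) -> "InjuryRule":
        spec = dict(spec)
        variant = spec.pop("variant", None)
        if variant is None:
            raise ValueError("injury rule needs a 'variant' key")
        allowed = {
            "p_evoke", "k_extra", "spacing", "omega", "phase_offset", "tau", "d",
        }
        unknown = set(spec) - allowed
        if unknown:
            raise ValueError(f"unknown injury rule parameters: {sorted(unknown)}")
        return cls(variant=variant, **spec)

    def to_dict(self) -> dict:
        out = {"variant": self.variant}
        keep = {
            "evoked": ("p_evoke", "k_extra", "spacing"),
            "block": ("omega", "phase_offset"),
            "refractory": ("tau",),
            "delay": ("d",),
        }.get(self.variant, ())
        for k in keep:
            out[k] = getattr(self, k)
        return out


def evoke_potentials(
    train: SpikeTrain,
    p_evoke: float,
    k_extra: int,
    spacing: float = 2.0,
    rng: np.random.Generator | int = 0,
) -> SpikeTrain:
    """Each input spike independently triggers k extra spikes with prob. p.

    Extra spikes are appended at +spacing, +2*spacing, ... after the trigger
    (a short burst).  Evoked spikes never trigger further bursts.  Every
    input spike is kept; coincident times after merging are collapsed.
    """
    if not 0.0 <= p_evoke <= 1.0:
        raise ValueError("p_evoke must lie in [0, 1]")
    if k_extra < 0:
        raise ValueError("k_extra must be >= 0")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t = train.times
    # always consume the RNG stream identically regardless of k_extra so
    # that the same seed yields the same trigger pattern
    triggers = rng.random(t.size) < p_evoke
    if t.size == 0 or k_extra == 0 or not triggers.any():
        return SpikeTrain(t.copy())
    extras = (
        t[triggers, None] + spacing * np.arange(1, k_extra + 1)[None, :]
    ).ravel()
    out = np.unique(np.concatenate([t, extras]))
    return SpikeTrain(out)


def intermittent_block(
    train: SpikeTrain, omega: float, phase_offset: float = 0.0
) -> SpikeTrain:
    """Periodic conduction gate: pass for half a period, block for half.

    The gate has period T = 2*pi/omega ms and starts in the passing phase at
    t = phase_offset.  A spike at time t survives iff
    ((t - phase_offset) mod T) < T/2.  Deterministic.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    period = 2.0 * np.pi / omega
    keep = ((train.times - phase_offset) % period) < period / 2.0
    return SpikeTrain(train.times[keep])


def increase_refractoriness(train: SpikeTrain, tau: float) -> SpikeTrain:
    """Delete spikes closer than tau ms to the previous *surviving* spike.

    This is a dead-time thinning: scanning left to right, a spike is removed
    when its interval to the most recent kept spike is < tau; the first
    spike always survives.  For a homogeneous Poisson train of rate r the
    surviving rate tends to r / (1 + r*tau), so high-rate trains are
    disproportionately attenuated.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    t = train.times
    if tau == 0 or t.size == 0:
        return SpikeTrain(t.copy())
    kept = [t[0]]
    last = t[0]
    for x in t[1:]:
        if x - last >= tau:
            kept.append(x)
            last = x
    return SpikeTrain(np.array(kept))


def delay_train(train: SpikeTrain, d: float) -> SpikeTrain:
    """Shift the whole spike train later by d ms (injury-induced slowing)."""
    return train.shifted(d)


def apply_rule(
    train: SpikeTrain, rule: InjuryRule, rng: np.random.Generator | int = 0
) -> SpikeTrain:
    """Dispatch a train through the rule's transform.

    ``none`` is the identity (faithful conduction, y = 1*x) and
    ``total_block`` deletes everything (y = 0*x).
    """
    if rule.variant == "none":
        return SpikeTrain(train.times.copy())
    if rule.variant == "total_block":
        return SpikeTrain(np.empty(0))
    if rule.variant == "evoked":
        return evoke_potentials(train, rule.p_evoke, rule.k_extra, rule.spacing, rng)
    if rule.variant == "block":
        return intermittent_block(train, rule.omega, rule.phase_offset)
    if rule.variant == "refractory":
        return increase_refractoriness(train, rule.tau)
    if rule.variant == "delay":
        return delay_train(train, rule.d)
    raise ValueError(f"unknown injury variant {rule.variant!r}")


def assign_injuries(
    n_fibers: int, fraction: float, rng: np.random.Generator | int = 0
) -> np.ndarray:
    """Choose which fibers of a bundle are injured.

    Returns a sorted array of round(fraction * n_fibers) distinct fiber
    indices drawn uniformly without replacement (round half away from
    zero).  Deterministic given the generator state.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_injured = int(np.floor(fraction * n_fibers + 0.5))
    if n_injured == 0:
        return np.empty(0, dtype=int)
    return np.sort(rng.choice(n_fibers, size=n_injured, replace=False))
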