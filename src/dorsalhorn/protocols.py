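"""End-to-end injury protocols: healthy baseline, sweeps and the mixed grid.

A *realization* is one complete pass through the pipeline: draw per-fiber
Poisson spike trains, injure a random subset of fibers, apply conduction
delays, reduce each bundle to its average rate, integrate the dorsal-horn
network and compute the pain markers of the projection output.

All protocols use common random numbers: realization i of every point in a
sweep shares the same fiber spike trains and conduction delays (derived
from the i-th child of the master seed), with injuries applied on top.
This pairing isolates the injury effect and sharpens the location of
optima and contours at modest realization counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .dh_model import simulate_dh
from .injury import InjuryRule, apply_rule, assign_injuries
from .markers import MARKER_NAMES, PainMarkers, compute_markers
from .spike_trains import (
    RateTrace,
    SpikeTrain,
    apply_conduction_delay,
    generate_population,
    population_rate,
)

__all__ = [
    "run_realization",
    "sweep_injury_fraction",
    "sweep_delay",
    "mixed_grid",
    "summarize",
    "SweepResult",
    "MixedGridResult",
]

logger = logging.getLogger(__name__)


def _fiber_rng(base_ss: np.random.SeedSequence, fiber_index: int) -> np.random.Generator:
    """Deterministic per-fiber stream, independent of which fibers are injured."""
    child = np.random.SeedSequence(
        entropy=base_ss.entropy, spawn_key=tuple(base_ss.spawn_key) + (fiber_index,)
    )
    return np.random.default_rng(child)


@dataclass
class _BaseRealization:
    """Healthy fiber draws for one realization index, reusable across sweep points."""

    ab_trains: list[SpikeTrain]
    ab_delays: np.ndarray
    c_trains: list[SpikeTrain]
    c_delays: np.ndarray
    ab_injury_ss: np.random.SeedSequence
    c_injury_ss: np.random.SeedSequence
    ab_rule_ss: np.random.SeedSequence
    c_rule_ss: np.random.SeedSequence
    _rate_cache: dict = field(default_factory=dict)


def _draw_base(config: ExperimentConfig, seed) -> _BaseRealization:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ab_gen, c_gen, ab_inj, c_inj, ab_rule, c_rule = ss.spawn(6)
    ab_trains, ab_delays = generate_population(config.abeta, config.duration, ab_gen)
    c_trains, c_delays = generate_population(config.c, config.duration, c_gen)
    return _BaseRealization(
        ab_trains, ab_delays, c_trains, c_delays, ab_inj, c_inj, ab_rule, c_rule
    )


def _population_trace(
    config: ExperimentConfig,
    base: _BaseRealization,
    population: str,
    rule: InjuryRule,
    fraction: float,
) -> RateTrace:
    """Injure, delay and average one bundle; healthy traces are cached."""
    if population == "abeta":
        trains, delays = base.ab_trains, base.ab_delays
        injury_ss, rule_ss = base.ab_injury_ss, base.ab_rule_ss
        n = config.abeta.n_fibers
    else:
        trains, delays = base.c_trains, base.c_delays
        injury_ss, rule_ss = base.c_injury_ss, base.c_rule_ss
        n = config.c.n_fibers

    healthy = fraction == 0.0 or rule.variant == "none"
    cache_key = population if healthy else None
    if cache_key is not None and cache_key in base._rate_cache:
        return base._rate_cache[cache_key]

    if healthy:
        injured: set[int] = set()
    else:
        injured = set(
            assign_injuries(n, fraction, np.random.default_rng(injury_ss)).tolist()
        )
    out = []
    for i, tr in enumerate(trains):
        if i in injured:
            tr = apply_rule(tr, rule, _fiber_rng(rule_ss, i))
        out.append(apply_conduction_delay(tr, delays[i]))
    trace = population_rate(
        out, n, config.duration, config.rate_dt, config.smoothing_width
    )
    if cache_key is not None:
        base._rate_cache[cache_key] = trace
    return trace


def _finish(
    config: ExperimentConfig, base: _BaseRealization
) -> tuple[dict[str, RateTrace], PainMarkers]:
    ab = _population_trace(config, base, "abeta", config.abeta_rule, config.abeta_fraction)
    c = _population_trace(config, base, "c", config.c_rule, config.c_fraction)
    r_p, r_e, r_i = simulate_dh(ab, c, config.params, dt=config.sim_dt)
    mk = compute_markers(r_p, config.window[0], config.window[1], config.threshold)
    traces = {"abeta": ab, "c": c, "r_p": r_p, "r_e": r_e, "r_i": r_i}
    return traces, mk


def run_realization(
    config: ExperimentConfig, seed
) -> tuple[dict[str, RateTrace], PainMarkers]:
    """Run one full realization; reproducible from (config, seed).

    Returns the five traces (A-beta drive, C drive, and the three
    population outputs) and the pain markers of the projection output.
    """
    try:
        return _finish(config, _draw_base(config, seed))
    except Exception as exc:
        raise type(exc)(f"realization with seed {seed!r} failed: {exc}") from exc


def _marker_rows(
    config: ExperimentConfig,
    bases: list[_BaseRealization],
    **grid_cols,
) -> list[dict]:
    rows = []
    for i, base in enumerate(bases):
        _, mk = _finish(config, base)
        row = {"realization": i, **grid_cols, **mk.as_dict(), "seed": config.master_seed}
        rows.append(row)
    return rows


@dataclass
class SweepResult:
    """Raw per-realization markers and per-grid-point summary of a 1-D sweep."""

    grid_name: str
    grid: np.ndarray
    raw: pd.DataFrame
    summary: pd.DataFrame  # one row per grid value: mean_<m>, sd_<m>

    @classmethod
    def from_raw(cls, grid_name: str, grid: np.ndarray, raw: pd.DataFrame) -> "SweepResult":
        g = raw.groupby(grid_name)
        pieces = {grid_name: np.asarray(sorted(raw[grid_name].unique()))}
        for m in MARKER_NAMES:
            pieces[f"mean_{m}"] = g[m].mean().to_numpy()
            pieces[f"sd_{m}"] = g[m].std(ddof=1).fillna(0.0).to_numpy()
        return cls(grid_name, np.asarray(grid, dtype=float), raw, pd.DataFrame(pieces))


def _bases(config: ExperimentConfig, n: int | None) -> list[_BaseRealization]:
    seeds = config.realization_seeds(n)
    return [_draw_base(config, ss) for ss in seeds]


def sweep_injury_fraction(
    config: ExperimentConfig,
    rule: InjuryRule,
    fractions,
    n_realizations: int | None = None,
    population: str = "c",
) -> SweepResult:
    """Pain markers versus the injured fraction of one fiber bundle.

    Applies ``rule`` to ``fraction`` of the chosen population (default the
    nociceptor bundle) for each fraction in the sorted grid, with
    ``n_realizations`` paired realizations per point.
    """
    fractions = np.asarray(sorted(fractions), dtype=float)
    if fractions.size == 0:
        raise ValueError("fraction grid must be non-empty")
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if population not in ("abeta", "c"):
        raise ValueError("population must be 'abeta' or 'c'")
    bases = _bases(config, n_realizations)
    rows = []
    for frac in fractions:
        if population == "c":
            cfg = config.with_(c_rule=rule, c_fraction=float(frac))
        else:
            cfg = config.with_(abeta_rule=rule, abeta_fraction=float(frac))
        rows += _marker_rows(cfg, bases, fraction=float(frac))
    return SweepResult.from_raw("fraction", fractions, pd.DataFrame(rows))


def sweep_delay(
    config: ExperimentConfig,
    fraction_abeta: float,
    delays,
    n_realizations: int | None = None,
) -> tuple[SweepResult, float]:
    """A_total versus the injury delay applied to a fraction of A-beta fibers.

    Returns the sweep result and the delay minimizing the mean total area
    (the optimal pain-inhibiting delay).
    """
    delays = np.asarray(sorted(delays), dtype=float)
    if delays.size == 0 or np.any(delays < 0):
        raise ValueError("delays must be a non-empty grid of non-negative values")
    bases = _bases(config, n_realizations)
    rows = []
    for d in delays:
        cfg = config.with_(
            abeta_rule=InjuryRule(variant="delay", d=float(d)),
            abeta_fraction=fraction_abeta,
        )
        rows += _marker_rows(cfg, bases, delay=float(d))
    result = SweepResult.from_raw("delay", delays, pd.DataFrame(rows))
    means = result.summary.set_index("delay")["mean_a_total"]
    optimal = float(means.idxmin())
    return result, optimal


@dataclass
class MixedGridResult:
    """Percent change of A_total over a (C-fraction x A-beta-fraction) grid."""

    c_fractions: np.ndarray
    abeta_fractions: np.ndarray
    percent_change: np.ndarray  # shape (len(abeta_fractions), len(c_fractions))
    raw: pd.DataFrame
    zero_contour: pd.DataFrame  # columns c_fraction, abeta_fraction

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, af in enumerate(self.abeta_fractions):
            for j, cf in enumerate(self.c_fractions):
                recs.append(
                    {
                        "abeta_fraction": af,
                        "c_fraction": cf,
                        "percent_change_a_total": self.percent_change[i, j],
                    }
                )
        return pd.DataFrame(recs)


def _zero_crossings(grid_x, grid_y, z) -> pd.DataFrame:
    """Linear-interpolated zero-level points along both grid directions."""
    pts = []
    n_y, n_x = z.shape
    for i in range(n_y):
        for j in range(n_x - 1):
            a, b = z[i, j], z[i, j + 1]
            if a == 0.0:
                pts.append((grid_x[j], grid_y[i]))
            if a * b < 0:
                frac = a / (a - b)
                pts.append((grid_x[j] + frac * (grid_x[j + 1] - grid_x[j]), grid_y[i]))
    for j in range(n_x):
        for i in range(n_y - 1):
            a, b = z[i, j], z[i + 1, j]
            if a * b < 0:
                frac = a / (a - b)
                pts.append((grid_x[j], grid_y[i] + frac * (grid_y[i + 1] - grid_y[i])))
    return pd.DataFrame(pts, columns=["c_fraction", "abeta_fraction"]).drop_duplicates()


def mixed_grid(
    config: ExperimentConfig,
    c_fractions,
    abeta_fractions,
    evoked_rule: InjuryRule | None = None,
    delay_rule: InjuryRule | None = None,
    n_realizations: int | None = None,
) -> MixedGridResult:
    """The tug-of-war protocol: evoked potentials on C versus delays on A-beta.

    For every (c_fraction, abeta_fraction) cell the percent change of
    A_total relative to the paired healthy realization is averaged over
    realizations:  100 * (A_injured - A_healthy) / A_healthy, per seed.
    The zero-level contour separates net pain increase from net inhibition.
    """
    evoked_rule = evoked_rule or InjuryRule(variant="evoked", p_evoke=0.1, k_extra=2)
    delay_rule = delay_rule or InjuryRule(variant="delay", d=125.0)
    c_fractions = np.asarray(sorted(c_fractions), dtype=float)
    abeta_fractions = np.asarray(sorted(abeta_fractions), dtype=float)
    if c_fractions.size == 0 or abeta_fractions.size == 0:
        raise ValueError("fraction grids must be non-empty")
    bases = _bases(config, n_realizations)

    healthy_cfg = config.with_(abeta_fraction=0.0, c_fraction=0.0)
    healthy_a = np.array([_finish(healthy_cfg, b)[1].a_total for b in bases])

    pc = np.empty((abeta_fractions.size, c_fractions.size))
    rows = []
    for i, af in enumerate(abeta_fractions):
        for j, cf in enumerate(c_fractions):
            cfg = config.with_(
                abeta_rule=delay_rule,
                abeta_fraction=float(af),
                c_rule=evoked_rule,
                c_fraction=float(cf),
            )
            per_seed = []
            for k, base in enumerate(bases):
                _, mk = _finish(cfg, base)
                change = 100.0 * (mk.a_total - healthy_a[k]) / healthy_a[k]
                per_seed.append(change)
                rows.append(
                    {
                        "realization": k,
                        "abeta_fraction": float(af),
                        "c_fraction": float(cf),
                        "a_total": mk.a_total,
                        "a_total_healthy": healthy_a[k],
                        "percent_change": change,
                    }
                )
            pc[i, j] = np.mean(per_seed)
    contour = _zero_crossings(c_fractions, abeta_fractions, pc)
    return MixedGridResult(c_fractions, abeta_fractions, pc, pd.DataFrame(rows), contour)


def summarize(result, outdir, figures: bool = False, prefix: str = "sweep"):
    """Write CSV tables (and optional figures) for a sweep or grid result.

    Returns the list of written paths.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if isinstance(result, SweepResult):
        if result.raw.empty:
            raise ValueError("empty sweep result")
        raw_path = outdir / f"{prefix}_raw.csv"
        sum_path = outdir / f"{prefix}_summary.csv"
        result.raw.to_csv(raw_path, index=False)
        result.summary.to_csv(sum_path, index=False)
        written += [raw_path, sum_path]
        if figures:
            written.append(_plot_sweep(result, outdir / f"{prefix}_markers.png"))
    elif isinstance(result, MixedGridResult):
        if result.raw.empty:
            raise ValueError("empty grid result")
        grid_path = outdir / f"{prefix}_grid.csv"
        contour_path = outdir / f"{prefix}_zero_contour.csv"
        raw_path = outdir / f"{prefix}_raw.csv"
        result.to_frame().to_csv(grid_path, index=False)
        result.zero_contour.to_csv(contour_path, index=False)
        result.raw.to_csv(raw_path, index=False)
        written += [grid_path, contour_path, raw_path]
        if figures:
            written.append(_plot_grid(result, outdir / f"{prefix}_heatmap.png"))
    else:
        raise TypeError("result must be a SweepResult or MixedGridResult")
    return written


def _plot_sweep(result: SweepResult, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 5, figsize=(18, 3.2))
    for ax, m in zip(axes, MARKER_NAMES):
        ax.errorbar(
            result.summary[result.grid_name],
            result.summary[f"mean_{m}"],
            yerr=result.summary[f"sd_{m}"],
            marker="o",
            capsize=2,
        )
        ax.set_xlabel(result.grid_name)
        ax.set_title(m)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return path


def _plot_grid(result: MixedGridResult, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.2, 4.2))
    vmax = np.max(np.abs(result.percent_change)) or 1.0
    im = ax.pcolormesh(
        result.c_fractions,
        result.abeta_fractions,
        result.percent_change,
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        shading="nearest",
    )
    if not result.zero_contour.empty:
        ax.plot(
            result.zero_contour["c_fraction"],
            result.zero_contour["abeta_fraction"],
            "g.",
            ms=4,
        )
    ax.set_xlabel("fraction of C fibers injured (evoked potentials)")
    ax.set_ylabel("fraction of A-beta fibers injured (delay)")
    fig.colorbar(im, ax=ax, label="% change of A_total")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
    return path
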