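"""Population statistics: growth-mode fits, cycle times, sizes, asymmetry, survival.

Works identically on simulated trees and on trees reconstructed from rendered
movies (same schema).  Conventions:

* exponential fits are ordinary least squares on ``log2(count)`` vs time, so
  the doubling time is the inverse slope and r² is computed on the log scale;
* linear fits are OLS on raw counts; with ``auto_window`` the "linear part"
  is the longest suffix of the series (after the post-shift transition
  period) whose r² clears a floor;
* the two are compared only through :func:`classify_growth_mode`, which
  evaluates both models on one common window;
* size asymmetry uses medians (robust to the lognormal cycle-time skew); the
  age-corrected variant aligns all births at time zero and reads sizes at a
  common age, removing the mother-older-than-daughter confound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .population_sim import CountSeries, LineageTree, StressParams

__all__ = [
    "GrowthFit",
    "SizeDistributions",
    "AsymmetryStats",
    "StressOutcome",
    "fit_exponential",
    "fit_linear",
    "classify_growth_mode",
    "interdivision_stats",
    "mother_interdivision_times",
    "size_distributions",
    "vacuole_fraction",
    "stress_survival",
    "pool_counts",
    "plot_counts",
    "plot_size_histograms",
]


@dataclass
class GrowthFit:
    """Result of a growth-curve fit.

    For ``model == 'exponential'``: ``tau`` is the doubling time (min) and
    ``rate`` the specific growth rate ln(2)/tau (1/min).  For
    ``model == 'linear'``: ``rate`` is the slope (cells/min) and ``tau``, if
    set, a per-mother inter-division summary supplied by the caller.
    """

    model: str
    tau: float | None
    rate: float | None
    r2: float
    fit_window: tuple[float, float]
    flag: str | None = None


@dataclass
class SizeDistributions:
    """Per-class size samples at one time point and their relative gap."""

    mother_sizes: np.ndarray
    daughter_sizes: np.ndarray
    gap: float | None  # 1 - median(daughter)/median(mother)
    age_corrected: bool
    flag: str | None = None


@dataclass
class AsymmetryStats:
    """Vacuole partition fractions per division, plus time-binned means.

    ``per_division`` columns: time, mother_fraction, daughter_fraction
    (fractions of the pre-loss pool; they sum to 1).  ``binned`` indexes bins
    by their left edge in minutes.
    """

    per_division: pd.DataFrame
    binned: pd.DataFrame
    n_undefined: int = 0


@dataclass
class StressOutcome:
    """Implosion/recovery tallies for one cell class after a stress."""

    n_exposed: int
    n_imploded: int
    n_recovered: int
    implosion_fraction: float
    implosion_se: float  # binomial standard error
    recovery_delays: np.ndarray = field(default_factory=lambda: np.empty(0))


def _positive_block(times: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Indices of the longest contiguous run of strictly positive counts."""
    pos = counts > 0
    best, cur_start, best_len = None, None, 0
    for i, p in enumerate(np.append(pos, False)):
        if p and cur_start is None:
            cur_start = i
        elif not p and cur_start is not None:
            if i - cur_start > best_len:
                best, best_len = (cur_start, i), i - cur_start
            cur_start = None
    if best is None:
        raise ValueError("count series has no positive samples to fit")
    return np.arange(best[0], best[1])


def fit_exponential(
    series: CountSeries, fit_window: tuple[float, float] | None = None
) -> GrowthFit:
    """OLS fit of log2(count) vs time; doubling time = 1/slope."""
    t, n = series.times, series.total
    if fit_window is not None:
        sel = (t >= fit_window[0]) & (t <= fit_window[1])
        t, n = t[sel], n[sel]
    flag = None
    if np.any(n <= 0):
        idx = _positive_block(t, n)
        t, n = t[idx], n[idx]
        flag = "window shrunk to longest positive run"
    if len(t) < 4:
        raise ValueError("need at least 4 positive samples for an exponential fit")
    res = stats.linregress(t, np.log2(n))
    if res.slope <= 0:
        return GrowthFit(
            model="exponential",
            tau=None,
            rate=float(res.slope * math.log(2)),
            r2=float(res.rvalue**2),
            fit_window=(float(t[0]), float(t[-1])),
            flag=(flag + "; " if flag else "") + "non-positive slope: tau undefined",
        )
    tau = 1.0 / res.slope
    return GrowthFit(
        model="exponential",
        tau=float(tau),
        rate=float(math.log(2) / tau),
        r2=float(res.rvalue**2),
        fit_window=(float(t[0]), float(t[-1])),
        flag=flag,
    )


def fit_linear(
    series: CountSeries,
    auto_window: bool = False,
    shift_time: float = 0.0,
    transition_exclude: float = 120.0,
    r2_floor: float = 0.98,
) -> GrowthFit:
    """OLS fit of counts vs time; optionally auto-select the linear part.

    With ``auto_window`` the fit considers suffixes of the series starting
    after ``shift_time + transition_exclude`` and returns the longest one
    whose r² is at least ``r2_floor`` (falling back to the best-r² suffix).
    """
    t, n = series.times, series.total
    if len(t) < 4:
        raise ValueError("need at least 4 samples for a linear fit")
    if auto_window:
        t0 = shift_time + transition_exclude
        start_candidates = [i for i in range(len(t) - 3) if t[i] >= t0] or [
            max(0, len(t) - 4)
        ]
        chosen, best_r2, best_i = None, -np.inf, start_candidates[0]
        for i in start_candidates:
            res = stats.linregress(t[i:], n[i:])
            r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0
            if chosen is None and r2 >= r2_floor:
                chosen = i
                break
            if r2 > best_r2:
                best_r2, best_i = r2, i
        i = chosen if chosen is not None else best_i
        t, n = t[i:], n[i:]
    res = stats.linregress(t, n)
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 1.0
    return GrowthFit(
        model="linear",
        tau=None,
        rate=float(res.slope),
        r2=r2,
        fit_window=(float(t[0]), float(t[-1])),
    )


def classify_growth_mode(
    series: CountSeries, margin: float = 0.01
) -> str:
    """Compare exponential vs linear r² on a common window.

    Returns ``'exponential'``, ``'linear'``, or ``'ambiguous'`` when the r²
    margin is below ``margin`` or the series is degenerate (flat).
    """
    if len(series.times) < 8:
        raise ValueError("need at least 8 samples to classify growth mode")
    idx = _positive_block(series.times, series.total)
    t, n = series.times[idx], series.total[idx]
    if len(t) < 4 or n.max() == n.min():
        return "ambiguous"
    window = CountSeries(
        times=t, total=n, mothers=np.zeros_like(n), daughters=np.zeros_like(n),
        imploded=np.zeros_like(n),
    )
    r2_exp = fit_exponential(window).r2
    r2_lin = fit_linear(window).r2
    if abs(r2_exp - r2_lin) < margin:
        return "ambiguous"
    return "exponential" if r2_exp > r2_lin else "linear"


def interdivision_stats(tree: LineageTree, shift_time: float | None = None) -> pd.DataFrame:
    """Per-generation-index cycle times: successive differences of each
    mother's post-shift division times, aggregated by division index.

    Returns a DataFrame indexed by division index (1 = interval between the
    first and second post-shift divisions) with columns mean, sd, n.
    """
    if shift_time is None:
        shift_time = tree.regime.shift_time
    rows = []
    for c in tree.cells.values():
        times = [t for t in c.division_times if t >= shift_time]
        for k, (t1, t2) in enumerate(zip(times, times[1:]), start=1):
            rows.append({"cell_id": c.id, "division_index": k, "cycle_min": t2 - t1})
    if not rows:
        raise ValueError("tree contains no mother with two or more divisions")
    df = pd.DataFrame(rows)
    agg = df.groupby("division_index")["cycle_min"].agg(["mean", "std", "count"])
    return agg.rename(columns={"std": "sd", "count": "n"})


def mother_interdivision_times(tree: LineageTree, shift_time: float | None = None) -> np.ndarray:
    """All successive division-time differences across mothers (minutes)."""
    if shift_time is None:
        shift_time = tree.regime.shift_time
    gaps: list[float] = []
    for c in tree.cells.values():
        times = [t for t in c.division_times if t >= shift_time]
        gaps.extend(np.diff(times))
    return np.asarray(gaps)


def size_distributions(
    tree: LineageTree, t: float, age_correct: bool = False
) -> SizeDistributions:
    """Mother/daughter size samples among cells alive at ``t``.

    ``age_correct`` evaluates every cell's growth curve at a common age (the
    age of the youngest cell alive at ``t``), as if all cells were born
    simultaneously.  Gap = 1 - median(daughter)/median(mother); undefined
    (None, flagged) when either class has fewer than 3 cells.
    """
    if not (0 <= t <= tree.duration):
        raise ValueError(f"t={t} outside the simulated span [0, {tree.duration}]")
    alive = tree.alive_at(t)
    if age_correct and alive:
        common_age = min(t - c.birth_time for c in alive)
        sizes = {c.id: tree.size_at_age(c.id, common_age) for c in alive}
    else:
        sizes = {c.id: tree.size_at(c.id, t) for c in alive}
    mothers = np.array(
        [sizes[c.id] for c in alive if any(dt <= t for dt in c.division_times)]
    )
    daughters = np.array(
        [sizes[c.id] for c in alive if not any(dt <= t for dt in c.division_times)]
    )
    if len(mothers) < 3 or len(daughters) < 3:
        return SizeDistributions(
            mothers, daughters, gap=None, age_corrected=age_correct,
            flag="fewer than 3 cells in a class: gap undefined",
        )
    gap = 1.0 - float(np.median(daughters)) / float(np.median(mothers))
    return SizeDistributions(mothers, daughters, gap=gap, age_corrected=age_correct)


def vacuole_fraction(tree: LineageTree, bin_minutes: float = 60.0) -> AsymmetryStats:
    """Fraction of the vacuolar pool inherited by each side at every division.

    Fractions are of the pre-loss pool (mother keeps ``f``, daughter gets
    ``1-f``), so they sum to one per division; divisions with a zero pool are
    counted as undefined and excluded from the bins.
    """
    rows, undefined = [], 0
    for d in tree.divisions:
        total = d.resource_before
        if not (total > 0) or math.isnan(total):
            undefined += 1
            continue
        daughter_frac = d.daughter_at_birth / total
        rows.append(
            {
                "time": d.time,
                "mother_fraction": 1.0 - daughter_frac,
                "daughter_fraction": daughter_frac,
            }
        )
    per_division = pd.DataFrame(rows, columns=["time", "mother_fraction", "daughter_fraction"])
    if len(per_division):
        bins = (per_division["time"] // bin_minutes * bin_minutes).astype(float)
        binned = per_division.groupby(bins)[["mother_fraction", "daughter_fraction"]].mean()
        binned.index.name = "bin_start_min"
    else:
        binned = pd.DataFrame(columns=["mother_fraction", "daughter_fraction"])
    return AsymmetryStats(per_division=per_division, binned=binned, n_undefined=undefined)


def stress_survival(
    tree: LineageTree, stress: StressParams
) -> dict[str, StressOutcome]:
    """Implosion and recovery tallies per class for a stressed tree.

    Classes are assigned as of the stress start (a mother has completed at
    least one division by then).  Survivors count as recovered; for
    zinc_shock/rapamycin their recovery delay (time from stress end to the
    stamped recovery time) is reported.
    """
    t0 = stress.start
    out: dict[str, StressOutcome] = {}
    exposed = [c for c in tree.cells.values() if c.birth_time <= t0]
    for klass in ("mother", "daughter"):
        members = [
            c
            for c in exposed
            if (any(dt <= t0 for dt in c.division_times)) == (klass == "mother")
        ]
        n = len(members)
        imploded = [c for c in members if c.status == "imploded"]
        survivors = [c for c in members if c.status != "imploded"]
        delays = np.array(
            [
                c.recovery_time - (stress.start + stress.duration)
                for c in survivors
                if c.recovery_time is not None
            ]
        )
        frac = len(imploded) / n if n else 0.0
        se = math.sqrt(frac * (1 - frac) / n) if n else 0.0
        out[klass] = StressOutcome(
            n_exposed=n,
            n_imploded=len(imploded),
            n_recovered=len(survivors),
            implosion_fraction=frac,
            implosion_se=se,
            recovery_delays=delays,
        )
    return out


def plot_counts(
    series: CountSeries,
    fits: list[GrowthFit] | None = None,
    path: str | None = None,
):
    """Cell counts over time with optional fit overlays (total, mothers,
    daughters); saves to ``path`` when given, else returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(series.times, series.total, "k.", ms=3, label="total")
    ax.plot(series.times, series.mothers, "b-", lw=1, label="mothers")
    ax.plot(series.times, series.daughters, "r-", lw=1, label="daughters")
    for fit in fits or []:
        lo, hi = fit.fit_window
        t = np.linspace(lo, hi, 100)
        sel = (series.times >= lo) & (series.times <= hi)
        if not sel.any():
            continue
        t0, n0 = series.times[sel][0], series.total[sel][0]
        if fit.model == "exponential" and fit.tau:
            ax.plot(t, n0 * 2 ** ((t - t0) / fit.tau), "--",
                    label=f"exp fit tau={fit.tau:.0f} min")
        elif fit.model == "linear" and fit.rate is not None:
            ax.plot(t, n0 + fit.rate * (t - t0), ":",
                    label=f"linear fit {fit.rate:.3f}/min")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cells")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def plot_size_histograms(dist: SizeDistributions, path: str | None = None):
    """Overlaid mother/daughter size histograms at one time point."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    bins = np.histogram_bin_edges(
        np.concatenate([dist.mother_sizes, dist.daughter_sizes]), bins=20
    )
    ax.hist(dist.mother_sizes, bins=bins, alpha=0.6, color="tab:blue", label="mothers")
    ax.hist(dist.daughter_sizes, bins=bins, alpha=0.6, color="tab:red", label="daughters")
    title = "age-corrected sizes" if dist.age_corrected else "sizes"
    if dist.gap is not None:
        title += f" (gap {100 * dist.gap:.0f}%)"
    ax.set_title(title, fontsize=10)
    ax.set_xlabel("size (a.u.)")
    ax.set_ylabel("cells")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def pool_counts(series_list: list[CountSeries]) -> CountSeries:
    """Pool colonies by summing counts at matched times."""
    if not series_list:
        raise ValueError("nothing to pool")
    base = series_list[0].times
    for s in series_list[1:]:
        if len(s.times) != len(base) or not np.allclose(s.times, base):
            raise ValueError("count series have mismatched time grids")
    return CountSeries(
        times=base.copy(),
        total=sum(s.total for s in series_list),
        mothers=sum(s.mothers for s in series_list),
        daughters=sum(s.daughters for s in series_list),
        imploded=sum(s.imploded for s in series_list),
    )
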