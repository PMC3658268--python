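"""Agent-based simulation of budding cell populations on a limiting resource.

Each cell carries a vacuolar resource pool Z (same units as
:class:`~asymdiv.resource_model.ResourceParams`) and a size (volume proxy).
Division is gated by two checkpoints:

* a Start size rule — a newborn must grow to ``critical_size`` before it can
  complete a cycle; growth itself requires the resource level to be at least
  ``Zc`` (growth in a zinc-starved cell stalls);
* a resource-completion rule — a cell commits to a division only if the pool
  it retains afterwards, ``f*Z - deltaZ``, stays at or above ``Zc``.  This
  makes the simulator agree exactly with the closed-form capacities of
  :mod:`asymdiv.resource_model` (``floor((Z0-Zc)/deltaZ)`` divisions at
  ``f=1``; maximal generation ``floor(log2(Z0/Zc))`` at ``f=0.5``).

At division the mother retains a fraction ``f`` of the pool (minus the loss
``deltaZ``) and the daughter receives ``1-f``; before ``shift_time`` the
partition is symmetric (``f=0.5``), emulating rich-medium vacuole
inheritance.  Between divisions the pool is replenished from the medium at
``regeneration_rate`` (a pre-shift and a post-shift value), capped at
``storage_max``.

Cycle durations are lognormal with mean ``mean_cycle_time`` and coefficient
of variation ``cycle_cv``, scaled by ``max(1, K/Z)**gamma`` so that cells
whose pool falls below the sufficiency scale ``K`` slow down — this is what
makes symmetric dilution (the *whi5*-like regime) produce progressively
longer cycles.

Cells do not interact; each lineage is simulated independently with an RNG
stream derived from the master seed and the cell's lineage position, so
adding cells or extending the horizon never perturbs the draws of existing
ones, and identical seeds give bit-identical trees.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .resource_model import ResourceParams

__all__ = [
    "Cell",
    "DivisionRecord",
    "RegimeParams",
    "StressParams",
    "LineageTree",
    "CountSeries",
    "REGIMES",
    "STRESS_PRESETS",
    "preset",
    "stress_preset",
    "simulate_population",
    "apply_stress",
    "count_series",
    "make_cohort",
    "cell_size_at",
]

Status = Literal["alive", "arrested", "imploded"]

_ELIG_TOL = 1e-9


@dataclass
class Cell:
    """Per-cell state.

    A cell with at least one completed division is a *mother*, otherwise a
    *daughter* (the paper's operational classification).  Size follows a
    piecewise-linear law: constant at ``birth_size`` until ``growth_start``
    (``None`` if growth never becomes possible), then linear at
    ``growth_rate`` up to ``size_cap``.
    """

    id: int
    parent_id: int | None
    birth_time: float
    birth_size: float
    size_cap: float
    growth_rate: float
    growth_start: float | None
    generation: int
    born_pre_shift: bool
    division_times: list[float] = field(default_factory=list)
    size: float = 0.0  # size at end of simulation
    resource: float = 0.0  # resource at end of simulation
    status: Status = "alive"
    implosion_time: float | None = None
    recovery_time: float | None = None

    @property
    def is_mother(self) -> bool:
        return len(self.division_times) >= 1


@dataclass(frozen=True)
class DivisionRecord:
    """One division event: partition of the mother's pool at time ``time``.

    ``resource_before`` is the mother's pool at the moment of division
    (regeneration during the cycle included); ``f_used`` the partition
    fraction retained by the mother.  Conservation holds exactly:
    ``mother_after + daughter_at_birth + deltaZ == resource_before``.
    """

    mother_id: int
    daughter_id: int
    time: float
    resource_before: float
    f_used: float
    mother_after: float
    daughter_at_birth: float


@dataclass(frozen=True)
class RegimeParams:
    """A growth/medium regime (see :data:`REGIMES` for the presets)."""

    name: str
    mean_cycle_time: float
    partition_fraction: float  # f: fraction of pool the mother retains post-shift
    regeneration_rate: float  # resource units/min after the shift
    resource_params: ResourceParams
    daughter_size_fraction: float
    cycle_cv: float = 0.15
    regeneration_rate_pre: float = 1.0  # before the shift (rich medium)
    storage_max: float = 10.0
    critical_size: float = 1.0
    shift_time: float = 0.0
    growth_time_fraction: float = 0.6  # newborn reaches critical size in this * cycle
    cycle_resource_scale: float | None = None  # K; defaults to Zc
    cycle_resource_gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (0.5 <= self.partition_fraction <= 1.0):
            raise ValueError(
                f"partition fraction must be in [0.5, 1], got {self.partition_fraction}"
            )
        if self.mean_cycle_time <= 0:
            raise ValueError("mean_cycle_time must be > 0")
        if not (0.0 < self.daughter_size_fraction < 1.0):
            raise ValueError("daughter_size_fraction must be in (0, 1)")
        if self.cycle_cv < 0 or self.regeneration_rate < 0 or self.regeneration_rate_pre < 0:
            raise ValueError("rates and CV must be non-negative")

    @property
    def K(self) -> float:
        """Resource scale below which cycles lengthen."""
        if self.cycle_resource_scale is not None:
            return self.cycle_resource_scale
        return self.resource_params.Zc

    @property
    def growth_rate(self) -> float:
        """Size units/min: a half-critical newborn reaches critical size in
        ``growth_time_fraction`` of a mean cycle."""
        return (0.5 * self.critical_size) / (
            self.growth_time_fraction * self.mean_cycle_time
        )


@dataclass(frozen=True)
class StressParams:
    """An acute stress applied to an existing population."""

    kind: Literal["zinc_shock", "osmotic", "rapamycin"]
    start: float
    duration: float
    p_implode_mother: float
    p_implode_daughter: float
    recovery_delay_mother: float = 0.0
    recovery_delay_daughter: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_implode_mother, self.p_implode_daughter):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"implosion probability must be in [0, 1], got {p}")
        if self.duration < 0:
            raise ValueError("stress duration must be >= 0")


@dataclass
class CountSeries:
    """Cell counts sampled on a regular time grid (default every 6 min)."""

    times: np.ndarray
    total: np.ndarray
    mothers: np.ndarray
    daughters: np.ndarray
    imploded: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("total", "mothers", "daughters", "imploded"):
            arr = np.asarray(getattr(self, name))
            if np.any(arr < 0):
                raise ValueError(f"{name} counts must be non-negative")
            setattr(self, name, arr.astype(int))


@dataclass
class LineageTree:
    """A forest of budding lineages: cells plus mother->daughter divisions."""

    cells: dict[int, Cell]
    divisions: list[DivisionRecord]
    regime: RegimeParams
    seed: int
    duration: float

    def founders(self) -> list[Cell]:
        return [c for c in self.cells.values() if c.parent_id is None]

    def children(self, cell_id: int) -> list[Cell]:
        return [c for c in self.cells.values() if c.parent_id == cell_id]

    def n_cells(self) -> int:
        return len(self.cells)

    def max_generation(self) -> int:
        return max((c.generation for c in self.cells.values()), default=0)

    def alive_at(self, t: float) -> list[Cell]:
        return [
            c
            for c in self.cells.values()
            if c.birth_time <= t
            and (c.implosion_time is None or c.implosion_time > t)
        ]

    def size_at(self, cell_id: int, t: float) -> float:
        return cell_size_at(self.cells[cell_id], t)

    def size_at_age(self, cell_id: int, age: float) -> float:
        c = self.cells[cell_id]
        return cell_size_at(c, c.birth_time + age)

    def validate(self) -> None:
        """Structural invariants: acyclic parenthood, ordered divisions,
        birth times matching parent division times, resource conservation."""
        div_lookup = {(d.mother_id, d.daughter_id): d for d in self.divisions}
        for c in self.cells.values():
            times = c.division_times
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError(f"cell {c.id}: division times not increasing")
            if times and times[0] < c.birth_time:
                raise ValueError(f"cell {c.id}: division before birth")
            if c.parent_id is not None:
                parent = self.cells[c.parent_id]
                if c.birth_time not in parent.division_times:
                    raise ValueError(
                        f"cell {c.id}: birth time not among parent divisions"
                    )
                if (c.parent_id, c.id) not in div_lookup:
                    raise ValueError(f"cell {c.id}: missing division record")
        # acyclicity: walking up parents must terminate
        for c in self.cells.values():
            seen = set()
            cur: Cell | None = c
            while cur is not None:
                if cur.id in seen:
                    raise ValueError("parent cycle detected")
                seen.add(cur.id)
                cur = self.cells.get(cur.parent_id) if cur.parent_id is not None else None
        dz = self.regime.resource_params.deltaZ
        for d in self.divisions:
            if math.isnan(d.resource_before):
                continue  # reconstructed trees carry no resource bookkeeping
            if not math.isclose(
                d.mother_after + d.daughter_at_birth + dz,
                d.resource_before,
                rel_tol=1e-9,
                abs_tol=1e-9,
            ):
                raise ValueError(f"resource not conserved at division {d}")


def cell_size_at(cell: Cell, t: float) -> float:
    """Size of ``cell`` at absolute time ``t`` (piecewise-linear growth law)."""
    if t < cell.birth_time:
        return cell.birth_size
    if cell.growth_start is None or t <= cell.growth_start:
        return cell.birth_size
    grown = cell.birth_size + cell.growth_rate * (t - cell.growth_start)
    return min(cell.size_cap, grown)


# ---------------------------------------------------------------------------
# regime presets
# ---------------------------------------------------------------------------

def _regimes() -> dict[str, RegimeParams]:
    rich = RegimeParams(
        name="rich",
        mean_cycle_time=103.0,
        partition_fraction=0.5,
        regeneration_rate=1.0,
        resource_params=ResourceParams(Z0=10.0, Zc=1.0, deltaZ=0.1),
        daughter_size_fraction=0.5,
    )
    low_metal = RegimeParams(
        name="low_metal",
        mean_cycle_time=120.0,
        partition_fraction=0.98,
        regeneration_rate=0.0,
        # deltaZ tuned so a founder entering with a full pool completes
        # exactly 8 post-shift divisions before arrest (the mother also
        # sheds (1-f)*Z to the bud at every division)
        resource_params=ResourceParams(Z0=10.0, Zc=1.0, deltaZ=0.95),
        daughter_size_fraction=0.65,
    )
    preadapted = replace(
        low_metal,
        name="low_metal_preadapted",
        mean_cycle_time=150.0,
        # 4 post-shift divisions (pre-adaptation leaves a smaller usable pool)
        resource_params=ResourceParams(Z0=10.0, Zc=1.0, deltaZ=1.9),
    )
    whi5 = RegimeParams(
        name="whi5",
        mean_cycle_time=120.0,
        partition_fraction=0.5,  # no daughter arrest: vacuole split evenly
        regeneration_rate=0.0,
        resource_params=ResourceParams(Z0=10.0, Zc=1.0, deltaZ=0.1),
        daughter_size_fraction=0.5,
        critical_size=0.7,  # whi5 cells pass Start ~30% smaller
        cycle_resource_scale=6.0,  # dilution slows every subsequent cycle
    )
    whi5_rich = replace(
        rich,
        name="whi5_rich",
        critical_size=0.7,
    )
    semi_low = RegimeParams(
        name="semi_low",
        mean_cycle_time=130.0,
        partition_fraction=0.5,
        regeneration_rate=0.15,
        resource_params=ResourceParams(Z0=10.0, Zc=1.0, deltaZ=0.1),
        daughter_size_fraction=0.5,
    )
    vac17_rich = replace(
        rich,
        name="vac17_rich",
        partition_fraction=1.0,  # no vacuole transported to the bud ...
        regeneration_rate=1.0,  # ... but daughters rapidly regenerate one
    )
    vac17_semi_low = RegimeParams(
        name="vac17_semi_low",
        mean_cycle_time=180.0,
        partition_fraction=1.0,
        regeneration_rate=0.0,  # regeneration impaired in semi-low zinc
        resource_params=ResourceParams(Z0=10.0, Zc=1.0, deltaZ=1.125),
        daughter_size_fraction=0.65,
    )
    zrc1cot1 = replace(
        low_metal,
        name="zrc1cot1",
        mean_cycle_time=140.0,
        # no vacuolar zinc storage: smaller usable pool, earlier arrest
        resource_params=ResourceParams(Z0=5.5, Zc=1.0, deltaZ=0.95),
    )
    presets = [
        rich,
        low_metal,
        preadapted,
        whi5,
        whi5_rich,
        semi_low,
        vac17_rich,
        vac17_semi_low,
        zrc1cot1,
    ]
    return {p.name: p for p in presets}


REGIMES: dict[str, RegimeParams] = _regimes()

STRESS_PRESETS: dict[str, StressParams] = {
    # ~30% of daughters vs ~8% of mothers die under osmotic stress
    "osmotic": StressParams(
        kind="osmotic",
        start=510.0,
        duration=120.0,
        p_implode_mother=0.08,
        p_implode_daughter=0.30,
    ),
    # mothers recover promptly from a zinc shock, daughters ~4 h later
    "zinc_shock": StressParams(
        kind="zinc_shock",
        start=420.0,
        duration=120.0,
        p_implode_mother=0.05,
        p_implode_daughter=0.15,
        recovery_delay_mother=30.0,
        recovery_delay_daughter=270.0,
    ),
    # rapamycin targets the dividing mothers; daughters mostly recover
    "rapamycin": StressParams(
        kind="rapamycin",
        start=720.0,
        duration=960.0,
        p_implode_mother=0.70,
        p_implode_daughter=0.15,
        recovery_delay_mother=120.0,
        recovery_delay_daughter=60.0,
    ),
}


def preset(name: str, **overrides) -> RegimeParams:
    """Return a regime preset by name, optionally overriding fields."""
    if name not in REGIMES:
        raise KeyError(
            f"unknown regime {name!r}; available: {sorted(REGIMES)}"
        )
    base = REGIMES[name]
    return replace(base, **overrides) if overrides else base


def stress_preset(name: str, **overrides) -> StressParams:
    if name not in STRESS_PRESETS:
        raise KeyError(
            f"unknown stress preset {name!r}; available: {sorted(STRESS_PRESETS)}"
        )
    base = STRESS_PRESETS[name]
    return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _f_at(regime: RegimeParams, t: float) -> float:
    """Partition fraction in effect for a division at time t."""
    return 0.5 if t < regime.shift_time else regime.partition_fraction


def _dsf_at(regime: RegimeParams, t: float) -> float:
    return 0.5 if t < regime.shift_time else regime.daughter_size_fraction


def _regen_at(regime: RegimeParams, t: float) -> float:
    return regime.regeneration_rate_pre if t < regime.shift_time else regime.regeneration_rate


def _advance_resource(regime: RegimeParams, z: float, t0: float, t1: float) -> float:
    """Resource at t1 given level z at t0 (piecewise-linear refill, capped)."""
    if t1 <= t0:
        return z
    s = regime.shift_time
    if t0 < s <= t1:
        z = min(regime.storage_max, z + regime.regeneration_rate_pre * (s - t0))
        t0 = s
    z = min(regime.storage_max, z + _regen_at(regime, t0) * (t1 - t0))
    return z


def _time_to_reach(regime: RegimeParams, z: float, t0: float, target: float) -> float | None:
    """Earliest time >= t0 at which the pool reaches ``target`` (None if never)."""
    if z >= target - _ELIG_TOL:
        return t0
    if target > regime.storage_max + _ELIG_TOL:
        return None
    s = regime.shift_time
    if t0 < s:
        r = regime.regeneration_rate_pre
        if r > 0:
            t_hit = t0 + (target - z) / r
            if t_hit <= s:
                return t_hit
        z = min(regime.storage_max, z + r * (s - t0))
        t0 = s
        if z >= target - _ELIG_TOL:
            return t0
    r = _regen_at(regime, t0)
    if r <= 0:
        return None
    return t0 + (target - z) / r


def _resource_feasible_time(regime: RegimeParams, z: float, t0: float) -> float | None:
    """Earliest time the completion rule f*Z - deltaZ >= Zc can be met."""
    rp = regime.resource_params
    s = regime.shift_time
    if t0 < s:
        target_pre = (rp.Zc + rp.deltaZ) / 0.5
        t_hit = _time_to_reach(regime, z, t0, target_pre)
        if t_hit is not None and t_hit < s:
            return t_hit
        z = _advance_resource(regime, z, t0, s)
        t0 = s
    target = (rp.Zc + rp.deltaZ) / regime.partition_fraction
    return _time_to_reach(regime, z, t0, target)


def _growth_start_time(regime: RegimeParams, z: float, t_birth: float) -> float | None:
    """Growth requires the pool to be at the critical level Zc."""
    return _time_to_reach(regime, z, t_birth, regime.resource_params.Zc)


def _draw_cycle(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Lognormal with exact mean ``mean`` and coefficient of variation ``cv``."""
    if cv == 0:
        return mean
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def simulate_population(
    regime: RegimeParams, n_founders: int, duration: float, seed: int
) -> LineageTree:
    """Simulate ``n_founders`` independent lineages for ``duration`` minutes.

    Founders start at ``critical_size`` with a full pool ``Z0`` and represent
    cells grown in rich medium before the shift (``born_pre_shift=True``).
    Returns a :class:`LineageTree`; deterministic for a given seed.
    """
    if n_founders < 0:
        raise ValueError("n_founders must be >= 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    rp = regime.resource_params
    cells: dict[int, Cell] = {}
    divisions: list[DivisionRecord] = []
    next_id = 0
    queue: list[Cell] = []
    # RNG streams are keyed by lineage position (founder index, then the
    # division index at each ancestor), so extending the horizon or adding
    # founders never perturbs the draws of existing lineages
    stream_key: dict[int, tuple[int, ...]] = {}

    for _ in range(n_founders):
        founder = Cell(
            id=next_id,
            parent_id=None,
            birth_time=0.0,
            birth_size=regime.critical_size,
            size_cap=regime.critical_size,
            growth_rate=regime.growth_rate,
            growth_start=0.0,
            generation=0,
            born_pre_shift=True,
            resource=rp.Z0,
        )
        stream_key[founder.id] = (founder.id,)
        next_id += 1
        queue.append(founder)

    while queue:
        cell = queue.pop(0)
        cells[cell.id] = cell
        rng = np.random.default_rng([seed & 0x7FFFFFFF, *stream_key[cell.id]])
        t = cell.birth_time
        z = cell.resource  # pool at cycle start

        # earliest time this cell reaches critical size
        g0 = _growth_start_time(regime, z, t)
        cell.growth_start = g0
        if cell.birth_size >= regime.critical_size:
            t_size: float | None = t
        elif g0 is None:
            t_size = None
        else:
            t_size = g0 + (regime.critical_size - cell.birth_size) / regime.growth_rate

        while True:
            t_res = _resource_feasible_time(regime, z, t)
            if t_res is None or t_size is None:
                cell.status = "arrested"
                break
            t_ready = max(t_size, t_res)
            if t_ready > duration:
                break  # checkpoints not passable within the horizon
            z_ready = _advance_resource(regime, z, t, t_ready)
            mult = max(1.0, regime.K / max(z_ready, 1e-12)) ** regime.cycle_resource_gamma
            cycle = _draw_cycle(rng, regime.mean_cycle_time * mult, regime.cycle_cv)
            t_div = max(t + cycle, t_ready)
            if t_div > duration:
                break
            z_div = _advance_resource(regime, z, t, t_div)
            f_e = _f_at(regime, t_div)
            mother_after = max(0.0, f_e * z_div - rp.deltaZ)
            daughter_z = (1.0 - f_e) * z_div
            dsf = _dsf_at(regime, t_div)
            daughter = Cell(
                id=next_id,
                parent_id=cell.id,
                birth_time=t_div,
                birth_size=dsf * cell_size_at(cell, t_div),
                size_cap=regime.critical_size,
                growth_rate=regime.growth_rate,
                growth_start=None,
                generation=cell.generation + 1,
                born_pre_shift=t_div <= regime.shift_time,
                resource=daughter_z,
            )
            stream_key[daughter.id] = stream_key[cell.id] + (len(cell.division_times),)
            next_id += 1
            divisions.append(
                DivisionRecord(
                    mother_id=cell.id,
                    daughter_id=daughter.id,
                    time=t_div,
                    resource_before=z_div,
                    f_used=f_e,
                    mother_after=mother_after,
                    daughter_at_birth=daughter_z,
                )
            )
            cell.division_times.append(t_div)
            queue.append(daughter)
            t = t_div
            z = mother_after
            t_size = t  # a mother stays at critical size

        cell.resource = _advance_resource(regime, z, t, duration) if cell.status != "arrested" else z
        cell.size = cell_size_at(cell, duration)

    divisions.sort(key=lambda d: (d.time, d.mother_id))
    return LineageTree(
        cells=cells, divisions=divisions, regime=regime, seed=seed, duration=duration
    )


# ---------------------------------------------------------------------------
# stress
# ---------------------------------------------------------------------------

def apply_stress(tree: LineageTree, stress: StressParams, seed: int) -> LineageTree:
    """Return a copy of ``tree`` with stress outcomes applied.

    Every cell alive during the stress window implodes independently with
    its class probability (mother/daughter classification as of the stress
    start); implosion times are uniform within the stress window.  Divisions
    and descendants dated after a cell's implosion are pruned.  Survivors of
    ``zinc_shock``/``rapamycin`` are stamped with a recovery time (stress end
    plus the class recovery delay)."""
    out = copy.deepcopy(tree)
    t0 = stress.start
    exposed = [
        c
        for c in out.cells.values()
        if c.birth_time <= t0 + stress.duration and c.status in ("alive", "arrested")
    ]
    for c in exposed:
        was_mother = any(dt <= t0 for dt in c.division_times)
        p = stress.p_implode_mother if was_mother else stress.p_implode_daughter
        rng = np.random.default_rng([seed & 0x7FFFFFFF, c.id, 7])
        if rng.random() < p:
            c.status = "imploded"
            c.implosion_time = max(
                c.birth_time, t0 + float(rng.random()) * stress.duration
            )
        elif stress.kind in ("zinc_shock", "rapamycin"):
            delay = (
                stress.recovery_delay_mother
                if was_mother
                else stress.recovery_delay_daughter
            )
            c.recovery_time = t0 + stress.duration + delay

    # prune post-implosion divisions and descendants
    for c in list(out.cells.values()):
        if c.implosion_time is not None:
            c.division_times = [t for t in c.division_times if t <= c.implosion_time]
    removed: set[int] = set()

    def doomed(c: Cell) -> bool:
        if c.parent_id is None:
            return False
        parent = out.cells.get(c.parent_id)
        if parent is None or parent.id in removed:
            return True
        return (
            parent.implosion_time is not None
            and c.birth_time > parent.implosion_time
        )

    for c in sorted(out.cells.values(), key=lambda c: c.birth_time):
        if doomed(c):
            removed.add(c.id)
    out.cells = {i: c for i, c in out.cells.items() if i not in removed}
    out.divisions = [
        d
        for d in out.divisions
        if d.mother_id in out.cells
        and d.daughter_id in out.cells
        and d.time in out.cells[d.mother_id].division_times
    ]
    return out


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_series(
    tree: LineageTree, interval: float = 6.0, horizon: float | None = None
) -> CountSeries:
    """Cell counts on a regular grid: a cell is counted at time t iff it was
    born at or before t and had not imploded by t; it counts as a mother iff
    it has completed >= 1 division by t."""
    if interval <= 0:
        raise ValueError("interval must be > 0")
    if horizon is None:
        horizon = tree.duration
    n_samples = int(math.floor(horizon / interval)) + 1
    times = np.arange(n_samples) * interval
    cells = list(tree.cells.values())
    births = np.array([c.birth_time for c in cells]) if cells else np.empty(0)
    implosions = np.array(
        [c.implosion_time if c.implosion_time is not None else np.inf for c in cells]
    ) if cells else np.empty(0)
    first_div = np.array(
        [c.division_times[0] if c.division_times else np.inf for c in cells]
    ) if cells else np.empty(0)
    total = np.zeros(n_samples, dtype=int)
    mothers = np.zeros(n_samples, dtype=int)
    imploded = np.zeros(n_samples, dtype=int)
    for i, t in enumerate(times):
        present = births <= t
        alive = present & (implosions > t)
        total[i] = int(alive.sum())
        mothers[i] = int((alive & (first_div <= t)).sum())
        imploded[i] = int((present & (implosions <= t)).sum())
    return CountSeries(
        times=times,
        total=total,
        mothers=mothers,
        daughters=total - mothers,
        imploded=imploded,
    )


# ---------------------------------------------------------------------------
# deterministic cohorts (stress assays)
# ---------------------------------------------------------------------------

def make_cohort(
    n_mothers: int,
    n_daughters: int,
    regime: RegimeParams | None = None,
    division_interval: float = 120.0,
    horizon: float = 600.0,
) -> LineageTree:
    """Build a deterministic tree with exactly ``n_mothers`` cells that have
    divided and ``n_daughters`` arrested daughters (distributed round-robin
    over the mothers).  Used for stress assays at fixed class sizes."""
    if n_daughters > 0 and n_mothers == 0:
        raise ValueError("daughters need mothers")
    regime = regime or preset("low_metal")
    rp = regime.resource_params
    cells: dict[int, Cell] = {}
    divisions: list[DivisionRecord] = []
    for m in range(n_mothers):
        cells[m] = Cell(
            id=m,
            parent_id=None,
            birth_time=0.0,
            birth_size=regime.critical_size,
            size_cap=regime.critical_size,
            growth_rate=regime.growth_rate,
            growth_start=0.0,
            generation=0,
            born_pre_shift=True,
            size=regime.critical_size,
            resource=rp.Z0,
        )
    next_id = n_mothers
    f = regime.partition_fraction
    for d in range(n_daughters):
        mother = cells[d % n_mothers]
        k = len(mother.division_times)
        t_div = division_interval * (k + 1)
        z_before = max(rp.Zc, mother.resource)
        mother_after = max(0.0, f * z_before - rp.deltaZ)
        daughter_z = (1.0 - f) * z_before
        bud = Cell(
            id=next_id,
            parent_id=mother.id,
            birth_time=t_div,
            birth_size=regime.daughter_size_fraction * regime.critical_size,
            size_cap=regime.critical_size,
            growth_rate=regime.growth_rate,
            growth_start=None,
            generation=1,
            born_pre_shift=False,
            size=regime.daughter_size_fraction * regime.critical_size,
            resource=daughter_z,
            status="arrested",
        )
        mother.division_times.append(t_div)
        mother.resource = mother_after
        divisions.append(
            DivisionRecord(
                mother_id=mother.id,
                daughter_id=bud.id,
                time=t_div,
                resource_before=z_before,
                f_used=f,
                mother_after=mother_after,
                daughter_at_birth=daughter_z,
            )
        )
        cells[next_id] = bud
        next_id += 1
    divisions.sort(key=lambda d: (d.time, d.mother_id))
    return LineageTree(
        cells=cells, divisions=divisions, regime=regime, seed=0, duration=horizon
    )
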