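"""Simulator dynamics against the closed-form oracles and count invariants."""

import math

import numpy as np
import pytest
from scipy import stats

from asymdiv import io as aio
from asymdiv.population_sim import (
    count_series,
    preset,
    simulate_population,
)
from asymdiv.resource_model import ResourceParams, asymmetric_capacity, symmetric_capacity


def test_empty_population():
    tree = simulate_population(preset("rich"), 0, 600, seed=1)
    assert tree.n_cells() == 0
    cs = count_series(tree)
    assert cs.total.sum() == 0


@pytest.mark.parametrize("bad", [dict(n_founders=-1, duration=100), dict(n_founders=1, duration=-5)])
def test_negative_inputs_raise(bad):
    with pytest.raises(ValueError):
        simulate_population(preset("rich"), seed=1, **bad)


def test_determinism_bit_identical():
    a = simulate_population(preset("low_metal"), 5, 700, seed=9)
    b = simulate_population(preset("low_metal"), 5, 700, seed=9)
    assert aio.tree_to_dict(a) == aio.tree_to_dict(b)
    c = simulate_population(preset("low_metal"), 5, 700, seed=10)
    assert aio.tree_to_dict(a) != aio.tree_to_dict(c)


def test_extending_horizon_preserves_existing_draws():
    """Lengthening the run adds cells but never perturbs the division times
    of lineages that already existed (per-cell RNG streams).  Cells are
    matched by lineage path because numeric ids depend on spawn order."""

    def paths(tree):
        out = {}
        for c in tree.cells.values():
            path = []
            cur = c
            while cur.parent_id is not None:
                parent = tree.cells[cur.parent_id]
                path.append(parent.division_times.index(cur.birth_time))
                cur = parent
            out[(cur.id,) + tuple(reversed(path))] = c
        return out

    short = paths(simulate_population(preset("rich"), 1, 300, seed=4))
    long = paths(simulate_population(preset("rich"), 1, 600, seed=4))
    assert set(short) <= set(long)
    for key, cell in short.items():
        other = long[key].division_times
        assert other[: len(cell.division_times)] == pytest.approx(cell.division_times)


def test_full_retention_matches_asymmetric_capacity():
    """f=1, no regeneration: division count per founder equals the
    closed-form (Z0 - Zc)/deltaZ exactly."""
    rp = ResourceParams(Z0=10.0, Zc=1.0, deltaZ=1.125)
    regime = preset("low_metal", partition_fraction=1.0, resource_params=rp)
    tree = simulate_population(regime, 4, 3000, seed=3)
    expected = math.floor(asymmetric_capacity(rp).Nas + 1e-9)
    assert expected == 8
    for f in tree.founders():
        assert len(f.division_times) == expected
        assert f.status == "arrested"


def test_symmetric_split_matches_symmetric_capacity():
    """f=0.5, no loss, no regeneration: maximal generation equals
    floor(log2(Z0/Zc))."""
    rp = ResourceParams(Z0=10.0, Zc=1.0, deltaZ=0.0)
    regime = preset("whi5", resource_params=rp, cycle_resource_scale=1.0)
    tree = simulate_population(regime, 2, 6000, seed=6)
    assert tree.max_generation() == symmetric_capacity(rp).cycles_symmetric == 3


def test_resource_conservation_and_structure():
    for name in ("rich", "low_metal", "whi5", "vac17_semi_low"):
        tree = simulate_population(preset(name), 2, 500, seed=8)
        tree.validate()  # raises on any violated invariant


def test_low_metal_founders_divide_eight_times_then_arrest():
    tree = simulate_population(preset("low_metal"), 10, 1500, seed=1)
    for f in tree.founders():
        assert len(f.division_times) == 8
        assert f.status == "arrested"
    daughters = [c for c in tree.cells.values() if c.parent_id is not None]
    assert daughters and all(len(d.division_times) == 0 for d in daughters)
    # daughters inherit a tiny pool, below the critical level
    zc = tree.regime.resource_params.Zc
    assert all(d.resource < zc for d in daughters)


def test_pre_shift_daughters_divide_but_late_daughters_arrest():
    """With the shift during the run, daughters born in rich medium keep a
    half share of a replenished pool and go on dividing; daughters born
    well after the shift (> 2 h) never do."""
    regime = preset("low_metal", shift_time=300.0)
    tree = simulate_population(regime, 5, 1200, seed=7)
    pre = [c for c in tree.cells.values() if c.parent_id is not None and c.born_pre_shift]
    late = [
        c
        for c in tree.cells.values()
        if c.parent_id is not None and c.birth_time > regime.shift_time + 120.0
    ]
    assert pre and any(len(c.division_times) > 0 for c in pre)
    assert late and all(len(c.division_times) == 0 for c in late)


def test_count_series_matches_brute_force():
    tree = simulate_population(preset("low_metal"), 4, 800, seed=12)
    cs = count_series(tree, interval=6.0)
    for i, t in enumerate(cs.times):
        alive = [c for c in tree.cells.values() if c.birth_time <= t]
        mothers = [c for c in alive if any(d <= t for d in c.division_times)]
        assert cs.total[i] == len(alive)
        assert cs.mothers[i] == len(mothers)
        assert cs.daughters[i] == len(alive) - len(mothers)


def test_count_series_interval_validation():
    tree = simulate_population(preset("rich"), 1, 100, seed=1)
    with pytest.raises(ValueError):
        count_series(tree, interval=0.0)


def test_low_metal_count_slope_is_founders_over_tau():
    m, tau = 30, 120.0
    tree = simulate_population(preset("low_metal"), m, 700, seed=5)
    cs = count_series(tree)
    sel = cs.times >= 150  # past the first-division ramp
    slope = stats.linregress(cs.times[sel], cs.total[sel]).slope
    assert slope == pytest.approx(m / tau, rel=0.15)


def test_rich_regime_log_counts_linear():
    trees = [simulate_population(preset("rich"), 1, 600, seed=100 + i) for i in range(8)]
    total = sum(count_series(t).total for t in trees)
    times = count_series(trees[0]).times
    res = stats.linregress(times, np.log2(total))
    assert res.rvalue**2 > 0.99
    assert 1.0 / res.slope == pytest.approx(103.0, rel=0.05)


def test_unknown_regime_raises():
    with pytest.raises(KeyError, match="unknown regime"):
        preset("hyperosmotic")
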