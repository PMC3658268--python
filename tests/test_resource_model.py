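"""Closed-form capacities vs brute-force resource-depletion loops."""

import math

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from asymdiv.resource_model import (
    ResourceParams,
    asymmetric_capacity,
    preferred_strategy,
    symmetric_capacity,
)


def brute_force_symmetric_cycles(z0: float, zc: float) -> int:
    """Halve the pool while both halves stay viable (>= Zc)."""
    z, n = z0, 0
    while z / 2.0 >= zc:
        z /= 2.0
        n += 1
    return n


def brute_force_asymmetric_divisions(z0: float, zc: float, dz: float) -> int:
    """Subtract the division loss while the retained pool stays >= Zc."""
    z, n = z0, 0
    while z - dz >= zc:
        z -= dz
        n += 1
    return n


@pytest.mark.parametrize(
    "z0, zc, ns, cycles, cells",
    [
        (16.0, 1.0, 16.0, 4, 16),  # exact power of two
        (5.0, 5.0, 1.0, 0, 1),  # no division possible
        (10.0, 3.0, 10.0 / 3.0, 1, 2),  # 10 -> 5 -> 2.5 stops after one halving
    ],
)
def test_symmetric_capacity_examples(z0, zc, ns, cycles, cells):
    r = symmetric_capacity(ResourceParams(Z0=z0, Zc=zc))
    assert r.Ns == pytest.approx(ns)
    assert r.cycles_symmetric == cycles
    assert r.cells_symmetric_discrete == cells
    assert r.cells_symmetric_discrete <= r.Ns + 1e-12


@pytest.mark.parametrize(
    "z0, zc, dz, nas",
    [(16.0, 1.0, 1.0, 15.0), (5.0, 5.0, 0.5, 0.0)],
)
def test_asymmetric_capacity_examples(z0, zc, dz, nas):
    r = asymmetric_capacity(ResourceParams(Z0=z0, Zc=zc, deltaZ=dz))
    assert r.Nas == pytest.approx(nas)
    assert not r.unbounded


def test_zero_loss_is_unbounded():
    r = asymmetric_capacity(ResourceParams(Z0=16.0, Zc=1.0, deltaZ=0.0))
    assert r.unbounded and math.isinf(r.Nas)


@pytest.mark.parametrize(
    "dz, expected",
    [(0.1, "asymmetric"), (1.0, "symmetric")],
)
def test_preferred_strategy_flips_with_loss(dz, expected):
    assert preferred_strategy(ResourceParams(Z0=16.0, Zc=1.0, deltaZ=dz)) == expected


def test_preferred_strategy_tie():
    # Ns = 2 and Nas = (2-1)/0.5 = 2
    assert preferred_strategy(ResourceParams(Z0=2.0, Zc=1.0, deltaZ=0.5)) == "tie"


def test_strategy_crossing_point():
    z0, zc = 16.0, 1.0
    dz_cross = (z0 - zc) * zc / z0  # Nas == Ns
    below = preferred_strategy(ResourceParams(z0, zc, dz_cross * 0.9))
    above = preferred_strategy(ResourceParams(z0, zc, dz_cross * 1.1))
    assert (below, above) == ("asymmetric", "symmetric")


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(Z0=1.0, Zc=0.0), "Zc"),
        (dict(Z0=1.0, Zc=-2.0), "Zc"),
        (dict(Z0=1.0, Zc=2.0), "Z0"),
        (dict(Z0=3.0, Zc=1.0, deltaZ=-0.1), "deltaZ"),
    ],
)
def test_invalid_params_raise(kwargs, match):
    with pytest.raises(ValueError, match=match):
        ResourceParams(**kwargs)


def test_preferred_strategy_requires_positive_loss():
    with pytest.raises(ValueError):
        preferred_strategy(ResourceParams(Z0=4.0, Zc=1.0, deltaZ=0.0))


@given(
    zc=st.floats(0.1, 10.0),
    ratio=st.floats(1.0, 1000.0),
    dz=st.floats(0.01, 20.0),
)
def test_brute_force_equivalence(zc, ratio, dz):
    z0 = zc * ratio
    nas = (z0 - zc) / dz
    # skip float knife edges where repeated subtraction and the closed form
    # legitimately disagree by rounding, and keep the loop bounded
    assume(nas < 1e4 and abs(nas - round(nas)) > 1e-6)
    assume(abs(math.log2(z0 / zc) - round(math.log2(z0 / zc))) > 1e-9)
    p = ResourceParams(Z0=z0, Zc=zc, deltaZ=dz)
    s = symmetric_capacity(p)
    a = asymmetric_capacity(p)
    assert s.cycles_symmetric == brute_force_symmetric_cycles(z0, zc)
    assert math.floor(a.Nas + 1e-9) == brute_force_asymmetric_divisions(z0, zc, dz)


@given(
    zc=st.floats(0.1, 10.0),
    ratio=st.floats(1.5, 100.0),
    dz=st.floats(0.01, 5.0),
    bump=st.floats(1.1, 3.0),
)
def test_monotonicity(zc, ratio, dz, bump):
    z0 = zc * ratio
    base_s = symmetric_capacity(ResourceParams(z0, zc, dz)).Ns
    base_a = asymmetric_capacity(ResourceParams(z0, zc, dz)).Nas
    # Nas strictly decreases in deltaZ
    assert asymmetric_capacity(ResourceParams(z0, zc, dz * bump)).Nas < base_a
    # Ns and Nas strictly increase in Z0
    assert symmetric_capacity(ResourceParams(z0 * bump, zc, dz)).Ns > base_s
    assert asymmetric_capacity(ResourceParams(z0 * bump, zc, dz)).Nas > base_a
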