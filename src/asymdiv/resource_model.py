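"""Closed-form capacity of a population dividing on a non-replenishable resource.

A progenitor cell enters a poor environment carrying an amount ``Z0`` of a
limiting resource (here: the vacuolar zinc pool).  Division is impossible once
the pool falls below a critical level ``Zc``, and each division additionally
consumes ``deltaZ`` of the pool.

Two segregation strategies are compared:

* **symmetric** — the pool is halved at every division, so after ``k`` cycles
  every cell holds ``Z0 / 2**k``.  Division stops after
  ``floor(log2(Z0/Zc))`` cycles, and the population can grow at most by a
  factor ``N_s = Z0/Zc``.
* **asymmetric** — the progenitor retains the whole pool, handing the daughter
  essentially nothing.  Only the loss ``deltaZ`` per division depletes the
  pool, so the progenitor can produce ``N_as = (Z0 - Zc)/deltaZ`` daughters
  (unbounded when ``deltaZ == 0``).

When ``deltaZ`` is small relative to ``Zc`` the asymmetric strategy wins,
which is the quantitative argument for mother-restricted division in
low-nutrient media.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "ResourceParams",
    "CapacityResult",
    "symmetric_capacity",
    "asymmetric_capacity",
    "preferred_strategy",
]

#: relative tolerance used when comparing the two continuous capacities
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class ResourceParams:
    """Parameters of the limiting-resource model (arbitrary resource units).

    Attributes
    ----------
    Z0:
        Initial resource amount per progenitor; must satisfy ``Z0 >= Zc``.
    Zc:
        Critical level below which division is impossible; ``Zc > 0``.
    deltaZ:
        Resource lost at each division; ``deltaZ >= 0``.
    """

    Z0: float
    Zc: float
    deltaZ: float = 0.0

    def __post_init__(self) -> None:
        if not (self.Zc > 0):
            raise ValueError(f"critical level Zc must be > 0, got Zc={self.Zc}")
        if self.Z0 < self.Zc:
            raise ValueError(
                f"initial pool must satisfy Z0 >= Zc, got Z0={self.Z0} < Zc={self.Zc}"
            )
        if self.deltaZ < 0:
            raise ValueError(f"per-division loss deltaZ must be >= 0, got {self.deltaZ}")


@dataclass(frozen=True)
class CapacityResult:
    """Predicted growth capacity under one segregation strategy.

    ``Ns`` and ``Nas`` are the continuous idealizations; the discrete fields
    floor them to realizable integer cell/cycle counts.  ``Nas`` is
    ``math.inf`` (``unbounded=True``) when division costs nothing.
    """

    Ns: float | None = None
    Nas: float | None = None
    cycles_symmetric: int | None = None
    cells_symmetric_discrete: int | None = None
    unbounded: bool = False


def _symmetric_cycles(Z0: float, Zc: float) -> int:
    """Number of feasible halvings: largest k with Z0 / 2**k >= Zc."""
    k = max(0, math.floor(math.log2(Z0 / Zc)))
    # guard against float noise at exact powers of two
    while Zc * (2.0 ** (k + 1)) <= Z0 * (1 + 1e-12):
        k += 1
    while k > 0 and Zc * (2.0**k) > Z0 * (1 + 1e-12):
        k -= 1
    return k


def symmetric_capacity(params: ResourceParams) -> CapacityResult:
    """Capacity when the resource is halved at every division.

    Returns a :class:`CapacityResult` with ``Ns = Z0/Zc``,
    ``cycles_symmetric = floor(log2(Z0/Zc))`` and
    ``cells_symmetric_discrete = 2**cycles_symmetric``.
    """
    k = _symmetric_cycles(params.Z0, params.Zc)
    return CapacityResult(
        Ns=params.Z0 / params.Zc,
        cycles_symmetric=k,
        cells_symmetric_discrete=2**k,
    )


def asymmetric_capacity(params: ResourceParams) -> CapacityResult:
    """Capacity when the progenitor retains the whole pool at each division.

    ``Nas = (Z0 - Zc)/deltaZ`` daughters for ``deltaZ > 0``; with
    ``deltaZ == 0`` division can proceed indefinitely and the result is
    flagged ``unbounded``.
    """
    if params.deltaZ == 0:
        return CapacityResult(Nas=math.inf, unbounded=True)
    return CapacityResult(Nas=(params.Z0 - params.Zc) / params.deltaZ)


def preferred_strategy(
    params: ResourceParams,
) -> Literal["symmetric", "asymmetric", "tie"]:
    """Which segregation strategy yields the larger continuous capacity.

    Compares ``Nas`` against ``Ns`` with relative tolerance 1e-9 to avoid
    spurious flips from float noise near the crossing point
    ``deltaZ = (Z0 - Zc) * Zc / Z0``.
    """
    if params.deltaZ <= 0:
        raise ValueError("preferred_strategy requires deltaZ > 0")
    ns = symmetric_capacity(params).Ns
    nas = asymmetric_capacity(params).Nas
    assert ns is not None and nas is not None
    if math.isclose(ns, nas, rel_tol=_TIE_RTOL):
        return "tie"
    return "asymmetric" if nas > ns else "symmetric"
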