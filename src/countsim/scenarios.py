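"""Observer-to-(site, year) assignment under spatial and temporal
observer-change scenarios.

The canonical grid crosses spatial allocation (O1: one observer counts all
sites in a year; O24: the 24-observer pool is spread over the sites) with
temporal rotation (T1: no change over the series; T5: identity changes
every 5 years; T25: identity changes annually). Generalisations — k
observers over S sites, arbitrary rotation period — are expressed by the
same :class:`ScenarioSpec`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScenarioSpec",
    "CANONICAL_SCENARIOS",
    "draw_temporal_rotation",
    "draw_spatial_allocation",
    "build_assignment",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One monitoring design.

    ``n_spatial_observers`` (k) is the number of observers active in any
    one year: 1 means a single observer covers every site; k > 1 means k
    observers partition the sites as evenly as possible.
    ``rotation_period`` is the number of consecutive years an observer
    identity persists (1 = annual change; ``n_years`` = never changes).
    ``redraw_allocation`` controls whether the site partition is redrawn at
    each temporal block boundary under spread mode.
    """

    name: str
    n_sites: int = 100
    n_years: int = 25
    n_spatial_observers: int = 1
    rotation_period: int = 25
    redraw_allocation: bool = True

    def __post_init__(self):
        if not 1 <= self.rotation_period <= self.n_years:
            raise ValueError("rotation_period must be in [1, n_years]")
        if self.n_spatial_observers < 1:
            raise ValueError("n_spatial_observers must be >= 1")
        if self.n_spatial_observers > self.n_sites:
            raise ValueError("more spatial observers than sites")

    @property
    def n_blocks(self) -> int:
        return math.ceil(self.n_years / self.rotation_period)

    @classmethod
    def from_name(cls, name: str, n_sites: int = 100, n_years: int = 25) -> "ScenarioSpec":
        """Build a spec from a canonical name like ``"O1T5"`` or ``"O24T25"``.

        ``O<k>`` gives the number of spatial observers; ``T<c>`` the number
        of distinct temporal identities over the series (T1 = constant,
        T<n_years> = annual change), i.e. rotation_period = n_years // c.
        """
        m = re.fullmatch(r"O(\d+)\s*T(\d+)", name.replace(" ", ""))
        if not m:
            raise ValueError(f"unrecognised scenario name: {name!r}")
        k, changes = int(m.group(1)), int(m.group(2))
        if changes < 1 or changes > n_years:
            raise ValueError(f"temporal label T{changes} outside [1, {n_years}]")
        rotation = max(1, n_years // changes)
        return cls(name=name, n_sites=n_sites, n_years=n_years,
                   n_spatial_observers=k, rotation_period=rotation)


CANONICAL_SCENARIOS = ("O1T1", "O1T5", "O1T25", "O24T1", "O24T5", "O24T25")


def draw_temporal_rotation(pool, rotation_period: int, n_years: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Observer identity for each temporal block.

    Blocks are filled by sampling the pool without replacement; once the
    pool is exhausted, remaining blocks are re-selected with replacement
    from the full pool (e.g. a 24-observer pool under annual rotation over
    25 years: 24 distinct observers then one re-drawn for year 25).
    """
    pool = np.asarray(pool)
    if pool.size == 0:
        raise ValueError("observer pool is empty")
    n_blocks = math.ceil(n_years / rotation_period)
    head = rng.permutation(pool)[: min(n_blocks, pool.size)]
    if n_blocks <= pool.size:
        return head
    tail = rng.choice(pool, size=n_blocks - pool.size, replace=True)
    return np.concatenate([head, tail])


def draw_spatial_allocation(observers, n_sites: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Partition sites among observers as evenly as possible.

    Returns the observer for each site. With k observers over S sites,
    ``S mod k`` observers get ``ceil(S/k)`` sites and the rest get
    ``floor(S/k)``; both the partition and which observers take the extra
    site are randomised. Every observer must receive at least one site.
    """
    observers = np.asarray(observers)
    k = observers.size
    if k == 0:
        raise ValueError("no observers to allocate")
    if k > n_sites:
        raise ValueError(f"{k} observers cannot each get a site among {n_sites}")
    counts = np.full(k, n_sites // k)
    counts[: n_sites % k] += 1
    order = rng.permutation(k)
    alloc = np.repeat(observers[order], counts[order])
    site_order = rng.permutation(n_sites)
    out = np.empty(n_sites, dtype=observers.dtype)
    out[site_order] = alloc
    return out


def build_assignment(spec: ScenarioSpec, pool, rng: np.random.Generator) -> np.ndarray:
    """Assignment table: observer for every (site, year) cell.

    Single-observer mode applies one temporal rotation across all sites.
    Spread mode draws k active observers per temporal block — chunks of a
    without-replacement pass through the pool, re-drawing with replacement
    once the pool is exhausted, so with k equal to the pool size every
    block uses the whole pool and temporal change acts purely through
    re-partitioning. At each block boundary a fresh site partition is
    drawn (unless ``redraw_allocation`` is False, in which case both the
    active set and the partition of the first block are frozen).
    """
    pool = np.asarray(pool)
    table = np.empty((spec.n_sites, spec.n_years), dtype=pool.dtype)
    blocks = [
        slice(b * spec.rotation_period, min((b + 1) * spec.rotation_period, spec.n_years))
        for b in range(spec.n_blocks)
    ]
    if spec.n_spatial_observers == 1:
        seq = draw_temporal_rotation(pool, spec.rotation_period, spec.n_years, rng)
        for b, sl in enumerate(blocks):
            table[:, sl] = seq[b]
        return table

    k = spec.n_spatial_observers
    if k > pool.size:
        raise ValueError(f"spread mode needs {k} observers but pool has {pool.size}")
    n_blocks = len(blocks)
    # per-block active sets: consecutive chunks of without-replacement
    # passes through the pool (a fresh permutation once a pass is
    # exhausted), so with k = pool size every block re-spreads the whole
    # pool, and with k < pool observer identities rotate across blocks
    slots_needed = n_blocks * k
    n_passes = -(-slots_needed // pool.size)
    deck = np.concatenate([rng.permutation(pool) for _ in range(n_passes)])
    alloc = None
    for b, sl in enumerate(blocks):
        if b == 0 or spec.redraw_allocation:
            active = deck[b * k: (b + 1) * k] if spec.redraw_allocation else deck[:k]
            alloc = draw_spatial_allocation(active, spec.n_sites, rng)
        table[:, sl] = alloc[:, None]
    return table
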