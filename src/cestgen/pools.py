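"""Proton-pool and tissue-system domain types.

A :class:`TissueSystem` is the complete multi-pool parameter set consumed by
one Bloch-McConnell simulation: a water pool, up to five CEST solute pools
(amide, guanidine, amine, OH, NOE, ...), and an optional semisolid pool.

The magnetization state vector is laid out as three components (Mx, My, Mz)
per *full* pool in order water, solutes, semisolid-if-full, followed by a
single Mz component for a lineshape-approximated semisolid pool.  All
magnetizations are fractions of the equilibrium water magnetization M0, so at
thermal equilibrium Mz of each pool equals its proton volume fraction f
(water: 1) and the transverse components vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional


import numpy as np

LINESHAPE_FULL = "full-3-component"
LINESHAPE_LORENTZIAN = "lorentzian"
LINESHAPE_SUPER_LORENTZIAN = "super-lorentzian"
LINESHAPES = (LINESHAPE_FULL, LINESHAPE_LORENTZIAN, LINESHAPE_SUPER_LORENTZIAN)


@dataclass(frozen=True)
class Pool:
    """One proton pool.

    Parameters
    ----------
    name
        Label, e.g. ``"water"``, ``"amine"``, ``"mt"``.
    t1_s, t2_s
        Longitudinal / transverse relaxation times in seconds.
    f
        Proton volume fraction relative to water (water has f = 1).
    k_sw
        Exchange rate toward water, s^-1 (0 for water).
    delta_ppm
        Chemical shift relative to water, ppm (positive downfield).
    lineshape
        ``"full-3-component"`` for pools whose transverse magnetization is
        simulated explicitly (water and CEST solutes), or an absorption
        lineshape (``"lorentzian"`` / ``"super-lorentzian"``) for a semisolid
        pool treated with a longitudinal saturation-rate term only.
    """

    name: str
    t1_s: float
    t2_s: float
    f: float = 1.0
    k_sw: float = 0.0
    delta_ppm: float = 0.0
    lineshape: str = LINESHAPE_FULL

    def __post_init__(self):
        if self.t1_s <= 0 or self.t2_s <= 0:
            raise ValueError(
                f"pool {self.name!r}: relaxation times must be positive "
                f"(T1={self.t1_s}, T2={self.t2_s})"
            )
        if self.k_sw < 0:
            raise ValueError(f"pool {self.name!r}: exchange rate must be >= 0")
        if not 0 <= self.f <= 1:
            raise ValueError(f"pool {self.name!r}: f must be in [0, 1]")
        if self.lineshape not in LINESHAPES:
            raise ValueError(
                f"pool {self.name!r}: unknown lineshape {self.lineshape!r}"
            )

    def replace(self, **kw) -> "Pool":
        return replace(self, **kw)


@dataclass(frozen=True)
class TissueSystem:
    """Water + CEST solutes + optional semisolid pool.

    Invariants: between 1 and 7 pools in total, the non-water proton volume
    fractions sum to < 1, and the super-Lorentzian lineshape is permitted
    only on the semisolid pool.
    """

    water: Pool
    solutes: tuple = field(default_factory=tuple)
    semisolid: Optional[Pool] = None

    def __post_init__(self):
        object.__setattr__(self, "solutes", tuple(self.solutes))
        if self.water.f != 1.0:
            raise ValueError("water pool must have f = 1")
        for p in self.solutes:
            if p.lineshape != LINESHAPE_FULL:
                raise ValueError(
                    f"CEST pool {p.name!r} must use the full 3-component "
                    f"treatment, not {p.lineshape!r}"
                )
            if not p.f < 1:
                raise ValueError(f"solute pool {p.name!r} must have f < 1")
        if self.n_pools > 7:
            raise ValueError("at most 7 pools are supported")
        total_f = sum(p.f for p in self.solutes)
        if self.semisolid is not None:
            total_f += self.semisolid.f
        if total_f >= 1:
            raise ValueError("non-water proton volume fractions must sum to < 1")
        names = [p.name for p in self.pools]
        if len(set(names)) != len(names):
            raise ValueError("pool names must be unique")

    # -- structure ---------------------------------------------------------
    @property
    def pools(self) -> tuple:
        ps = (self.water,) + self.solutes
        if self.semisolid is not None:
            ps = ps + (self.semisolid,)
        return ps

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def full_pools(self) -> tuple:
        """Pools simulated with all three magnetization components."""
        ps = (self.water,) + self.solutes
        if self.semisolid is not None and self.semisolid.lineshape == LINESHAPE_FULL:
            ps = ps + (self.semisolid,)
        return ps

    @property
    def approx_pool(self) -> Optional[Pool]:
        """The semisolid pool if it uses an absorption-lineshape treatment."""
        if self.semisolid is not None and self.semisolid.lineshape != LINESHAPE_FULL:
            return self.semisolid
        return None

    @property
    def dim(self) -> int:
        """Length of the magnetization state vector."""
        return 3 * len(self.full_pools) + (1 if self.approx_pool is not None else 0)

    def pool_by_name(self, name: str) -> Pool:
        for p in self.pools:
            if p.name == name:
                return p
        raise KeyError(name)

    def equilibrium(self) -> np.ndarray:
        """Thermal-equilibrium state vector (M0-normalized)."""
        m = np.zeros(self.dim)
        for i, p in enumerate(self.full_pools):
            m[3 * i + 2] = p.f
        if self.approx_pool is not None:
            m[-1] = self.approx_pool.f
        return m


def two_pool(
    t1w_s: float,
    t2w_s: float,
    t1s_s: float,
    t2s_s: float,
    f: float,
    k_sw: float,
    delta_ppm: float,
    name: str = "solute",
    lineshape: str = LINESHAPE_FULL,
) -> TissueSystem:
    """Convenience constructor for a water + single-solute system."""
    water = Pool("water", t1w_s, t2w_s)
    pool = Pool(name, t1s_s, t2s_s, f, k_sw, delta_ppm, lineshape)
    if lineshape == LINESHAPE_FULL:
        return TissueSystem(water, (pool,))
    return TissueSystem(water, (), pool)


def water_only(t1w_s: float, t2w_s: float) -> TissueSystem:
    return TissueSystem(Pool("water", t1w_s, t2w_s))
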