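"""Per-site binding constants and standard free energies from restrained FEP.

A binding site j holds up to ``n_j_max`` ligands.  For each occupancy level
n the FEP input supplies the cumulative reversible work W*_n (kcal/mol) of
transferring the n ligands from gas phase into the site while each ligand i
is held by an isotropic harmonic restraint of force constant k_i
(kcal/mol/Å²).  The level-n equilibrium constant of the site is

    K_n = (1/n!) · ∏_i (2π / β k_i)^(3/2) · exp(−β [W*_n − n μ̄])

in Å³ⁿ, where μ̄ is the ligand's excess chemical potential in the reservoir;
the (2π/βk)^(3/2) factor is the effective configurational volume sampled
under the restraint, and 1/n! corrects for ligand indistinguishability
inside the site volume.  The standard binding free energy follows as

    ΔG°_n = −β⁻¹ ln (K_n · (C°)ⁿ)

against the 1 M standard concentration.  All K's are computed in log space
and exponentiated last, so large |W*| cannot overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .thermo import (
    MM_TO_INV_A3,
    LigandReservoir,
    ThermoContext,
)

__all__ = [
    "AffinityLevel",
    "SiteAffinity",
    "PerSiteConstants",
    "effective_volume",
    "compose_two_step_work",
    "ComposedWork",
    "site_binding_constant",
    "log_site_binding_constant",
    "standard_binding_free_energy",
    "free_energy_decomposition",
    "compute_site_constants",
]

_LN_MM_TO_A3 = math.log(MM_TO_INV_A3)


@dataclass(frozen=True)
class AffinityLevel:
    """FEP input for one occupancy level of one site.

    ``force_constants`` has one entry per ligand bound at this level (the
    restraint applied to each ligand in the level's FEP setup); ``work`` is
    the cumulative reversible work W*_n, gas phase → n bound.
    """

    force_constants: tuple[float, ...]
    work: float
    work_error: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "force_constants", tuple(float(k) for k in self.force_constants)
        )
        if not self.force_constants:
            raise ValueError("level needs at least one force constant")
        if any(k <= 0 for k in self.force_constants):
            raise ValueError(
                f"force constants must be positive, got {self.force_constants}"
            )
        if self.work_error < 0:
            raise ValueError("work_error must be >= 0")


@dataclass(frozen=True)
class SiteAffinity:
    """All FEP inputs for one binding site.

    ``levels`` maps occupancy level n (1, 2, …) to its :class:`AffinityLevel`;
    the levels present must form a contiguous range 1..max_occupancy, and
    level n must carry exactly n force constants.
    """

    site_id: str
    region: str
    levels: dict[int, AffinityLevel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ns = sorted(self.levels)
        if ns != list(range(1, len(ns) + 1)):
            raise ValueError(
                f"site {self.site_id}: levels {ns} are not contiguous from 1"
            )
        for n, lvl in self.levels.items():
            if len(lvl.force_constants) != n:
                raise ValueError(
                    f"site {self.site_id} level {n}: expected {n} force "
                    f"constants, got {len(lvl.force_constants)}"
                )

    @property
    def max_occupancy(self) -> int:
        return len(self.levels)

    def level(self, n: int) -> AffinityLevel:
        try:
            return self.levels[n]
        except KeyError:
            raise KeyError(
                f"site {self.site_id} has no occupancy level {n} "
                f"(max {self.max_occupancy})"
            ) from None


def effective_volume(k: float, ctx: ThermoContext) -> float:
    """Configurational volume (Å³) sampled under a harmonic restraint.

    A ligand centroid restrained by u(R) = ½ k |R − R*|² explores an
    effective volume (2π/βk)^(3/2); stiffer restraints confine it more.
    """
    if k <= 0:
        raise ValueError(f"force constant must be positive, got {k!r}")
    return (2.0 * math.pi / (ctx.beta * k)) ** 1.5


class ComposedWork(NamedTuple):
    work: float
    error: float


def compose_two_step_work(
    w1: float, w2_given_1: float, error1: float = 0.0, error2: float = 0.0
) -> ComposedWork:
    """Cumulative two-ligand work from a two-step FEP protocol.

    The double-occupancy work is obtained by coupling a first ligand to the
    vacant site (W*₁) and then a second ligand to the pre-occupied site
    (W*₂|₁): W*₂ = W*₁ + W*₂|₁.  Statistical errors of the two independent
    steps add in quadrature.
    """
    return ComposedWork(w1 + w2_given_1, math.hypot(error1, error2))


def log_site_binding_constant(
    aff: SiteAffinity,
    level: int,
    res: LigandReservoir,
    ctx: ThermoContext,
) -> float:
    """ln K_n with K_n in mM⁻ⁿ; the numerically safe primitive."""
    lvl = aff.level(level)
    n = level
    ln_veff = sum(
        1.5 * math.log(2.0 * math.pi / (ctx.beta * k)) for k in lvl.force_constants
    )
    ln_k_A3 = (
        -math.lgamma(n + 1)
        + ln_veff
        - ctx.beta * (lvl.work - n * res.excess_chemical_potential)
    )
    return ln_k_A3 + n * _LN_MM_TO_A3


def site_binding_constant(
    aff: SiteAffinity,
    level: int,
    res: LigandReservoir,
    ctx: ThermoContext,
) -> float:
    """Equilibrium constant K_n (mM⁻ⁿ) for level-n occupancy of one site."""
    return math.exp(log_site_binding_constant(aff, level, res, ctx))


def standard_binding_free_energy(
    K_n: float, n: int, ctx: ThermoContext
) -> float:
    """ΔG° (kcal/mol) of binding n ligands, from K_n in mM⁻ⁿ.

    ΔG° = −β⁻¹ ln(K_n (C°)ⁿ) with C° = 1000 mM.
    """
    if K_n <= 0:
        raise ValueError(f"K must be positive, got {K_n!r}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    return -math.log(K_n * 1e3**n) / ctx.beta


def free_energy_decomposition(
    aff: SiteAffinity,
    level: int,
    res: LigandReservoir,
    ctx: ThermoContext,
) -> tuple[float, float, float]:
    """Three additive contributions to ΔG°_n (kcal/mol).

    Returns ``(work, expansion, indistinguishability)``:

    1. W*_n − n μ̄ — restrained binding from gas phase, less the reservoir
       solvation of the n ligands;
    2. −β⁻¹ Σ_i ln[C° (2π/βk_i)^(3/2)] — letting the restrained ligands
       expand from their effective volumes to the standard volume (C°)⁻¹;
    3. +β⁻¹ ln n! — the correction for n indistinguishable ligands in one
       site volume (zero for n = 1).

    The three terms sum to :func:`standard_binding_free_energy` exactly.
    """
    lvl = aff.level(level)
    n = level
    c0 = ctx.standard_concentration
    work_term = lvl.work - n * res.excess_chemical_potential
    expansion = -(
        sum(
            math.log(c0 * (2.0 * math.pi / (ctx.beta * k)) ** 1.5)
            for k in lvl.force_constants
        )
        / ctx.beta
    )
    indist = math.lgamma(n + 1) / ctx.beta
    return work_term, expansion, indist


@dataclass(frozen=True)
class PerSiteConstants:
    """Computed equilibrium constants for one site, all occupancy levels.

    ``log_K`` holds ln K_n (K_n in mM⁻ⁿ) for n = 0..max_occupancy, with
    K_0 ≡ 1.  ``log_K_bounds`` are the (lower, upper) ln K from propagating
    the W* statistical error ε as the multiplicative factor exp(±βε).
    """

    site_id: str
    region: str
    log_K: tuple[float, ...]
    log_K_bounds: tuple[tuple[float, float], ...]

    @property
    def max_occupancy(self) -> int:
        return len(self.log_K) - 1

    def K(self, n: int) -> float:
        """Equilibrium constant K_n in mM⁻ⁿ (K_0 = 1)."""
        return math.exp(self.log_K[n])

    def K_bounds(self, n: int) -> tuple[float, float]:
        lo, hi = self.log_K_bounds[n]
        return math.exp(lo), math.exp(hi)

    def dG0(self, n: int, ctx: ThermoContext) -> float:
        """Standard binding free energy ΔG°_n in kcal/mol (n ≥ 1)."""
        if n < 1:
            raise ValueError("dG0 is undefined for the empty level")
        return -(self.log_K[n] + n * math.log(1e3)) / ctx.beta

    def level_log_weights(self, rho_mM: float) -> np.ndarray:
        """ln[ρ̄ⁿ K_n] for n = 0..max; the site's occupancy-level weights.

        ρ̄ = 0 gives weight 1 for the empty level and 0 (−inf in log space)
        for every occupied level.
        """
        if rho_mM < 0:
            raise ValueError("concentration must be >= 0 mM")
        out = np.asarray(self.log_K, dtype=float).copy()
        ns = np.arange(len(out))
        if rho_mM == 0.0:
            out[1:] = -np.inf
        else:
            out += ns * math.log(rho_mM)
        return out


def compute_site_constants(
    aff: SiteAffinity,
    res: LigandReservoir,
    ctx: ThermoContext,
) -> PerSiteConstants:
    """Evaluate K_n and error bounds for every level of one site."""
    log_K = [0.0]
    bounds = [(0.0, 0.0)]
    for n in range(1, aff.max_occupancy + 1):
        lk = log_site_binding_constant(aff, n, res, ctx)
        eps = aff.level(n).work_error
        log_K.append(lk)
        bounds.append((lk - ctx.beta * eps, lk + ctx.beta * eps))
    return PerSiteConstants(
        site_id=aff.site_id,
        region=aff.region,
        log_K=tuple(log_K),
        log_K_bounds=tuple(bounds),
    )


def compute_all_constants(
    sites: Sequence[SiteAffinity],
    res: LigandReservoir,
    ctx: ThermoContext,
) -> list[PerSiteConstants]:
    """Per-site constants for a whole receptor."""
    return [compute_site_constants(s, res, ctx) for s in sites]
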