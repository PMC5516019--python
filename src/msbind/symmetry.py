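"""Symmetry averaging over indistinguishable sites of an oligomer.

An f-fold symmetric receptor (e.g. a homotetrameric channel) carries f
copies of each structurally distinguishable binding region, so the s sites
group into s′ ≤ s symmetry classes {j}_k.  The per-copy affinities differ
only through finite conformational sampling, and the class-average
estimator

    Ā_k = (1/f) Σ_{j∈{j}_k} A_j

with its population variance gives the statistically improved per-region
constant.  Averaging is done on K (linear scale), not on ΔG°; state
constants of the symmetrized receptor are rebuilt as products of class
constants, one factor per member-site occupancy (so the symmetry numbers
χ(n_k) of a state sum to s over the classes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .affinity import PerSiteConstants
from .occupancy import OccupancyState, state_constant

__all__ = [
    "SymmetryClass",
    "ClassConstants",
    "class_average",
    "validate_classes",
    "class_constants",
    "symmetrize_affinities",
    "symmetric_state_constant",
]


@dataclass(frozen=True)
class SymmetryClass:
    """One group of indistinguishable sites related by oligomer symmetry."""

    class_id: str
    member_sites: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(str(m) for m in self.member_sites)
        if not members:
            raise ValueError(f"class {self.class_id}: empty member set")
        if len(set(members)) != len(members):
            raise ValueError(f"class {self.class_id}: duplicate members")
        object.__setattr__(self, "member_sites", members)

    @property
    def fold(self) -> int:
        return len(self.member_sites)


def class_average(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation (divisor f).

    The spread reflects structural heterogeneity across the oligomer
    subunits, a finite-sampling error of the ensemble, so the population
    (not sample) estimator is used.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("class_average needs at least one value")
    return float(v.mean()), float(v.std(ddof=0))


def validate_classes(
    classes: Sequence[SymmetryClass], site_ids: Sequence[str]
) -> None:
    """Check the classes partition the site set exactly."""
    covered: list[str] = []
    for c in classes:
        covered.extend(c.member_sites)
    if len(covered) != len(set(covered)):
        raise ValueError("a site appears in more than one symmetry class")
    missing = set(site_ids) - set(covered)
    if missing:
        raise ValueError(f"sites not covered by any class: {sorted(missing)}")
    extra = set(covered) - set(site_ids)
    if extra:
        raise ValueError(f"classes reference unknown sites: {sorted(extra)}")


@dataclass(frozen=True)
class ClassConstants:
    """Class-averaged constants: K̄_n ± σ for n = 0..max_occupancy."""

    class_id: str
    member_sites: tuple[str, ...]
    K_mean: tuple[float, ...]
    K_sd: tuple[float, ...]

    @property
    def fold(self) -> int:
        return len(self.member_sites)

    @property
    def max_occupancy(self) -> int:
        return len(self.K_mean) - 1


def class_constants(
    per_site: Sequence[PerSiteConstants],
    classes: Sequence[SymmetryClass],
) -> list[ClassConstants]:
    """Average the per-site K_n over each symmetry class.

    All members of a class must share the same maximum occupancy.
    """
    validate_classes(classes, [p.site_id for p in per_site])
    by_id = {p.site_id: p for p in per_site}
    out = []
    for c in classes:
        members = [by_id[m] for m in c.member_sites]
        nmax = {m.max_occupancy for m in members}
        if len(nmax) != 1:
            raise ValueError(
                f"class {c.class_id}: members disagree on max occupancy {nmax}"
            )
        means, sds = [], []
        for n in range(nmax.pop() + 1):
            mean, sd = class_average([m.K(n) for m in members])
            means.append(mean)
            sds.append(sd)
        out.append(
            ClassConstants(
                class_id=c.class_id,
                member_sites=c.member_sites,
                K_mean=tuple(means),
                K_sd=tuple(sds),
            )
        )
    return out


def symmetrize_affinities(
    per_site: Sequence[PerSiteConstants],
    classes: Sequence[SymmetryClass],
) -> list[PerSiteConstants]:
    """Replace every site's constants by its class means.

    Site order and ids are preserved; the K bounds of each symmetrized site
    are mean ∓ population sd (lower bound floored just above zero when the
    spread exceeds the mean).  Because the class mean is arithmetic in K,
    the dilute-limit slope Σ_j K₁ⱼ of the titration curve is exactly
    preserved.
    """
    cc = class_constants(per_site, classes)
    class_of = {
        m: c for c in cc for m in c.member_sites
    }
    out = []
    for p in per_site:
        c = class_of[p.site_id]
        log_K, bounds = [], []
        for n in range(c.max_occupancy + 1):
            k, sd = c.K_mean[n], c.K_sd[n]
            log_K.append(math.log(k))
            lo = max(k - sd, k * 1e-12)
            bounds.append((math.log(lo), math.log(k + sd)))
        out.append(
            PerSiteConstants(
                site_id=p.site_id,
                region=c.class_id,
                log_K=tuple(log_K),
                log_K_bounds=tuple(bounds),
            )
        )
    return out


def symmetric_state_constant(
    per_site: Sequence[PerSiteConstants],
    classes: Sequence[SymmetryClass],
    state: OccupancyState,
) -> float:
    """State constant K(n₁,…,n_s) rebuilt from class-average affinities.

    Each member site of class k at occupancy n contributes one factor of
    the class constant K̄_{kn}; member sites of a class may carry different
    occupancies within one state (general multiset reading of the symmetry
    numbers).  Identical to :func:`msbind.occupancy.state_constant` applied
    to the symmetrized per-site table.
    """
    return state_constant(symmetrize_affinities(per_site, classes), state)
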