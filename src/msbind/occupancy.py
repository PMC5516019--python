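"""Occupancy-state statistics of a multi-site receptor.

The receptor exposes s independent saturable sites; site j holds
0..n_j_max ligands.  An occupancy state O(n₁,…,n_s) has statistical weight
ρ̄ⁿ K(n₁,…,n_s) against a reservoir at density ρ̄, with the state constant
factorizing over sites, K = ∏_j K_{n_j}.  Normalizing over all
∏_j (n_j_max + 1) states gives the state probabilities

    ρ(n₁,…,n_s) = ρ̄ⁿ K(n₁,…,n_s) / Σ_{n'} ρ̄ⁿ' K(n'₁,…,n'_s)

from which marginals, macrostate probabilities ρ(n), ensemble averages and
titration curves follow.  Because the sites are independent, everything can
also be computed without enumeration from per-site level weights
w_j(n) = ρ̄ⁿ K_{jn}: marginals are per-site normalizations and ρ(n) is the
polynomial convolution of the per-site weight vectors.  Weights live in log
space and are normalized by log-sum-exp so arbitrarily strong binders are
safe.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .affinity import PerSiteConstants

__all__ = [
    "OccupancyState",
    "StateDistribution",
    "count_states",
    "state_constant",
    "state_probabilities",
    "factorized_distribution",
    "marginal_occupancy",
    "macrostate_probabilities",
    "ensemble_average",
    "mean_occupancy",
    "titration_curve",
    "ranked_states",
    "DEFAULT_ENUMERATION_CAP",
]

DEFAULT_ENUMERATION_CAP = 1_000_000

#: Reservoir concentration (mM) at or above which the dilute-solution
#: assumptions behind the state weights become questionable.
DILUTE_WARNING_MM = 1000.0


@dataclass(frozen=True)
class OccupancyState:
    """One receptor microstate: exactly n_j ligands bound at each site j."""

    occupancies: tuple[int, ...]

    def __post_init__(self) -> None:
        occ = tuple(int(n) for n in self.occupancies)
        if any(n < 0 for n in occ):
            raise ValueError(f"occupancies must be >= 0, got {occ}")
        object.__setattr__(self, "occupancies", occ)

    @property
    def total(self) -> int:
        return sum(self.occupancies)

    def __str__(self) -> str:
        return "".join(str(n) for n in self.occupancies)


def _dims(per_site: Sequence[PerSiteConstants]) -> tuple[int, ...]:
    return tuple(p.max_occupancy + 1 for p in per_site)


def count_states(sites: Sequence) -> int:
    """Number of enumerable occupancy states, ∏_j (n_j_max + 1).

    Accepts anything with a ``max_occupancy`` attribute per element
    (FEP inputs or computed constants).  An empty receptor has the single
    empty state.
    """
    out = 1
    for s in sites:
        out *= s.max_occupancy + 1
    return out


def _validate_state(
    per_site: Sequence[PerSiteConstants], state: OccupancyState
) -> None:
    if len(state.occupancies) != len(per_site):
        raise ValueError(
            f"state has {len(state.occupancies)} sites, receptor has "
            f"{len(per_site)}"
        )
    for p, n in zip(per_site, state.occupancies):
        if n > p.max_occupancy:
            raise ValueError(
                f"site {p.site_id}: occupancy {n} exceeds max "
                f"{p.max_occupancy}"
            )


def state_constant(
    per_site: Sequence[PerSiteConstants], state: OccupancyState
) -> float:
    """State equilibrium constant K(n₁,…,n_s) in mM⁻ⁿ, n = Σ n_j.

    Under site independence this is the product of the per-site level
    constants; the empty state has K = 1.
    """
    _validate_state(per_site, state)
    return math.exp(
        sum(p.log_K[n] for p, n in zip(per_site, state.occupancies))
    )


def _check_dilute(concentration: float) -> None:
    if concentration >= DILUTE_WARNING_MM:
        warnings.warn(
            f"concentration {concentration:g} mM is at or above 1 M; the "
            "dilute-reservoir model is unreliable there",
            UserWarning,
            stacklevel=3,
        )


@dataclass(frozen=True)
class StateDistribution:
    """Normalized occupancy-state distribution at one reservoir concentration.

    In ``enumerated`` mode ``log_probs`` holds the log probability of every
    state, flattened in C order over the per-site level axes (site 0
    slowest).  In ``factorized`` mode only the per-site marginal tables are
    stored; they are exact for independent sites and all derived quantities
    are computed from them.
    """

    concentration: float
    site_ids: tuple[str, ...]
    dims: tuple[int, ...]
    marginals: tuple[np.ndarray, ...]
    mode: str  # "enumerated" | "factorized"
    log_probs: np.ndarray | None = None

    def state_probability(self, state: OccupancyState) -> float:
        """Probability of one specific occupancy state."""
        if len(state.occupancies) != len(self.dims):
            raise ValueError("state/site count mismatch")
        for n, d in zip(state.occupancies, self.dims):
            if n >= d:
                raise ValueError(f"occupancy {n} out of range for dims {self.dims}")
        if self.mode == "enumerated":
            idx = int(np.ravel_multi_index(state.occupancies, self.dims))
            return float(np.exp(self.log_probs[idx]))
        return float(
            np.prod([m[n] for m, n in zip(self.marginals, state.occupancies)])
        )

    def states(self) -> np.ndarray:
        """All occupancy vectors, shape (n_states, s); enumerated mode only."""
        if self.mode != "enumerated":
            raise ValueError("state listing requires enumerated mode")
        grids = np.unravel_index(np.arange(len(self.log_probs)), self.dims)
        return np.stack(grids, axis=1)


def state_probabilities(
    per_site: Sequence[PerSiteConstants],
    concentration: float,
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
) -> StateDistribution:
    """Enumerate all occupancy states and their probabilities.

    Raises if the state space exceeds ``enumeration_cap``; use
    :func:`factorized_distribution` in that case — for independent sites it
    yields the same marginals, macrostates and averages without enumerating.
    """
    n_states = count_states(per_site)
    if n_states > enumeration_cap:
        raise ValueError(
            f"{n_states} states exceed the enumeration cap "
            f"{enumeration_cap}; use factorized_distribution() instead"
        )
    _check_dilute(concentration)
    dims = _dims(per_site)
    log_w = np.zeros(1)
    for p in per_site:
        log_w = np.add.outer(log_w, p.level_log_weights(concentration)).ravel()
    log_probs = log_w - logsumexp(log_w)
    probs = np.exp(log_probs).reshape(dims)
    marginals = tuple(
        probs.sum(axis=tuple(a for a in range(len(dims)) if a != j))
        for j in range(len(dims))
    )
    return StateDistribution(
        concentration=concentration,
        site_ids=tuple(p.site_id for p in per_site),
        dims=dims,
        marginals=marginals,
        mode="enumerated",
        log_probs=log_probs,
    )


def factorized_distribution(
    per_site: Sequence[PerSiteConstants], concentration: float
) -> StateDistribution:
    """Per-site marginal tables without enumerating the state space."""
    _check_dilute(concentration)
    marginals = []
    for p in per_site:
        lw = p.level_log_weights(concentration)
        marginals.append(np.exp(lw - logsumexp(lw)))
    return StateDistribution(
        concentration=concentration,
        site_ids=tuple(p.site_id for p in per_site),
        dims=_dims(per_site),
        marginals=tuple(marginals),
        mode="factorized",
    )


def marginal_occupancy(dist: StateDistribution, site_id: str) -> np.ndarray:
    """ρ(n_j): probability of each occupancy level of one site."""
    try:
        j = dist.site_ids.index(site_id)
    except ValueError:
        raise KeyError(f"unknown site id {site_id!r}") from None
    return dist.marginals[j].copy()


def macrostate_probabilities(dist: StateDistribution) -> np.ndarray:
    """ρ(n) over the total bound count n = 0..Σ n_j_max.

    Exact polynomial convolution of the per-site level distributions —
    no enumeration of the joint state space is needed.
    """
    acc = np.ones(1)
    for m in dist.marginals:
        acc = np.convolve(acc, m)
    return acc


def ensemble_average(
    dist: StateDistribution,
    state_fn: Callable[[tuple[int, ...]], float] | None = None,
    site_level_values: Mapping[str, Sequence[float]] | None = None,
) -> float:
    """Probability-weighted average ⟨A⟩ over occupancy states.

    Either supply ``state_fn`` mapping an occupancy vector to A (requires
    an enumerated distribution), or — for a per-site additive property
    A = Σ_j a_j(n_j) — ``site_level_values`` mapping site id to the values
    a_j(0..n_j_max), which is computed from the marginals in either mode.
    """
    if (state_fn is None) == (site_level_values is None):
        raise ValueError("supply exactly one of state_fn or site_level_values")
    if state_fn is not None:
        if dist.mode != "enumerated":
            raise ValueError("state_fn averaging requires enumerated mode")
        states = dist.states()
        vals = np.array([state_fn(tuple(s)) for s in states], dtype=float)
        return float(np.exp(dist.log_probs) @ vals)
    total = 0.0
    for sid, m in zip(dist.site_ids, dist.marginals):
        if sid not in site_level_values:
            raise ValueError(f"missing values for site {sid!r}")
        a = np.asarray(site_level_values[sid], dtype=float)
        if a.shape != m.shape:
            raise ValueError(
                f"site {sid!r}: expected {m.shape[0]} level values, got {a.shape}"
            )
        total += float(m @ a)
    return total


def mean_occupancy(dist: StateDistribution) -> tuple[float, dict[str, float]]:
    """⟨n⟩ and per-site ⟨n_j⟩ from the marginal tables."""
    per_site = {
        sid: float(m @ np.arange(len(m)))
        for sid, m in zip(dist.site_ids, dist.marginals)
    }
    return sum(per_site.values()), per_site


def titration_curve(
    per_site: Sequence[PerSiteConstants],
    concentrations: Sequence[float],
) -> pd.DataFrame:
    """⟨n⟩ and per-site ⟨n_j⟩ over a concentration series.

    Returns a DataFrame with columns ``concentration_mM``, ``n_mean`` and
    one ``n_<site_id>`` column per site.  ⟨n⟩ is non-decreasing in
    concentration and approaches Σ_j K₁ⱼ·ρ̄ in the dilute limit.
    """
    rows = []
    for c in concentrations:
        dist = factorized_distribution(per_site, c)
        n_tot, per = mean_occupancy(dist)
        row = {"concentration_mM": c, "n_mean": n_tot}
        row.update({f"n_{sid}": v for sid, v in per.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def ranked_states(
    dist: StateDistribution, top: int | None = None
) -> pd.DataFrame:
    """States sorted by descending probability.

    Ties are broken by lexicographic occupancy vector.  Returns columns
    ``state`` (the "n₁…n_s" digit string), ``total`` and ``probability``.
    """
    if dist.mode != "enumerated":
        raise ValueError("ranking requires enumerated mode")
    probs = np.exp(dist.log_probs)
    states = dist.states()
    # lexsort: last key is primary
    lex_cols = tuple(states[:, j] for j in range(states.shape[1] - 1, -1, -1))
    order = np.lexsort(lex_cols + (-probs,))
    if top is not None:
        order = order[:top]
    return pd.DataFrame(
        {
            "state": ["".join(map(str, states[i])) for i in order],
            "total": states[order].sum(axis=1),
            "probability": probs[order],
        }
    )
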