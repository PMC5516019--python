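"""Spatial ligand densities: from occupancy statistics to 3D maps.

The state-space description is mapped to a position-dependent ligand
density.  Within each site volume the density decomposes over the site's
occupancy levels,

    ρ_j(R) = Σ_n ρ(n_j = n) · ρ(R | n_j = n),

where ρ(R|n) — the conditional density given exactly n bound ligands — is
estimated as a Gaussian kernel density over the docked pose centroids at
that level, normalized so its grid integral equals n.  Outside the sites
the reservoir contributes its homogeneous density ρ̄, so the transmembrane
profile is ρ(z) = ρ̄·A(z) + Σ_j ρ_j(z) with A(z) the membrane-aqueous
cross-section area.  Grids use the OpenDX point convention (first value at
``origin``, points every ``spacing`` Å) and integrals are voxel sums ×
spacing³.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sites import BindingSite

__all__ = [
    "DensityGrid",
    "SystemGeometry",
    "grid_for_site",
    "conditional_density",
    "site_density",
    "z_projection",
    "export_grid",
    "read_grid",
]

DEFAULT_SPACING = 0.5  # Å
DEFAULT_BANDWIDTH_FLOOR = 0.8  # Å


@dataclass(frozen=True)
class DensityGrid:
    """Scalar number-density field (Å⁻³) on a regular isotropic grid."""

    origin: tuple[float, float, float]
    spacing: float
    values: np.ndarray  # shape (nx, ny, nz)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"values must be 3-D, got shape {v.shape}")
        if np.any(v < 0):
            raise ValueError("density values must be >= 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(
            self, "origin", tuple(float(x) for x in self.origin)
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        """Grid-point coordinates along one axis (Å)."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing * np.arange(n)

    def integral(self) -> float:
        """∫ρ dR approximated as voxel sum × spacing³ (number of ligands)."""
        return float(self.values.sum() * self.spacing**3)

    def z_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(z, ρ(z)) with ρ(z) in Å⁻¹: x/y voxel sums × spacing²."""
        prof = self.values.sum(axis=(0, 1)) * self.spacing**2
        return self.axis_coords(2), prof

    def same_lattice(self, other: "DensityGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.spacing, other.spacing)
        )


@dataclass(frozen=True)
class SystemGeometry:
    """Membrane-aqueous cross-section A(z) (Å²) over a z range (Å).

    ``area`` is either a constant Δx·Δy or a callable A(z).
    """

    area: float | Callable[[np.ndarray], np.ndarray]
    z_min: float
    z_max: float

    def cross_section(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if callable(self.area):
            a = np.asarray(self.area(z), dtype=float)
        else:
            a = np.full_like(z, float(self.area))
        if np.any(a <= 0):
            raise ValueError("cross-section area must be positive")
        return a


def grid_for_site(
    site: BindingSite,
    spacing: float = DEFAULT_SPACING,
    padding: float | None = None,
    bandwidth: float | None = None,
) -> DensityGrid:
    """Empty grid covering a site sphere, padded 3 bandwidths beyond it."""
    if padding is None:
        bw = bandwidth if bandwidth is not None else DEFAULT_BANDWIDTH_FLOOR
        padding = 3.0 * bw
    half = site.radius + padding
    n = int(np.ceil(2 * half / spacing)) + 1
    origin = tuple(c - spacing * (n - 1) / 2.0 for c in site.center)
    return DensityGrid(origin=origin, spacing=spacing, values=np.zeros((n, n, n)))


def _scott_bandwidth(points: np.ndarray, floor: float) -> float:
    """Scott-style isotropic bandwidth with a hard floor (Å)."""
    m = len(points)
    if m < 2:
        return floor
    sigma = float(points.std(axis=0, ddof=1).mean())
    return max(sigma * m ** (-1.0 / 7.0), floor)  # d = 3 → exponent −1/(d+4)


def conditional_density(
    site: BindingSite,
    points: Sequence[Sequence[float]],
    n_level: int,
    spacing: float = DEFAULT_SPACING,
    bandwidth: float | None = None,
    bandwidth_floor: float = DEFAULT_BANDWIDTH_FLOOR,
    grid: DensityGrid | None = None,
) -> DensityGrid:
    """Conditional ligand density ρ(R|n_j) from pose centroids.

    ``points`` are the ligand centroids observed with the site at occupancy
    ``n_level`` (for a doubly-occupied level, both ligand centroids of each
    pose contribute).  An isotropic Gaussian kernel is placed on every
    point and the field is rescaled so that its grid integral equals
    ``n_level`` — the grid domain is the numerical site volume δV_j.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError(
            f"site {site.site_id}: no poses at level {n_level}; a site with "
            "no observed poses at this level has zero density — skip it"
        )
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected (m, 3) points, got shape {pts.shape}")
    if n_level < 1:
        raise ValueError("n_level must be >= 1")
    h = bandwidth if bandwidth is not None else _scott_bandwidth(pts, bandwidth_floor)
    if grid is None:
        grid = grid_for_site(site, spacing=spacing, bandwidth=h)
    xs, ys, zs = (grid.axis_coords(a) for a in range(3))
    values = np.zeros(grid.shape)
    # separable kernel: accumulate outer products of per-axis Gaussians
    for p in pts:
        gx = np.exp(-0.5 * ((xs - p[0]) / h) ** 2)
        gy = np.exp(-0.5 * ((ys - p[1]) / h) ** 2)
        gz = np.exp(-0.5 * ((zs - p[2]) / h) ** 2)
        values += np.einsum("i,j,k->ijk", gx, gy, gz)
    total = values.sum() * grid.spacing**3
    if total <= 0:
        raise ValueError("kernel mass vanished on the grid; enlarge the grid")
    values *= n_level / total
    return DensityGrid(origin=grid.origin, spacing=grid.spacing, values=values)


def site_density(
    marginal: Sequence[float],
    conditionals: Mapping[int, DensityGrid],
) -> DensityGrid:
    """Site density ρ_j(R) = Σ_n ρ(n_j) ρ(R|n_j).

    ``marginal`` is the level-probability vector ρ(n_j), n = 0..n_max;
    levels with zero probability may omit their conditional grid.  The
    result integrates to ⟨n_j⟩ = Σ_n n·ρ(n_j).
    """
    m = np.asarray(marginal, dtype=float)
    if not np.isclose(m.sum(), 1.0, atol=1e-6):
        raise ValueError(f"marginal must be normalized, sums to {m.sum()}")
    ref = None
    for n in range(1, len(m)):
        if m[n] > 0 and n not in conditionals:
            raise ValueError(f"missing conditional density for level {n}")
        if n in conditionals:
            g = conditionals[n]
            if ref is None:
                ref = g
            elif not ref.same_lattice(g):
                raise ValueError("conditional grids are on different lattices")
    if ref is None:
        raise ValueError(
            "site has no occupied level with poses; its density is zero"
        )
    values = np.zeros(ref.shape)
    for n in range(1, len(m)):
        if m[n] > 0:
            values += m[n] * conditionals[n].values
    return DensityGrid(origin=ref.origin, spacing=ref.spacing, values=values)


def z_projection(
    site_densities: Mapping[str, DensityGrid],
    geometry: SystemGeometry,
    reservoir_density: float,
) -> pd.DataFrame:
    """Transmembrane density profile ρ(z) = ρ̄·A(z) + Σ_j ρ_j(z).

    ``reservoir_density`` is ρ̄ in Å⁻³; all grids must share one spacing but
    may sit at arbitrary z origins — each site's z slabs are deposited into
    the nearest global bin, which preserves every site column's mass: its z
    integral equals the site's 3-D grid integral exactly.  Returns a table
    with grid z (Å), one Å⁻¹ column per site, the reservoir term and the
    total; slabs falling outside the geometry's z range are an error.
    """
    spacings = {round(g.spacing, 12) for g in site_densities.values()}
    if len(spacings) > 1:
        raise ValueError(f"grids disagree on spacing: {sorted(spacings)}")
    spacing = spacings.pop() if spacings else 1.0

    z_lo = geometry.z_min
    n_z = int(np.floor((geometry.z_max - z_lo) / spacing)) + 1
    z = z_lo + spacing * np.arange(n_z)
    out = pd.DataFrame({"z": z})
    total = np.zeros(n_z)
    for sid, g in site_densities.items():
        gz, prof = g.z_profile()
        bins = np.rint((gz - z_lo) / spacing).astype(int)
        if bins.min() < 0 or bins.max() >= n_z:
            raise ValueError(
                f"site {sid}: grid z range [{gz[0]:.2f}, {gz[-1]:.2f}] Å "
                f"exceeds the geometry z range [{z_lo:.2f}, "
                f"{geometry.z_max:.2f}] Å"
            )
        col = np.zeros(n_z)
        np.add.at(col, bins, prof)
        out[f"rho_{sid}"] = col
        total += col
    reservoir = reservoir_density * geometry.cross_section(z)
    out["reservoir"] = reservoir
    out["total"] = total + reservoir
    return out


# ---------------------------------------------------------------------------
# OpenDX scalar-field I/O

def export_grid(grid: DensityGrid, path) -> None:
    """Write a grid as an OpenDX scalar field (readable by VMD/PyMOL)."""
    nx, ny, nz = grid.shape
    s = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6f} {:.6f} {:.6f}".format(*grid.origin),
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.values.ravel(order="C")
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.8e}" for v in flat[i : i + 3]))
    lines += [
        'attribute "dep" string "positions"',
        'object "density" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
        "",
    ]
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines))
    except OSError as exc:
        raise OSError(f"cannot write OpenDX grid to {path}: {exc}") from exc


def read_grid(path) -> DensityGrid:
    """Read an OpenDX scalar field written by :func:`export_grid`."""
    counts: tuple[int, int, int] | None = None
    origin: tuple[float, float, float] | None = None
    deltas: list[float] = []
    data: list[float] = []
    n_items = None
    try:
        fh = open(path)
    except OSError as exc:
        raise OSError(f"cannot read OpenDX grid from {path}: {exc}") from exc
    with fh:
        reading = False
        for line in fh:
            t = line.split()
            if not t:
                continue
            if reading:
                if t[0] in ("attribute", "object"):
                    reading = False
                else:
                    data.extend(float(v) for v in t)
                    continue
            if t[:4] == ["object", "1", "class", "gridpositions"]:
                counts = tuple(int(v) for v in t[-3:])  # type: ignore[assignment]
            elif t[0] == "origin":
                origin = tuple(float(v) for v in t[1:4])  # type: ignore[assignment]
            elif t[0] == "delta":
                deltas.append(max(float(v) for v in t[1:4]))
            elif t[0] == "object" and "data" in t and "follows" in t:
                n_items = int(t[t.index("items") + 1])
                reading = True
    if counts is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: not a grid written by export_grid")
    if not np.allclose(deltas, deltas[0]):
        raise ValueError(f"{path}: anisotropic spacing is not supported")
    if n_items is not None and len(data) != n_items:
        raise ValueError(f"{path}: expected {n_items} values, found {len(data)}")
    values = np.asarray(data, dtype=float).reshape(counts, order="C")
    return DensityGrid(origin=origin, spacing=deltas[0], values=values)
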