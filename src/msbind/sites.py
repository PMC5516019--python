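"""Binding-site resolution from docked ligand pose centroids.

Docking a small ligand over a receptor produces thousands of poses; each
pose is reduced to its heavy-atom centroid and the centroids are clustered
into disjoint site volumes δV_j.  Clustering is deterministic single-linkage
agglomeration at a distance cutoff — no assumed cluster count — and each
site is summarized as a sphere (mean member centroid, radius = furthest
member with a floor).  A second docking round, run with one ligand kept in
place, probes which sites can hold two ligands at once: a round-2 pose
marks its site as double-occupancy capable when its centroid falls inside
the site sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "PoseRecord",
    "BindingSite",
    "centroid",
    "cluster_poses",
    "assign_double_occupancy",
    "min_center_distance",
]

DEFAULT_LINKAGE_CUTOFF = 6.0  # Å
DEFAULT_RADIUS_FLOOR = 4.0  # Å
DEFAULT_SEPARATION_CHECK = 15.0  # Å


@dataclass(frozen=True)
class PoseRecord:
    """One docked pose, reduced to its ligand centroid (Å, receptor frame)."""

    pose_id: str
    centroid: tuple[float, float, float]
    occupancy_round: int = 1
    partner_site: str | None = None

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in self.centroid)
        if len(c) != 3 or not all(np.isfinite(c)):
            raise ValueError(f"pose {self.pose_id}: bad centroid {self.centroid}")
        if self.occupancy_round not in (1, 2):
            raise ValueError(
                f"pose {self.pose_id}: occupancy_round must be 1 or 2"
            )
        object.__setattr__(self, "centroid", c)


@dataclass(frozen=True)
class BindingSite:
    """A spherical site volume δV_j with its member poses."""

    site_id: str
    center: tuple[float, float, float]
    radius: float
    member_poses: tuple[str, ...] = ()
    double_poses: tuple[str, ...] = ()

    @property
    def supports_double(self) -> bool:
        return len(self.double_poses) > 0

    def contains(self, point: Sequence[float]) -> bool:
        d = np.linalg.norm(np.asarray(point, float) - np.asarray(self.center))
        return bool(d <= self.radius)


def centroid(atom_coordinates: Iterable[Sequence[float]]) -> tuple[float, float, float]:
    """Arithmetic-mean centroid of a set of atomic coordinates (Å)."""
    coords = np.asarray(list(atom_coordinates), dtype=float)
    if coords.size == 0:
        raise ValueError("centroid of an empty coordinate set is undefined")
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"expected (n, 3) coordinates, got shape {coords.shape}")
    return tuple(coords.mean(axis=0))


def min_center_distance(sites: Sequence[BindingSite]) -> float:
    """Smallest pairwise distance between site centers (inf for < 2 sites)."""
    if len(sites) < 2:
        return float("inf")
    centers = np.array([s.center for s in sites])
    return float(pdist(centers).min())


def cluster_poses(
    poses: Sequence[PoseRecord],
    linkage_cutoff: float = DEFAULT_LINKAGE_CUTOFF,
    radius_floor: float = DEFAULT_RADIUS_FLOOR,
    separation_check: float = DEFAULT_SEPARATION_CHECK,
) -> list[BindingSite]:
    """Cluster round-1 pose centroids into binding sites.

    Single-linkage agglomeration joins poses closer than ``linkage_cutoff``
    into one site; the result is independent of pose order, and sites are
    numbered by lexicographic (x, y, z) order of their centers so a shuffled
    input yields byte-identical output.  A warning is emitted when two site
    centers come closer than ``separation_check`` (well-separated sites are
    a premise of the independent-site model).
    """
    if not poses:
        raise ValueError("cluster_poses needs at least one pose")
    pts = np.array([p.centroid for p in poses])
    if len(poses) == 1:
        labels = np.array([1])
    else:
        Z = linkage(pts, method="single")
        labels = fcluster(Z, t=linkage_cutoff, criterion="distance")

    raw_sites = []
    for lab in np.unique(labels):
        mask = labels == lab
        members = pts[mask]
        center = members.mean(axis=0)
        radius = max(
            float(np.linalg.norm(members - center, axis=1).max()), radius_floor
        )
        raw_sites.append(
            (
                tuple(center),
                radius,
                tuple(poses[i].pose_id for i in np.flatnonzero(mask)),
            )
        )
    raw_sites.sort(key=lambda t: t[0])
    sites = [
        BindingSite(
            site_id=f"site_{i + 1}",
            center=center,
            radius=radius,
            member_poses=members,
        )
        for i, (center, radius, members) in enumerate(raw_sites)
    ]
    sep = min_center_distance(sites)
    if sep < separation_check:
        warnings.warn(
            f"minimum site-to-site center distance {sep:.1f} Å is below the "
            f"{separation_check:g} Å separation check; sites may overlap and "
            "the independent-site assumption may be poor",
            UserWarning,
            stacklevel=2,
        )
    return sites


def assign_double_occupancy(
    sites: Sequence[BindingSite],
    round2_poses: Sequence[PoseRecord],
) -> tuple[list[BindingSite], list[PoseRecord]]:
    """Attach second-round poses to the sites that can hold two ligands.

    A round-2 pose belongs to site j when its centroid lies inside the
    site sphere and, if the pose records which site held the pre-bound
    ligand, that partner site is j.  Returns the updated sites (with
    ``supports_double`` set where at least one pose attached) and the list
    of poses that matched no site.
    """
    doubles: dict[str, list[str]] = {s.site_id: [] for s in sites}
    unassigned: list[PoseRecord] = []
    for pose in round2_poses:
        if pose.occupancy_round != 2:
            raise ValueError(f"pose {pose.pose_id} is not a round-2 pose")
        home = None
        for s in sites:
            if not s.contains(pose.centroid):
                continue
            if pose.partner_site is not None and pose.partner_site != s.site_id:
                continue
            home = s.site_id
            break
        if home is None:
            unassigned.append(pose)
        else:
            doubles[home].append(pose.pose_id)
    updated = [
        replace(s, double_poses=tuple(doubles[s.site_id])) for s in sites
    ]
    return updated, unassigned
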