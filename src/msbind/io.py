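"""Tabular readers/writers and the bundled Kv1.2/sevoflurane dataset.

The universal tabular dialect is TSV with ``#``-prefixed header comments.
Output files carry a provenance header (tool version, config hash, input
checksums); numeric constants are printed in scientific notation with
3 significant digits.
"""

from __future__ import annotations

import hashlib
import math
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .affinity import (
    AffinityLevel,
    PerSiteConstants,
    SiteAffinity,
    compose_two_step_work,
)
from .sites import BindingSite, PoseRecord
from .symmetry import ClassConstants, SymmetryClass
from .thermo import ThermoContext

__all__ = [
    "read_affinity_table",
    "write_affinity_table",
    "write_constants_table",
    "read_classes",
    "write_class_table",
    "read_poses",
    "read_poses_pdb",
    "write_sites_table",
    "write_tsv",
    "load_kv12_affinities",
    "load_kv12_printed",
    "load_kv12_classes",
    "provenance_header",
    "file_checksum",
]


class TableFormatError(ValueError):
    """A tabular input failed validation; the message carries the row."""


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty:
        raise TableFormatError(f"{path}: table has no data rows")
    df.columns = [c.strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")


def _to_float(value: str, path, row: int, col: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TableFormatError(
            f"{path}: row {row}: non-numeric {col!r} value {value!r}"
        ) from None


def read_affinity_table(path) -> list[SiteAffinity]:
    """Read a per-site/per-level affinity TSV.

    Columns: ``site_id``, ``region``, ``level``, ``k_list`` (semicolon
    separated, kcal/mol/Å², one constant per bound ligand),
    ``work_kcal_mol`` (cumulative W*_n) and ``error_kcal_mol``.  Duplicate
    (site, level) rows and non-contiguous levels are rejected.
    """
    df = _read_tsv(path)
    _require_columns(
        df,
        ["site_id", "region", "level", "k_list", "work_kcal_mol", "error_kcal_mol"],
        path,
    )
    per_site: dict[str, dict] = {}
    for i, row in df.iterrows():
        rowno = int(i) + 1
        sid = str(row["site_id"]).strip()
        try:
            level = int(row["level"])
        except (TypeError, ValueError):
            raise TableFormatError(
                f"{path}: row {rowno}: bad level {row['level']!r}"
            ) from None
        ks = tuple(
            _to_float(v, path, rowno, "k_list")
            for v in str(row["k_list"]).split(";")
            if v.strip()
        )
        work = _to_float(row["work_kcal_mol"], path, rowno, "work_kcal_mol")
        err = _to_float(row["error_kcal_mol"], path, rowno, "error_kcal_mol")
        entry = per_site.setdefault(
            sid, {"region": str(row["region"]).strip(), "levels": {}}
        )
        if level in entry["levels"]:
            raise TableFormatError(
                f"{path}: row {rowno}: duplicate (site {sid}, level {level})"
            )
        try:
            entry["levels"][level] = AffinityLevel(
                force_constants=ks, work=work, work_error=err
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}: row {rowno}: {exc}") from None
    out = []
    for sid, entry in per_site.items():
        try:
            out.append(
                SiteAffinity(site_id=sid, region=entry["region"], levels=entry["levels"])
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}: {exc}") from None
    return out


def write_affinity_table(sites: Sequence[SiteAffinity], path, header: str = "") -> None:
    rows = []
    for s in sites:
        for n in range(1, s.max_occupancy + 1):
            lvl = s.level(n)
            rows.append(
                {
                    "site_id": s.site_id,
                    "region": s.region,
                    "level": n,
                    "k_list": ";".join(f"{k:g}" for k in lvl.force_constants),
                    "work_kcal_mol": f"{lvl.work:g}",
                    "error_kcal_mol": f"{lvl.work_error:g}",
                }
            )
    write_tsv(pd.DataFrame(rows), path, header)


def write_constants_table(
    per_site: Sequence[PerSiteConstants],
    ctx: ThermoContext,
    path,
    header: str = "",
) -> None:
    """Per-site constants: site_id, level, K (mM⁻ⁿ), ΔG° and K error bounds."""
    rows = []
    for p in per_site:
        for n in range(1, p.max_occupancy + 1):
            lo, hi = p.K_bounds(n)
            rows.append(
                {
                    "site_id": p.site_id,
                    "region": p.region,
                    "level": n,
                    "K_mM": f"{p.K(n):.3g}",
                    "dG0_kcal_mol": f"{p.dG0(n, ctx):.3g}",
                    "K_lo": f"{lo:.3g}",
                    "K_hi": f"{hi:.3g}",
                }
            )
    write_tsv(pd.DataFrame(rows), path, header)


def read_classes(path) -> list[SymmetryClass]:
    """Read a symmetry-class TSV with columns class_id, site_id."""
    df = _read_tsv(path)
    _require_columns(df, ["class_id", "site_id"], path)
    groups: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        groups.setdefault(str(row["class_id"]).strip(), []).append(
            str(row["site_id"]).strip()
        )
    return [
        SymmetryClass(class_id=cid, member_sites=tuple(members))
        for cid, members in groups.items()
    ]


def write_class_table(
    classes: Sequence[ClassConstants],
    ctx: ThermoContext,
    path,
    header: str = "",
) -> None:
    """Class-average constants: K̄ ± σ and ΔG° from the mean K, per level."""
    rows = []
    for c in classes:
        for n in range(1, c.max_occupancy + 1):
            dg = -(math.log(c.K_mean[n]) + n * math.log(1e3)) / ctx.beta
            rows.append(
                {
                    "class_id": c.class_id,
                    "fold": c.fold,
                    "level": n,
                    "K_mean_mM": f"{c.K_mean[n]:.3g}",
                    "K_sd_mM": f"{c.K_sd[n]:.3g}",
                    "dG0_kcal_mol": f"{dg:.3g}",
                }
            )
    write_tsv(pd.DataFrame(rows), path, header)


def read_poses(path) -> list[PoseRecord]:
    """Read a pose table: pose_id, x, y, z, round, partner_site (optional)."""
    df = _read_tsv(path)
    _require_columns(df, ["pose_id", "x", "y", "z", "round"], path)
    poses = []
    for i, row in df.iterrows():
        rowno = int(i) + 1
        partner = None
        if "partner_site" in df.columns:
            raw = row["partner_site"]
            if isinstance(raw, str) and raw.strip() not in ("", "-", "NA"):
                partner = raw.strip()
        try:
            rnd = int(row["round"])
        except (TypeError, ValueError):
            raise TableFormatError(
                f"{path}: row {rowno}: bad round {row['round']!r}"
            ) from None
        poses.append(
            PoseRecord(
                pose_id=str(row["pose_id"]).strip(),
                centroid=(
                    _to_float(row["x"], path, rowno, "x"),
                    _to_float(row["y"], path, rowno, "y"),
                    _to_float(row["z"], path, rowno, "z"),
                ),
                occupancy_round=rnd,
                partner_site=partner,
            )
        )
    return poses


def read_poses_pdb(path, ligand_resname: str, occupancy_round: int = 1) -> list[PoseRecord]:
    """Pose centroids from a multi-model PDB, one pose per model.

    The centroid is taken over the atoms of residues named
    ``ligand_resname`` in each model.
    """
    import MDAnalysis as mda  # deferred: only needed for PDB input

    u = mda.Universe(str(path))
    ligand = u.select_atoms(f"resname {ligand_resname}")
    if len(ligand) == 0:
        raise TableFormatError(
            f"{path}: no atoms with residue name {ligand_resname!r}"
        )
    poses = []
    for ts in u.trajectory:
        poses.append(
            PoseRecord(
                pose_id=f"model_{ts.frame + 1}",
                centroid=tuple(ligand.positions.mean(axis=0)),
                occupancy_round=occupancy_round,
            )
        )
    return poses


def write_sites_table(sites: Sequence[BindingSite], path, header: str = "") -> None:
    rows = [
        {
            "site_id": s.site_id,
            "cx": f"{s.center[0]:.3f}",
            "cy": f"{s.center[1]:.3f}",
            "cz": f"{s.center[2]:.3f}",
            "radius": f"{s.radius:.3f}",
            "n_poses": len(s.member_poses),
            "supports_double": int(s.supports_double),
        }
        for s in sites
    ]
    write_tsv(pd.DataFrame(rows), path, header)


def write_tsv(df: pd.DataFrame, path, header: str = "") -> None:
    """Write a DataFrame as TSV under a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def provenance_header(
    config: dict | None = None, inputs: Sequence = ()
) -> str:
    """``#`` comment block recording version, config hash and input sums."""
    lines = [f"# msbind {__version__}"]
    if config:
        digest = hashlib.sha256(
            repr(sorted(config.items())).encode()
        ).hexdigest()[:12]
        lines.append(f"# config_hash {digest}")
        for k, v in sorted(config.items()):
            lines.append(f"# config {k} = {v}")
    for p in inputs:
        lines.append(f"# input {Path(p).name} sha256:{file_checksum(p)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Bundled Kv1.2 / sevoflurane dataset

def _data_path(name: str):
    return resources.files("msbind").joinpath("data", name)


def load_kv12_printed() -> pd.DataFrame:
    """The published per-site table as printed (step works, K, ΔG°)."""
    with resources.as_file(_data_path("kv12_sevoflurane_fep.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    df["site_id"] = df["site_id"].astype(str)
    return df


def load_kv12_affinities() -> list[SiteAffinity]:
    """The bundled sevoflurane/Kv1.2 FEP inputs as SiteAffinity records.

    Level-2 works are composed from the published two-step protocol
    (W*₂ = W*₁ + W*₂|₁, errors in quadrature) and the level-2 restraint
    set combines the singly-occupied k for the first ligand with the
    doubly-occupied column's k for the second.
    """
    df = load_kv12_printed()
    sites = []
    for sid, g in df.groupby("site_id", sort=False):
        g = g.sort_values("level")
        levels: dict[int, AffinityLevel] = {}
        k1 = w1 = e1 = None
        for _, row in g.iterrows():
            n = int(row["level"])
            if n == 1:
                k1, w1, e1 = row["k"], row["work_step"], row["error"]
                levels[1] = AffinityLevel((k1,), float(w1), float(e1))
            elif n == 2:
                composed = compose_two_step_work(
                    float(w1), float(row["work_step"]), float(e1), float(row["error"])
                )
                levels[2] = AffinityLevel(
                    (float(k1), float(row["k"])), composed.work, composed.error
                )
            else:
                raise TableFormatError(f"unexpected level {n} in bundled table")
        sites.append(
            SiteAffinity(site_id=str(sid), region=str(g["region"].iloc[0]), levels=levels)
        )
    return sites


def load_kv12_classes() -> list[SymmetryClass]:
    """The three symmetry classes of the homotetramer (4 sites each)."""
    with resources.as_file(_data_path("kv12_classes.tsv")) as p:
        return read_classes(p)
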