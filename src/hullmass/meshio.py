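"""Mesh and table I/O for the geometry pipeline.

Segments arrive one file per functional unit in OBJ, PLY (ascii or binary
little-endian) or STL (ascii or binary). Only vertex records are consumed:
hulls depend on the point set alone, so faces, normals and manifold defects
in the source meshes are irrelevant. Labels come from the filename stem or
from a manifest CSV with columns ``file,label,is_foot``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import InputError
from .geometry import ConvexPolytope, HullVolumeTable, PointSet, SkeletonSegments

MESH_SUFFIXES = (".obj", ".ply", ".stl")

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n", ""}


def read_mesh_vertices(path: str | Path) -> np.ndarray:
    """Vertex coordinates (mm) of a mesh or point-cloud file."""
    path = Path(path)
    if path.suffix.lower() not in MESH_SUFFIXES:
        raise InputError(f"unsupported mesh format: {path.name}")
    try:
        loaded = trimesh.load(str(path), process=False)
    except Exception as exc:
        raise InputError(f"could not read mesh {path}: {exc}") from exc
    if isinstance(loaded, trimesh.Scene):
        parts = [np.asarray(g.vertices) for g in loaded.geometry.values()]
        if not parts:
            raise InputError(f"no geometry in {path}")
        verts = np.vstack(parts)
    else:
        verts = np.asarray(loaded.vertices)
    if verts.size == 0:
        raise InputError(f"no vertices in {path}")
    return verts.astype(float)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest CSV mapping mesh files to segment labels and foot flags."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"file", "label", "is_foot"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"manifest missing columns: {sorted(missing)}")
    flags = []
    for raw in df["is_foot"].str.strip().str.lower():
        if raw in _TRUE:
            flags.append(True)
        elif raw in _FALSE:
            flags.append(False)
        else:
            raise InputError(f"manifest is_foot value not boolean: {raw!r}")
    out = df[["file", "label"]].copy()
    out["is_foot"] = flags
    if out["label"].duplicated().any():
        dupes = sorted(out.loc[out["label"].duplicated(), "label"])
        raise InputError(f"duplicate segment labels in manifest: {dupes}")
    return out


def load_skeleton(
    mesh_dir: str | Path,
    specimen_id: str,
    manifest: str | Path | None = None,
    feet_labels: set[str] | None = None,
) -> SkeletonSegments:
    """Assemble a :class:`SkeletonSegments` from a directory of mesh files.

    Without a manifest every mesh file in the directory becomes a segment
    labelled by its filename stem, and ``feet_labels`` flags feet explicitly.
    """
    mesh_dir = Path(mesh_dir)
    segments: dict[str, PointSet] = {}
    feet: set[str] = set(feet_labels or ())
    if manifest is not None:
        man = read_manifest(manifest)
        for row in man.itertuples(index=False):
            verts = read_mesh_vertices(mesh_dir / row.file)
            segments[row.label] = PointSet(label=row.label, points=verts)
            if row.is_foot:
                feet.add(row.label)
    else:
        files = sorted(p for p in mesh_dir.iterdir() if p.suffix.lower() in MESH_SUFFIXES)
        if not files:
            raise InputError(f"no mesh files found in {mesh_dir}")
        for p in files:
            label = p.stem
            segments[label] = PointSet(label=label, points=read_mesh_vertices(p))
    missing_feet = feet - set(segments)
    if missing_feet:
        raise InputError(f"feet labels with no matching segment: {sorted(missing_feet)}")
    return SkeletonSegments(specimen_id=specimen_id, segments=segments, feet_labels=frozenset(feet))


def write_volume_table(table: HullVolumeTable, path: str | Path) -> None:
    """Write per-segment volumes plus totals rows as CSV."""
    table.to_frame().to_csv(path, index=False)


def read_volume_table(path: str | Path) -> list[HullVolumeTable]:
    """Read one or more specimens' segment volumes from a long-format CSV."""
    df = pd.read_csv(path)
    required = {"specimen", "segment", "volume_mm3"}
    if not required <= set(df.columns):
        raise InputError(f"volume table must have columns {sorted(required)}")
    tables = []
    for specimen, grp in df.groupby("specimen", sort=False):
        body = grp[~grp["segment"].isin(["TOTAL", "TOTAL_MINUS_FEET"])]
        volumes = dict(zip(body["segment"], body["volume_mm3"].astype(float)))
        tables.append(HullVolumeTable(specimen_id=str(specimen), volumes=volumes))
    return tables


def write_hull_obj(hull: ConvexPolytope, path: str | Path) -> None:
    """Dump a hull as a Wavefront OBJ for visual inspection."""
    with open(path, "w") as fh:
        for v in hull.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for tri in hull.facets:
            fh.write(f"f {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")
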