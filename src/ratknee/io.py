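"""Mesh, specimen, config and record serialization.

Meshes travel as ASCII PLY (per-vertex equivalent mineral density as a
scalar ``density`` property) or STL.  STL cannot carry vertex scalars or the
unreferenced marker vertices, so an STL export always writes a sidecar CSV
holding the full vertex table (index, x, y, z, density); reading the pair
reconstructs the mesh exactly.  Specimen-level metadata (markers, cartilage
patches, laterality) lives in a JSON manifest next to the mesh files.

trimesh writes custom PLY vertex properties but drops them on read, so the
density column of the package's own ASCII PLY files is recovered by a small
header-driven reader here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .cohort import CartilagePatch, FilmModel, GeneratorConfig, KneeSpecimen
from .mesh import SurfaceMesh


class ParseError(ValueError):
    """Raised for malformed mesh or config files."""


# ----------------------------------------------------------------------
# PLY
# ----------------------------------------------------------------------

def write_ply(mesh: SurfaceMesh, path) -> None:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if mesh.vertex_density is not None:
        tm.vertex_attributes["density"] = mesh.vertex_density.astype(np.float64)
    Path(path).write_bytes(tm.export(file_type="ply", encoding="ascii"))


def _read_ply_arrays(path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Vertices, faces and optional density column from an ASCII PLY."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ParseError(f"{path}: not a PLY file")
    n_vert = n_face = None
    vert_props: list[str] = []
    in_vertex = False
    header_end = None
    for i, line in enumerate(lines[1:], start=1):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if tok[1] == "vertex":
                n_vert = int(tok[2])
            elif tok[1] == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and in_vertex and tok[1] != "list":
            vert_props.append(tok[-1])
        elif tok[0] == "end_header":
            header_end = i
            break
    if header_end is None or n_vert is None or n_face is None:
        raise ParseError(f"{path}: malformed PLY header")
    body = lines[header_end + 1 :]
    if len(body) < n_vert + n_face:
        raise ParseError(
            f"{path}: truncated PLY body at line {header_end + 1 + len(body)} "
            f"(expected {n_vert + n_face} records)"
        )
    try:
        vdata = np.array([[float(v) for v in body[i].split()] for i in range(n_vert)])
        faces = []
        for i in range(n_vert, n_vert + n_face):
            tok = body[i].split()
            if int(tok[0]) != 3:
                raise ParseError(f"{path}: non-triangular face at line {header_end + 2 + i}")
            faces.append([int(t) for t in tok[1:4]])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: malformed PLY body ({exc})") from exc
    density = None
    if "density" in vert_props:
        density = vdata[:, vert_props.index("density")]
    return vdata[:, :3], np.asarray(faces, dtype=np.int64), density


def read_ply(path, body: str = "femur") -> SurfaceMesh:
    verts, faces, density = _read_ply_arrays(path)
    return SurfaceMesh(verts, faces, body, vertex_density=density)


# ----------------------------------------------------------------------
# STL + sidecar
# ----------------------------------------------------------------------

def write_stl(mesh: SurfaceMesh, path) -> None:
    """ASCII STL plus a sidecar CSV carrying the full vertex table."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    data = tm.export(file_type="stl_ascii")
    path.write_bytes(data.encode() if isinstance(data, str) else data)
    table = pd.DataFrame(mesh.vertices, columns=["x", "y", "z"])
    table.insert(0, "index", np.arange(mesh.n_vertices))
    table["density"] = mesh.vertex_density if mesh.vertex_density is not None else np.nan
    # %.17g round-trips IEEE doubles exactly through text
    table.to_csv(path.with_suffix(".vertices.csv"), index=False, float_format="%.17g")


def read_stl(path, body: str = "femur") -> SurfaceMesh:
    """Reconstruct shared topology from an STL and its sidecar vertex table.

    The STL triangle soup is mapped back onto the sidecar vertex list by
    nearest-coordinate matching (STL stores float32), restoring the original
    indexing including unreferenced marker vertices and the density column.
    """
    path = Path(path)
    sidecar = path.with_suffix(".vertices.csv")
    if not sidecar.exists():
        raise ParseError(f"{sidecar}: sidecar vertex table is required to read STL")
    table = pd.read_csv(sidecar, float_precision="round_trip")
    verts = table[["x", "y", "z"]].to_numpy(dtype=float)
    density = table["density"].to_numpy(dtype=float)
    if np.all(np.isnan(density)):
        density = None
    tm = trimesh.load(str(path), file_type="stl", process=False)
    soup = np.asarray(tm.vertices, dtype=float)
    from scipy.spatial import cKDTree

    dist, idx = cKDTree(verts).query(soup)
    if np.any(dist > 1e-3):
        raise ParseError(f"{path}: STL vertices do not match the sidecar table")
    faces = idx[np.asarray(tm.faces)].astype(np.int64)
    return SurfaceMesh(verts, faces, body, vertex_density=density)


def write_mesh(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        write_ply(mesh, path)
    elif path.suffix.lower() == ".stl":
        write_stl(mesh, path)
    else:
        raise ParseError(f"unsupported mesh format {path.suffix!r}")


def read_mesh(path, body: str = "femur") -> SurfaceMesh:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return read_ply(path, body)
    if path.suffix.lower() == ".stl":
        return read_stl(path, body)
    raise ParseError(f"unsupported mesh format {path.suffix!r}")


# ----------------------------------------------------------------------
# specimens
# ----------------------------------------------------------------------

def save_specimen(s: KneeSpecimen, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "animal_id": s.animal_id,
        "side_as_acquired": s.side_as_acquired,
        "is_mirrored": s.is_mirrored,
        "bodies": {},
        "cartilage": [
            {"host_body": p.host_body, "side": p.side, "thickness": p.thickness,
             "face_indices": p.face_indices.tolist()}
            for p in s.cartilage
        ],
    }
    for body in ("femur", "tibia_fibula", "patella"):
        mesh = s.body(body)
        write_ply(mesh, directory / f"{body}.ply")
        meta["bodies"][body] = {
            "file": f"{body}.ply",
            "markers": dict(mesh.markers),
            "face_region": mesh.face_region.tolist(),
        }
    (directory / "specimen.json").write_text(json.dumps(meta))


def load_specimen(directory) -> KneeSpecimen:
    directory = Path(directory)
    meta = json.loads((directory / "specimen.json").read_text())
    bodies = {}
    for body, info in meta["bodies"].items():
        mesh = read_ply(directory / info["file"], body)
        mesh.markers = {k: int(v) for k, v in info["markers"].items()}
        mesh.face_region = np.asarray(info["face_region"], dtype=object)
        mesh.validate()
        bodies[body] = mesh
    patches = [CartilagePatch(p["host_body"], p["side"], np.asarray(p["face_indices"]),
                              p["thickness"]) for p in meta["cartilage"]]
    return KneeSpecimen(meta["animal_id"], meta["side_as_acquired"], meta["is_mirrored"],
                        bodies["femur"], bodies["tibia_fibula"], bodies["patella"], patches)


# ----------------------------------------------------------------------
# configs and records
# ----------------------------------------------------------------------

def write_config(obj: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(obj, sort_keys=True))
    else:
        path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yml", ".yaml"):
            out = yaml.safe_load(text)
        else:
            out = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: malformed config ({exc})") from exc
    if not isinstance(out, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return out


def read_generator_config(path) -> GeneratorConfig:
    return GeneratorConfig.from_dict(read_config(path))


def read_film_model(path) -> FilmModel:
    return FilmModel.from_dict(read_config(path))


RECORDS_SCHEMA_VERSION = 1


def write_records(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out.insert(0, "schema_version", RECORDS_SCHEMA_VERSION)
    out.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "schema_version" in frame.columns:
        frame = frame.drop(columns=["schema_version"])
    return frame


def write_pressure_field_csv(outcome, path) -> None:
    """Per-element pressure export: id, centroid is omitted upstream -> area, pressure, side."""
    rows = []
    for comp in (outcome.medial, outcome.lateral):
        for fid, area, p in zip(comp.face_ids, comp.areas, comp.pressures):
            rows.append({"element": int(fid), "area_mm2": float(area),
                         "pressure_mpa": float(p), "side": comp.side})
    pd.DataFrame(rows).to_csv(path, index=False)
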