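"""File formats: meshes (PLY/OBJ/STL), landmark and patch tables, hinge and
transform JSON, report CSVs and colour-coded capsule exports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .gape_strain import CLASS_RGB, HingeAxis, SweepResult
from .geometry_core import GeometryError, LandmarkPair, RigidTransform, TriangleMesh
from .muscle_model import AttachmentPatch, MuscleGroup, VolumeReport

_MESH_SUFFIXES = {".ply", ".obj", ".stl"}


# --- meshes ---------------------------------------------------------------


def load_mesh(path: str | Path, name: str | None = None) -> TriangleMesh:
    """Read a PLY (ASCII or binary), OBJ or STL triangle mesh."""
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise GeometryError(f"unsupported mesh format: {path.suffix!r}")
    tm = trimesh.load(path, force="mesh", process=False)
    return TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces),
                        name if name is not None else path.stem)


def save_mesh(mesh: TriangleMesh, path: str | Path,
              vertex_colors: np.ndarray | None = None) -> Path:
    """Write a mesh; PLY supports per-vertex RGB colour."""
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise GeometryError(f"unsupported mesh format: {path.suffix!r}")
    tm = mesh.to_trimesh()
    if vertex_colors is not None:
        if path.suffix.lower() != ".ply":
            raise GeometryError("vertex colours are only supported on PLY export")
        tm.visual.vertex_colors = np.asarray(vertex_colors, dtype=np.uint8)
    tm.export(path)
    return path


# --- landmarks ------------------------------------------------------------


def load_landmarks(path: str | Path) -> list[LandmarkPair]:
    """Read landmarks from CSV (`name,side,x,y,z`; side L/R/M) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = pd.DataFrame(json.loads(path.read_text()))
    else:
        rows = pd.read_csv(path)
    required = {"name", "side", "x", "y", "z"}
    if not required.issubset(rows.columns):
        raise GeometryError(f"landmark table needs columns {sorted(required)}")
    pairs = []
    for name, grp in rows.groupby("name", sort=False):
        sides = dict(zip(grp["side"], grp[["x", "y", "z"]].to_numpy()))
        if "M" in sides:
            pairs.append(LandmarkPair(str(name), sides["M"], sides["M"], midline=True))
        elif "L" in sides and "R" in sides:
            pairs.append(LandmarkPair(str(name), sides["L"], sides["R"]))
        else:
            raise GeometryError(f"landmark {name!r}: need both L and R rows, or M")
    return pairs


def save_landmarks(pairs: list[LandmarkPair], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for p in pairs:
        if p.midline:
            rows.append((p.name, "M", *p.left))
        else:
            rows.append((p.name, "L", *p.left))
            rows.append((p.name, "R", *p.right))
    df = pd.DataFrame(rows, columns=["name", "side", "x", "y", "z"])
    if path.suffix.lower() == ".json":
        path.write_text(df.to_json(orient="records"))
    else:
        df.to_csv(path, index=False)
    return path


# --- attachment patches ---------------------------------------------------


def load_patches(path: str | Path) -> list[AttachmentPatch]:
    """Read attachment patches from CSV `muscle,role,side,x,y,z` (many rows
    per patch) or the JSON equivalent."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    patches = []
    for (muscle, role, side), grp in df.groupby(["muscle", "role", "side"],
                                                sort=False):
        bone = str(grp["bone"].iloc[0]) if "bone" in grp else ""
        patches.append(AttachmentPatch(str(muscle), str(role),
                                       grp[["x", "y", "z"]].to_numpy(),
                                       bone, str(side)))
    return patches


def save_patches(patches: list[AttachmentPatch], path: str | Path) -> Path:
    path = Path(path)
    rows = [(p.muscle, p.role, p.side, p.bone, *pt)
            for p in patches for pt in p.points]
    df = pd.DataFrame(rows, columns=["muscle", "role", "side", "bone",
                                     "x", "y", "z"])
    if path.suffix.lower() == ".json":
        path.write_text(df.to_json(orient="records"))
    else:
        df.to_csv(path, index=False)
    return path


# --- hinge / transforms ---------------------------------------------------


def load_hinge(path: str | Path) -> HingeAxis:
    d = json.loads(Path(path).read_text())
    return HingeAxis(d["point"], d["direction"])


def save_hinge(hinge: HingeAxis, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"point": hinge.point.tolist(),
                                "direction": hinge.direction.tolist()}, indent=1))
    return path


def load_transform(path: str | Path) -> RigidTransform:
    """Read a rigid transform stored as a 4x4 row-major homogeneous matrix."""
    m = np.asarray(json.loads(Path(path).read_text()), dtype=float)
    return RigidTransform.from_matrix(m)


def save_transform(T: RigidTransform, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(T.matrix().tolist(), indent=1))
    return path


# --- reports --------------------------------------------------------------


def save_volume_report(report: VolumeReport, path: str | Path) -> Path:
    """CSV `muscle,side,volume_mm3,fraction_pct` with >=6 significant digits."""
    path = Path(path)
    df = pd.DataFrame({"muscle": report.muscles, "side": report.sides,
                       "volume_mm3": report.volumes_mm3,
                       "fraction_pct": report.fractions_pct})
    df.to_csv(path, index=False, float_format="%.8g")
    return path


def save_sweep(result: SweepResult, path_csv: str | Path,
               path_json: str | Path | None = None,
               scenario: str = "default") -> Path:
    """Write the per-record sweep CSV and an optional max-gape summary JSON."""
    df = result.to_frame()
    df.insert(0, "scenario", scenario)
    df.to_csv(path_csv, index=False, float_format="%.8g")
    if path_json is not None:
        summary = {
            "scenario": scenario,
            "max_gape_deg": result.max_gape,
            "max_gape_per_muscle": result.max_gape_per_muscle,
            "limiting_fiber": list(result.limiting_fiber)
            if result.limiting_fiber else None,
            "at_limit_at_closure": bool(result.at_limit_at_closure),
        }
        Path(path_json).write_text(json.dumps(summary, indent=1))
    return Path(path_csv)


# --- colour-coded capsule export ------------------------------------------


def capsule_mesh(origin: np.ndarray, insertion: np.ndarray, radius: float,
                 sections: int = 24) -> trimesh.Trimesh:
    """Capsule surface along the origin->insertion segment."""
    seg = np.asarray(insertion, float) - np.asarray(origin, float)
    h = float(np.linalg.norm(seg))
    cap = trimesh.creation.capsule(height=h, radius=radius,
                                   count=(sections, sections))
    T = trimesh.geometry.align_vectors([0.0, 0.0, 1.0], seg / h)
    cap.apply_transform(T)
    cap.apply_translation(origin)
    return cap


def export_colored_capsules(groups: list[MuscleGroup], result: SweepResult,
                            theta_deg: float, path: str | Path) -> Path:
    """Write capsule surfaces posed at gape `theta` as PLY, vertex-coloured by
    strain band (green / yellow / red as 0,255,0 / 255,255,0 / 255,0,0)."""
    from .gape_strain import rotate_about_hinge
    from .muscle_model import MuscleError

    grid = result.config.grid()
    if not np.any(np.isclose(grid, theta_deg, atol=1e-9)):
        raise MuscleError(f"theta {theta_deg} is not on the sweep grid")
    by_fiber = {(r.muscle, r.fiber_id): r.strain_class
                for r in result.records
                if np.isclose(r.theta_deg, theta_deg, atol=1e-9)}
    parts, colors = [], []
    for g in groups:
        for f in g.fibers:
            cls = by_fiber.get((g.muscle, f.id))
            if cls is None:
                raise MuscleError(f"fiber {g.muscle}/{f.id} missing from sweep")
            moved = (rotate_about_hinge(f.insertion[None, :], result.hinge,
                                        theta_deg)[0]
                     if result.hinge is not None else f.insertion)
            cap = capsule_mesh(f.origin, moved, max(f.radius, 1e-3))
            parts.append(cap)
            rgb = CLASS_RGB[cls]
            colors.append(np.tile((*rgb, 255), (len(cap.vertices), 1)))
    joined = trimesh.util.concatenate(parts)
    mesh = TriangleMesh(np.asarray(joined.vertices), np.asarray(joined.faces),
                        f"capsules_theta{theta_deg:g}")
    return save_mesh(mesh, path, vertex_colors=np.vstack(colors))
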