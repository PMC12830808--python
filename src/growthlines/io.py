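"""Readers and writers for meshes, series manifests, patches and landmarks.

OBJ files are read and written with a small order-preserving codec: vertex
order and quad faces must survive a round trip exactly, because vertex index
is the correspondence key between stages.  General-purpose loaders tend to
merge, reindex or triangulate on load, which would silently break that key;
PLY input (triangles only) goes through :mod:`trimesh` with processing
disabled.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mesh import StageMesh, StageSeries, SurfacePoint

__all__ = [
    "read_obj",
    "write_obj",
    "read_ply",
    "load_mesh",
    "save_series",
    "load_series",
    "write_patch",
    "read_patch",
    "read_landmarks",
    "write_landmarks",
]


def read_obj(path, stage_label: str = "") -> StageMesh:
    """Read an OBJ file preserving vertex order and quad faces."""
    verts: list[list[float]] = []
    faces: list[tuple[int, ...]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = tuple(int(tok.split("/")[0]) - 1 for tok in parts[1:])
                if len(idx) not in (3, 4):
                    raise ValueError(
                        f"{path}: face with {len(idx)} vertices; only tris/quads supported"
                    )
                faces.append(idx)
    if not verts or not faces:
        raise ValueError(f"{path}: no vertices or faces found")
    return StageMesh(np.asarray(verts), faces, stage_label=stage_label or Path(path).stem)


def write_obj(path, mesh: StageMesh) -> None:
    with open(path, "w") as fh:
        fh.write(f"# growthlines stage mesh: {mesh.stage_label}\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write("f " + " ".join(str(i + 1) for i in f) + "\n")


def read_ply(path, stage_label: str = "") -> StageMesh:
    import trimesh

    tm = trimesh.load(str(path), file_type="ply", process=False)
    return StageMesh(
        np.asarray(tm.vertices, dtype=float),
        [tuple(f) for f in np.asarray(tm.faces)],
        stage_label=stage_label or Path(path).stem,
    )


def load_mesh(path, stage_label: str = "") -> StageMesh:
    suffix = Path(path).suffix.lower()
    if suffix == ".obj":
        return read_obj(path, stage_label)
    if suffix == ".ply":
        return read_ply(path, stage_label)
    raise ValueError(f"unsupported mesh format: {suffix}")


def save_series(series: StageSeries, outdir, name: str = "series", strict: bool = True) -> Path:
    """Write one OBJ per stage plus a manifest naming files and labels."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, mesh in enumerate(series.stages):
        fname = f"{name}_stage{k}.obj"
        write_obj(outdir / fname, mesh)
        entries.append({"file": fname, "label": mesh.stage_label})
    manifest = {"format": "growthlines-series", "version": 1, "stages": entries}
    mpath = outdir / f"{name}.series.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def load_series(manifest_path, strict: bool = True) -> StageSeries:
    """Load a stage series from a JSON or YAML manifest.

    In strict mode (default) the face blocks of all stage files must be
    identical; a mismatch is rejected rather than repaired.
    """
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text()
    manifest = (
        yaml.safe_load(text)
        if manifest_path.suffix in (".yaml", ".yml")
        else json.loads(text)
    )
    stages = []
    for entry in manifest["stages"]:
        mesh = load_mesh(manifest_path.parent / entry["file"], entry.get("label", ""))
        stages.append(mesh)
    if strict:
        ref = stages[0]
        for k, m in enumerate(stages[1:], start=1):
            if m.faces != ref.faces:
                raise ValueError(
                    f"strict mode: stage file {manifest['stages'][k]['file']} has a "
                    "different face block from stage 0"
                )
    return StageSeries(stages)


# -- dye patch files ---------------------------------------------------------------


def write_patch(path, patch) -> None:
    """Patch samples as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    rows = []
    for sid, (tri, bary) in enumerate(zip(patch.sample_tris, patch.sample_bary)):
        rows.append(
            {
                "face_index": int(patch.mesh.tri_face[tri]),
                "tri_index": int(tri),
                "bary_a": bary[0],
                "bary_b": bary[1],
                "bary_c": bary[2],
                "sample_id": sid,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    meta = {
        "faces": [int(f) for f in patch.faces],
        "seed_tri": int(patch.seed.tri),
        "seed_bary": list(patch.seed.bary),
        "meta": patch.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_patch(path, mesh: StageMesh):
    from .dye import DyePatch

    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    seed = SurfacePoint(tri=meta["seed_tri"], bary=tuple(meta["seed_bary"]))
    return DyePatch(
        mesh=mesh,
        faces=np.asarray(meta["faces"], dtype=np.intp),
        sample_tris=df["tri_index"].to_numpy(dtype=np.intp),
        sample_bary=df[["bary_a", "bary_b", "bary_c"]].to_numpy(dtype=float),
        seed=seed,
        meta=meta.get("meta", {}),
    )


# -- landmark files ----------------------------------------------------------------


def read_landmarks(path):
    """Landmarks CSV with columns name, x, y[, polyline_id, order]."""
    from .morphometry import LandmarkSet

    df = pd.read_csv(path)
    points: dict[str, np.ndarray] = {}
    polylines: dict[str, np.ndarray] = {}
    if "polyline_id" not in df.columns:
        df["polyline_id"] = np.nan
    for name, grp in df.groupby("name", sort=False):
        if grp["polyline_id"].notna().any() or len(grp) > 1:
            if "order" in grp.columns:
                grp = grp.sort_values("order")
            polylines[name] = grp[["x", "y"]].to_numpy(dtype=float)
        else:
            points[name] = grp[["x", "y"]].to_numpy(dtype=float)[0]
    return LandmarkSet(points=points, polylines=polylines)


def write_landmarks(path, landmarks) -> None:
    rows = []
    for name, p in landmarks.points.items():
        rows.append({"name": name, "x": p[0], "y": p[1], "polyline_id": "", "order": 0})
    for name, poly in landmarks.polylines.items():
        for i, p in enumerate(poly):
            rows.append({"name": name, "x": p[0], "y": p[1], "polyline_id": name, "order": i})
    pd.DataFrame(rows).to_csv(path, index=False)
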