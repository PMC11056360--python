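"""Reading, writing and mesh export of hemi-pelvis models.

The native format is a structured-text JSON file (conventional extension
``.pelvis.json``) holding the ordered brim vertices, the acetabular rim
point set (plus optional socket sphere), the body axis and side/sex
metadata.  Floats are serialized with full ``repr`` precision, so a
write/read round trip reproduces the model exactly.

For visualization a model can be exported as a surface mesh (binary STL or
ascii PLY): a thin tube swept along the brim plus the socket sphere.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import trimesh

from .errors import ModelFileError
from .geometry import Polyline3, _unit, resample_polyline
from .model import AcetabulumModel, HemiPelvisModel

FORMAT_NAME = "brimplan.hemipelvis"
FORMAT_VERSION = 1


def write_model(model: HemiPelvisModel, path) -> Path:
    """Serialize a model to a ``.pelvis.json`` structured-text file."""
    path = Path(path)
    doc = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "side": model.side,
        "sex": model.sex,
        "body_axis": model.body_axis.tolist(),
        "brim_vertices": model.brim.vertices.tolist(),
        "acetabular_rim": model.acetabulum.rim_points.tolist(),
        "sphere_center": (
            None if model.acetabulum.sphere_center is None
            else model.acetabulum.sphere_center.tolist()
        ),
        "sphere_radius": model.acetabulum.sphere_radius,
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_model(path) -> HemiPelvisModel:
    """Parse a ``.pelvis.json`` file; malformed input raises
    :class:`ModelFileError` naming the offending field."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFileError(f"{path}: not valid JSON (line {exc.lineno}: {exc.msg})") from exc
    if not isinstance(doc, dict) or doc.get("format") != FORMAT_NAME:
        raise ModelFileError(f"{path}: missing or wrong 'format' field")
    for key in ("side", "sex", "body_axis", "brim_vertices", "acetabular_rim"):
        if key not in doc:
            raise ModelFileError(f"{path}: missing required field {key!r}")
    center = doc.get("sphere_center")
    radius = doc.get("sphere_radius")
    try:
        return HemiPelvisModel(
            brim=Polyline3(np.asarray(doc["brim_vertices"], dtype=float)),
            acetabulum=AcetabulumModel(
                rim_points=np.asarray(doc["acetabular_rim"], dtype=float),
                sphere_center=None if center is None else np.asarray(center, dtype=float),
                sphere_radius=None if radius is None else float(radius),
            ),
            body_axis=np.asarray(doc["body_axis"], dtype=float),
            side=doc["side"],
            sex=doc["sex"],
        )
    except (ValueError, TypeError) as exc:
        raise ModelFileError(f"{path}: {exc}") from exc


def _tube_mesh(curve: Polyline3, radius: float, sides: int = 8) -> trimesh.Trimesh:
    """Sweep a small circle along the polyline with parallel-transported frames."""
    pts = curve.vertices
    tangents = np.gradient(pts, curve.arc_positions, axis=0)
    tangents = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    # initial normal: any direction orthogonal to the first tangent
    seed = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ seed) > 0.9:
        seed = np.array([1.0, 0.0, 0.0])
    n = _unit(seed - (seed @ tangents[0]) * tangents[0])
    rings = []
    ang = 2 * np.pi * np.arange(sides) / sides
    for i, (p, t) in enumerate(zip(pts, tangents)):
        if i > 0:  # parallel transport of the frame normal
            n = n - (n @ t) * t
            n = _unit(n)
        bvec = np.cross(t, n)
        rings.append(p + radius * (np.cos(ang)[:, None] * n + np.sin(ang)[:, None] * bvec))
    verts = np.vstack(rings)
    faces = []
    for i in range(len(rings) - 1):
        base = i * sides
        for j in range(sides):
            a0, a1 = base + j, base + (j + 1) % sides
            b0, b1 = a0 + sides, a1 + sides
            faces.append([a0, a1, b1])
            faces.append([a0, b1, b0])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)


def export_mesh(model: HemiPelvisModel, path, tube_radius: float = 1.5) -> Path:
    """Export a visualization mesh (brim tube + socket sphere) to STL or PLY.

    The format follows the suffix: ``.stl`` (binary) or ``.ply`` (ascii).
    """
    path = Path(path)
    curve = resample_polyline(model.brim, 2.0)
    parts = [_tube_mesh(curve, tube_radius)]
    acet = model.acetabulum
    if acet.sphere_center is not None:
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=acet.sphere_radius)
        sphere.apply_translation(acet.sphere_center)
        parts.append(sphere)
    mesh = trimesh.util.concatenate(parts)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        mesh.export(path)
    elif suffix == ".ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
    else:
        raise ModelFileError(f"unsupported mesh format {suffix!r} (use .stl or .ply)")
    return path
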