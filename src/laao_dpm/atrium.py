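"""Idealized left-atrium geometry generator.

Stand-in for patient-specific CT meshes: an ellipsoidal chamber with 4-6
pulmonary-vein (PV) tubes on its posterior wall, a tapering tubular left
atrial appendage (LAA) on the left-anterior wall, and a planar mitral-valve
(MV) outlet cut at the chamber floor.  The body is built as the zero level
set of a signed-distance union and triangulated by marching cubes, so the
surface is closed and oriented, with the declared inlet/outlet caps as
exactly planar facets of the same surface.

Region labels (disjoint, per face): ``chamber``, ``laa_wall``,
``pv_inlet_0`` ... ``pv_inlet_{k-1}``, ``mv_outlet``.  ``pv_inlet_0`` is the
left superior pulmonary vein (LSPV), whose fold with the appendage defines
the pulmonary ridge.  The ostium contour is stored as an analytic planar
circle polyline; the LSPV/LAA fold point and the MV centre as landmarks.

All lengths in mm.  Generation is a pure function of the spec (the seed is
recorded but the default construction uses no randomness).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.measure import marching_cubes

from .errors import ValidationError
from .meshes import LabeledSurfaceMesh

__all__ = ["IdealizedAtriumSpec", "generate_atrium"]

# PV axis directions (unit-ish, normalized at use).  Index 0 is the LSPV:
# left (+x), posterior (+y), superior (+z).
_PV_DIRS = {
    4: [(0.55, 0.72, 0.42), (0.60, 0.72, -0.35), (-0.55, 0.72, 0.42), (-0.60, 0.72, -0.35)],
    5: [(0.55, 0.72, 0.42), (0.60, 0.72, -0.35), (-0.55, 0.72, 0.42), (-0.60, 0.72, -0.35),
        (0.0, 0.80, 0.60)],
    6: [(0.55, 0.72, 0.42), (0.60, 0.72, -0.35), (-0.55, 0.72, 0.42), (-0.60, 0.72, -0.35),
        (0.0, 0.80, 0.60), (0.0, 0.80, -0.60)],
}
_LAA_DIR = (0.92, -0.30, 0.35)
_MV_FRACTION = 0.85  # outlet plane at z = -0.85 * c
_EMBED_MM = 2.0      # how far tube axes start inside the chamber surface


@dataclass
class IdealizedAtriumSpec:
    """Parameters of the synthetic atrium.

    ``device_depth`` is the signed distance from the ostium plane to the
    proximal device face along the appendage centerline; values <= 0 mean a
    proximal, pulmonary-ridge-covering pose.  It is carried here so that the
    flow generator can account for the device pose; the device surface
    itself is built and deployed by :mod:`laao_dpm.devices`.
    """

    chamber_semi_axes: tuple[float, float, float] = (40.0, 33.0, 29.0)
    pv_count: int = 4
    pv_radius: float = 6.0
    pv_length: float = 15.0
    laa_length: float = 30.0
    laa_ostium_diameter: float = 20.0
    laa_taper_ratio: float = 0.7
    lspv_fold_point: tuple[float, float, float] | None = None
    device_depth: float = 0.0
    mesh_edge_length: float = 0.68
    seed: int = 0

    def validate(self) -> None:
        axes = np.asarray(self.chamber_semi_axes, dtype=float)
        if axes.shape != (3,) or np.any(axes <= 0):
            raise ValidationError("chamber_semi_axes must be three positive lengths")
        if self.pv_count not in (4, 5, 6):
            raise ValidationError("pv_count must be in {4, 5, 6}")
        for name in ("pv_radius", "pv_length", "laa_length", "laa_ostium_diameter",
                     "mesh_edge_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 < self.laa_taper_ratio <= 1.0:
            raise ValidationError("laa_taper_ratio must lie in (0, 1]")


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _ellipsoid_point(direction: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Surface point of the chamber ellipsoid along a direction from the origin."""
    d = _unit(direction)
    scale = 1.0 / np.sqrt(np.sum((d / axes) ** 2))
    return d * scale


def _tube_frames(spec: IdealizedAtriumSpec):
    axes = np.asarray(spec.chamber_semi_axes, dtype=float)
    frames = []
    for d in _PV_DIRS[spec.pv_count]:
        u = _unit(d)
        anchor = _ellipsoid_point(u, axes)
        frames.append({"origin": anchor - _EMBED_MM * u, "dir": u,
                       "length": spec.pv_length + _EMBED_MM, "radius": spec.pv_radius})
    return frames


def _laa_frame(spec: IdealizedAtriumSpec):
    axes = np.asarray(spec.chamber_semi_axes, dtype=float)
    d = _unit(_LAA_DIR)
    o0 = _ellipsoid_point(d, axes)
    return {"origin": o0, "dir": d, "length": spec.laa_length,
            "r0": 0.5 * spec.laa_ostium_diameter,
            "r1": 0.5 * spec.laa_ostium_diameter * spec.laa_taper_ratio}


def _sdf_chamber(p: np.ndarray, axes: np.ndarray) -> np.ndarray:
    r = np.sqrt(np.sum((p / axes) ** 2, axis=-1))
    return (r - 1.0) * float(axes.min())


def _sdf_tube(p: np.ndarray, frame) -> np.ndarray:
    rel = p - frame["origin"]
    s = rel @ frame["dir"]
    rho = np.linalg.norm(rel - s[..., None] * frame["dir"], axis=-1)
    return np.maximum.reduce([rho - frame["radius"], s - frame["length"], -s])


def _sdf_laa(p: np.ndarray, frame) -> np.ndarray:
    rel = p - frame["origin"]
    s = rel @ frame["dir"]
    rho = np.linalg.norm(rel - s[..., None] * frame["dir"], axis=-1)
    t = np.clip(s, 0.0, frame["length"]) / frame["length"]
    r_s = frame["r0"] + (frame["r1"] - frame["r0"]) * t
    return np.maximum.reduce([rho - r_s, s - frame["length"], -s - _EMBED_MM])


def _largest_component(verts: np.ndarray, faces: np.ndarray):
    """Drop stray sliver components the discretized level set can produce."""
    import trimesh

    labels = trimesh.graph.connected_component_labels(
        trimesh.Trimesh(vertices=verts, faces=faces, process=False).face_adjacency,
        node_count=len(faces),
    )
    keep = labels == np.bincount(labels).argmax()
    faces = faces[keep]
    used = np.unique(faces)
    remap = np.full(len(verts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return verts[used], remap[faces]


def generate_atrium(spec: IdealizedAtriumSpec) -> LabeledSurfaceMesh:
    """Build the labeled synthetic atrium surface for a spec.

    Deterministic for a fixed spec; the returned mesh is watertight (the
    inlet/outlet caps are planar facets of the closed surface) and carries
    the ostium contour, LSPV fold point and MV centre.
    """
    spec.validate()
    axes = np.asarray(spec.chamber_semi_axes, dtype=float)
    tubes = _tube_frames(spec)
    laa = _laa_frame(spec)
    z_mv = -_MV_FRACTION * axes[2]
    h = spec.mesh_edge_length

    # Grid bounds: chamber plus every protruding primitive, with margin.
    pts = [np.array([-axes[0], -axes[1], z_mv]), axes.copy()]
    for fr in tubes:
        pts.append(fr["origin"] + fr["length"] * fr["dir"] + fr["radius"] + 2)
        pts.append(fr["origin"] + fr["length"] * fr["dir"] - fr["radius"] - 2)
    tip = laa["origin"] + laa["length"] * laa["dir"]
    pts += [tip + laa["r0"] + 2, tip - laa["r0"] - 2]
    lo = np.min(pts, axis=0) - 2 * h
    hi = np.max(pts, axis=0) + 2 * h
    lo[2] = max(lo[2], z_mv - 2 * h)

    xs = np.arange(lo[0], hi[0] + h, h)
    ys = np.arange(lo[1], hi[1] + h, h)
    zs = np.arange(lo[2], hi[2] + h, h)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)

    f = _sdf_chamber(grid, axes)
    for fr in tubes:
        f = np.minimum(f, _sdf_tube(grid, fr))
    f = np.minimum(f, _sdf_laa(grid, laa))
    f = np.maximum(f, z_mv - grid[..., 2])  # planar outlet cut

    verts, faces, _, _ = marching_cubes(f, level=0.0, spacing=(h, h, h))
    verts = verts + lo
    verts, faces = _largest_component(verts, faces)

    # ---------------------------------------------------------------- labels
    cent = verts[faces].mean(axis=1)
    fnorm = np.cross(verts[faces][:, 1] - verts[faces][:, 0],
                     verts[faces][:, 2] - verts[faces][:, 0])
    fnorm = fnorm / np.maximum(np.linalg.norm(fnorm, axis=1, keepdims=True), 1e-300)
    cand = [_sdf_chamber(cent, axes), _sdf_laa(cent, laa)]
    cand += [_sdf_tube(cent, fr) for fr in tubes]
    nearest = np.argmin(np.abs(np.stack(cand, axis=0)), axis=0)

    rel = cent - laa["origin"]
    s_laa = rel @ laa["dir"]

    labels: dict[str, np.ndarray] = {}
    assigned = np.zeros(len(faces), dtype=bool)

    # caps are exactly planar facets; the bevel ring the discretized level
    # set produces at the cap rim stays with the wall regions
    mv_mask = (cent[:, 2] < z_mv + 0.6 * h) & (np.abs(fnorm[:, 2]) > 1.0 - 1e-7)
    labels["mv_outlet"] = np.flatnonzero(mv_mask)
    assigned |= mv_mask

    for k, fr in enumerate(tubes):
        relk = cent - fr["origin"]
        sk = relk @ fr["dir"]
        rhok = np.linalg.norm(relk - sk[:, None] * fr["dir"], axis=1)
        cap = ((~assigned) & (sk > fr["length"] - 0.7 * h)
               & (rhok < fr["radius"] + h) & (np.abs(fnorm @ fr["dir"]) > 1.0 - 1e-7))
        labels[f"pv_inlet_{k}"] = np.flatnonzero(cap)
        assigned |= cap

    laa_mask = (~assigned) & (nearest == 1) & (s_laa > 0.5 * h)
    labels["laa_wall"] = np.flatnonzero(laa_mask)
    assigned |= laa_mask
    labels["chamber"] = np.flatnonzero(~assigned)

    # ------------------------------------------------- contour and landmarks
    d = laa["dir"]
    e1 = _unit(np.cross(d, [0.0, 0.0, 1.0]))
    e2 = np.cross(d, e1)
    theta = np.linspace(0.0, 2.0 * np.pi, 257)[:-1]
    contour = (laa["origin"][None, :]
               + laa["r0"] * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2))

    if spec.lspv_fold_point is not None:
        fold = np.asarray(spec.lspv_fold_point, dtype=float)
    else:
        # the pulmonary ridge abuts the ostium rim on the LSPV side: take the
        # ostium-contour point nearest the LSPV anchor
        lspv_anchor = _ellipsoid_point(_unit(_PV_DIRS[spec.pv_count][0]), axes)
        fold = contour[np.argmin(np.linalg.norm(contour - lspv_anchor, axis=1))].copy()

    mv_faces = labels["mv_outlet"]
    if len(mv_faces) > 0:
        mv_center = verts[faces[mv_faces]].mean(axis=(0, 1))
    else:  # extremely coarse meshes
        mv_center = np.array([0.0, 0.0, z_mv])

    mesh = LabeledSurfaceMesh(
        vertices=verts,
        faces=faces,
        labels=labels,
        polylines={"ostium_contour": contour},
        points={"lspv_endpoint": fold, "ostium_center": laa["origin"].copy(),
                "mv_center": mv_center},
        metadata={
            "spec": asdict(spec),
            "laa_axis": d.tolist(),
            "laa_length": spec.laa_length,
            "laa_taper_ratio": spec.laa_taper_ratio,
            "ostium_radius": laa["r0"],
            "z_mv": z_mv,
            "mv_normal": [0.0, 0.0, -1.0],
            "device_depth": spec.device_depth,
            "pv_frames": [{"origin": fr["origin"].tolist(), "dir": fr["dir"].tolist(),
                           "length": fr["length"], "radius": fr["radius"]} for fr in tubes],
            "seed": spec.seed,
        },
    )
    return mesh
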