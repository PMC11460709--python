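"""Parametric occluder models, deployment, and ostium/landing-zone metrics.

Two idealized occluder families are modeled, matching the device classes
used clinically:

* ``plug`` -- a single capped cylinder (lobe) seated inside the appendage
  neck (Watchman class);
* ``pacifier`` -- a lobe cylinder plus a proximal sealing disk of larger
  diameter covering the ostium (Amulet / Amplatzer Cardiac Plug class).

Struts, anchors, hubs and the catheter tip are deliberately omitted; the
proximal face is sealed.  Deployment is rigid: the device axis is aligned
with the appendage centerline tangent and the proximal face placed at a
signed depth from the ostium plane (depth <= 0 = proximal, ridge-covering
pose).  Wall penetration is reported, not mechanically resolved.

Lengths in mm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import trimesh
from scipy.spatial import ConvexHull

from .errors import (
    ConfigurationError,
    GeometryError,
    OutOfRangeError,
    PlacementError,
    ValidationError,
)
from .meshes import LabeledSurfaceMesh
from .spatial import TriangleCollider, point_mesh_distance

__all__ = [
    "DeviceSpec",
    "OstiumMetrics",
    "LandingZone",
    "PRCoverage",
    "build_device",
    "compute_centerline",
    "place_device",
    "ostium_metrics",
    "landing_zone_diagonals",
    "pr_coverage",
    "recommend_size",
    "default_sizing_table",
]

_SECTIONS = 64          # azimuthal facets of the cylinders
_DISK_THICKNESS = 3.0   # mm, proximal sealing disk of the pacifier


@dataclass
class DeviceSpec:
    """Nominal occluder description.

    ``size`` is the nominal lobe diameter (mm); pacifiers additionally carry
    a ``disk_diameter`` >= size.  ``pose`` is an optional 4x4 rigid transform
    applied after construction.
    """

    device_type: Literal["plug", "pacifier"]
    size: float
    lobe_length: float = 20.0
    disk_diameter: float | None = None
    pose: np.ndarray | None = None

    def validate(self) -> None:
        if self.device_type not in ("plug", "pacifier"):
            raise ValidationError("device_type must be 'plug' or 'pacifier'")
        if self.size <= 0:
            raise ValidationError("size must be positive")
        if self.lobe_length <= 0:
            raise ValidationError("lobe_length must be positive")
        if self.device_type == "pacifier":
            if self.disk_diameter is None:
                raise ValidationError("pacifier requires disk_diameter")
            if self.disk_diameter < self.size:
                raise ValidationError("disk_diameter must be >= size")
        elif self.disk_diameter is not None:
            raise ValidationError("plug has no disk_diameter")


@dataclass
class OstiumMetrics:
    """Planar area (mm^2) and perimeter (mm) of the ostium contour."""

    area: float
    perimeter: float

    def __post_init__(self) -> None:
        # isoperimetric inequality: a closed planar curve satisfies P^2 >= 4*pi*A
        if self.perimeter**2 < 4.0 * np.pi * self.area * (1.0 - 1e-9):
            raise GeometryError("perimeter^2 >= 4*pi*area violated; contour is inconsistent")


@dataclass
class LandingZone:
    """Landing-zone cross-section characterized by its diagonals (mm)."""

    contour: np.ndarray
    d_max: float
    d_min: float
    d_mean: float = field(init=False)

    def __post_init__(self) -> None:
        if self.d_min > self.d_max:
            raise GeometryError("d_min must not exceed d_max")
        self.d_mean = 0.5 * (self.d_max + self.d_min)


@dataclass
class PRCoverage:
    """Pulmonary-ridge coverage assessment.

    The ridge counts as covered when the LSPV endpoint lies within
    ``threshold`` (default 10 mm, inclusive) of the device surface; an
    uncovered ridge exposes a band of appendage wall between the ostium
    plane and the proximal device face, whose area is reported.
    """

    lspv_endpoint: np.ndarray
    min_distance_to_device: float
    uncovered_region_area: float
    covered: bool
    threshold: float = 10.0


# ----------------------------------------------------------------- build


def _cylinder(radius: float, length: float, z0: float) -> trimesh.Trimesh:
    cyl = trimesh.creation.cylinder(radius=radius, height=length, sections=_SECTIONS)
    cyl.apply_translation([0.0, 0.0, z0 + 0.5 * length])
    return cyl


def build_device(spec: DeviceSpec) -> LabeledSurfaceMesh:
    """Construct the closed device surface in its reference frame.

    The proximal face sits on the z = 0 plane with the device extending
    toward +z (distal); ``spec.pose`` is applied last.
    """
    spec.validate()
    if spec.device_type == "plug":
        lobe = _cylinder(0.5 * spec.size, spec.lobe_length, 0.0)
        vertices, faces = lobe.vertices, lobe.faces
        labels = {"lobe": np.arange(len(faces))}
    else:
        disk = _cylinder(0.5 * float(spec.disk_diameter), _DISK_THICKNESS, 0.0)
        lobe = _cylinder(0.5 * spec.size, spec.lobe_length, _DISK_THICKNESS)
        vertices = np.vstack([disk.vertices, lobe.vertices])
        faces = np.vstack([disk.faces, lobe.faces + len(disk.vertices)])
        labels = {
            "disk": np.arange(len(disk.faces)),
            "lobe": np.arange(len(disk.faces), len(faces)),
        }
    mesh = LabeledSurfaceMesh(
        vertices=np.asarray(vertices, dtype=float),
        faces=np.asarray(faces),
        labels=labels,
        points={"proximal_center": np.zeros(3)},
        metadata={"device_spec": {"device_type": spec.device_type, "size": spec.size,
                                  "lobe_length": spec.lobe_length,
                                  "disk_diameter": spec.disk_diameter},
                  "axis": [0.0, 0.0, 1.0]},
    )
    if spec.pose is not None:
        pose = np.asarray(spec.pose, dtype=float)
        if pose.shape != (4, 4):
            raise ValidationError("pose must be a 4x4 rigid transform")
        mesh = _apply_transform(mesh, pose)
    return mesh


def _apply_transform(mesh: LabeledSurfaceMesh, T: np.ndarray) -> LabeledSurfaceMesh:
    R, t = T[:3, :3], T[:3, 3]
    out = LabeledSurfaceMesh(
        vertices=mesh.vertices @ R.T + t,
        faces=mesh.faces.copy(),
        labels={k: v.copy() for k, v in mesh.labels.items()},
        polylines={k: v @ R.T + t for k, v in mesh.polylines.items()},
        points={k: R @ v + t for k, v in mesh.points.items()},
        metadata=dict(mesh.metadata),
    )
    if "axis" in out.metadata:
        out.metadata["axis"] = (R @ np.asarray(mesh.metadata["axis"], dtype=float)).tolist()
    return out


# ------------------------------------------------------------- centerline


def compute_centerline(mesh: LabeledSurfaceMesh, step: float = 1.0) -> np.ndarray:
    """Appendage centerline as cross-section centroids at fixed arc steps.

    Marches from the ostium centroid along the local tangent, slicing the
    ``laa_wall`` region with planes perpendicular to the running direction
    and re-centering on each section centroid.
    """
    if "ostium_center" not in mesh.points:
        raise ConfigurationError("mesh lacks an 'ostium_center' landmark")
    laa = mesh.as_trimesh("laa_wall")
    point = np.asarray(mesh.points["ostium_center"], dtype=float)
    direction = np.asarray(mesh.metadata.get("laa_axis", [0, 0, 1]), dtype=float)
    direction = direction / np.linalg.norm(direction)
    r_ost = float(mesh.metadata.get("ostium_radius", 12.0))
    pts = [point.copy()]
    max_len = float(mesh.metadata.get("laa_length", 100.0)) + 5.0
    n_max = int(max_len / step) + 2
    for k in range(n_max):
        probe = pts[-1] + step * direction
        section = laa.section(plane_origin=probe, plane_normal=direction)
        if section is None or len(section.vertices) == 0:
            break
        sec_pts = np.asarray(section.vertices)
        # guard against capturing geometrically distant folds of the slice
        near = sec_pts[np.linalg.norm(sec_pts - probe, axis=1) < 1.8 * r_ost]
        if len(near) == 0:
            break
        centroid = near.mean(axis=0)
        new_dir = centroid - pts[-1]
        n = np.linalg.norm(new_dir)
        if n < 1e-9:
            break
        # near the chamber junction the appendage wall is one-sided; hold the
        # ostium-plane normal there and only then follow the section centroids
        if k * step > 0.4 * r_ost:
            direction = 0.3 * direction + 0.7 * new_dir / n
            direction = direction / np.linalg.norm(direction)
            pts.append(centroid)
        else:
            pts.append(pts[-1] + step * direction)
    if len(pts) < 2:
        raise GeometryError("could not march a centerline into the appendage")
    return np.asarray(pts)


def place_device(
    device: LabeledSurfaceMesh,
    mesh: LabeledSurfaceMesh,
    depth: float,
    centerline_step: float = 1.0,
) -> LabeledSurfaceMesh:
    """Rigidly deploy the device at a signed depth from the ostium plane.

    Positive depth moves the proximal face distally along the centerline
    (deep, ridge-uncovering implantation); depth = 0 puts it on the ostium
    plane; negative depth pulls it proximally into the chamber.  Penetration
    of the device into the wall is measured and reported in the metadata,
    never resolved.
    """
    centerline = compute_centerline(mesh, step=centerline_step)
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if depth > arc[-1]:
        raise PlacementError(
            f"depth {depth:.1f} mm exceeds appendage centerline length {arc[-1]:.1f} mm"
        )
    if depth <= 0:
        tangent = centerline[1] - centerline[0]
        tangent = tangent / np.linalg.norm(tangent)
        anchor = centerline[0] + depth * tangent
    else:
        i = int(np.searchsorted(arc, depth, side="right")) - 1
        i = min(i, len(seg) - 1)
        frac = (depth - arc[i]) / seg[i]
        anchor = centerline[i] + frac * (centerline[i + 1] - centerline[i])
        # tangent from a +-3-step window: single-step centroids carry
        # mesh-resolution jitter that would tilt the device axis
        a = max(i - 3, 0)
        b = min(i + 3, len(centerline) - 1)
        tangent = centerline[b] - centerline[a]
        tangent = tangent / np.linalg.norm(tangent)

    z = np.array([0.0, 0.0, 1.0])
    R = _rotation_between(z, tangent)
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = anchor
    placed = _apply_transform(device, T)

    # report (not resolve) wall penetration: device vertices outside the
    # closed atrial surface
    atrium = mesh.as_trimesh()
    if atrium.is_watertight:
        collider = TriangleCollider(mesh.vertices[mesh.faces])
        outside = ~collider.contains(placed.vertices)
        if outside.any():
            dist, _ = point_mesh_distance(placed.vertices[outside],
                                          mesh.vertices[mesh.faces])
            penetration = float(dist.max())
        else:
            penetration = 0.0
    else:
        penetration = float("nan")
    placed.metadata["deployment"] = {
        "depth": float(depth),
        "anchor": anchor.tolist(),
        "axis": tangent.tolist(),
        "penetration_depth_mm": penetration,
        "centerline_length_mm": float(arc[-1]),
    }
    return placed


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(a, a)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


# ----------------------------------------------------------- measurements


def _project_planar(contour: np.ndarray, planarity_tol: float = 1e-3):
    """Best-fit-plane 2D coordinates of a closed contour."""
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 3 or len(contour) < 3:
        raise GeometryError("contour must be (k>=3, 3)")
    center = contour.mean(axis=0)
    rel = contour - center
    _, s, vt = np.linalg.svd(rel, full_matrices=False)
    normal = vt[2]
    off_plane = np.abs(rel @ normal)
    scale = max(1.0, float(np.abs(rel).max()))
    if off_plane.max() > max(planarity_tol * scale, 1e-6):
        raise GeometryError(
            f"contour deviates from planarity by {off_plane.max():.3g} mm"
        )
    return rel @ vt[0], rel @ vt[1]


def ostium_metrics(contour: np.ndarray) -> OstiumMetrics:
    """Area (shoelace) and perimeter (arc length) of a closed planar contour."""
    x, y = _project_planar(contour)
    from shapely.geometry import Polygon

    poly = Polygon(np.stack([x, y], axis=1))
    if not poly.is_valid:
        raise GeometryError("contour is self-intersecting or degenerate")
    return OstiumMetrics(area=float(poly.area), perimeter=float(poly.length))


def landing_zone_diagonals(contour: np.ndarray) -> LandingZone:
    """Maximum diagonal and minimum caliper width of the landing-zone contour.

    ``d_max`` is the largest point-pair distance in the contour plane;
    ``d_min`` the minimum rotating-caliper width of the convex hull;
    ``d_mean`` their average.
    """
    x, y = _project_planar(contour)
    pts = np.stack([x, y], axis=1)
    if len(pts) < 3:
        raise GeometryError("need at least 3 contour points")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # collinear input
        raise GeometryError(f"degenerate contour: {exc}") from exc
    hp = pts[hull.vertices]
    diff = hp[:, None, :] - hp[None, :, :]
    d_max = float(np.sqrt((diff**2).sum(-1)).max())
    widths = []
    for i in range(len(hp)):
        e = hp[(i + 1) % len(hp)] - hp[i]
        n = np.linalg.norm(e)
        if n < 1e-12:
            continue
        normal = np.array([-e[1], e[0]]) / n
        proj = hp @ normal
        widths.append(proj.max() - proj.min())
    d_min = float(min(widths))
    return LandingZone(contour=np.asarray(contour, dtype=float), d_max=d_max, d_min=d_min)


def pr_coverage(
    mesh: LabeledSurfaceMesh,
    device: LabeledSurfaceMesh,
    lspv_endpoint: np.ndarray | None = None,
    threshold_mm: float = 10.0,
) -> PRCoverage:
    """Classify pulmonary-ridge coverage of a deployed device.

    Coverage is the Euclidean distance from the LSPV endpoint to the device
    surface: <= threshold (inclusive) means covered; strictly greater means
    an uncovered ridge.  The exposed-wall area is the appendage-wall band
    between the ostium plane and the proximal device face.
    """
    if lspv_endpoint is None:
        if "lspv_endpoint" not in mesh.points:
            raise ConfigurationError("mesh lacks an 'lspv_endpoint' landmark")
        lspv_endpoint = mesh.points["lspv_endpoint"]
    lspv_endpoint = np.asarray(lspv_endpoint, dtype=float)
    if device.n_faces == 0:
        raise ConfigurationError("device mesh is empty")

    dist, _ = point_mesh_distance(lspv_endpoint[None, :], device.vertices[device.faces])
    min_distance = float(dist[0])

    area = 0.0
    if "laa_wall" in mesh.labels and "deployment" in device.metadata:
        dep = device.metadata["deployment"]
        axis = np.asarray(dep["axis"], dtype=float)
        prox = np.asarray(dep["anchor"], dtype=float)
        ost = np.asarray(mesh.points["ostium_center"], dtype=float)
        ost_axis = np.asarray(mesh.metadata.get("laa_axis", axis), dtype=float)
        cent = mesh.face_centroids("laa_wall")
        between = ((cent - ost) @ ost_axis > 0.0) & ((cent - prox) @ axis < 0.0)
        area = float(mesh.face_areas("laa_wall")[between].sum())

    return PRCoverage(
        lspv_endpoint=lspv_endpoint,
        min_distance_to_device=min_distance,
        uncovered_region_area=area,
        covered=min_distance <= threshold_mm,
        threshold=threshold_mm,
    )


# ------------------------------------------------------------------ sizing


def default_sizing_table() -> list[dict]:
    """Generic landing-zone-diameter to nominal-size chart.

    A documented stand-in for manufacturer sizing charts (which are cited by
    vendors, not reproduced here): half-open ``[d_min, d_max)`` intervals of
    the mean landing-zone diagonal map to nominal device sizes; a boundary
    value therefore resolves to the larger size.
    """
    plug = [(17, 20, 21), (20, 23, 24), (23, 26, 27), (26, 29, 30), (29, 32, 33)]
    pacifier = [(11, 13, 16), (13, 15, 18), (15, 17, 20), (17, 19, 22),
                (19, 22, 25), (22, 25, 28), (25, 28, 31), (28, 32, 34)]
    rows = [{"device_type": "plug", "d_mean_min": a, "d_mean_max": b, "size_mm": s}
            for a, b, s in plug]
    rows += [{"device_type": "pacifier", "d_mean_min": a, "d_mean_max": b, "size_mm": s}
             for a, b, s in pacifier]
    return rows


def recommend_size(
    zone: LandingZone,
    device_type: str,
    sizing_table: list[dict] | None = None,
) -> float:
    """Nominal device size whose interval contains the mean diagonal.

    Intervals are half-open ``[d_mean_min, d_mean_max)`` so a tie on a
    boundary resolves toward the larger size.
    """
    table = sizing_table if sizing_table is not None else default_sizing_table()
    rows = [r for r in table if r["device_type"] == device_type]
    if not rows:
        raise OutOfRangeError(f"sizing table has no rows for device_type {device_type!r}")
    rows = sorted(rows, key=lambda r: r["d_mean_min"])
    d = zone.d_mean
    for r in rows:
        if r["d_mean_min"] <= d < r["d_mean_max"]:
            return float(r["size_mm"])
    lo, hi = rows[0]["d_mean_min"], rows[-1]["d_mean_max"]
    raise OutOfRangeError(
        f"d_mean {d:.2f} mm outside sizing range [{lo}, {hi}) for {device_type}"
    )
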