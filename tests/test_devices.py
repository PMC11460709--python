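"""Occluder construction, deployment, ostium/landing-zone metrics, coverage."""

import numpy as np
import pytest

from laao_dpm.devices import (
    DeviceSpec,
    build_device,
    landing_zone_diagonals,
    ostium_metrics,
    place_device,
    pr_coverage,
    recommend_size,
)
from laao_dpm.errors import (
    GeometryError,
    OutOfRangeError,
    PlacementError,
    ValidationError,
)


def circle(r, n=256, z=0.0):
    th = np.linspace(0.0, 2 * np.pi, n + 1)[:-1]
    return np.stack([r * np.cos(th), r * np.sin(th), np.full(n, z)], axis=1)


def ellipse(a, b, n=256):
    th = np.linspace(0.0, 2 * np.pi, n + 1)[:-1]
    return np.stack([a * np.cos(th), b * np.sin(th), np.zeros(n)], axis=1)


# ------------------------------------------------------------------ build


def test_plug_surface_area_closed_form():
    """Capped cylinder: area = pi d L + 2 pi r^2 within 2% (64-gon facets)."""
    mesh = build_device(DeviceSpec("plug", 24.0, 20.0))
    target = np.pi * 24 * 20 + 2 * np.pi * 12**2
    assert mesh.area() == pytest.approx(target, rel=0.02)


def test_pacifier_has_lobe_and_disk_components():
    mesh = build_device(DeviceSpec("pacifier", 25.0, 18.0, disk_diameter=32.0))
    assert set(mesh.labels) == {"lobe", "disk"}
    assert all(len(v) > 0 for v in mesh.labels.values())


@pytest.mark.parametrize("spec", [
    DeviceSpec("plug", 0.0),
    DeviceSpec("pacifier", 25.0),                         # missing disk
    DeviceSpec("pacifier", 25.0, disk_diameter=20.0),     # disk < lobe
    DeviceSpec("plug", 24.0, disk_diameter=30.0),         # plug with disk
])
def test_invalid_device_specs_rejected(spec):
    with pytest.raises(ValidationError):
        build_device(spec)


# -------------------------------------------------------------- deployment


def test_depth_zero_puts_proximal_face_on_ostium_plane(coarse_atrium):
    dev = build_device(DeviceSpec("plug", 19.0, 12.0))
    placed = place_device(dev, coarse_atrium, depth=0.0)
    anchor = np.asarray(placed.metadata["deployment"]["anchor"])
    ost = coarse_atrium.points["ostium_center"]
    axis = np.asarray(coarse_atrium.metadata["laa_axis"])
    assert abs((anchor - ost) @ axis) < 1e-6


def test_depth_advances_along_straight_centerline(coarse_atrium):
    """On a straight tubular appendage, depth 8 mm lands the face ~8 mm
    distal along the appendage axis (centerline discretization tolerance)."""
    dev = build_device(DeviceSpec("plug", 19.0, 12.0))
    placed = place_device(dev, coarse_atrium, depth=8.0)
    anchor = np.asarray(placed.metadata["deployment"]["anchor"])
    ost = coarse_atrium.points["ostium_center"]
    axis = np.asarray(coarse_atrium.metadata["laa_axis"])
    assert (anchor - ost) @ axis == pytest.approx(8.0, abs=0.8)


def test_depth_beyond_appendage_raises(coarse_atrium):
    dev = build_device(DeviceSpec("plug", 19.0, 12.0))
    with pytest.raises(PlacementError):
        place_device(dev, coarse_atrium, depth=200.0)


def test_rigid_placement_preserves_surface_area(coarse_atrium, deployed_plug):
    dev = build_device(DeviceSpec("plug", 19.0, 12.0))
    assert deployed_plug.area() == pytest.approx(dev.area(), rel=1e-9)


# ------------------------------------------------------------ measurements


def test_ostium_metrics_circle():
    m = ostium_metrics(circle(12.8))
    assert m.area == pytest.approx(514.7, abs=0.5)
    assert m.perimeter == pytest.approx(80.4, abs=0.1)


def test_ostium_metrics_unit_square():
    sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    m = ostium_metrics(sq)
    assert m.area == pytest.approx(1.0)
    assert m.perimeter == pytest.approx(4.0)


def test_ostium_metrics_ellipse():
    m = ostium_metrics(ellipse(10.0, 5.0))
    assert m.area == pytest.approx(np.pi * 50.0, rel=0.005)


def test_ostium_metrics_rejects_self_intersection():
    bow = np.array([[0, 0, 0], [1, 1, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
    with pytest.raises(GeometryError):
        ostium_metrics(bow)


def test_isoperimetric_inequality_holds_for_generated_contours(coarse_atrium):
    m = ostium_metrics(coarse_atrium.polylines["ostium_contour"])
    assert m.perimeter**2 >= 4 * np.pi * m.area * (1 - 1e-9)


def test_diagonals_circle():
    lz = landing_zone_diagonals(circle(12.0))
    assert lz.d_max == pytest.approx(24.0, abs=0.1)
    assert lz.d_min == pytest.approx(24.0, abs=0.1)
    assert lz.d_mean == pytest.approx(24.0, abs=0.1)


def test_diagonals_ellipse_calipers():
    lz = landing_zone_diagonals(ellipse(15.0, 10.0))
    assert lz.d_max == pytest.approx(30.0, abs=0.2)
    assert lz.d_min == pytest.approx(20.0, abs=0.2)
    assert lz.d_mean == pytest.approx(25.0, abs=0.2)
    assert lz.d_min <= lz.d_mean <= lz.d_max


def test_diagonals_degenerate_input():
    with pytest.raises(GeometryError):
        landing_zone_diagonals(np.array([[0, 0, 0], [1, 0, 0]], dtype=float))


# ---------------------------------------------------------------- coverage


def test_device_through_fold_point_is_covered(coarse_atrium, deployed_plug):
    """Distance 0 when the query point lies on the device surface."""
    on_surface = deployed_plug.vertices[0]
    cov = pr_coverage(coarse_atrium, deployed_plug, lspv_endpoint=on_surface)
    assert cov.min_distance_to_device == pytest.approx(0.0, abs=1e-9)
    assert cov.covered


def test_deep_device_in_straight_appendage_uncovers_ridge(coarse_atrium, deployed_plug):
    """Fold on the ostium rim, face 12 mm distal -> distance ~12 mm, uncovered."""
    cov = pr_coverage(coarse_atrium, deployed_plug)
    assert cov.min_distance_to_device == pytest.approx(12.0, abs=1.5)
    assert cov.min_distance_to_device > 10.0
    assert not cov.covered
    assert cov.uncovered_region_area > 0.0


def test_coverage_threshold_inclusive_at_exactly_ten(coarse_atrium, deployed_plug):
    """Exactly 10 mm counts as covered (uncovered requires strictly more)."""
    dist = pr_coverage(coarse_atrium, deployed_plug).min_distance_to_device
    cov = pr_coverage(coarse_atrium, deployed_plug, threshold_mm=dist)
    assert cov.covered


def test_coverage_distance_monotone_in_depth(coarse_atrium):
    dev = build_device(DeviceSpec("plug", 19.0, 12.0))
    dists = []
    for depth in (0.0, 4.0, 8.0, 12.0, 16.0):
        placed = place_device(dev, coarse_atrium, depth=depth)
        dists.append(pr_coverage(coarse_atrium, placed).min_distance_to_device)
    assert all(b >= a - 1e-6 for a, b in zip(dists, dists[1:]))


# ------------------------------------------------------------------ sizing


def test_recommend_size_lookup_and_boundary_tie():
    from laao_dpm.devices import LandingZone

    lz = LandingZone(contour=circle(12.0), d_max=24.5, d_min=24.5)  # row (23, 26)
    assert recommend_size(lz, "plug") == 27.0
    table = [
        {"device_type": "plug", "d_mean_min": 20.0, "d_mean_max": 24.0, "size_mm": 24},
        {"device_type": "plug", "d_mean_min": 24.0, "d_mean_max": 28.0, "size_mm": 27},
    ]
    # a d_mean exactly on the interval boundary resolves to the larger size
    lz24 = LandingZone(contour=circle(12.0), d_max=24.0, d_min=24.0)
    assert recommend_size(lz24, "plug", table) == 27.0


def test_recommend_size_out_of_range_lists_range():
    lz = landing_zone_diagonals(circle(40.0))
    with pytest.raises(OutOfRangeError, match=r"\["):
        recommend_size(lz, "plug")


def test_recommend_size_empty_table():
    lz = landing_zone_diagonals(circle(12.0))
    with pytest.raises(OutOfRangeError):
        recommend_size(lz, "plug", sizing_table=[])
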