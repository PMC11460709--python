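"""Field sampling, phase statistics, device regions, recirculation score."""

import numpy as np
import pytest

from laao_dpm.errors import EmptyRegionError, OutOfDomainError
from laao_dpm.flowfield import (
    PhaseWindow,
    device_region,
    phase_average_speed,
    recirculation_index,
)

from conftest import make_series, uniform_series


# ---------------------------------------------------------------- sampling


def test_uniform_field_samples_exactly():
    u0 = np.array([0.2, -0.1, 0.05])
    ser = uniform_series(u0)
    fs = ser.sample(np.array([3.3, -7.1, 12.9]), 0.123)
    assert np.allclose(fs.u, u0)
    assert np.allclose(fs.grad_u, 0.0)
    assert fs.shear_magnitude == pytest.approx(0.0, abs=1e-12)


def test_simple_shear_gradient_and_magnitude():
    """u = (gamma * y, 0, 0): single gradient entry gamma, and
    sqrt(d:d) = gamma / sqrt(2) for the symmetric part."""
    gamma = 4.0  # 1/s
    ser = make_series(lambda p, t: np.stack(
        [gamma * p[:, 1] * 1e-3, np.zeros(len(p)), np.zeros(len(p))], axis=1))
    fs = ser.sample(np.array([5.0, 5.0, 5.0]), 0.5)
    assert fs.grad_u[0, 1] == pytest.approx(gamma, rel=1e-9)
    assert np.abs(fs.grad_u).sum() == pytest.approx(gamma, rel=1e-9)
    assert fs.shear_magnitude == pytest.approx(gamma / np.sqrt(2), rel=1e-9)


def test_sampling_exact_on_stored_step_and_node():
    rng = np.random.default_rng(0)
    ser = make_series(lambda p, t: rng.normal(size=(len(p), 3)), n_steps=4, n_nodes=5)
    node = np.array([ser.axes[0][2], ser.axes[1][3], ser.axes[2][1]])
    u = ser.sample_batch(node[None, :], float(ser.times[2]), with_grad=False)
    stored = ser.values[2, 2, 3, 1]
    assert np.array_equal(u[0], stored)


def test_sample_outside_support_raises():
    ser = uniform_series([0.1, 0, 0])
    with pytest.raises(OutOfDomainError):
        ser.sample(np.array([999.0, 0.0, 0.0]), 0.5)
    with pytest.raises(OutOfDomainError):
        ser.sample(np.zeros(3), 99.0)


# ------------------------------------------------------------ phase windows


def test_phase_windows_partition_the_beat():
    ser = uniform_series([0.1, 0, 0])
    sy = ser.beat_steps(PhaseWindow.systole(), 1)
    di = ser.beat_steps(PhaseWindow.diastole(), 1)
    fu = ser.beat_steps(PhaseWindow.full_cycle(), 1)
    assert len(sy) == 30 and len(di) == 58 and len(fu) == 88
    assert np.array_equal(np.sort(np.concatenate([sy, di])), fu)


def test_phase_average_constant_speed():
    ser = uniform_series([0.25, 0, 0])
    pts = np.zeros((4, 3))
    mean, sd = phase_average_speed(ser, pts, PhaseWindow.full_cycle())
    assert mean == pytest.approx(0.25)
    assert sd == pytest.approx(0.0, abs=1e-12)


def test_phase_average_rectified_sine_closed_form():
    """|u|(t) = A |sin(pi t / T)| averages to 2A/pi within 1% at 88 steps."""
    A, T = 0.4, 0.88
    ser = make_series(lambda p, t: np.stack(
        [np.full(len(p), A * np.sin(np.pi * (t - 0.88) / T)),
         np.zeros(len(p)), np.zeros(len(p))], axis=1))
    mean, _ = phase_average_speed(ser, np.zeros((1, 3)), PhaseWindow.full_cycle())
    assert mean == pytest.approx(2 * A / np.pi, rel=0.01)


def test_full_cycle_mean_is_window_weighted_combination():
    rng = np.random.default_rng(3)
    ser = make_series(lambda p, t: np.broadcast_to(
        rng.normal(scale=0.2, size=3), (len(p), 3)).copy())
    pts = np.zeros((2, 3))
    sy = phase_average_speed(ser, pts, PhaseWindow.systole())[0]
    di = phase_average_speed(ser, pts, PhaseWindow.diastole())[0]
    fu = phase_average_speed(ser, pts, PhaseWindow.full_cycle())[0]
    assert fu == pytest.approx((30 * sy + 58 * di) / 88, rel=1e-12)


def test_empty_region_rejected():
    ser = uniform_series([0.1, 0, 0])
    with pytest.raises(EmptyRegionError):
        phase_average_speed(ser, np.empty((0, 3)), PhaseWindow.full_cycle())


# ------------------------------------------------------------ recirculation


def test_recirculation_zero_for_steady_unidirectional():
    ser = uniform_series([0.3, 0, 0])
    score, flag = recirculation_index(ser, np.zeros((3, 3)), PhaseWindow.full_cycle())
    assert score == pytest.approx(0.0, abs=1e-12)
    assert not flag


def test_recirculation_one_for_fully_reversing():
    """+v for half the window, -v for the other half -> vector mean ~ 0."""
    v = np.array([0.1, 0, 0])

    def u(p, t):
        step = int(round(t / 0.01))          # robust to float round-off
        sign = 1.0 if (step - 88) <= 44 else -1.0
        return np.broadcast_to(sign * v, (len(p), 3)).copy()

    ser = make_series(u)
    score, flag = recirculation_index(ser, np.zeros((1, 3)), PhaseWindow.full_cycle())
    assert score == pytest.approx(1.0, abs=1e-9)
    assert flag  # score 1 and mean speed 0.1 < 0.2


def test_recirculation_flag_requires_low_speed_conjunction():
    """Steady slow flow: score 0 -> no flag despite speed below 0.2 m/s."""
    ser = uniform_series([0.1, 0, 0])
    score, flag = recirculation_index(ser, np.zeros((1, 3)), PhaseWindow.full_cycle())
    assert score == pytest.approx(0.0, abs=1e-12)
    assert not flag


def test_recirculation_invariant_under_rigid_rotation():
    rng = np.random.default_rng(5)
    coeffs = rng.normal(scale=0.1, size=(8, 3))

    def u(p, t):
        k = int(round(t / 0.01)) % 8
        return np.broadcast_to(coeffs[k], (len(p), 3)).copy()

    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("xyz", [0.3, -1.1, 0.7]).as_matrix()
    ser = make_series(u)
    ser_rot = make_series(lambda p, t: u(p @ R, t) @ R.T)
    pts = rng.uniform(-10, 10, size=(5, 3))
    s1, _ = recirculation_index(ser, pts, PhaseWindow.full_cycle())
    s2, _ = recirculation_index(ser_rot, pts @ R.T, PhaseWindow.full_cycle())
    assert s2 == pytest.approx(s1, rel=1e-9)
    assert 0.0 <= s1 <= 1.0


# ----------------------------------------------------------- device region


def test_device_region_collapses_at_depth_zero(coarse_atrium):
    from laao_dpm.devices import DeviceSpec, build_device, place_device

    dev = build_device(DeviceSpec("plug", 19.0, 12.0))
    placed = place_device(dev, coarse_atrium, depth=0.0)
    region = device_region(coarse_atrium, placed)
    assert len(region.band_points) == 0
    assert region.volume_mm3 == 0.0
    assert len(region.points) == placed.n_faces


def test_device_region_band_volume_cylinder_slab(coarse_atrium, deployed_plug):
    """Straight tube radius 10, device at 12 mm: band volume ~ pi r^2 h."""
    region = device_region(coarse_atrium, deployed_plug, band_spacing=1.0)
    expected = np.pi * 10.0**2 * 12.0
    assert region.volume_mm3 == pytest.approx(expected, rel=0.12)
    assert len(region.band_points) > 0


def test_device_region_membership_deterministic(coarse_atrium, deployed_plug):
    r1 = device_region(coarse_atrium, deployed_plug, band_spacing=2.0)
    r2 = device_region(coarse_atrium, deployed_plug, band_spacing=2.0)
    pts = np.vstack([r1.points, r1.points + 0.01])
    assert np.array_equal(r1.membership(pts), r2.membership(pts))
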