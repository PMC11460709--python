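"""Time-resolved velocity fields: sampling, regions, phase statistics.

The carrier flow lives on a regular grid (mm) with one velocity snapshot
(m/s) per time step.  Sampling is trilinear in space and linear in time and
is exact at stored nodes and steps; the velocity gradient is obtained from
central differences on the grid (interpolated the same way) and returned in
1/s.  Phase statistics follow the beat phases of the driving waveform:
systole t = 0-0.30 s, diastole t = 0.31-0.88 s, evaluated by default on the
second simulated beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CoverageError,
    EmptyRegionError,
    OutOfDomainError,
    ValidationError,
)

__all__ = [
    "VelocityFieldSeries",
    "FlowSample",
    "PhaseWindow",
    "DeviceRegion",
    "device_region",
    "phase_average_speed",
    "recirculation_index",
]


@dataclass
class FlowSample:
    """Pointwise flow state: velocity, gradient, deformation, shear scale.

    ``shear_magnitude`` is the double contraction ``sqrt(d:d)`` of the
    deformation tensor (symmetric part of the velocity gradient), in 1/s.
    """

    u: np.ndarray          # m/s
    grad_u: np.ndarray     # 1/s, grad_u[i, j] = du_i/dx_j
    d_ij: np.ndarray = field(init=False)
    shear_magnitude: float = field(init=False)

    def __post_init__(self) -> None:
        self.d_ij = 0.5 * (self.grad_u + self.grad_u.T)
        self.shear_magnitude = float(np.sqrt(np.sum(self.d_ij * self.d_ij)))


@dataclass
class PhaseWindow:
    """Beat-relative analysis window.

    Membership on the sample grid is ``t_start < t <= t_end`` (samples sit
    at (i+1)*dt), which partitions the beat into systole (0, 0.30],
    diastole (0.30, 0.88] and full cycle (0, 0.88] without double counting.
    """

    name: str
    t_start: float
    t_end: float

    @classmethod
    def systole(cls) -> "PhaseWindow":
        return cls("systole", 0.0, 0.30)

    @classmethod
    def diastole(cls) -> "PhaseWindow":
        return cls("diastole", 0.30, 0.88)

    @classmethod
    def full_cycle(cls) -> "PhaseWindow":
        return cls("full_cycle", 0.0, 0.88)


class VelocityFieldSeries:
    """Velocity snapshots on a regular grid over n_beats * steps_per_beat steps."""

    def __init__(self, times: np.ndarray, axes: tuple[np.ndarray, np.ndarray, np.ndarray],
                 values: np.ndarray, beat_period: float = 0.88,
                 steps_per_beat: int = 88, metadata: dict | None = None):
        self.times = np.asarray(times, dtype=float)
        self.axes = tuple(np.asarray(a, dtype=float) for a in axes)
        self.values = np.asarray(values)
        self.beat_period = float(beat_period)
        self.steps_per_beat = int(steps_per_beat)
        self.metadata = metadata or {}
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("time grid must be strictly increasing")
        expected = (len(self.times),) + tuple(len(a) for a in self.axes) + (3,)
        if self.values.shape != expected:
            raise ValidationError(f"values shape {self.values.shape} != {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("velocity samples must be finite")
        self._grad_cache: dict[int, np.ndarray] = {}
        self._spacing = np.array([float(a[1] - a[0]) if len(a) > 1 else 1.0
                                  for a in self.axes])

    # ------------------------------------------------------------------ time
    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def _time_bracket(self, t: float):
        times = self.times
        if t < times[0] - 1e-12 or t > times[-1] + 1e-12:
            raise OutOfDomainError(f"t={t} outside series span [{times[0]}, {times[-1]}]")
        i = int(np.searchsorted(times, t - 1e-12))
        i = min(i, len(times) - 1)
        if abs(times[i] - t) <= 1e-12:
            return i, i, 0.0
        i0 = max(i - 1, 0)
        w = (t - times[i0]) / (times[i] - times[i0])
        return i0, i, float(w)

    # ----------------------------------------------------------------- space
    def _locate(self, points: np.ndarray):
        idx = []
        frac = []
        for d, ax in enumerate(self.axes):
            x = points[:, d]
            if np.any(x < ax[0] - 1e-9) or np.any(x > ax[-1] + 1e-9):
                raise OutOfDomainError("point outside spatial support")
            i = np.clip(np.searchsorted(ax, x, side="right") - 1, 0, len(ax) - 2)
            f = (x - ax[i]) / (ax[i + 1] - ax[i])
            idx.append(i)
            frac.append(np.clip(f, 0.0, 1.0))
        return idx, frac

    def _trilinear(self, arr: np.ndarray, idx, frac) -> np.ndarray:
        ix, iy, iz = idx
        fx, fy, fz = frac
        out = 0.0
        for dx in (0, 1):
            wx = np.where(dx == 1, fx, 1.0 - fx)
            for dy in (0, 1):
                wy = np.where(dy == 1, fy, 1.0 - fy)
                for dz in (0, 1):
                    wz = np.where(dz == 1, fz, 1.0 - fz)
                    w = (wx * wy * wz)[:, None]
                    vals = arr[ix + dx, iy + dy, iz + dz]
                    vals = vals.reshape(len(ix), -1)
                    out = out + w * vals
        return out

    def _grad_of_step(self, step: int) -> np.ndarray:
        """(nx, ny, nz, 3, 3) du_i/dx_j in 1/s (grid spacing is mm)."""
        if step not in self._grad_cache:
            if len(self._grad_cache) > 4:
                self._grad_cache.clear()
            u = self.values[step]
            comps = []
            for j in range(3):
                comps.append(np.gradient(u, self._spacing[j], axis=j))
            g = np.stack(comps, axis=-1) * 1000.0  # per-mm -> per-m
            self._grad_cache[step] = g
        return self._grad_cache[step]

    def inside(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        ok = np.ones(len(points), dtype=bool)
        for d, ax in enumerate(self.axes):
            ok &= (points[:, d] >= ax[0] - 1e-9) & (points[:, d] <= ax[-1] + 1e-9)
        return ok

    def sample_batch(self, points: np.ndarray, t: float, with_grad: bool = True,
                     with_dudt: bool = False):
        """Velocities (and gradients, time derivative) at many points, one time."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        i0, i1, w = self._time_bracket(t)
        idx, frac = self._locate(points)
        u0 = self._trilinear(self.values[i0], idx, frac).reshape(-1, 3)
        if i1 != i0:
            u1 = self._trilinear(self.values[i1], idx, frac).reshape(-1, 3)
            u = (1.0 - w) * u0 + w * u1
        else:
            u1 = u0
            u = u0
        out = [u]
        if with_grad:
            g0 = self._trilinear(self._grad_of_step(i0), idx, frac).reshape(-1, 3, 3)
            if i1 != i0:
                g1 = self._trilinear(self._grad_of_step(i1), idx, frac).reshape(-1, 3, 3)
                g = (1.0 - w) * g0 + w * g1
            else:
                g = g0
            out.append(g)
        if with_dudt:
            if i1 != i0:
                dudt = (u1 - u0) / (self.times[i1] - self.times[i0])
            elif i0 + 1 < len(self.times):
                u_next = self._trilinear(self.values[i0 + 1], idx, frac).reshape(-1, 3)
                dudt = (u_next - u0) / (self.times[i0 + 1] - self.times[i0])
            else:
                dudt = np.zeros_like(u0)
            out.append(dudt)
        return tuple(out) if len(out) > 1 else out[0]

    def sample(self, x: np.ndarray, t: float) -> FlowSample:
        """Single-point flow sample with velocity-gradient tensor."""
        u, g = self.sample_batch(np.asarray(x, dtype=float)[None, :], t, with_grad=True)
        return FlowSample(u=u[0], grad_u=g[0])

    def beat_steps(self, window: PhaseWindow, beat_index: int = 1) -> np.ndarray:
        """Indices of stored steps falling in a beat-relative window."""
        t0 = beat_index * self.beat_period
        rel = self.times - t0
        mask = (rel > window.t_start + 1e-12) & (rel <= window.t_end + 1e-12)
        steps = np.flatnonzero(mask)
        if len(steps) == 0:
            raise CoverageError(
                f"series does not cover window {window.name!r} of beat {beat_index}"
            )
        return steps


# -------------------------------------------------------------------- region


@dataclass
class DeviceRegion:
    """Measurement region: the band from the LSPV-fold plane to the proximal
    device face, plus the device surface itself.

    ``points`` carries the sample points used for velocity statistics
    (device-surface face centroids and band points); membership of arbitrary
    points is a signed-distance test against the two bounding planes.
    """

    device_points: np.ndarray
    band_points: np.ndarray
    fold_plane: tuple[np.ndarray, np.ndarray]   # (origin, normal), band side: normal-positive
    device_plane: tuple[np.ndarray, np.ndarray] # (origin, normal), band side: normal-negative
    volume_mm3: float
    tolerance: float = 1e-6

    @property
    def points(self) -> np.ndarray:
        if len(self.band_points) == 0:
            return self.device_points
        return np.vstack([self.device_points, self.band_points])

    def membership(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        o1, n1 = self.fold_plane
        o2, n2 = self.device_plane
        return (((points - o1) @ n1 >= -self.tolerance)
                & ((points - o2) @ n2 <= self.tolerance))


def device_region(mesh, device, band_spacing: float = 1.5) -> DeviceRegion:
    """Build the device-neighbourhood region of a deployed configuration.

    The band is bounded proximally by the ostium-side plane through the LSPV
    fold (normal along the appendage axis) and distally by the proximal
    device face; it collapses to the device surface alone when the device
    sits at the fold plane (depth <= 0).  The band volume is estimated by
    voxel counting inside the closed atrial surface.
    """
    from .errors import ConfigurationError
    from .spatial import TriangleCollider

    if "lspv_endpoint" not in mesh.points:
        raise ConfigurationError("mesh lacks 'lspv_endpoint' landmark")
    if "deployment" not in device.metadata:
        raise ConfigurationError("device is not deployed (no 'deployment' metadata)")
    axis = np.asarray(mesh.metadata["laa_axis"], dtype=float)
    fold = np.asarray(mesh.points["lspv_endpoint"], dtype=float)
    ost = np.asarray(mesh.points["ostium_center"], dtype=float)
    # ostium-side plane through the fold: use the appendage axis as normal
    fold_origin = ost + ((fold - ost) @ axis) * axis
    dep = device.metadata["deployment"]
    dev_axis = np.asarray(dep["axis"], dtype=float)
    dev_origin = np.asarray(dep["anchor"], dtype=float)

    device_points = device.face_centroids()

    gap = (dev_origin - fold_origin) @ axis
    band_points = np.empty((0, 3))
    volume = 0.0
    if gap > band_spacing * 0.5:
        lo = np.minimum(fold_origin, dev_origin) - 25.0
        hi = np.maximum(fold_origin, dev_origin) + 25.0
        h = band_spacing
        gx = np.arange(lo[0], hi[0], h)
        gy = np.arange(lo[1], hi[1], h)
        gz = np.arange(lo[2], hi[2], h)
        collider = TriangleCollider(mesh.vertices[mesh.faces])
        inside = collider.contains_grid(gx, gy, gz).reshape(-1)
        grid = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1).reshape(-1, 3)
        between = (((grid - fold_origin) @ axis >= 0.0)
                   & ((grid - dev_origin) @ dev_axis <= 0.0))
        keep = between & inside
        band_points = grid[keep]
        volume = float(keep.sum()) * h**3

    return DeviceRegion(
        device_points=device_points,
        band_points=band_points,
        fold_plane=(fold_origin, axis),
        device_plane=(dev_origin, dev_axis),
        volume_mm3=volume,
    )


# ---------------------------------------------------------------- statistics


def _region_points(region) -> np.ndarray:
    pts = region.points if hasattr(region, "points") else np.atleast_2d(region)
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    if len(pts) == 0:
        raise EmptyRegionError("region contains no sample points")
    return pts


def _window_speeds(series: VelocityFieldSeries, points: np.ndarray,
                   window: PhaseWindow, beat_index: int):
    steps = series.beat_steps(window, beat_index)
    speeds = np.empty((len(steps), len(points)))
    vecs = np.empty((len(steps), len(points), 3))
    for row, s in enumerate(steps):
        u = series.sample_batch(points, float(series.times[s]), with_grad=False)
        vecs[row] = u
        speeds[row] = np.linalg.norm(u, axis=1)
    return speeds, vecs


def phase_average_speed(series: VelocityFieldSeries, region, window: PhaseWindow,
                        beat_index: int = 1) -> tuple[float, float]:
    """Mean and SD of |u| over region points and window steps (node weighting)."""
    points = _region_points(region)
    speeds, _ = _window_speeds(series, points, window, beat_index)
    return float(speeds.mean()), float(speeds.std(ddof=0))


def recirculation_index(series: VelocityFieldSeries, region, window: PhaseWindow,
                        beat_index: int = 1, threshold: float = 0.5,
                        low_speed_ms: float = 0.2) -> tuple[float, bool]:
    """Directional-coherence score in [0, 1] with a stasis flag.

    Per point: ``1 - |mean velocity vector| / mean speed`` -- 0 for steady
    unidirectional flow, 1 for fully reversing flow.  The flag quantifies
    the visual streamline judgement of recirculating slow flow: it raises
    only when the score exceeds ``threshold`` AND the region mean speed is
    below ``low_speed_ms``.
    """
    points = _region_points(region)
    speeds, vecs = _window_speeds(series, points, window, beat_index)
    mean_speed_per_pt = speeds.mean(axis=0)
    mean_vec_norm = np.linalg.norm(vecs.mean(axis=0), axis=1)
    ok = mean_speed_per_pt > 1e-12
    if not ok.any():
        import warnings

        warnings.warn("degenerate flow: zero mean speed everywhere in region")
        return 1.0, False
    score = float(np.mean(1.0 - mean_vec_norm[ok] / mean_speed_per_pt[ok]))
    score = min(max(score, 0.0), 1.0)
    mean_speed = float(speeds.mean())
    return score, bool(score >= threshold and mean_speed < low_speed_ms)
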