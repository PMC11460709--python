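"""Shared fixtures: analytic field factories, small synthetic worlds, and
the two-configuration demo pipeline (session-scoped, reused by several
tests to keep the suite fast)."""

from __future__ import annotations

import numpy as np
import pytest

from laao_dpm.atrium import IdealizedAtriumSpec, generate_atrium
from laao_dpm.devices import DeviceSpec, build_device, place_device
from laao_dpm.flowfield import VelocityFieldSeries
from laao_dpm.meshes import LabeledSurfaceMesh
from laao_dpm.waveforms import WaveformSet


def make_series(u_of_xt, n_steps: int = 176, dt: float = 0.01,
                extent: float = 50.0, n_nodes: int = 11,
                steps_per_beat: int = 88) -> VelocityFieldSeries:
    """Velocity series from a callable u(points_mm, t) -> (n, 3) m/s."""
    ax = np.linspace(-extent, extent, n_nodes)
    times = dt * np.arange(1, n_steps + 1)
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    values = np.empty((n_steps, n_nodes, n_nodes, n_nodes, 3))
    for i, t in enumerate(times):
        values[i] = np.asarray(u_of_xt(pts, t)).reshape(n_nodes, n_nodes, n_nodes, 3)
    return VelocityFieldSeries(times, (ax, ax, ax), values,
                               beat_period=steps_per_beat * dt,
                               steps_per_beat=steps_per_beat)


def uniform_series(u0, **kw) -> VelocityFieldSeries:
    u0 = np.asarray(u0, dtype=float)
    return make_series(lambda p, t: np.broadcast_to(u0, (len(p), 3)), **kw)


def quad_mesh(z: float = 0.0, half: float = 20.0, label: str = "device",
              flip: bool = False) -> LabeledSurfaceMesh:
    """Two-triangle horizontal square patch at height z (normal +z)."""
    v = np.array([[-half, -half, z], [half, -half, z],
                  [half, half, z], [-half, half, z]], dtype=float)
    f = np.array([[0, 1, 2], [0, 2, 3]])
    if flip:
        f = f[:, ::-1]
    return LabeledSurfaceMesh(v, f, labels={label: np.arange(2)})


@pytest.fixture(scope="session")
def coarse_atrium() -> LabeledSurfaceMesh:
    """Straight-appendage atrium at test resolution (deep-device pose)."""
    return generate_atrium(IdealizedAtriumSpec(
        mesh_edge_length=2.0, laa_taper_ratio=1.0, device_depth=12.0))


@pytest.fixture(scope="session")
def mini_waveforms() -> WaveformSet:
    """Halved temporal resolution (44 steps of 20 ms) for cheap episodes."""
    return WaveformSet(steps_per_beat=44, dt=0.02)


@pytest.fixture(scope="session")
def deployed_plug(coarse_atrium):
    dev = build_device(DeviceSpec("plug", 19.0, 12.0))
    return place_device(dev, coarse_atrium, depth=12.0)


@pytest.fixture(scope="session")
def demo_result():
    """The two-configuration study (uncovered depth 12 mm vs covered depth 0)."""
    from laao_dpm.report import run_pipeline

    cfg = {
        "seed": 1,
        "atrium": {"mesh_edge_length": 1.5, "laa_taper_ratio": 1.0},
        "device": {"device_type": "plug", "size": 19.0, "lobe_length": 12.0},
        "flow": {"grid_spacing": 3.0},
        "transport": {"facet_stride": 4, "vol_la_ml": 160.0},
        "configurations": [{"name": "uncovered", "depth": 12.0},
                           {"name": "covered", "depth": 0.0}],
    }
    return run_pipeline(cfg)
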