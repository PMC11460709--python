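"""Analytic pulsatile flow and wall-shear-stress synthesis.

The synthetic field replaces (never imitates pointwise) a Navier-Stokes
solution: it superposes

* a drainage term directed at the mitral outlet whose speed equals the
  imposed transmitral waveform (exactly at the outlet cap, so the boundary
  profile is recovered from the generated field),
* a solenoidal chamber vortex,
* an intra-appendage recirculation (swirl + weak outward drift) that decays
  exponentially with depth into the appendage at a rate set by the
  ``stasis`` parameter,
* a pulmonary-ridge jet sweeping the left-superior-vein inflow across the
  appendage mouth -- into the appendage while the band proximal of the
  device face is open (uncovered ridge), deflected toward the outlet when a
  covering device closes it,
* a converging ostium funnel plus band inflow, likewise gated by the open
  band (a ridge-covering device at depth <= 0 closes both), and
* an optional divergence-free stochastic perturbation (curl of a random
  smooth vector potential) with amplitude a stated fraction of peak speed.

Every term scales with the beat waveform, so zero forcing yields a zero
field.  A deeper device therefore sits in slower flow and leaves appendage
wall exposed to slow recirculation -- the covered-versus-uncovered velocity
ordering holds by construction.  Wall shear stress is Newtonian: dynamic
viscosity times the near-wall tangential velocity gradient, sampled one
offset length off each wall face along the inward normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ConsistencyError
from .flowfield import VelocityFieldSeries
from .meshes import LabeledSurfaceMesh
from .waveforms import WaveformSet

__all__ = ["FlowParams", "generate_flow", "generate_wss", "WSSeries"]


@dataclass
class FlowParams:
    """Tunables of the synthetic flow construction.

    ``stasis`` controls how fast speed decays with depth into the appendage
    (dimensionless rate per appendage length; higher = more stagnant LAA).
    ``perturbation_amplitude`` is the stochastic component's peak amplitude
    as a fraction of peak transmitral speed.
    """

    grid_spacing: float = 2.5        # mm
    stasis: float = 1.0
    decay_rate: float = 2.5          # e-folds of LAA through-flow per (stasis * laa_length)
    vortex_strength: float = 0.3     # chamber swirl / drainage-speed ratio
    laa_swirl: float = 0.5           # appendage swirl / drainage-speed ratio
    laa_radial: float = 0.3          # outward drift / drainage-speed ratio
    laa_inflow: float = 0.8          # open-band/funnel inflow / drainage-speed ratio
    ridge_jet: float = 0.8           # LSPV-to-ostium sweep / drainage-speed ratio
    ridge_jet_width: float = 8.0     # mm, gaussian radius of the sweep jet
    perturbation_amplitude: float = 0.05
    mask_width: float = 10.0         # mm, suppression of non-drainage terms at outlet


def _perturbation_modes(rng: np.random.Generator, n_modes: int = 3):
    """Random smooth vector potential psi; u' = curl(psi) is divergence-free."""
    k = rng.uniform(2 * np.pi / 60.0, 2 * np.pi / 25.0, size=(3, n_modes, 3))
    k *= rng.choice([-1.0, 1.0], size=k.shape)
    phase = rng.uniform(0.0, 2 * np.pi, size=(3, n_modes))
    amp = rng.uniform(0.5, 1.0, size=(3, n_modes))
    return k, phase, amp


def _curl_psi(points: np.ndarray, modes) -> np.ndarray:
    """Analytic curl of the random potential at given points (arbitrary scale)."""
    k, phase, amp = modes
    # psi_c(x) = sum_m amp[c, m] * sin(k[c, m] . x + phase[c, m])
    # d psi_c / d x_j = amp * k_j * cos(...)
    grad = np.zeros((len(points), 3, 3))  # grad[c][j] = d psi_c / d x_j
    for c in range(3):
        arg = points @ k[c].T + phase[c]          # (n, m)
        cos = np.cos(arg) * amp[c]
        grad[:, c, :] = cos @ k[c]
    curl = np.stack([
        grad[:, 2, 1] - grad[:, 1, 2],
        grad[:, 0, 2] - grad[:, 2, 0],
        grad[:, 1, 0] - grad[:, 0, 1],
    ], axis=1)
    return curl


def generate_flow(
    mesh: LabeledSurfaceMesh,
    waveforms: WaveformSet,
    seed: int = 0,
    params: FlowParams | None = None,
) -> VelocityFieldSeries:
    """Build the pulsatile velocity series for a (possibly device-bearing) atrium."""
    params = params or FlowParams()
    waveforms.validate()
    if "mv_outlet" not in mesh.labels:
        raise ConfigurationError("mesh has no 'mv_outlet' label")

    meta = mesh.metadata
    mv_center = np.asarray(mesh.points["mv_center"], dtype=float)
    ost = np.asarray(mesh.points["ostium_center"], dtype=float)
    laa_axis = np.asarray(meta["laa_axis"], dtype=float)
    laa_len = float(meta.get("laa_length", 30.0))
    r_ost = float(meta.get("ostium_radius", 10.0))
    z_mv = float(meta.get("z_mv", mv_center[2]))
    depth_dev = meta.get("device_depth", None)
    band_len = laa_len if depth_dev is None else max(float(depth_dev), 0.0)

    h = params.grid_spacing
    lo, hi = mesh.bounds()
    xs = np.arange(lo[0] - h, hi[0] + 2 * h, h)
    ys = np.arange(lo[1] - h, hi[1] + 2 * h, h)
    zs = np.arange(lo[2] - h, hi[2] + 2 * h, h)
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)

    # geometry helpers evaluated once
    rel_laa = pts - ost
    s_laa = rel_laa @ laa_axis                      # depth into the appendage, mm
    rho_vec = rel_laa - s_laa[:, None] * laa_axis
    rho = np.linalg.norm(rho_vec, axis=1)
    rho_hat = np.divide(rho_vec, np.maximum(rho, 1e-12)[:, None])
    in_laa = s_laa > 0.0
    decay = np.exp(-params.stasis * params.decay_rate
                   * np.clip(s_laa, 0.0, None) / laa_len)
    # trapped eddies persist deeper into the appendage than through-flow
    decay_swirl = np.sqrt(decay)
    scale = np.where(in_laa, decay, 1.0)

    # suppress rotational/stochastic terms near the outlet cap so the
    # imposed waveform is recovered there
    mask_mv = np.clip((pts[:, 2] - z_mv) / params.mask_width, 0.0, 1.0)

    to_mv = mv_center - pts
    e_mv = to_mv / np.maximum(np.linalg.norm(to_mv, axis=1), 1e-9)[:, None]
    # near the outlet the drainage direction blends into the uniform cap
    # normal, so interpolated speed matches the imposed waveform exactly
    e_mv = (mask_mv[:, None] * e_mv
            + (1.0 - mask_mv)[:, None] * np.array([0.0, 0.0, -1.0]))
    e_mv = e_mv / np.maximum(np.linalg.norm(e_mv, axis=1), 1e-9)[:, None]

    zhat = np.array([0.0, 0.0, 1.0])
    r_ref = float(np.max(np.abs(mesh.vertices[:, 0])))
    vort = np.cross(np.broadcast_to(zhat, pts.shape), pts) / max(r_ref, 1.0)

    swirl_dir = np.cross(np.broadcast_to(laa_axis, pts.shape), rho_hat)
    radial_prof = np.clip(rho / r_ost, 0.0, 1.2)

    # appendage inflow: only while the band proximal of the device face is
    # open (an uncovered ridge); a covering device closes it.  Upstream of
    # the mouth the inflow converges toward the ostium centre (a sink-like
    # funnel that gathers approaching clusters onto the axis); inside the
    # band it runs axially and tapers at the device face.
    inflow_profile = np.zeros(len(pts))
    inflow_dir = np.broadcast_to(laa_axis, pts.shape)
    if band_len > 0.5:
        band = s_laa < band_len
        band_taper = np.clip((band_len - s_laa) / 5.0, 0.0, 1.0) * band
        funnel_radial = np.exp(-0.5 * (rho / (1.5 * r_ost)) ** 2)
        amp = np.where(
            s_laa >= 0.0,
            np.exp(-params.stasis * np.clip(s_laa, 0.0, None) / laa_len),
            np.clip((s_laa + 18.0) / 6.0, 0.0, 1.0),  # funnel reach ~18 mm
        )
        inflow_profile = band_taper * amp * funnel_radial
        converge = ost[None, :] - pts
        converge = converge / np.maximum(np.linalg.norm(converge, axis=1, keepdims=True), 1e-9)
        w_ax = np.clip(s_laa / 3.0 + 1.0, 0.0, 1.0)  # axial once past the mouth
        inflow_dir = w_ax[:, None] * laa_axis[None, :] + (1.0 - w_ax)[:, None] * converge
        inflow_dir = inflow_dir / np.maximum(
            np.linalg.norm(inflow_dir, axis=1, keepdims=True), 1e-9)

    rng = np.random.default_rng(seed)
    modes = _perturbation_modes(rng)
    pert = _curl_psi(pts, modes)
    pmax = np.max(np.linalg.norm(pert, axis=1))
    if pmax > 0:
        pert = pert / pmax

    g = np.concatenate([waveforms.mv_velocity] * waveforms.n_beats)
    g_peak = max(waveforms.mv_peak(), 1e-12)
    times = waveforms.all_times()

    # pulmonary-ridge jet: the LSPV inflow sweeps across the appendage
    # mouth.  With an open band (uncovered ridge) it turns into the
    # appendage; with a covering device it deflects tangentially toward the
    # outlet, washing the device face instead of impinging on it.  The
    # drainage term is damped inside the jet core so the jet sets the local
    # streamline direction.
    pv_frames = meta.get("pv_frames", [])
    jet_gauss = np.zeros(len(pts))
    jet_term = np.zeros((len(pts), 3))
    if pv_frames:
        p0 = np.asarray(pv_frames[0]["origin"], dtype=float)
        m0 = ost - 4.0 * laa_axis
        seg = m0 - p0
        seg_len = np.linalg.norm(seg)
        t_hat = seg / max(seg_len, 1e-9)
        w_seg = np.clip(((pts - p0) @ t_hat) / seg_len, 0.0, 1.0)
        rho_seg = np.linalg.norm(pts - (p0 + w_seg[:, None] * seg), axis=1)
        jet_gauss = np.exp(-0.5 * (rho_seg / params.ridge_jet_width) ** 2)
        if band_len > 0.5:
            # open mouth: the jet hands over to the converging funnel
            eta = np.clip((s_laa + 20.0) / 12.0, 0.0, 1.0)
            d_target = ost[None, :] - pts
            d_target = d_target / np.maximum(
                np.linalg.norm(d_target, axis=1, keepdims=True), 1e-9)
            near_mouth = np.linalg.norm(pts - ost, axis=1) < 3.0
            d_target = np.where(near_mouth[:, None], laa_axis[None, :], d_target)
            jet_amp = jet_gauss * np.where(s_laa > 0.0, np.exp(-s_laa / 8.0), 1.0)
        else:
            # closed mouth: deflect early toward the outlet and decelerate in
            # the stagnation zone ahead of the device face, so clusters wash
            # across it instead of impacting
            eta = np.clip((s_laa + 20.0) / 12.0, 0.0, 1.0)
            d_target = (mv_center - pts)
            d_target = d_target / np.maximum(
                np.linalg.norm(d_target, axis=1, keepdims=True), 1e-9)
            jet_amp = jet_gauss * np.clip(-s_laa / 12.0, 0.0, 1.0)
        jet_dir = (1.0 - eta)[:, None] * t_hat + eta[:, None] * d_target
        jet_dir = jet_dir / np.maximum(np.linalg.norm(jet_dir, axis=1, keepdims=True), 1e-9)
        jet_term = params.ridge_jet * jet_dir * jet_amp[:, None]

    shape = (len(times), len(xs), len(ys), len(zs), 3)
    values = np.empty(shape)
    # with a covering device the mouth is washed by drainage (only mildly
    # damped); an open mouth hands the core over to the jet/funnel
    damp_coef = 0.75 if band_len > 0.5 else 0.4
    drain_damp = 1.0 - damp_coef * np.maximum(jet_gauss, inflow_profile)
    base_static = (
        e_mv * (scale * drain_damp)[:, None]
        + params.vortex_strength * vort * (scale * mask_mv)[:, None]
        + params.laa_radial * rho_hat * (in_laa * decay * mask_mv)[:, None]
        + params.laa_inflow * inflow_dir * (inflow_profile * mask_mv)[:, None]
        + jet_term * mask_mv[:, None]
    )

    # inside the PV tubes the flow is axial (inward), so injected clusters
    # ride the tube into the chamber instead of being pushed into its wall
    for fr in meta.get("pv_frames", []):
        o = np.asarray(fr["origin"], dtype=float)
        u_t = np.asarray(fr["dir"], dtype=float)
        rel_t = pts - o
        s_t = rel_t @ u_t
        rho_t = np.linalg.norm(rel_t - s_t[:, None] * u_t, axis=1)
        w = (np.clip((fr["radius"] + 1.0 - rho_t) / 2.0, 0.0, 1.0)
             * np.clip((s_t - 1.0) / 3.0, 0.0, 1.0)
             * np.clip((fr["length"] + 2.0 - s_t) / 2.0 + 1.0, 0.0, 1.0))
        w = np.clip(w, 0.0, 1.0)
        base_static = (1.0 - w)[:, None] * base_static + w[:, None] * (-u_t)[None, :]
    # the stochastic term, like every other term, scales with the waveform,
    # peaking at perturbation_amplitude * g_peak
    base_static = base_static + params.perturbation_amplitude * pert * mask_mv[:, None]
    # the intra-appendage swirl reverses between filling and emptying, so
    # slow appendage eddies register as direction-incoherent (recirculating)
    swirl_static = (params.laa_swirl * swirl_dir
                    * (in_laa * decay_swirl * radial_prof * mask_mv)[:, None])
    grid_shape = (len(xs), len(ys), len(zs), 3)
    t_rel = np.mod(times, waveforms.beat_period)
    swirl_env = g_peak * np.sin(2.0 * np.pi * t_rel / waveforms.beat_period)
    for i in range(len(times)):
        values[i] = (g[i] * base_static + swirl_env[i] * swirl_static).reshape(grid_shape)

    series = VelocityFieldSeries(
        times=times,
        axes=(xs, ys, zs),
        values=values,
        beat_period=waveforms.beat_period,
        steps_per_beat=waveforms.steps_per_beat,
        metadata={"seed": seed, "params": params.__dict__.copy(),
                  "device_depth": depth_dev,
                  "perturbation_amplitude_ms": params.perturbation_amplitude * g_peak},
    )
    return series


# ---------------------------------------------------------------------- WSS


@dataclass
class WSSeries:
    """Per-surface-element wall-shear-stress vectors over one analysis beat.

    ``tau`` has shape (n_steps, n_elements, 3) in Pa; vectors are tangent to
    the surface.  ``face_areas`` (mm^2) support area-weighted statistics.
    """

    element_ids: np.ndarray
    tau: np.ndarray
    times: np.ndarray
    dt: float
    face_areas: np.ndarray
    beat_period: float = 0.88

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.tau, axis=2)


def generate_wss(
    series: VelocityFieldSeries,
    mesh: LabeledSurfaceMesh,
    labels: tuple[str, ...] = ("device",),
    mu: float = 0.0035,
    offset_mm: float = 0.5,
    beat_index: int = 1,
) -> WSSeries:
    """Newtonian wall shear stress on labeled wall faces over one beat.

    tau = mu * u_t / h with u_t the tangential velocity one offset length
    off the wall along the inward normal; by construction tau . n = 0.
    """
    faces = np.concatenate([mesh.label_faces(lb) for lb in labels])
    cent = mesh.vertices[mesh.faces[faces]].mean(axis=1)
    normals_all = mesh.face_normals()
    normals = normals_all[faces]
    areas = mesh.face_areas()[faces]

    # inward = toward the fluid; marching-cubes normals point outward from
    # the solid body for the atrium and outward from the device for devices,
    # so probe both sides and keep the one inside the field support
    probe_out = cent + offset_mm * normals
    probe_in = cent - offset_mm * normals
    use_out = series.inside(probe_out)
    probes = np.where(use_out[:, None], probe_out, probe_in)
    if not series.inside(probes).all():
        raise ConsistencyError("wall probes fall outside the velocity-field support")

    from .flowfield import PhaseWindow

    steps = series.beat_steps(PhaseWindow.full_cycle(), beat_index)
    tau = np.empty((len(steps), len(faces), 3))
    h_m = offset_mm * 1e-3
    for row, s in enumerate(steps):
        u = series.sample_batch(probes, float(series.times[s]), with_grad=False)
        u_t = u - (np.einsum("ij,ij->i", u, normals))[:, None] * normals
        tau[row] = mu * u_t / h_m
    return WSSeries(
        element_ids=faces,
        tau=tau,
        times=series.times[steps],
        dt=series.dt,
        face_areas=areas,
        beat_period=series.beat_period,
    )
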