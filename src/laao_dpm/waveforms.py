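"""Beat waveforms driving the synthetic pulsatile flow.

One cardiac cycle lasts 0.88 s sampled at 88 steps (dt = 0.01 s): systole
occupies t = 0-0.3 s, diastole t = 0.31-0.88 s.  The mitral-valve (outlet)
velocity profile carries the transmitral E-wave (early filling) and A-wave
(atrial kick) peaks typical of a Doppler trace; the pulmonary-vein pressure
profile is a smooth systolic/diastolic modulation around a mean atrial
pressure.  Neither profile is tabulated anywhere as patient data -- the
shapes here are documented defaults with the stated period and phase
structure, not a claim of fidelity to any individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["WaveformSet", "default_waveforms"]

BEAT_PERIOD_S = 0.88
STEPS_PER_BEAT = 88
DT_S = 0.01
SYSTOLE_END_S = 0.30


@dataclass
class WaveformSet:
    """Sampled one-beat boundary profiles.

    ``mv_velocity`` (m/s) is imposed at the mitral outlet; ``pv_pressure``
    (mmHg) is carried for completeness (the synthetic flow generator is
    velocity-driven).  Sample ``i`` corresponds to time ``(i + 1) * dt`` so
    the final sample sits at end-diastole t = 0.88 s.
    """

    beat_period: float = BEAT_PERIOD_S
    steps_per_beat: int = STEPS_PER_BEAT
    dt: float = DT_S
    pv_pressure: np.ndarray = field(default=None)  # type: ignore[assignment]
    mv_velocity: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_beats: int = 2

    def __post_init__(self) -> None:
        if self.pv_pressure is None or self.mv_velocity is None:
            t = self.sample_times()
            if self.pv_pressure is None:
                self.pv_pressure = _default_pv_pressure(t, self.beat_period)
            if self.mv_velocity is None:
                self.mv_velocity = _default_mv_velocity(t, self.beat_period)
        self.pv_pressure = np.asarray(self.pv_pressure, dtype=float)
        self.mv_velocity = np.asarray(self.mv_velocity, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.steps_per_beat <= 0:
            raise ValidationError("steps_per_beat must be positive")
        if abs(self.steps_per_beat * self.dt - self.beat_period) > 1e-9:
            raise ValidationError(
                "steps_per_beat * dt must equal beat_period "
                f"({self.steps_per_beat} * {self.dt} != {self.beat_period})"
            )
        for name in ("pv_pressure", "mv_velocity"):
            arr = getattr(self, name)
            if arr.shape != (self.steps_per_beat,):
                raise ValidationError(f"{name} must have steps_per_beat samples")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite samples")
        if self.n_beats < 1:
            raise ValidationError("n_beats must be >= 1")
        if float(self.mv_velocity.sum()) * self.dt < 0:
            raise ValidationError("mv_velocity must integrate to positive net outflow")

    def sample_times(self, beat: int = 0) -> np.ndarray:
        """Times of the stored samples for a given beat (absolute seconds)."""
        return beat * self.beat_period + self.dt * np.arange(1, self.steps_per_beat + 1)

    def all_times(self) -> np.ndarray:
        return np.concatenate([self.sample_times(b) for b in range(self.n_beats)])

    def mv_peak(self) -> float:
        return float(np.max(np.abs(self.mv_velocity)))


def _default_mv_velocity(t: np.ndarray, period: float) -> np.ndarray:
    """E/A-wave transmitral profile: quiet systole, E peak ~0.65 m/s, A ~0.45 m/s."""
    e = 0.65 * np.exp(-0.5 * ((t - 0.45) / 0.055) ** 2)
    a = 0.45 * np.exp(-0.5 * ((t - 0.76) / 0.045) ** 2)
    base = 0.06 * np.sin(np.pi * t / period) ** 2
    return e + a + base


def _default_pv_pressure(t: np.ndarray, period: float) -> np.ndarray:
    """Atrial-like pressure around 10 mmHg with systolic s-wave and diastolic decay."""
    s = 4.0 * np.exp(-0.5 * ((t - 0.18) / 0.08) ** 2)
    v = 2.0 * np.exp(-0.5 * ((t - 0.42) / 0.07) ** 2)
    return 10.0 + s - v + 0.5 * np.cos(2 * np.pi * t / period)


def default_waveforms(n_beats: int = 2) -> WaveformSet:
    """The default study conditions: 0.88 s beat, 88 steps, two beats."""
    return WaveformSet(n_beats=n_beats)
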