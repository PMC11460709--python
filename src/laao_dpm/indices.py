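"""Wall-shear-stress thrombogenicity indices: TAWSS, OSI, ECAP.

Computed per surface element from the shear-vector series of one analysis
beat (the second simulated beat, like the velocity statistics):

* TAWSS  — time-averaged magnitude of the wall shear stress,
  ``(1/T) * sum |tau(t_i)| dt``  (Pa);
* OSI    — oscillatory shear index,
  ``0.5 * (1 - |sum tau dt| / sum |tau| dt)``, 0 for unidirectional shear
  up to 0.5 for fully reversing shear (vector-accumulation form);
* ECAP   — endothelial cell activation potential, the ratio OSI / TAWSS
  (1/Pa); high where shear is weak and oscillatory, i.e. on stagnant,
  flow-reversing wall patches prone to thrombus.

Elements with vanishing TAWSS have undefined ECAP; they are flagged,
excluded from the summary means, and counted in the metadata.  Regional
summaries are area-weighted (shear is an element field).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoverageError
from .flowgen import WSSeries

__all__ = ["SurfaceIndexMap", "tawss", "osi", "ecap", "classify_thresholds",
           "RegionSummary"]

ECAP_TAWSS_FLOOR = 1e-9  # Pa, below which ECAP is undefined


def _check_coverage(series: WSSeries) -> None:
    span = len(series.times) * series.dt
    if span < series.beat_period - 1e-9:
        raise CoverageError(
            f"shear series spans {span:.3f} s < one beat ({series.beat_period} s)"
        )


def tawss(series: WSSeries) -> np.ndarray:
    """Time-averaged wall-shear-stress magnitude per element (Pa)."""
    _check_coverage(series)
    mags = series.magnitudes()
    return mags.sum(axis=0) * series.dt / (len(series.times) * series.dt)


def osi(series: WSSeries) -> np.ndarray:
    """Oscillatory shear index per element, in [0, 0.5].

    Defined as 0 (unidirectional) where the accumulated shear magnitude
    vanishes.
    """
    _check_coverage(series)
    num = np.linalg.norm(series.tau.sum(axis=0) * series.dt, axis=1)
    den = series.magnitudes().sum(axis=0) * series.dt
    out = np.zeros(series.tau.shape[1])
    nz = den > 0
    out[nz] = 0.5 * (1.0 - num[nz] / den[nz])
    return np.clip(out, 0.0, 0.5)


def ecap(series: WSSeries, tawss_floor: float = ECAP_TAWSS_FLOOR):
    """ECAP = OSI / TAWSS per element (1/Pa) with undefined-element mask."""
    t = tawss(series)
    o = osi(series)
    defined = t > tawss_floor
    e = np.full_like(t, np.nan)
    e[defined] = o[defined] / t[defined]
    return e, defined


@dataclass
class RegionSummary:
    """Area-weighted max / mean +- sd of one index over a surface region."""

    maximum: float
    mean: float
    sd: float
    n_elements: int
    n_undefined: int = 0


@dataclass
class SurfaceIndexMap:
    """Per-element index maps for one surface region, with summaries."""

    element_ids: np.ndarray
    face_areas: np.ndarray
    tawss: np.ndarray
    osi: np.ndarray
    ecap: np.ndarray          # NaN where undefined
    ecap_defined: np.ndarray  # bool mask
    summaries: dict[str, RegionSummary] = field(default_factory=dict)

    @classmethod
    def from_series(cls, series: WSSeries) -> "SurfaceIndexMap":
        t = tawss(series)
        o = osi(series)
        e, defined = ecap(series)
        m = cls(element_ids=series.element_ids, face_areas=series.face_areas,
                tawss=t, osi=o, ecap=e, ecap_defined=defined)
        for name, vals, mask in (("tawss", t, np.ones_like(defined)),
                                 ("osi", o, np.ones_like(defined)),
                                 ("ecap", e, defined)):
            m.summaries[name] = m._summarize(vals, mask)
        return m

    def _summarize(self, values: np.ndarray, mask: np.ndarray) -> RegionSummary:
        v = values[mask]
        w = self.face_areas[mask]
        if len(v) == 0:
            return RegionSummary(np.nan, np.nan, np.nan, 0,
                                 int((~mask).sum()))
        mean = float(np.average(v, weights=w))
        var = float(np.average((v - mean) ** 2, weights=w))
        return RegionSummary(maximum=float(v.max()), mean=mean, sd=float(np.sqrt(var)),
                             n_elements=int(mask.sum()), n_undefined=int((~mask).sum()))


def classify_thresholds(
    index_map: SurfaceIndexMap,
    velocity_summary: tuple[float, float] | None = None,
    velocity_threshold_ms: float = 0.2,
    ecap_threshold: float = 0.5,
) -> dict[str, bool]:
    """Binary DRT-risk descriptors from the index map and velocity summary.

    ``low_velocity`` is strict: full-cycle mean < 0.2 m/s (a mean of exactly
    0.2 does not flag).  ``high_ecap`` uses the regional ECAP maximum
    (strictly > 0.5 1/Pa); the mean-based flag is reported alongside.
    """
    out: dict[str, bool] = {}
    if velocity_summary is not None:
        out["low_velocity"] = bool(velocity_summary[0] < velocity_threshold_ms)
    s = index_map.summaries.get("ecap")
    if s is not None and s.n_elements > 0:
        out["high_ecap"] = bool(s.maximum > ecap_threshold)
        out["high_mean_ecap"] = bool(s.mean > ecap_threshold)
    else:
        out["high_ecap"] = False
        out["high_mean_ecap"] = False
    return out
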