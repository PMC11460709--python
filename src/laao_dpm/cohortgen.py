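"""Synthetic cohort fixtures with the statistical structure of the study.

Draws per-patient records (LA/LAA volumes, ostium geometry, device type and
size, ridge-coverage flag, outcome label) from truncated normal
distributions whose group means and spreads mirror the reference cohort:
control LA volume 163.6 +- 39 mL vs 177.1 +- 58 mL for the DRT stratum, LAA
volumes 12.75 +- 4.6 vs 15.29 +- 6.29 mL, a plug/pacifier split of 6/4 in
controls and 4/6 in the DRT group, and roughly two-thirds of DRT patients
with an uncovered pulmonary ridge.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .report import ConfigRecord

__all__ = ["CohortEffectSpec", "generate_cohort_fixture"]


@dataclass
class GroupDists:
    la_volume: tuple[float, float]
    laa_volume: tuple[float, float]
    ostium_area: tuple[float, float]
    ostium_perimeter: tuple[float, float]
    p_plug: float
    p_uncovered: float


@dataclass
class CohortEffectSpec:
    """Group-level distributions of the synthetic cohort."""

    control: GroupDists = field(default_factory=lambda: GroupDists(
        la_volume=(163.6, 39.0), laa_volume=(12.75, 4.6),
        ostium_area=(579.2, 120.0), ostium_perimeter=(39.7, 4.2),
        p_plug=0.6, p_uncovered=0.5))
    drt: GroupDists = field(default_factory=lambda: GroupDists(
        la_volume=(177.1, 58.0), laa_volume=(15.29, 6.29),
        ostium_area=(717.3, 290.0), ostium_perimeter=(42.8, 9.6),
        p_plug=0.4, p_uncovered=0.65))
    sizes_mm: tuple[float, ...] = (16, 20, 22, 24, 25, 27, 28, 30, 33)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal draws truncated at zero by resampling."""
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def generate_cohort_fixture(
    n_control: int,
    n_drt: int,
    effect_spec: CohortEffectSpec | None = None,
    seed: int = 0,
) -> list[ConfigRecord]:
    """Draw a synthetic cohort of post-LAAO configuration records."""
    if n_control < 0 or n_drt < 0:
        raise ValidationError("n_control and n_drt must be non-negative")
    spec = effect_spec or CohortEffectSpec()
    rng = np.random.default_rng(seed)
    records: list[ConfigRecord] = []
    pid = 0
    for outcome, n, dists in (("control", n_control, spec.control),
                              ("DRT", n_drt, spec.drt)):
        if n == 0:
            continue
        la = _trunc_normal(rng, *dists.la_volume, n)
        laa = _trunc_normal(rng, *dists.laa_volume, n)
        area = _trunc_normal(rng, *dists.ostium_area, n)
        # perimeter must respect the isoperimetric bound of its area
        perim = np.maximum(_trunc_normal(rng, *dists.ostium_perimeter, n),
                           np.sqrt(4.0 * np.pi * area) * (1.0 + 1e-6))
        is_plug = rng.random(n) < dists.p_plug
        uncovered = rng.random(n) < dists.p_uncovered
        sizes = rng.choice(spec.sizes_mm, size=n)
        for i in range(n):
            records.append(ConfigRecord(
                patient=pid,
                outcome=outcome,
                config="post_laao",
                device_type="plug" if is_plug[i] else "pacifier",
                device_size=float(sizes[i]),
                la_volume=float(la[i]),
                laa_volume=float(laa[i]),
                ostium_area=float(area[i]),
                ostium_perimeter=float(perim[i]),
                pr_covered=not bool(uncovered[i]),
            ))
            pid += 1
    return records
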