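#!/usr/bin/env python
"""Simulate both device configurations end to end.

Runs the full synthetic study for the deep (ridge-uncovering) and proximal
(ridge-covering) poses: pulsatile flow over two beats, phase-resolved
device-surface velocity statistics, the recirculation score, TAWSS/OSI/ECAP
on the device surface, and the two-beat platelet-cluster episode.  Writes
the per-configuration records and risk rows to results/.
"""

from pathlib import Path

from laao_dpm.report import run_pipeline

RESULTS = Path(__file__).resolve().parents[1] / "results"

CONFIG = {
    "seed": 1,
    "atrium": {"mesh_edge_length": 1.5, "laa_taper_ratio": 1.0},
    "device": {"device_type": "plug", "size": 19.0, "lobe_length": 12.0},
    "flow": {"grid_spacing": 3.0},
    "transport": {"facet_stride": 4, "vol_la_ml": 160.0},
    "configurations": [{"name": "uncovered", "depth": 12.0},
                       {"name": "covered", "depth": 0.0}],
}


def main() -> None:
    res = run_pipeline(CONFIG, out_dir=RESULTS)
    for r in res.records:
        row = res.risk_rows[r.config]
        flags = [n for n, v in (("low-velocity", row.low_avg_velocity),
                                ("recirculation", row.recirculation),
                                ("high-ECAP", row.high_ecap),
                                ("high-adhesion", row.high_platelet_adhesion)) if v]
        print(f"{r.config:>9}: cycle {r.vel_cycle[0]:.3f}±{r.vel_cycle[1]:.3f} m/s, "
              f"max ECAP {r.max_ecap:.2f} 1/Pa, adhesion {r.pct_attached:.1f}%  "
              f"-> flags: {', '.join(flags) or 'none'}")
    cov = {r.config: r for r in res.records}
    dv = cov["covered"].vel_cycle[0] - cov["uncovered"].vel_cycle[0]
    da = cov["uncovered"].pct_attached - cov["covered"].pct_attached
    print(f"covering the ridge raises the device-surface cycle velocity by "
          f"{dv:.3f} m/s and lowers adhesion by {da:.1f} percentage points")


if __name__ == "__main__":
    main()
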