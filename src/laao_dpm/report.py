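"""Per-configuration records, risk descriptors, cohort statistics, and the
end-to-end synthetic pipeline driver.

A configuration is one device pose in one atrium.  Its record collects the
anatomical measurements, the phase-resolved device-surface velocities, the
ECAP summary, and the particle-adhesion percentage; the four binary DRT
risk descriptors follow from the study thresholds:

* low average velocity     — full-cycle mean < 0.2 m/s (strict),
* re-circulation           — the recirculation flag of the device region,
* high ECAP                — regional maximum ECAP > 0.5 1/Pa (strict),
* high platelet adhesion   — adhered clusters > 10 % of injected (strict).

Concordance scores how many descriptors agree with the clinical outcome:
for a DRT patient a descriptor agrees when it raises, for a control when it
does not.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "Thresholds",
    "ConfigRecord",
    "RiskRow",
    "GroupSummary",
    "build_risk_table",
    "risk_row_from_record",
    "cohort_summary",
    "threshold_counts",
    "concordance",
    "run_pipeline",
]


@dataclass
class Thresholds:
    velocity_ms: float = 0.2
    ecap_pa_inv: float = 0.5
    adhesion_pct: float = 10.0
    pr_distance_mm: float = 10.0


@dataclass
class ConfigRecord:
    """Metrics of one device configuration (units: mL, mm, m/s, 1/Pa, %)."""

    patient: int | str
    outcome: str | None = None          # "control" | "DRT" | None (synthetic)
    config: str = "post_laao"           # "post_laao" | "pr_covered"
    device_type: str | None = None
    device_size: float | None = None
    la_volume: float | None = None
    laa_volume: float | None = None
    ostium_area: float | None = None
    ostium_perimeter: float | None = None
    vel_systole: tuple[float, float] | None = None
    vel_diastole: tuple[float, float] | None = None
    vel_cycle: tuple[float, float] | None = None
    max_ecap: float | None = None
    mean_ecap: tuple[float, float] | None = None
    pct_attached: float | None = None
    recirculation_score: float | None = None
    recirculation: bool | None = None
    pr_covered: bool | None = None
    pr_distance_mm: float | None = None


@dataclass
class RiskRow:
    """The four binary DRT descriptors of one configuration."""

    low_avg_velocity: bool
    recirculation: bool
    high_ecap: bool
    high_platelet_adhesion: bool

    def as_tuple(self) -> tuple[bool, bool, bool, bool]:
        return (self.low_avg_velocity, self.recirculation, self.high_ecap,
                self.high_platelet_adhesion)


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float            # sample sd (ddof=1); NaN for n == 1
    n_missing: int = 0


def risk_row_from_record(record: ConfigRecord,
                         thresholds: Thresholds | None = None) -> RiskRow:
    """Derive the four descriptors; raises naming any missing metric."""
    th = thresholds or Thresholds()
    missing = [name for name, value in [
        ("vel_cycle", record.vel_cycle),
        ("max_ecap", record.max_ecap),
        ("pct_attached", record.pct_attached),
        ("recirculation", record.recirculation),
    ] if value is None]
    if missing:
        raise ValidationError(
            f"record for patient {record.patient!r} ({record.config}) lacks "
            f"metrics: {', '.join(missing)}")
    return RiskRow(
        low_avg_velocity=record.vel_cycle[0] < th.velocity_ms,
        recirculation=bool(record.recirculation),
        high_ecap=record.max_ecap > th.ecap_pa_inv,
        high_platelet_adhesion=record.pct_attached > th.adhesion_pct,
    )


def build_risk_table(records: Iterable[ConfigRecord],
                     thresholds: Thresholds | None = None) -> list[RiskRow]:
    return [risk_row_from_record(r, thresholds) for r in records]


def records_to_frame(records: Iterable[ConfigRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        for key in ("vel_systole", "vel_diastole", "vel_cycle", "mean_ecap"):
            pair = d.pop(key)
            d[f"{key}_mean"], d[f"{key}_sd"] = (pair if pair is not None
                                                else (np.nan, np.nan))
        rows.append(d)
    return pd.DataFrame(rows)


def cohort_summary(records: Iterable[ConfigRecord] | pd.DataFrame, metric: str,
                   group_by: str = "outcome") -> list[GroupSummary]:
    """Per-group arithmetic mean and sample SD of one metric.

    Missing entries are excluded and counted; empty groups are dropped with
    a warning; a single-record group reports SD = NaN (flagged by n = 1).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    out: list[GroupSummary] = []
    for group, sub in df.groupby(group_by, dropna=False):
        vals = sub[metric].astype(float)
        ok = vals.dropna()
        if len(ok) == 0:
            warnings.warn(f"group {group!r} has no values for {metric!r}; omitted")
            continue
        out.append(GroupSummary(group=str(group), n=int(len(ok)),
                                mean=float(ok.mean()),
                                sd=float(ok.std(ddof=1)) if len(ok) > 1 else float("nan"),
                                n_missing=int(vals.isna().sum())))
    return out


def threshold_counts(records: Iterable[ConfigRecord] | pd.DataFrame,
                     predicate: Callable) -> int:
    """Count records (or frame rows) satisfying a predicate."""
    if isinstance(records, pd.DataFrame):
        return int(sum(bool(predicate(row)) for _, row in records.iterrows()))
    return int(sum(bool(predicate(r)) for r in records))


def concordance(risk_rows: dict, outcomes: dict) -> dict:
    """Descriptor-outcome agreement per patient plus cohort tallies.

    ``risk_rows`` maps patient id to its post-LAAO RiskRow, ``outcomes`` to
    "control"/"DRT".  Returns per-patient agreement counts (0-4) and the
    number of patients with 4/4 and >= 3/4 agreement; order-invariant.
    """
    per_patient: dict = {}
    for pid, row in risk_rows.items():
        if pid not in outcomes:
            raise ValidationError(f"missing outcome for patient {pid!r}")
        expect = outcomes[pid] == "DRT"
        per_patient[pid] = sum(1 for v in row.as_tuple() if v == expect)
    tallies = {
        "complete": sum(1 for v in per_patient.values() if v == 4),
        "at_least_three": sum(1 for v in per_patient.values() if v >= 3),
    }
    return {"per_patient": per_patient, "tallies": tallies}


# --------------------------------------------------------------------- pipeline


@dataclass
class PipelineResult:
    records: list[ConfigRecord]
    risk_rows: dict[str, RiskRow]
    log: dict
    summaries: dict = field(default_factory=dict)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        if str(config).endswith((".yaml", ".yml")):
            import yaml

            return yaml.safe_load(text)
        return json.loads(text)
    return dict(config)


def run_pipeline(config, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic study for every configuration in a config.

    The config (dict, JSON or YAML path) names an atrium spec, a device, the
    flow/transport settings, and a list of configurations ``{name, depth}``.
    Every threshold and seed used is echoed in the result log.  Outputs are
    serialized under ``out_dir`` when given (records CSV, risk rows and log
    JSON).
    """
    from .atrium import IdealizedAtriumSpec, generate_atrium
    from .devices import DeviceSpec, build_device, place_device, ostium_metrics, pr_coverage
    from .flowfield import PhaseWindow, device_region, phase_average_speed, recirculation_index
    from .flowgen import FlowParams, generate_flow, generate_wss
    from .indices import SurfaceIndexMap
    from .transport import (TransportOptions, inlet_facets, plan_injection,
                            run_transport)
    from .waveforms import WaveformSet

    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    th = Thresholds(**cfg.get("thresholds", {}))
    configurations = cfg.get("configurations", [])
    if not configurations:
        warnings.warn("empty configuration list; nothing to simulate")
        return PipelineResult([], {}, {"seed": seed, "thresholds": asdict(th)})

    atrium_kwargs = dict(cfg.get("atrium", {}))
    device_kwargs = dict(cfg.get("device", {"device_type": "plug", "size": 19.0,
                                            "lobe_length": 12.0}))
    flow_params = FlowParams(**cfg.get("flow", {}))
    wf = WaveformSet(**cfg.get("waveforms", {}))
    transport_cfg = dict(cfg.get("transport", {}))
    stride = int(transport_cfg.get("facet_stride", 4))
    vol_la = float(transport_cfg.get("vol_la_ml", 160.0))

    records: list[ConfigRecord] = []
    risk_rows: dict[str, RiskRow] = {}
    for entry in configurations:
        name = entry["name"]
        depth = float(entry["depth"])
        spec = IdealizedAtriumSpec(**{**atrium_kwargs, "device_depth": depth,
                                      "seed": seed})
        mesh = generate_atrium(spec)
        device = build_device(DeviceSpec(**device_kwargs))
        placed = place_device(device, mesh, depth=depth)
        full = mesh.merged_with(placed, prefix="device_")

        om = ostium_metrics(mesh.polylines["ostium_contour"])
        cov = pr_coverage(mesh, placed, threshold_mm=th.pr_distance_mm)

        series = generate_flow(mesh, wf, seed=seed, params=flow_params)
        region = device_region(mesh, placed, band_spacing=2.0)
        vel = {w.name: phase_average_speed(series, region, w)
               for w in (PhaseWindow.systole(), PhaseWindow.diastole(),
                         PhaseWindow.full_cycle())}
        score, flag = recirculation_index(series, region, PhaseWindow.full_cycle(),
                                          low_speed_ms=th.velocity_ms)

        device_labels = tuple(k for k in full.labels if k.startswith("device_"))
        wss = generate_wss(series, full, labels=device_labels)
        imap = SurfaceIndexMap.from_series(wss)

        facets = inlet_facets(full, stride=stride)
        plan = plan_injection(2e8, vol_la, len(facets[0]), 10, wf.dt)
        summary = run_transport(series, full, plan, seed=seed,
                                options=TransportOptions(facet_stride=stride))

        rec = ConfigRecord(
            patient="synthetic",
            outcome=None,
            config=name,
            device_type=device_kwargs["device_type"],
            device_size=float(device_kwargs["size"]),
            la_volume=vol_la,
            laa_volume=None,
            ostium_area=om.area,
            ostium_perimeter=om.perimeter,
            vel_systole=vel["systole"],
            vel_diastole=vel["diastole"],
            vel_cycle=vel["full_cycle"],
            max_ecap=imap.summaries["ecap"].maximum,
            mean_ecap=(imap.summaries["ecap"].mean, imap.summaries["ecap"].sd),
            pct_attached=summary.pct_attached,
            recirculation_score=score,
            recirculation=flag,
            pr_covered=cov.covered,
            pr_distance_mm=cov.min_distance_to_device,
        )
        records.append(rec)
        risk_rows[name] = risk_row_from_record(rec, th)

    log = {"seed": seed, "thresholds": asdict(th),
           "flow_params": asdict(flow_params),
           "facet_stride": stride, "vol_la_ml": vol_la,
           "configurations": configurations}
    result = PipelineResult(records=records, risk_rows=risk_rows, log=log)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records_to_frame(records).to_csv(out / "config_records.csv", index=False)
        (out / "risk_rows.json").write_text(json.dumps(
            {k: asdict(v) for k, v in risk_rows.items()}, indent=1))
        (out / "pipeline_log.json").write_text(json.dumps(log, indent=1))
    return result
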