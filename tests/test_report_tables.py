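"""Cohort tables, risk rows, group statistics, concordance, fixtures."""

import numpy as np
import pandas as pd
import pytest

from laao_dpm import tables
from laao_dpm.cohortgen import generate_cohort_fixture
from laao_dpm.errors import ValidationError
from laao_dpm.report import (
    ConfigRecord,
    RiskRow,
    build_risk_table,
    cohort_summary,
    concordance,
    records_to_frame,
    risk_row_from_record,
    threshold_counts,
)

# Control-group LA volumes as printed, for the hand-computed oracle
CONTROL_LA_ML = [171, 181, 216, 94, 179, 196, 158, 127, 214, 100]


def table_risk_rows(config: str = "post"):
    risk = tables.load_risk_descriptors()
    rows, outcomes = {}, {}
    for r in risk.itertuples():
        rows[int(r.patient)] = RiskRow(
            getattr(r, f"low_vel_{config}") == "YES",
            getattr(r, f"recirc_{config}") == "YES",
            getattr(r, f"ecap_{config}") == "YES",
            getattr(r, f"adhesion_{config}") == "YES",
        )
        outcomes[int(r.patient)] = r.outcome
    return rows, outcomes


# ----------------------------------------------------------------- risk rows


def test_risk_row_from_low_velocity_high_ecap_record():
    """Cycle mean 0.10 m/s and max ECAP 1.42 1/Pa flag both descriptors."""
    rec = ConfigRecord(patient=9, vel_cycle=(0.10, 0.09), max_ecap=1.42,
                       pct_attached=2.0, recirculation=True)
    row = risk_row_from_record(rec)
    assert row.low_avg_velocity and row.high_ecap
    assert not row.high_platelet_adhesion


def test_risk_row_all_benign():
    rec = ConfigRecord(patient=0, vel_cycle=(0.3, 0.1), max_ecap=0.2,
                       pct_attached=2.0, recirculation=False)
    assert risk_row_from_record(rec).as_tuple() == (False, False, False, False)


def test_risk_row_strict_thresholds_at_boundaries():
    rec = ConfigRecord(patient=0, vel_cycle=(0.2, 0.0), max_ecap=0.5,
                       pct_attached=10.0, recirculation=False)
    row = risk_row_from_record(rec)
    assert row.as_tuple() == (False, False, False, False)


def test_risk_row_missing_metric_lists_fields():
    rec = ConfigRecord(patient=3, vel_cycle=(0.1, 0.1))
    with pytest.raises(ValidationError, match="max_ecap"):
        risk_row_from_record(rec)


def test_build_risk_table_idempotent():
    recs = [ConfigRecord(patient=i, vel_cycle=(0.1, 0.1), max_ecap=1.0,
                         pct_attached=20.0, recirculation=True) for i in range(3)]
    assert build_risk_table(recs) == build_risk_table(recs)


# ------------------------------------------------------------ group summaries


def test_cohort_summary_reproduces_hand_arithmetic():
    recs = [ConfigRecord(patient=i, outcome="control", la_volume=v)
            for i, v in enumerate(CONTROL_LA_ML)]
    (s,) = cohort_summary(recs, "la_volume")
    assert s.mean == pytest.approx(np.mean(CONTROL_LA_ML))
    assert s.mean == pytest.approx(163.6)
    assert s.sd == pytest.approx(np.std(CONTROL_LA_ML, ddof=1))
    assert s.n == 10


def test_cohort_summary_single_record_group_flagged():
    recs = [ConfigRecord(patient=0, outcome="DRT", la_volume=100.0)]
    (s,) = cohort_summary(recs, "la_volume")
    assert s.n == 1 and np.isnan(s.sd)


def test_cohort_summary_counts_missing():
    recs = [ConfigRecord(patient=0, outcome="control", la_volume=100.0),
            ConfigRecord(patient=1, outcome="control", la_volume=None)]
    (s,) = cohort_summary(recs, "la_volume")
    assert s.n == 1 and s.n_missing == 1


# --------------------------------------------------------------- concordance


def test_concordance_trivial_rows():
    rows = {"a": RiskRow(True, True, True, True),
            "b": RiskRow(True, True, True, True)}
    outcomes = {"a": "DRT", "b": "control"}
    c = concordance(rows, outcomes)
    assert c["per_patient"] == {"a": 4, "b": 0}


def test_concordance_order_invariant():
    rows, outcomes = table_risk_rows()
    shuffled = dict(reversed(list(rows.items())))
    assert (concordance(rows, outcomes)["tallies"]
            == concordance(shuffled, outcomes)["tallies"])


def test_concordance_missing_outcome():
    with pytest.raises(ValidationError):
        concordance({"a": RiskRow(True, True, True, True)}, {})


# ----------------------------------------------------------- reference tables


def test_threshold_counts_on_velocity_table():
    vel = tables.load_device_velocities()
    n = threshold_counts(vel, lambda r: (not pd.isna(r.cycle_post_mean))
                         and r.cycle_post_mean < 0.2)
    assert n == 9
    assert threshold_counts(vel, lambda r: False) == 0


def test_reference_table_shapes():
    assert len(tables.load_cohort_characteristics()) == 20
    assert tables.configuration_count() == 33
    assert tables.pr_covered_counts() == (13, 8)


@pytest.mark.xfail(reason="documented internal inconsistency of the reference "
                          "tables: the narrative count of post-LAAO max-ECAP "
                          "entries above 0.5 1/Pa (14) disagrees with the "
                          "direct table tally (15)", strict=True)
def test_narrative_high_ecap_count_matches_table():
    ec = tables.load_device_ecap()
    assert int((ec["max_post"] > 0.5).sum()) == 14


@pytest.mark.xfail(reason="documented inconsistency: the narrative DRT-group "
                          "LA-volume mean (177.1 mL) is not the arithmetic "
                          "mean of the per-patient values (197.1 mL)",
                   strict=True)
def test_narrative_drt_la_volume_matches_table():
    coh = tables.load_cohort_characteristics()
    assert tables.group_mean(coh, "la_volume_ml", "DRT") == pytest.approx(177.1, abs=0.05)


@pytest.mark.xfail(reason="documented inconsistency: the control-group pooled "
                          "cycle velocity (0.2 m/s) is not the mean of the "
                          "per-patient means (0.186 m/s); the pooling "
                          "convention is unstated", strict=True)
def test_control_pooled_velocity_matches_per_patient_mean():
    vel = tables.load_device_velocities()
    assert tables.group_mean(vel, "cycle_post_mean", "control") == pytest.approx(0.2, abs=0.005)


# ------------------------------------------------------------- cohort fixture


def test_cohort_fixture_law_of_large_numbers():
    """At n = 10000 the control LA-volume mean lands within 1 mL of 163.6."""
    recs = generate_cohort_fixture(10000, 0, seed=42)
    df = records_to_frame(recs)
    assert df["la_volume"].mean() == pytest.approx(163.6, abs=1.0)
    assert (df["la_volume"] > 0).all()


def test_cohort_fixture_empty_stratum_and_determinism():
    assert generate_cohort_fixture(5, 0, seed=0)[-1].outcome == "control"
    a = generate_cohort_fixture(4, 3, seed=9)
    b = generate_cohort_fixture(4, 3, seed=9)
    assert records_to_frame(a).equals(records_to_frame(b))
    with pytest.raises(ValidationError):
        generate_cohort_fixture(-1, 0)
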