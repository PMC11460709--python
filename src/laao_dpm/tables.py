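"""Reference cohort tables and their headline statistics.

The package ships a transcription (printed values only) of the per-patient
tables of a published 20-patient left-atrial-appendage-occlusion fluid-
simulation cohort: baseline anatomy and device assignments, device-surface
phase velocities, device-surface ECAP, and the four binary DRT-risk
descriptors, each for the implanted post-LAAO configuration and, where one
was simulated, the alternative pulmonary-ridge-covering configuration.
These make the cohort-level arithmetic executable without any patient data.

All statistics here are recomputed from the per-patient printed values; the
sample standard deviation (ddof=1) is used throughout.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_cohort_characteristics",
    "load_device_velocities",
    "load_device_ecap",
    "load_risk_descriptors",
    "configuration_count",
    "pr_covered_counts",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("laao_dpm.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_cohort_characteristics() -> pd.DataFrame:
    """Baseline anatomy, outcomes and device assignments (one row per patient).

    ``pr_size_mm`` is NaN for patients without a ridge-covering alternative
    configuration.
    """
    return _read("cohort_characteristics.csv")


def load_device_velocities() -> pd.DataFrame:
    """Device-surface velocity mean +- sd per phase and configuration (m/s)."""
    return _read("device_surface_velocities.csv")


def load_device_ecap() -> pd.DataFrame:
    """Device-surface ECAP maxima and mean +- sd per configuration (1/Pa)."""
    return _read("device_surface_ecap.csv")


def load_risk_descriptors() -> pd.DataFrame:
    """The four binary risk descriptors per patient and configuration."""
    return _read("risk_descriptors.csv")


def configuration_count() -> int:
    """Total simulated device configurations: one per patient plus one
    ridge-covering alternative wherever it exists."""
    df = load_cohort_characteristics()
    return int(len(df) + df["pr_size_mm"].notna().sum())


def pr_covered_counts() -> tuple[int, int]:
    """(total ridge-covering configurations, how many in the DRT stratum)."""
    df = load_cohort_characteristics()
    has = df["pr_size_mm"].notna()
    return int(has.sum()), int((has & (df["outcome"] == "DRT")).sum())


def group_mean(df: pd.DataFrame, column: str, outcome: str) -> float:
    """Arithmetic mean of one column within an outcome group (NaN dropped)."""
    vals = df.loc[df["outcome"] == outcome, column].dropna()
    return float(vals.mean())


def group_sd(df: pd.DataFrame, column: str, outcome: str) -> float:
    vals = df.loc[df["outcome"] == outcome, column].dropna()
    return float(vals.std(ddof=1))


def count_below(df: pd.DataFrame, column: str, threshold: float) -> int:
    """Strict-< count over non-missing entries of a column."""
    vals = df[column].dropna()
    return int((vals < threshold).sum())


def mean_of_exceeding(df: pd.DataFrame, column: str, threshold: float,
                      outcome: str | None = None) -> float:
    """Mean of the entries strictly above a threshold (optionally per group)."""
    sel = df if outcome is None else df[df["outcome"] == outcome]
    vals = sel[column].dropna()
    vals = vals[vals > threshold]
    return float(vals.mean())
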