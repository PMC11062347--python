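"""Cohort assembly: per-subject records, outcome coding, normalization.

A cohort is a tidy table with one row per subject: clinical covariates
(height, age, sex, BMI, six-month weight loss, BIA muscle-mass flag),
hospital-course variables (length of stay in days, whether discharge was to
home), the per-subject ultrasound metrics, and optionally a CT-derived
skeletal muscle area at L3 (cm²) produced by external segmentation
software and consumed here only as a number.

Outcome coding is a composite of stay length and discharge destination:
a stay of at most 5 days ending at home is a good outcome; a stay of 10+
days, or any non-home discharge (home hospitalisation, social health
centre, death), is a poor outcome; home discharges after 6–9 days are
excluded, because stays in that band are driven as much by logistics as by
medical course.  The composite avoids misclassifying short stays that end
in death as good.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EchomorphError

GOOD, POOR, EXCLUDED = "good", "poor", "excluded"

#: columns every cohort table must carry
REQUIRED_COLUMNS = ("subject_id", "height_m", "los_days", "discharge_home")

#: the ultrasound metric columns an analysis may evaluate
METRIC_COLUMNS = ("area_cm2", "x_cm", "y_cm", "x_eigen_cm", "y_eigen_cm", "gray_mean")


@dataclass
class CohortTable:
    """Thin validated wrapper around a one-row-per-subject DataFrame."""

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise EchomorphError(f"cohort table missing columns: {missing}")
        if self.df["subject_id"].duplicated().any():
            raise EchomorphError("subject_id values must be unique")
        h = self.df["height_m"].dropna()
        if ((h <= 1.0) | (h >= 2.5)).any():
            raise EchomorphError("heights must lie in (1.0, 2.5) m")
        if (self.df["los_days"].dropna() < 0).any():
            raise EchomorphError("length of stay cannot be negative")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read_csv(cls, path, provenance: str = "") -> "CohortTable":
        return cls(pd.read_csv(path), provenance=provenance or str(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def with_outcomes(self) -> "CohortTable":
        """Return a copy with an ``outcome`` column (good/poor/excluded)."""
        df = self.df.copy()
        df["outcome"] = [
            outcome_label(l, d) for l, d in zip(df["los_days"], df["discharge_home"])
        ]
        return CohortTable(df, provenance=self.provenance)


def normalize_by_height(value, height_m):
    """Standardize a metric by stature squared (cm² → cm²/m², cm → cm/m²)."""
    height_m = np.asarray(height_m, dtype=float)
    if (height_m <= 0).any() if height_m.ndim else height_m <= 0:
        raise EchomorphError("height must be positive")
    return value / height_m**2


def outcome_label(los_days: float, discharge_home: bool) -> str:
    """Composite clinical outcome from stay length and destination.

    good: stay ≤ 5 days and discharged home.
    poor: stay ≥ 10 days, or any non-home discharge regardless of stay.
    excluded: home discharge after a 6–9-day stay (ambiguous band).
    """
    if los_days < 0:
        raise EchomorphError("length of stay cannot be negative")
    if not discharge_home:
        return POOR
    if los_days <= 5:
        return GOOD
    if los_days >= 10:
        return POOR
    return EXCLUDED


def glim_malnutrition(
    weight_loss_6m_pct: float,
    bmi: float,
    age_y: float,
    reduced_muscle_mass: bool,
) -> bool:
    """Malnutrition by GLIM phenotypic criteria, OR-combined.

    The etiologic criterion (disease burden) is assumed present for every
    subject in this surgical-oncology setting, so malnutrition holds as
    soon as one phenotypic criterion does: >5% weight loss over 6 months,
    age-stratified low BMI (<20 kg/m² under 70 years, <22 kg/m² at 70+),
    or reduced muscle mass on bioimpedance.
    """
    if weight_loss_6m_pct > 5:
        return True
    if age_y < 70 and bmi < 20:
        return True
    if age_y >= 70 and bmi < 22:
        return True
    return bool(reduced_muscle_mass)


def stratify_overflow(cohort: CohortTable):
    """Partition the cohort by the image-overflow flag.

    Returns ``(with_overflow, without_overflow)`` sub-cohorts; an empty
    side raises a warning rather than an error.
    """
    if "overflow" not in cohort.df.columns:
        raise EchomorphError("cohort has no 'overflow' column")
    flag = cohort.df["overflow"].astype(bool)
    with_df, without_df = cohort.df[flag], cohort.df[~flag]
    for name, part in (("with", with_df), ("without", without_df)):
        if part.empty:
            warnings.warn(f"overflow stratum '{name}' is empty", stacklevel=2)
    return (
        CohortTable(with_df.reset_index(drop=True), provenance=cohort.provenance),
        CohortTable(without_df.reset_index(drop=True), provenance=cohort.provenance),
    )


def join_metrics(clinical: pd.DataFrame, metrics: pd.DataFrame) -> CohortTable:
    """Join a clinical table with per-image metric rows on subject/image id."""
    m = metrics.rename(columns={"image_id": "subject_id"})
    df = clinical.merge(m, on="subject_id", how="left", validate="one_to_one")
    return CohortTable(df, provenance="joined")
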