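"""Bilateral aggregation and the per-subject cohort table.

Each muscle group (erector spinae ES, psoas PS) is measured on both sides;
reported values are volume-weighted bilateral means, so the larger muscle
dominates, exactly as for mean PDFF.  The cohort table has one row per
subject with 26 candidate predictors (age, BMI, two bilateral mean PDFF
values, and 11 texture features x 2 muscle groups) plus the two strength
outcomes and sex.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import DomainError, SchemaError
from .texture_features import TEXTURE_FEATURE_NAMES

__all__ = [
    "MuscleFeatureSet",
    "SubjectRecord",
    "bilateral_average",
    "build_cohort_table",
    "predictor_columns",
    "texture_columns",
]


@dataclass
class MuscleFeatureSet:
    """Mean PDFF, physical volume and the 11 texture features of one muscle ROI."""

    muscle: str                  # "ES" | "PS"
    side: str                    # "right" | "left" | "bilateral"
    mean_pdff: float             # %
    physical_volume: float       # mm^3
    voxel_count: int
    features: dict[str, float]   # the 11 named texture features
    skipped_directions: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        missing = set(TEXTURE_FEATURE_NAMES) - set(self.features)
        extra = set(self.features) - set(TEXTURE_FEATURE_NAMES)
        if missing or extra:
            raise SchemaError(
                f"feature set must contain exactly the {len(TEXTURE_FEATURE_NAMES)} "
                f"texture features; missing={sorted(missing)} extra={sorted(extra)}")
        if self.physical_volume <= 0:
            raise DomainError("physical_volume must be positive")


@dataclass
class SubjectRecord:
    """One subject: covariates, bilateral ES/PS feature sets, torques (Nm)."""

    subject_id: str
    sex: str                     # "male" | "female"
    age: float                   # years
    bmi: float                   # kg/m^2
    es: MuscleFeatureSet
    ps: MuscleFeatureSet
    mvic_ext: float              # extension torque, Nm
    mvic_flex: float             # flexion torque, Nm

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise SchemaError(f"sex must be male/female, got {self.sex!r}")
        if self.mvic_ext <= 0 or self.mvic_flex <= 0:
            raise DomainError("torques must be positive")


def bilateral_average(right: MuscleFeatureSet, left: MuscleFeatureSet
                      ) -> MuscleFeatureSet:
    """Volume-weighted bilateral mean of every feature and of mean PDFF.

    f_bilat = (f_R * V_R + f_L * V_L) / (V_R + V_L), with V the physical
    muscle volumes in mm^3 (resolution independent).
    """
    if right.muscle != left.muscle:
        raise SchemaError(
            f"cannot aggregate different muscles: {right.muscle} vs {left.muscle}")
    if {right.side, left.side} != {"right", "left"}:
        raise SchemaError("bilateral_average needs one right and one left side")
    vr, vl = right.physical_volume, left.physical_volume
    vtot = vr + vl
    if vtot <= 0:
        raise DomainError("total volume must be positive")

    def w(a: float, b: float) -> float:
        return (a * vr + b * vl) / vtot

    return MuscleFeatureSet(
        muscle=right.muscle, side="bilateral",
        mean_pdff=w(right.mean_pdff, left.mean_pdff),
        physical_volume=vtot,
        voxel_count=right.voxel_count + left.voxel_count,
        features={n: w(right.features[n], left.features[n])
                  for n in TEXTURE_FEATURE_NAMES},
        skipped_directions=right.skipped_directions + left.skipped_directions,
        degenerate=right.degenerate or left.degenerate)


def texture_columns() -> list[str]:
    """The 22 texture feature column names (<feature>_<muscle>)."""
    return [f"{feat}_{m.lower()}" for m in ("ES", "PS")
            for feat in TEXTURE_FEATURE_NAMES]


def predictor_columns() -> list[str]:
    """The 26 candidate predictors: age, BMI, 2 mean PDFF, 22 texture features."""
    return ["age", "bmi", "pdff_es", "pdff_ps"] + texture_columns()


def build_cohort_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """One row per subject; validates the column census.

    Columns: subject_id, sex, age, bmi, pdff_es, pdff_ps, the 22
    `<feature>_<muscle>` texture columns, mvic_ext, mvic_flex.
    """
    if len(records) < 2:
        raise SchemaError("a cohort needs at least 2 subjects")
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise SchemaError("duplicate subject ids")
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "sex": r.sex,
               "age": r.age, "bmi": r.bmi,
               "pdff_es": r.es.mean_pdff, "pdff_ps": r.ps.mean_pdff}
        for m, fs in (("es", r.es), ("ps", r.ps)):
            if fs.side != "bilateral":
                raise SchemaError(
                    f"subject {r.subject_id}: {m} feature set must be bilateral")
            for feat in TEXTURE_FEATURE_NAMES:
                row[f"{feat}_{m}"] = fs.features[feat]
        row["mvic_ext"] = r.mvic_ext
        row["mvic_flex"] = r.mvic_flex
        rows.append(row)
    table = pd.DataFrame(rows)
    expected = (["subject_id", "sex"] + predictor_columns()
                + ["mvic_ext", "mvic_flex"])
    if sorted(table.columns) != sorted(expected):
        raise SchemaError("cohort table column census failed")
    return table[expected]
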