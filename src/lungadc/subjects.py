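"""The bundled study cohort: per-subject ADC and CT measurements.

The package ships a 14-subject reference cohort (4 older never-smokers and
10 COPD ex-smokers) with whole-lung mean ADC per gas and b-value (He-3 at
b = 1.6 s/cm^2; Xe-129 at b = 12, 20, 30 s/cm^2), CT density-threshold
metrics (RA950/RA910/RA856 in %, HU15% in HU), and a radiologist visual
emphysema score. Missing cells are genuine: Xe-129 ADC at b = 30 exists
for only three COPD subjects, CT was not acquired for never-smokers, and
one COPD subject lacks a visual score.

A subject is classified as having CT evidence of emphysema when
RA950 > 6.8%, the upper 95% limit of predicted normal values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .ct import EMPHYSEMA_RA950_CUTOFF
from .errors import StatsError

#: ADC column names, in gas / b-value order.
ADC_COLUMNS = ("adc_he3_b1p6", "adc_xe129_b12", "adc_xe129_b20", "adc_xe129_b30")

#: CT metric column names.
CT_COLUMNS = ("ra950_pct", "ra910_pct", "ra856_pct", "hu15_hu", "visual_score")

GROUPS = ("never-smoker", "COPD", "COPD-with-emphysema")


@dataclass
class SubjectRecord:
    """One subject of the reference cohort. Missing values are NaN."""

    subject_id: str
    group: str
    adc_he3_b1p6: float
    adc_xe129_b12: float
    adc_xe129_b20: float
    adc_xe129_b30: float
    ra950_pct: float
    ra910_pct: float
    ra856_pct: float
    hu15_hu: float
    visual_score: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise StatsError(f"unknown group {self.group!r}")
        ra = (self.ra950_pct, self.ra910_pct, self.ra856_pct)
        if not any(math.isnan(v) for v in ra):
            if not (0 <= ra[0] <= ra[1] <= ra[2] <= 100):
                raise StatsError(
                    f"{self.subject_id}: RA thresholds must nest, "
                    f"0 <= RA950 <= RA910 <= RA856 <= 100; got {ra}"
                )
        if not math.isnan(self.hu15_hu) and self.hu15_hu >= 0:
            raise StatsError(f"{self.subject_id}: HU15% must be negative in lung")

    @property
    def is_copd(self) -> bool:
        return self.group != "never-smoker"

    @property
    def emphysema(self) -> bool | None:
        """CT emphysema flag (RA950 > 6.8%); None when CT is missing."""
        if math.isnan(self.ra950_pct):
            return None
        return self.ra950_pct > EMPHYSEMA_RA950_CUTOFF


def load_subject_table() -> list[SubjectRecord]:
    """Load the bundled cohort, deriving the emphysema group label from CT."""
    df = cohort_dataframe()
    records = []
    for _, row in df.iterrows():
        records.append(SubjectRecord(
            subject_id=row["subject_id"],
            group=row["group"],
            **{c: float(row[c]) for c in ADC_COLUMNS + CT_COLUMNS},
        ))
    return records


def cohort_dataframe() -> pd.DataFrame:
    """The cohort as a DataFrame with the derived three-level group label."""
    with resources.files("lungadc.data").joinpath("cohort.csv").open() as fh:
        df = pd.read_csv(fh)
    emph = df["ra950_pct"] > EMPHYSEMA_RA950_CUTOFF
    df.loc[(df["group"] == "COPD") & emph, "group"] = "COPD-with-emphysema"
    return df


def reference_correlations() -> pd.DataFrame:
    """Published correlation family for the cohort (r, raw and corrected p).

    Used as an oracle fixture: applying the step-down correction to the
    ``p_raw`` column should reproduce ``p_holm`` at its printed precision.
    """
    with resources.files("lungadc.data").joinpath("reference_correlations.csv").open() as fh:
        return pd.read_csv(fh)
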