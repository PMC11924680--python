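"""Participants, mid-parental height, and diagnostic subtype classification.

The diagnostic scheme distinguishes five short-stature subtypes:

* ``PRIMARY`` — intrinsic growth disorders (syndromic, SGA without catch-up);
* ``SECONDARY`` — growth failure secondary to another disease or exposure;
* ``ISS_DP`` — constitutional delay of puberty;
* ``ISS_F`` — familial idiopathic short stature: height within +/-1.6 SD of
  the mid-parental height (MPH) target;
* ``ISS_NF`` — non-familial idiopathic short stature (everything else).

The clinical label (primary / secondary / constitutional delay / none) is an
input from chart review; classification only layers the MPH band and the
growth-hormone re-categorization rule (a GH-deficiency label with a normal
stimulation maximum, >= 10 ng/ml, becomes ISS-NF) on top of it.

MPH here is on the SDS scale: 0.72 x mean of the parents' height SDS, the
coefficient shrinking the parental average toward the population mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

MPH_COEFFICIENT = 0.72
ISSF_BAND_SD = 1.6
GH_NORMAL_MIN = 10.0          # ng/ml; stimulation maximum at/above this is normal
SHORT_STATURE_SDS = -2.0
GH_DEFICIENCY_SUBTYPE = "growth_hormone_deficiency"


class ClinicalLabel(str, Enum):
    NONE = "none"
    PRIMARY = "primary_growth_disorder"
    SECONDARY = "secondary_growth_disorder"
    CONSTITUTIONAL_DELAY = "constitutional_delay"


class Diagnosis(str, Enum):
    ISS_F = "ISS-F"
    ISS_NF = "ISS-NF"
    ISS_DP = "ISS-DP"
    PRIMARY = "primary"
    SECONDARY = "secondary"


ISS_DIAGNOSES = (Diagnosis.ISS_F, Diagnosis.ISS_NF, Diagnosis.ISS_DP)
DISORDER_DIAGNOSES = (Diagnosis.PRIMARY, Diagnosis.SECONDARY)


@dataclass
class Participant:
    id: str
    sex: str
    age_at_initial_visit: float            # years
    initial_height_sds: float
    mother_height_sds: Optional[float] = None
    father_height_sds: Optional[float] = None
    clinical_label: Optional[ClinicalLabel] = None
    clinical_subtype: Optional[str] = None  # free text, e.g. growth_hormone_deficiency
    gh_stim_max: Optional[float] = None     # ng/ml
    adult_height_measurements: Sequence[float] = field(default_factory=tuple)
    pc_covariates: Sequence[float] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.gh_stim_max is not None and not self.gh_stim_max >= 0:
            raise ValidationError(f"{self.id}: gh_stim_max must be >= 0")
        if not math.isfinite(self.initial_height_sds):
            raise ValidationError(f"{self.id}: non-finite initial height SDS")


def _present(x) -> bool:
    return x is not None and not (isinstance(x, float) and math.isnan(x))


def compute_mph(mother_sds: float, father_sds: float) -> float:
    """Mid-parental height SDS: 0.72 x mean of the parental SDS values."""
    if not (_present(mother_sds) and _present(father_sds)):
        raise ValidationError("both parental height SDS are required to compute MPH")
    return MPH_COEFFICIENT * (float(mother_sds) + float(father_sds)) / 2.0


def classify(participant: Participant, mph: float, band: float = ISSF_BAND_SD) -> Diagnosis:
    """Assign the diagnostic subtype.

    Precedence: clinical primary/secondary labels win (with the GH
    re-categorization exception), then constitutional delay, then the MPH
    band splits the remainder into ISS-F (|height - MPH| < band) and ISS-NF.
    """
    label = participant.clinical_label
    if label is None:
        raise ValidationError(f"{participant.id}: clinical_label must be set before classification")
    label = ClinicalLabel(label)
    if label is ClinicalLabel.SECONDARY:
        if (
            participant.clinical_subtype == GH_DEFICIENCY_SUBTYPE
            and _present(participant.gh_stim_max)
            and participant.gh_stim_max >= GH_NORMAL_MIN
        ):
            return Diagnosis.ISS_NF
        return Diagnosis.SECONDARY
    if label is ClinicalLabel.PRIMARY:
        return Diagnosis.PRIMARY
    if label is ClinicalLabel.CONSTITUTIONAL_DELAY:
        return Diagnosis.ISS_DP
    if abs(participant.initial_height_sds - mph) < band:
        return Diagnosis.ISS_F
    return Diagnosis.ISS_NF


def flag_mph_deviation(participant: Participant, mph: float, threshold: float = ISSF_BAND_SD) -> bool:
    """True when |initial height SDS - MPH SDS| >= threshold (default 1.6)."""
    return abs(participant.initial_height_sds - mph) >= threshold


def flag_short_stature(participant: Participant) -> bool:
    """True when initial height SDS <= -2 (boundary included)."""
    return participant.initial_height_sds <= SHORT_STATURE_SDS


def flag_monogenic_risk(participant: Participant) -> bool:
    """True when either parent has height SDS < -2 (a short parent)."""
    parents = [participant.mother_height_sds, participant.father_height_sds]
    present = [p for p in parents if _present(p)]
    if not present:
        return False
    return min(present) < SHORT_STATURE_SDS


def aggregate_adult_height(measurements: Sequence[float]) -> Optional[float]:
    """Median of available adult height measurements (cm); None when empty."""
    vals = [float(m) for m in (measurements or []) if _present(m)]
    if not vals:
        return None
    return float(np.median(vals))


@dataclass(frozen=True)
class PredictionPair:
    """The within-child pair of adult-height predictions and its discordance.

    ``delta`` is the PGS-minus-MPH prediction gap; ``height_diff`` is the
    single-variable classifier measure, initial visit height minus the
    PGS-predicted height (strongly negative when a child is far shorter
    than the polygenic prediction).
    """

    mph_pred: float
    pgs_pred: float
    initial_height_sds: float

    @property
    def delta(self) -> float:
        return self.pgs_pred - self.mph_pred

    @property
    def height_diff(self) -> float:
        return self.initial_height_sds - self.pgs_pred

    @property
    def mph_height_diff(self) -> float:
        return self.initial_height_sds - self.mph_pred

    @property
    def averaged_height_diff(self) -> float:
        return 0.5 * (self.height_diff + self.mph_height_diff)


# ---------------------------------------------------------------------------
# Phenotype table I/O
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = [
    "id", "sex", "age_years", "initial_height_cm",
    "mother_height_cm", "father_height_cm",
    "clinical_label", "clinical_subtype", "gh_stim_max", "adult_heights_cm",
]


def load_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype CSV (one row per participant).

    ``adult_heights_cm`` is a semicolon-separated list; PC covariates live
    in columns named ``pc1..pcK``; missing values are empty cells.
    """
    frame = pd.read_csv(path, dtype={"id": str})
    missing = set(PHENOTYPE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: phenotype table missing columns {sorted(missing)}")
    return frame


def pc_columns(frame: pd.DataFrame) -> list[str]:
    cols = [c for c in frame.columns if c.startswith("pc") and c[2:].isdigit()]
    return sorted(cols, key=lambda c: int(c[2:]))


def parse_adult_heights(cell) -> tuple[float, ...]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
        return ()
    return tuple(float(tok) for tok in str(cell).split(";") if tok.strip() != "")


def participants_from_frame(
    frame: pd.DataFrame,
    growth_ref,
    adult_ref,
) -> list[Participant]:
    """Build Participant objects, converting cm heights to SDS via the references."""
    from . import references as refs

    out: list[Participant] = []
    pcs = pc_columns(frame)
    for row in frame.itertuples(index=False):
        sex = row.sex
        height_sds = refs.height_to_sds(
            float(row.initial_height_cm), float(row.age_years) * 12.0, sex, growth_ref
        )
        mother = (
            refs.adult_height_to_sds(float(row.mother_height_cm), refs.FEMALE, adult_ref)
            if _present(row.mother_height_cm) else None
        )
        father = (
            refs.adult_height_to_sds(float(row.father_height_cm), refs.MALE, adult_ref)
            if _present(row.father_height_cm) else None
        )
        label = None
        if _present(row.clinical_label) and str(row.clinical_label).strip():
            label = ClinicalLabel(str(row.clinical_label))
        subtype = str(row.clinical_subtype) if _present(row.clinical_subtype) and str(row.clinical_subtype).strip() else None
        gh = float(row.gh_stim_max) if _present(row.gh_stim_max) else None
        out.append(
            Participant(
                id=str(row.id),
                sex=sex,
                age_at_initial_visit=float(row.age_years),
                initial_height_sds=float(height_sds),
                mother_height_sds=mother,
                father_height_sds=father,
                clinical_label=label,
                clinical_subtype=subtype,
                gh_stim_max=gh,
                adult_height_measurements=parse_adult_heights(row.adult_heights_cm),
                pc_covariates=tuple(float(getattr(row, c)) for c in pcs),
            )
        )
    return out
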