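"""Height standardization against growth references.

Two reference scales are used throughout the package:

* a pediatric growth reference in LMS form — per sex and age (months), a
  Box–Cox power ``L``, median height ``M`` (cm) and coefficient of
  variation ``S``.  A measured height ``x`` becomes a standard deviation
  score (SDS) via the LMS transform::

      z = ((x / M)**L - 1) / (L * S)     if L != 0
      z = ln(x / M) / S                  if L == 0

* an adult reference — per sex, a mean and standard deviation in cm, so
  ``z = (x - mu) / sigma``.

L, M and S are linearly interpolated in age between tabulated rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import OutOfRangeError, ParseError, ValidationError

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

GROWTH_COLUMNS = ["sex", "age_months", "L", "M", "S"]
ADULT_COLUMNS = ["sex", "mean_cm", "sd_cm"]


def _check_sex(sex: str) -> str:
    if sex not in SEXES:
        raise ValidationError(f"unknown sex code {sex!r}; expected one of {SEXES}")
    return sex


@dataclass(frozen=True)
class GrowthReference:
    """Pediatric LMS reference table (sex x age in months)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = set(GROWTH_COLUMNS) - set(t.columns)
        if missing:
            raise ParseError(f"growth reference missing columns: {sorted(missing)}")
        bad_sex = t.loc[~t["sex"].isin(SEXES)]
        if len(bad_sex):
            raise ParseError(f"growth reference has unknown sex codes in rows {bad_sex.index.tolist()}")
        for col in ("M", "S"):
            bad = t.loc[~(t[col] > 0)]
            if len(bad):
                raise ParseError(f"growth reference requires {col} > 0; violated at rows {bad.index.tolist()}")
        if not np.isfinite(t[["age_months", "L", "M", "S"]].to_numpy(float)).all():
            raise ParseError("growth reference contains non-finite values")
        for sex, sub in t.groupby("sex"):
            ages = sub["age_months"].to_numpy(float)
            if len(ages) < 2:
                raise ParseError(f"growth reference needs at least 2 ages for sex {sex!r}")
            dup = sub.loc[sub["age_months"].duplicated()]
            if len(dup):
                raise ParseError(f"duplicate ages for sex {sex!r} at rows {dup.index.tolist()}")
            order = sub.sort_index()["age_months"].to_numpy(float)
            if not (np.diff(order) > 0).all():
                raise ParseError(f"ages not strictly increasing for sex {sex!r}")

    def age_range(self, sex: str) -> tuple[float, float]:
        sub = self.table.loc[self.table["sex"] == _check_sex(sex), "age_months"]
        return float(sub.min()), float(sub.max())

    def lms_at(self, age_months, sex: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Linearly interpolated (L, M, S) at the given age(s)."""
        _check_sex(sex)
        sub = self.table.loc[self.table["sex"] == sex].sort_values("age_months")
        ages = sub["age_months"].to_numpy(float)
        a = np.asarray(age_months, dtype=float)
        if np.any(a < ages[0]) or np.any(a > ages[-1]):
            raise OutOfRangeError(
                f"age {a} months outside reference range [{ages[0]}, {ages[-1]}] for sex {sex!r}"
            )
        L = np.interp(a, ages, sub["L"].to_numpy(float))
        M = np.interp(a, ages, sub["M"].to_numpy(float))
        S = np.interp(a, ages, sub["S"].to_numpy(float))
        return L, M, S


@dataclass(frozen=True)
class AdultReference:
    """Sex-specific adult height mean/SD in cm."""

    mean_cm: dict
    sd_cm: dict

    def __post_init__(self) -> None:
        for sex in SEXES:
            if sex not in self.mean_cm or sex not in self.sd_cm:
                raise ParseError(f"adult reference missing sex {sex!r}")
            if not self.sd_cm[sex] > 0:
                raise ParseError(f"adult reference requires sd > 0 for sex {sex!r}")


def height_to_sds(height, age_months, sex: str, ref: GrowthReference):
    """Pediatric height (cm) -> age/sex SDS via the LMS transform.

    Accepts scalars or arrays for ``height`` and ``age_months``.
    """
    h = np.asarray(height, dtype=float)
    if np.any(h <= 0):
        raise ValidationError("height must be positive")
    L, M, S = ref.lms_at(age_months, sex)
    with np.errstate(divide="ignore"):
        z = np.where(
            np.abs(L) > 1e-12,
            (np.power(h / M, L) - 1.0) / (np.where(np.abs(L) > 1e-12, L, 1.0) * S),
            np.log(h / M) / S,
        )
    return float(z) if np.isscalar(height) or np.ndim(height) == 0 else z


def sds_to_height(z, age_months, sex: str, ref: GrowthReference):
    """Inverse LMS transform: SDS -> height in cm."""
    zz = np.asarray(z, dtype=float)
    L, M, S = ref.lms_at(age_months, sex)
    base = 1.0 + np.where(np.abs(L) > 1e-12, L, 1.0) * S * zz
    if np.any(base <= 0):
        raise ValidationError("SDS outside the invertible range of the LMS transform")
    h = np.where(
        np.abs(L) > 1e-12,
        M * np.power(base, 1.0 / np.where(np.abs(L) > 1e-12, L, 1.0)),
        M * np.exp(S * zz),
    )
    return float(h) if np.ndim(z) == 0 else h


def adult_height_to_sds(height, sex: str, ref: AdultReference):
    """Adult height (cm) -> SDS against the sex-specific adult reference."""
    _check_sex(sex)
    h = np.asarray(height, dtype=float)
    if np.any(h <= 0):
        raise ValidationError("height must be positive")
    z = (h - ref.mean_cm[sex]) / ref.sd_cm[sex]
    return float(z) if np.ndim(height) == 0 else z


def sds_to_adult_height(z, sex: str, ref: AdultReference):
    _check_sex(sex)
    zz = np.asarray(z, dtype=float)
    h = ref.mean_cm[sex] + ref.sd_cm[sex] * zz
    return float(h) if np.ndim(z) == 0 else h


def load_growth_reference(path) -> GrowthReference:
    """Read a growth-reference CSV with columns sex, age_months, L, M, S."""
    frame = pd.read_csv(path)
    missing = set(GROWTH_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    try:
        return GrowthReference(frame[GROWTH_COLUMNS].copy())
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_growth_reference(ref: GrowthReference, path) -> None:
    ref.table[GROWTH_COLUMNS].to_csv(path, index=False)


def load_adult_reference(path) -> AdultReference:
    """Read an adult-reference CSV with columns sex, mean_cm, sd_cm."""
    frame = pd.read_csv(path)
    missing = set(ADULT_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    dup = frame.loc[frame["sex"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate sex rows {dup.index.tolist()}")
    try:
        return AdultReference(
            mean_cm={r.sex: float(r.mean_cm) for r in frame.itertuples()},
            sd_cm={r.sex: float(r.sd_cm) for r in frame.itertuples()},
        )
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_adult_reference(ref: AdultReference, path) -> None:
    pd.DataFrame(
        {
            "sex": list(SEXES),
            "mean_cm": [ref.mean_cm[s] for s in SEXES],
            "sd_cm": [ref.sd_cm[s] for s in SEXES],
        }
    ).to_csv(path, index=False)


def synthetic_growth_reference(step_months: int = 6) -> GrowthReference:
    """A smooth synthetic pediatric LMS table (2-19 y, both sexes).

    Shapes are loosely modeled on US growth curves so simulated heights are
    plausible, but the table is synthetic: it is NOT the CDC reference and
    carries no claim of fidelity to it.
    """
    anchors = {
        MALE: ([24, 72, 120, 168, 204, 228], [86.5, 116.0, 138.0, 163.5, 174.5, 176.5]),
        FEMALE: ([24, 72, 120, 144, 168, 228], [85.0, 115.0, 138.0, 151.5, 160.5, 163.0]),
    }
    rows = []
    ages = np.arange(24, 229, step_months, dtype=float)
    for sex, (ax, ay) in anchors.items():
        M = np.interp(ages, ax, ay)
        # mild skew, increasing dispersion through puberty
        L = np.interp(ages, [24, 228], [1.2, 0.9])
        S = np.interp(ages, [24, 120, 168, 228], [0.038, 0.043, 0.048, 0.040])
        for a, l, m, s in zip(ages, L, M, S):
            rows.append({"sex": sex, "age_months": a, "L": l, "M": m, "S": s})
    return GrowthReference(pd.DataFrame(rows, columns=GROWTH_COLUMNS))


def synthetic_adult_reference() -> AdultReference:
    """Synthetic adult height reference (cm), loosely NHANES-like."""
    return AdultReference(
        mean_cm={MALE: 176.1, FEMALE: 162.6},
        sd_cm={MALE: 7.4, FEMALE: 6.9},
    )
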