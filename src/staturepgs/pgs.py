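"""Polygenic score computation, QC, standardization and height calibration.

The score for sample *i* is the weighted allele-dosage sum

    score_i = sum_j w_j * d_ij

where ``w_j`` is the per-effect-allele weight of variant *j* and ``d_ij``
the dosage (0-2) of that allele.  Before summing, dosages are aligned to
the weight table's effect allele: variants coded on the other allele are
flipped (d -> 2 - d), strand-ambiguous variants (A/T, C/G) and variants
below the imputation-quality threshold are dropped.

Scores are reported as SDS relative to an external adult reference cohort
(never the pediatric cohort itself), and a linear calibration model maps
PGS SDS (plus optional principal components) to predicted adult-height SDS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import AlignmentError, ParseError, ValidationError

_BASES = {"A", "C", "G", "T"}
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})

WEIGHT_COLUMNS = ["id", "effect_allele", "other_allele", "weight"]


@dataclass(frozen=True)
class WeightTable:
    """Per-variant effect-allele weights (PGS-Catalog-style)."""

    frame: pd.DataFrame  # columns: id, effect_allele, other_allele, weight[, imputation_r2]

    def __post_init__(self) -> None:
        f = self.frame
        missing = set(WEIGHT_COLUMNS) - set(f.columns)
        if missing:
            raise ParseError(f"weight table missing columns: {sorted(missing)}")
        if f["id"].duplicated().any():
            dup = f.loc[f["id"].duplicated(), "id"].tolist()
            raise ParseError(f"duplicate variant ids in weight table: {dup[:5]}")
        for col in ("effect_allele", "other_allele"):
            bad = f.loc[~f[col].isin(_BASES)]
            if len(bad):
                raise ParseError(f"non-ACGT {col} at rows {bad.index.tolist()[:5]}")
        same = f.loc[f["effect_allele"] == f["other_allele"]]
        if len(same):
            raise ParseError(f"effect_allele == other_allele at rows {same.index.tolist()[:5]}")
        if not np.isfinite(f["weight"].to_numpy(float)).all():
            raise ParseError("non-finite weights in weight table")

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.frame["id"])

    def __len__(self) -> int:
        return len(self.frame)


def load_weight_table(path) -> WeightTable:
    """Read a comma- or tab-separated weight table with a header row."""
    frame = pd.read_csv(path, sep=None, engine="python")
    try:
        return WeightTable(frame)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_weight_table(table: WeightTable, path) -> None:
    table.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class DosageMatrix:
    """Samples x variants allele-dosage matrix with per-variant allele coding.

    ``dosages`` holds the dosage of the *coded* allele (NaN = missing);
    ``alleles`` is indexed by variant id with columns ``coded`` and ``other``.
    """

    dosages: pd.DataFrame
    alleles: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.dosages.columns) != set(self.alleles.index):
            raise ValidationError("dosage columns and allele table ids disagree")
        if not {"coded", "other"} <= set(self.alleles.columns):
            raise ValidationError("allele table needs columns 'coded' and 'other'")
        vals = self.dosages.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 2)):
                raise ValidationError("dosages must lie in [0, 2]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.columns

    def missingness(self) -> pd.Series:
        """Per-sample fraction of missing dosages."""
        return self.dosages.isna().mean(axis=1)


def read_dosage_csv(dosage_path, alleles_path) -> DosageMatrix:
    """Read a sample x variant dosage CSV plus its coded-allele sidecar."""
    dosages = pd.read_csv(dosage_path, index_col=0)
    alleles = pd.read_csv(alleles_path).set_index("id")
    if not {"coded", "other"} <= set(alleles.columns):
        raise ParseError(f"{alleles_path}: expected columns id, coded, other")
    return DosageMatrix(dosages, alleles[["coded", "other"]])


def write_dosage_csv(dosages: DosageMatrix, dosage_path, alleles_path) -> None:
    dosages.dosages.to_csv(dosage_path, index_label="sample_id")
    dosages.alleles.reset_index().rename(columns={"index": "id"}).to_csv(alleles_path, index=False)


def read_dosage_vcf(path) -> DosageMatrix:
    """Read dosages from a VCF carrying a per-genotype DS field.

    The coded allele is ALT (the allele DS counts); REF is the other allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, coded, other, cols = [], [], [], []
    for variant in vcf:
        ds = variant.format("DS")
        if ds is None:
            raise ParseError(f"{path}: variant {variant.ID} lacks a DS FORMAT field")
        ids.append(variant.ID)
        coded.append(variant.ALT[0])
        other.append(variant.REF)
        cols.append(np.asarray(ds, dtype=float).reshape(-1))
    if not ids:
        raise ParseError(f"{path}: no variants")
    dosages = pd.DataFrame(np.column_stack(cols), index=pd.Index(samples, name="sample_id"), columns=ids)
    alleles = pd.DataFrame({"coded": coded, "other": other}, index=pd.Index(ids, name="id"))
    return DosageMatrix(dosages, alleles)


def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1, a2} in _AMBIGUOUS


def align_and_filter(
    weights: WeightTable,
    dosages: DosageMatrix,
    min_imputation_r2: float = 0.7,
) -> tuple[DosageMatrix, dict]:
    """Align dosages to the weight table's effect allele and apply variant filters.

    Returns the effect-allele-coded dosage matrix (restricted to usable
    variants) and a match report with counts:
    matched, flipped, dropped_ambiguous, dropped_low_r2, dropped_unmatched.
    """
    wf = weights.frame.set_index("id")
    overlap = [v for v in dosages.variant_ids if v in wf.index]
    if not overlap:
        raise AlignmentError("no overlapping variant ids between weights and dosages")

    report = {
        "matched": 0,
        "flipped": 0,
        "dropped_ambiguous": 0,
        "dropped_low_r2": 0,
        "dropped_unmatched": 0,
        "absent_from_dosages": int(len(wf) - len(overlap)),
    }
    keep_cols: list[str] = []
    flip_cols: list[str] = []
    has_r2 = "imputation_r2" in wf.columns
    for vid in overlap:
        eff, oth = wf.at[vid, "effect_allele"], wf.at[vid, "other_allele"]
        if has_r2:
            r2 = wf.at[vid, "imputation_r2"]
            if np.isfinite(r2) and r2 < min_imputation_r2:
                report["dropped_low_r2"] += 1
                continue
        if _is_ambiguous(eff, oth):
            report["dropped_ambiguous"] += 1
            continue
        coded, other = dosages.alleles.at[vid, "coded"], dosages.alleles.at[vid, "other"]
        if coded == eff and other == oth:
            keep_cols.append(vid)
        elif coded == oth and other == eff:
            keep_cols.append(vid)
            flip_cols.append(vid)
        else:
            report["dropped_unmatched"] += 1
    if report["dropped_unmatched"]:
        warnings.warn(
            f"{report['dropped_unmatched']} variant(s) matched neither allele orientation and were dropped",
            stacklevel=2,
        )
    if not keep_cols:
        raise AlignmentError("all overlapping variants were filtered out during alignment")

    out = dosages.dosages[keep_cols].copy()
    if flip_cols:
        out[flip_cols] = 2.0 - out[flip_cols]
        report["flipped"] = len(flip_cols)
    report["matched"] = len(keep_cols)
    alleles = pd.DataFrame(
        {"coded": wf.loc[keep_cols, "effect_allele"].to_numpy(), "other": wf.loc[keep_cols, "other_allele"].to_numpy()},
        index=pd.Index(keep_cols, name="id"),
    )
    return DosageMatrix(out, alleles), report


def compute_pgs(weights: WeightTable, dosages_aligned: DosageMatrix) -> pd.Series:
    """Weighted dosage sum per sample; expects effect-allele-coded dosages.

    Missing dosages are mean-imputed per variant (2 x cohort effect-allele
    frequency); all-missing variants are excluded with a warning.
    """
    wf = weights.frame.set_index("id")
    cols = [c for c in dosages_aligned.variant_ids if c in wf.index]
    if not cols:
        raise AlignmentError("no scored variants: dosage columns not found in the weight table")
    D = dosages_aligned.dosages[cols].to_numpy(float)
    w = wf.loc[cols, "weight"].to_numpy(float)
    all_missing = np.isnan(D).all(axis=0)
    if all_missing.any():
        warnings.warn(f"{int(all_missing.sum())} variant(s) with no called dosages excluded", stacklevel=2)
        D = D[:, ~all_missing]
        w = w[~all_missing]
    col_mean = np.nanmean(D, axis=0) if D.size else np.array([])
    if D.size:
        nan_r, nan_c = np.nonzero(np.isnan(D))
        D[nan_r, nan_c] = col_mean[nan_c]
    scores = D @ w if D.size else np.zeros(len(dosages_aligned.sample_ids))
    return pd.Series(scores, index=dosages_aligned.sample_ids, name="pgs_raw")


@dataclass(frozen=True)
class QCThresholds:
    """Sample-level QC limits."""

    kinship_max: float = 0.2       # pi-hat above which one of a pair is dropped
    missingness_max: float = 0.02  # fraction of missing genotypes
    het_sd_max: float = 4.0        # |het - mean| in cohort SD units

    def __post_init__(self) -> None:
        if min(self.kinship_max, self.missingness_max, self.het_sd_max) <= 0:
            raise ValidationError("QC thresholds must be positive")


def heterozygosity(dosages: DosageMatrix) -> pd.Series:
    """Per-sample heterozygote fraction on hard-called (rounded) genotypes."""
    g = np.round(dosages.dosages.to_numpy(float))
    het = np.nanmean(np.where(np.isnan(g), np.nan, (g == 1).astype(float)), axis=1)
    return pd.Series(het, index=dosages.sample_ids, name="het_rate")


def sample_qc(
    dosages: DosageMatrix,
    kinships: Iterable[tuple] = (),
    thresholds: QCThresholds = QCThresholds(),
    rng: np.random.Generator | int | None = None,
) -> tuple[list, dict]:
    """Apply the sample-level QC cascade; returns (retained ids, removal ledger).

    ``kinships`` is an iterable of (id_i, id_j, pi_hat); for each pair above
    ``kinship_max`` one member is removed at random (seeded).  Samples with
    missingness above ``missingness_max`` or heterozygosity more than
    ``het_sd_max`` SD from the cohort mean are then removed.
    """
    rng = np.random.default_rng(rng)
    retained = set(dosages.sample_ids)
    ledger: dict[str, list] = {"kinship": [], "missingness": [], "heterozygosity": []}

    for i, j, pihat in kinships:
        if pihat > thresholds.kinship_max and i in retained and j in retained:
            drop = (i, j)[int(rng.integers(2))]
            retained.discard(drop)
            ledger["kinship"].append(drop)

    miss = dosages.missingness()
    for sid in sorted(retained, key=list(dosages.sample_ids).index):
        if miss[sid] > thresholds.missingness_max:
            retained.discard(sid)
            ledger["missingness"].append(sid)

    if retained:
        het = heterozygosity(dosages)
        het = het.loc[[s for s in dosages.sample_ids if s in retained]]
        mu = float(het.mean())
        sd = float(het.std(ddof=1)) if len(het) > 1 else 0.0
        if sd > 0:
            out = het.index[np.abs(het - mu) > thresholds.het_sd_max * sd]
            for sid in out:
                retained.discard(sid)
                ledger["heterozygosity"].append(sid)

    kept = [s for s in dosages.sample_ids if s in retained]
    return kept, ledger


@dataclass(frozen=True)
class PgsResult:
    """Raw and standardized scores plus the reference moments used."""

    raw: pd.Series
    sds: pd.Series
    ref_mean: float
    ref_sd: float
    reference: str = "external_adult_cohort"


def standardize_pgs(raw_scores: pd.Series, adult_reference_scores) -> PgsResult:
    """Standardize raw scores against an external adult reference cohort.

    The pediatric cohort is never its own reference (ascertainment on short
    stature would bias the scale).
    """
    ref = np.asarray(adult_reference_scores, dtype=float)
    if ref.size < 2:
        raise ValidationError("adult reference cohort needs at least 2 samples")
    mu = float(ref.mean())
    sd = float(ref.std(ddof=1))
    if sd == 0:
        raise ValidationError("adult reference scores have zero variance")
    raw = pd.Series(np.asarray(raw_scores, dtype=float), index=getattr(raw_scores, "index", None), name="pgs_raw")
    sds = ((raw - mu) / sd).rename("pgs_sds")
    return PgsResult(raw=raw, sds=sds, ref_mean=mu, ref_sd=sd)


@dataclass(frozen=True)
class CalibrationModel:
    """OLS map from PGS SDS (+ PCs, optional sex) to adult-height SDS."""

    params: pd.Series          # const, pgs_sds, pc..., [sex]
    r_squared: float
    n: int
    covariates: tuple

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    @property
    def slope(self) -> float:
        return float(self.params["pgs_sds"])


def _check_full_rank(X: pd.DataFrame) -> None:
    from scipy.linalg import qr

    A = X.to_numpy(float)
    _, R, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        collinear = [X.columns[piv[k]] for k in range(rank, X.shape[1])]
        raise ValidationError(f"rank-deficient design; collinear columns: {collinear}")


def _design(pgs_sds, pcs, sex) -> pd.DataFrame:
    X = pd.DataFrame({"pgs_sds": np.asarray(pgs_sds, dtype=float)})
    if pcs is not None:
        pcs = pd.DataFrame(pcs).reset_index(drop=True)
        X = pd.concat([X, pcs], axis=1)
    if sex is not None:
        X["sex_female"] = (np.asarray(sex) == "female").astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_calibration(adult_height_sds, pgs_sds, pcs=None, sex=None) -> CalibrationModel:
    """OLS of adult-height SDS on PGS SDS and optional PC/sex covariates."""
    y = np.asarray(adult_height_sds, dtype=float)
    X = _design(pgs_sds, pcs, sex)
    if len(y) != len(X):
        raise ValidationError("response and covariates have different lengths")
    if len(y) < X.shape[1] + 2:
        raise ValidationError(f"need at least {X.shape[1] + 2} samples to fit, got {len(y)}")
    _check_full_rank(X)
    fit = sm.OLS(y, X).fit()
    return CalibrationModel(
        params=pd.Series(fit.params, index=X.columns),
        r_squared=float(fit.rsquared),
        n=len(y),
        covariates=tuple(c for c in X.columns if c != "const"),
    )


def predict_height_sds(model: CalibrationModel, pgs_sds, pcs=None, sex=None):
    """Predicted adult-height SDS; PC terms default to 0 (reference centroid)."""
    pgs = np.asarray(pgs_sds, dtype=float)
    pred = model.intercept + model.slope * pgs
    if pcs is not None:
        pcs = pd.DataFrame(pcs)
        for col in pcs.columns:
            if col in model.params.index:
                pred = pred + model.params[col] * pcs[col].to_numpy(float)
    if sex is not None and "sex_female" in model.params.index:
        pred = pred + model.params["sex_female"] * (np.asarray(sex) == "female").astype(float)
    return float(pred) if np.ndim(pgs_sds) == 0 else pred
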