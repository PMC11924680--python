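"""End-to-end analysis: score -> standardize -> classify -> compare -> discriminate.

``run_pipeline`` reproduces the full analysis sequence on any conforming
input bundle and returns a machine-readable report:

1. cohort summary (counts, medians, IQRs by diagnostic subtype);
2. Tukey HSD pairwise PGS / height comparisons across subtypes;
3. within-child MPH-vs-PGS adult-height prediction comparisons (paired
   Wilcoxon and paired Cohen's d) by subtype;
4. discrimination between non-familial ISS and growth disorders:
   baseline (age, sex, PCs) vs +MPH vs +PGS logistic models, ΔAUC with
   BCa bootstrap CIs, overall and within primary / secondary subsets,
   with and without initial-height adjustment;
5. single-variable height-difference classifiers (PGS-based, MPH-based,
   averaged) with Youden-optimal thresholds and bootstrap CIs;
6. variance in measured adult height explained by MPH, PGS and their
   combination, with bootstrap CIs, where adult heights exist.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cohort as coh
from . import discrimination as disc
from . import pgs as pgs_mod
from . import references as refs
from . import stats as nps
from .errors import ValidationError

log = logging.getLogger("staturepgs")


def _spawn(seed, n: int) -> list:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(n)

SUBSETS = ("all", "short_stature", "mph_deviation", "iss", "disorders")


@dataclass
class RunConfig:
    """Paths and knobs for a full pipeline run."""

    weights: str
    child_dosages: str
    phenotypes: str
    adult_dosages: str
    adult_cohort: str
    growth_reference: str
    adult_reference: str
    out_dir: str
    child_alleles: Optional[str] = None    # required for CSV dosages
    adult_alleles: Optional[str] = None
    kinship: Optional[str] = None          # optional CSV: id_i,id_j,pi_hat
    min_imputation_r2: float = 0.7
    qc: pgs_mod.QCThresholds = field(default_factory=pgs_mod.QCThresholds)
    issf_band: float = coh.ISSF_BAND_SD
    n_boot: int = 5000
    seed: int = 0
    subset: str = "all"
    stratified_bootstrap: bool = False

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if self.subset not in SUBSETS:
            raise ValidationError(f"unknown subset {self.subset!r}; expected one of {SUBSETS}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = pgs_mod.QCThresholds(**raw["qc"])
        cfg = cls(**raw)
        for attr in ("weights", "child_dosages", "phenotypes", "adult_dosages",
                     "adult_cohort", "growth_reference", "adult_reference"):
            p = getattr(cfg, attr)
            if not Path(p).exists():
                raise ValidationError(f"config path for {attr!r} does not exist: {p}")
        return cfg


def _read_dosages(path, alleles_path) -> pgs_mod.DosageMatrix:
    if str(path).endswith((".vcf", ".vcf.gz")):
        return pgs_mod.read_dosage_vcf(path)
    if alleles_path is None:
        raise ValidationError(f"CSV dosage file {path} requires an allele sidecar path")
    return pgs_mod.read_dosage_csv(path, alleles_path)


def _stage(name: str, n_in: int, n_out: int) -> None:
    log.info("stage=%s rows_in=%d rows_out=%d", name, n_in, n_out)


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

def _median_iqr(series) -> dict:
    v = np.asarray(series, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return {"median": None, "iqr_low": None, "iqr_high": None}
    return {
        "median": float(np.median(v)),
        "iqr_low": float(np.quantile(v, 0.25)),
        "iqr_high": float(np.quantile(v, 0.75)),
    }


def summarize_cohort(frame: pd.DataFrame) -> dict:
    """Table-1-style summary: subtype counts and shares, medians (IQR), flags.

    Expects a classified cohort frame with a ``diagnosis`` column; numeric
    and flag columns are summarized when present.  Percentages are exact in
    the returned JSON; round to 1 decimal for display.
    """
    n = len(frame)
    counts = {d.value: 0 for d in coh.Diagnosis}
    if n:
        for d, c in frame["diagnosis"].value_counts().items():
            counts[str(d)] = int(c)
    iss = sum(counts[d.value] for d in coh.ISS_DIAGNOSES)
    summary = {
        "n": n,
        "counts": counts,
        "percent": {k: (100.0 * v / n if n else 0.0) for k, v in counts.items()},
        "iss_total": {"count": iss, "percent": 100.0 * iss / n if n else 0.0},
        "disorder_total": {
            "count": counts["primary"] + counts["secondary"],
            "percent": 100.0 * (counts["primary"] + counts["secondary"]) / n if n else 0.0,
        },
    }
    for col, key in (
        ("initial_height_sds", "height_sds"),
        ("mph_sds", "mph_sds"),
        ("pgs_sds", "pgs_sds"),
        ("age_years", "age_years"),
    ):
        if col in frame.columns:
            summary[key] = _median_iqr(frame[col])
    for col in ("flag_short_stature", "flag_mph_deviation", "flag_monogenic_risk"):
        if col in frame.columns and n:
            summary[col] = {"count": int(frame[col].sum()), "percent": 100.0 * float(frame[col].mean())}
    return summary


# ---------------------------------------------------------------------------
# Cohort preparation
# ---------------------------------------------------------------------------

def prepare_cohort(pheno: pd.DataFrame, growth_ref, adult_ref, pgs_sds: pd.Series,
                   calib: pgs_mod.CalibrationModel, issf_band: float) -> pd.DataFrame:
    """Convert phenotypes to SDS, attach scores and predictions, classify."""
    participants = coh.participants_from_frame(pheno, growth_ref, adult_ref)
    rows = []
    for p in participants:
        if p.id not in pgs_sds.index:
            continue
        z = float(pgs_sds[p.id])
        mph = coh.compute_mph(p.mother_height_sds, p.father_height_sds)
        pcs = {f"pc{k+1}": v for k, v in enumerate(p.pc_covariates)}
        pgs_pred = calib.intercept + calib.slope * z + sum(
            calib.params.get(name, 0.0) * val for name, val in pcs.items()
        )
        pair = coh.PredictionPair(mph_pred=mph, pgs_pred=float(pgs_pred),
                                  initial_height_sds=p.initial_height_sds)
        adult_cm = coh.aggregate_adult_height(p.adult_height_measurements)
        adult_sds = (
            refs.adult_height_to_sds(adult_cm, p.sex, adult_ref) if adult_cm is not None else np.nan
        )
        diagnosis = coh.classify(p, mph, band=issf_band)
        rows.append(
            {
                "id": p.id,
                "sex": p.sex,
                "age_years": p.age_at_initial_visit,
                "initial_height_sds": p.initial_height_sds,
                "mother_height_sds": p.mother_height_sds,
                "father_height_sds": p.father_height_sds,
                "mph_sds": mph,
                "pgs_sds": z,
                "mph_pred": pair.mph_pred,
                "pgs_pred": pair.pgs_pred,
                "delta_pred": pair.delta,
                "height_diff_pgs": pair.height_diff,
                "height_diff_mph": pair.mph_height_diff,
                "height_diff_avg": pair.averaged_height_diff,
                "adult_height_sds": adult_sds,
                "diagnosis": diagnosis.value,
                "flag_short_stature": coh.flag_short_stature(p),
                "flag_mph_deviation": coh.flag_mph_deviation(p, mph, threshold=issf_band),
                "flag_monogenic_risk": coh.flag_monogenic_risk(p),
                **pcs,
            }
        )
    return pd.DataFrame(rows)


def apply_subset(frame: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset == "all":
        return frame
    if subset == "short_stature":
        return frame.loc[frame["flag_short_stature"]]
    if subset == "mph_deviation":
        return frame.loc[frame["flag_mph_deviation"]]
    if subset == "iss":
        return frame.loc[frame["diagnosis"].isin([d.value for d in coh.ISS_DIAGNOSES])]
    if subset == "disorders":
        return frame.loc[frame["diagnosis"].isin([d.value for d in coh.DISORDER_DIAGNOSES])]
    raise ValidationError(f"unknown subset {subset!r}")


# ---------------------------------------------------------------------------
# Analysis blocks
# ---------------------------------------------------------------------------

def _tukey_block(frame: pd.DataFrame, value_col: str) -> list[dict]:
    groups = {
        d: frame.loc[frame["diagnosis"] == d, value_col].to_numpy(float)
        for d in sorted(frame["diagnosis"].unique())
    }
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        return []
    return [dataclasses.asdict(r) for r in nps.tukey_hsd(groups)]


def _paired_block(frame: pd.DataFrame) -> list[dict]:
    out = []
    for d in sorted(frame["diagnosis"].unique()):
        sub = frame.loc[frame["diagnosis"] == d]
        if len(sub) < 2:
            continue
        res = nps.wilcoxon_paired(sub["pgs_pred"], sub["mph_pred"], comparison=f"{d}: PGS pred - MPH pred")
        try:
            es = nps.paired_effect_size(sub["pgs_pred"], sub["mph_pred"])
        except ValidationError:
            es = float("nan")
        rec = dataclasses.asdict(res)
        rec["cohens_d"] = es
        rec["n"] = int(len(sub))
        out.append(rec)
    return out


def _pc_cols(frame: pd.DataFrame) -> list[str]:
    return coh.pc_columns(frame)


def _discrimination_block(frame: pd.DataFrame, n_boot: int, seed, stratified: bool) -> dict:
    """ΔAUC analyses: ISS-NF (0) vs growth disorders (1)."""
    out: dict = {}
    rng_seed = _spawn(seed, 8)
    scenarios = [
        ("overall", [coh.Diagnosis.PRIMARY.value, coh.Diagnosis.SECONDARY.value], False),
        ("overall_height_adjusted", [coh.Diagnosis.PRIMARY.value, coh.Diagnosis.SECONDARY.value], True),
        ("primary", [coh.Diagnosis.PRIMARY.value], False),
        ("secondary", [coh.Diagnosis.SECONDARY.value], False),
    ]
    pcs = _pc_cols(frame)
    for i, (name, disorder_set, adjust_height) in enumerate(scenarios):
        sub = frame.loc[
            frame["diagnosis"].isin([coh.Diagnosis.ISS_NF.value] + disorder_set)
        ].reset_index(drop=True)
        y = sub["diagnosis"].isin(disorder_set).astype(float)
        if y.nunique() < 2 or len(sub) < 20:
            out[name] = {"skipped": f"insufficient data (n={len(sub)})"}
            continue
        base_cols = ["age_years"] + pcs
        covars = sub[base_cols].copy()
        covars["sex_female"] = (sub["sex"] == "female").astype(float)
        if adjust_height:
            covars["initial_height_sds"] = sub["initial_height_sds"]
        base = covars.copy()
        with_mph = covars.copy()
        with_mph["mph_sds"] = sub["mph_sds"]
        with_pgs = with_mph.copy()
        with_pgs["pgs_sds"] = sub["pgs_sds"]
        try:
            model = disc.fit_logistic(y, with_pgs)
            or_table = model.odds_ratios().loc[["mph_sds", "pgs_sds"]].to_dict("index")
            res = disc.delta_auc_bca(
                y, with_mph, with_pgs, n_boot=n_boot, seed=rng_seed[i], stratified=stratified
            )
            base_auc = disc.auc(disc.fit_logistic(y, base).predict_proba(base), y)
            out[name] = {
                "n": int(len(sub)),
                "n_disorder": int(y.sum()),
                "auc_baseline": base_auc,
                "auc_mph": res.auc_base,
                "auc_mph_pgs": res.auc_full,
                "delta_auc_pgs": dataclasses.asdict(res),
                "odds_ratios": or_table,
            }
        except Exception as exc:  # surfaced per scenario, not fatal for the run
            out[name] = {"error": f"{type(exc).__name__}: {exc}"}
    return out


def _metric_dict(m: disc.MetricCI) -> dict:
    return {"value": m.value, "ci_low": m.ci_low, "ci_high": m.ci_high}


def _classifier_block(frame: pd.DataFrame, n_boot: int, seed) -> dict:
    """Single-variable height-difference classifiers (disease when measure is low)."""
    sub = frame.loc[
        frame["diagnosis"].isin(
            [coh.Diagnosis.ISS_NF.value, coh.Diagnosis.PRIMARY.value, coh.Diagnosis.SECONDARY.value]
        )
    ].reset_index(drop=True)
    y = sub["diagnosis"].isin([coh.Diagnosis.PRIMARY.value, coh.Diagnosis.SECONDARY.value]).astype(float)
    out: dict = {}
    seeds = _spawn(seed, 3)
    if y.nunique() < 2:
        return {"skipped": "single outcome class"}
    for s, measure in zip(seeds, ("height_diff_pgs", "height_diff_mph", "height_diff_avg")):
        roc = disc.youden_cutpoint(sub[measure], y, positive_low=True, n_boot=n_boot, seed=s)
        out[measure] = {
            "auc": _metric_dict(roc.auc),
            "threshold": _metric_dict(roc.threshold),
            "sensitivity": _metric_dict(roc.sensitivity),
            "specificity": _metric_dict(roc.specificity),
            "ppv": _metric_dict(roc.ppv),
            "npv": _metric_dict(roc.npv),
            "youden_j": roc.youden_j,
            "n": int(len(sub)),
        }
    return out


def _adult_height_block(frame: pd.DataFrame, n_boot: int, seed) -> dict:
    out: dict = {}
    seeds = _spawn(seed, 6)
    scopes = {
        "all": frame,
        "iss": frame.loc[frame["diagnosis"].isin([d.value for d in coh.ISS_DIAGNOSES])],
    }
    k = 0
    for scope, sub0 in scopes.items():
        sub = sub0.loc[~sub0["adult_height_sds"].isna()].reset_index(drop=True)
        if len(sub) < 10:
            out[scope] = {"skipped": f"only {len(sub)} adult heights"}
            k += 3
            continue
        y = sub["adult_height_sds"]
        block = {"n": int(len(sub))}
        for predictors, name in (
            (["mph_sds"], "mph"),
            (["pgs_pred"], "pgs"),
            (["mph_sds", "pgs_pred"], "combined"),
        ):
            r = disc.r2_bootstrap(y, sub[predictors], n_boot=n_boot, seed=seeds[k])
            block[name] = dataclasses.asdict(r)
            k += 1
        out[scope] = block
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> tuple[dict, pd.DataFrame]:
    """Run the full analysis; returns (report dict, classified cohort frame)
    and writes report.json plus tidy CSV tables under ``config.out_dir``."""
    growth_ref = refs.load_growth_reference(config.growth_reference)
    adult_ref = refs.load_adult_reference(config.adult_reference)
    weights = pgs_mod.load_weight_table(config.weights)
    child_dos = _read_dosages(config.child_dosages, config.child_alleles)
    adult_dos = _read_dosages(config.adult_dosages, config.adult_alleles)
    pheno = coh.load_phenotypes(config.phenotypes)
    adult_pheno = pd.read_csv(config.adult_cohort, dtype={"id": str})

    kinships = []
    if config.kinship:
        kin = pd.read_csv(config.kinship)
        kinships = list(kin.itertuples(index=False, name=None))

    retained, qc_ledger = pgs_mod.sample_qc(child_dos, kinships, config.qc, rng=config.seed)
    _stage("sample_qc", len(child_dos.sample_ids), len(retained))
    child_dos = pgs_mod.DosageMatrix(child_dos.dosages.loc[retained], child_dos.alleles)

    child_aligned, match_report = pgs_mod.align_and_filter(weights, child_dos, config.min_imputation_r2)
    adult_aligned, _ = pgs_mod.align_and_filter(weights, adult_dos, config.min_imputation_r2)
    _stage("align", len(child_dos.variant_ids), len(child_aligned.variant_ids))

    raw_child = pgs_mod.compute_pgs(weights, child_aligned)
    raw_adult = pgs_mod.compute_pgs(weights, adult_aligned)
    child_result = pgs_mod.standardize_pgs(raw_child, raw_adult.to_numpy())
    adult_result = pgs_mod.standardize_pgs(raw_adult, raw_adult.to_numpy())
    _stage("score", len(raw_child), len(raw_child))

    # calibration in the adult cohort: height SDS ~ PGS SDS + PCs
    adult_pheno = adult_pheno.set_index("id").loc[raw_adult.index].reset_index()
    adult_height_sds = np.array(
        [
            refs.adult_height_to_sds(h, s, adult_ref)
            for h, s in zip(adult_pheno["height_cm"], adult_pheno["sex"])
        ]
    )
    pc_cols = coh.pc_columns(adult_pheno)
    calib = pgs_mod.fit_calibration(
        adult_height_sds, adult_result.sds.to_numpy(), pcs=adult_pheno[pc_cols] if pc_cols else None
    )
    _stage("calibration", len(adult_pheno), calib.n)

    frame = prepare_cohort(pheno, growth_ref, adult_ref, child_result.sds, calib, config.issf_band)
    _stage("classify", len(pheno), len(frame))
    frame = apply_subset(frame, config.subset).reset_index(drop=True)
    _stage("subset", len(pheno), len(frame))

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    report = {
        "config": {
            "subset": config.subset,
            "issf_band": config.issf_band,
            "n_boot": config.n_boot,
            "seed": config.seed,
            "min_imputation_r2": config.min_imputation_r2,
        },
        "qc": {"retained": len(retained), "removed": {k: sorted(map(str, v)) for k, v in qc_ledger.items()}},
        "match_report": match_report,
        "calibration": {
            "slope": calib.slope,
            "intercept": calib.intercept,
            "r_squared": calib.r_squared,
            "n": calib.n,
        },
        "summary": summarize_cohort(frame),
        "wilcoxon_vs_zero": {
            "mph_sds": dataclasses.asdict(
                nps.wilcoxon_one_sample(frame["mph_sds"], comparison="MPH SDS vs 0")
            ),
            "pgs_sds": dataclasses.asdict(
                nps.wilcoxon_one_sample(frame["pgs_sds"], comparison="PGS SDS vs 0")
            ),
        }
        if len(frame)
        else {},
        "tukey_pgs": _tukey_block(frame, "pgs_sds"),
        "tukey_height": _tukey_block(frame, "initial_height_sds"),
        "paired_predictions": _paired_block(frame),
        "discrimination": _discrimination_block(
            frame, config.n_boot, seeds[0], config.stratified_bootstrap
        ),
        "classifier": _classifier_block(frame, config.n_boot, seeds[1]),
        "adult_height_r2": _adult_height_block(frame, config.n_boot, seeds[2]),
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    frame.to_csv(out / "cohort_classified.csv", index=False)
    if report["tukey_pgs"]:
        pd.DataFrame(report["tukey_pgs"]).to_csv(out / "tukey_pgs.csv", index=False)
    if report["paired_predictions"]:
        pd.DataFrame(report["paired_predictions"]).to_csv(out / "paired_predictions.csv", index=False)
    return report, frame


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Human-readable rendering
# ---------------------------------------------------------------------------

def _fmt(x, nd=2):
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{x:.{nd}f}"


def render_report(report: dict) -> str:
    """Render the JSON report as a compact text summary (1 decimal for
    percentages, 2 for SDS and AUC)."""
    lines = []
    s = report.get("summary", {})
    lines.append(f"Cohort: n = {s.get('n', 0)}")
    for name, c in s.get("counts", {}).items():
        pct = s["percent"][name]
        lines.append(f"  {name:<10} {c:>5}  ({pct:.1f}%)")
    if "iss_total" in s:
        lines.append(f"  ISS total  {s['iss_total']['count']:>5}  ({s['iss_total']['percent']:.1f}%)")
    for key, label in (("height_sds", "Initial height SDS"), ("mph_sds", "MPH SDS"), ("pgs_sds", "PGS SDS")):
        if key in s and s[key]["median"] is not None:
            m = s[key]
            lines.append(f"  {label}: median {_fmt(m['median'])} (IQR {_fmt(m['iqr_low'])} to {_fmt(m['iqr_high'])})")
    if report.get("paired_predictions"):
        lines.append("Within-child prediction gap (PGS pred - MPH pred):")
        for rec in report["paired_predictions"]:
            lines.append(
                f"  {rec['comparison']}: delta = {_fmt(rec['estimate'])}, d = {_fmt(rec.get('cohens_d'))}, "
                f"p = {rec['p_value']:.2g} (n={rec['n']})"
            )
    d = report.get("discrimination", {})
    if d:
        lines.append("Discrimination (ISS-NF vs growth disorders):")
        for name, rec in d.items():
            if "delta_auc_pgs" not in rec:
                lines.append(f"  {name}: {rec.get('skipped', rec.get('error', ''))}")
                continue
            da = rec["delta_auc_pgs"]
            lines.append(
                f"  {name}: AUC {_fmt(da['auc_base'])} -> {_fmt(da['auc_full'])}, "
                f"dAUC = {_fmt(da['delta'])} [{_fmt(da['ci_low'])} to {_fmt(da['ci_high'])}], "
                f"p = {da['p_value']:.2g}"
            )
    c = report.get("classifier", {})
    if c and "skipped" not in c:
        lines.append("Height-difference classifiers (positive = growth disorder, flagged when low):")
        for name, rec in c.items():
            lines.append(
                f"  {name}: threshold {_fmt(rec['threshold']['value'])} "
                f"[{_fmt(rec['threshold']['ci_low'])} to {_fmt(rec['threshold']['ci_high'])}], "
                f"sens {100 * rec['sensitivity']['value']:.1f}%, spec {100 * rec['specificity']['value']:.1f}%, "
                f"AUC {_fmt(rec['auc']['value'])}"
            )
    r2 = report.get("adult_height_r2", {})
    for scope, rec in r2.items():
        if "skipped" in rec:
            continue
        lines.append(
            f"Adult-height variance explained ({scope}, n={rec['n']}): "
            f"MPH {100 * rec['mph']['r2']:.0f}%, PGS {100 * rec['pgs']['r2']:.0f}%, "
            f"combined {100 * rec['combined']['r2']:.0f}%"
        )
    return "\n".join(lines)
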