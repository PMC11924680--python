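"""Synthetic referral-cohort generator with explicit quantitative-genetic structure.

The generative model, per family:

* parental genotypes are Hardy-Weinberg draws at each variant's allele
  frequency; the child receives one allele per variant drawn uniformly
  from each parent (Mendelian segregation);
* the true polygenic score is the weighted dosage sum, standardized
  against a separately simulated adult reference cohort;
* adult height SDS = sqrt(h2_pgs) * PGS_sds + sqrt(c2) * F + e, where F is
  a family-shared environment term and e individual noise scaled so the
  unselected population has unit variance;
* disorder causes (primary, secondary, constitutional delay) are assigned
  independently of the PGS; primary/monogenic deficits reduce adult
  potential, secondary and delay deficits are transient and reduce the
  pediatric visit height only;
* monogenic variants follow a carrier/transmission model layered on top:
  a carrier parent is shorter by the effect size, and a transmitting
  carrier makes the child a primary (monogenic) case;
* reported parental heights carry Gaussian reporting error;
* the cohort is finally ascertained by a referral rule on the child's
  pediatric height SDS (and optionally the deviation from mid-parental
  height), which is what makes the cohort's mean PGS negative.

Pediatric height is modeled directly on the SDS scale as adult potential
plus transient deficits plus visit noise; no growth-curve model is used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import references as refs
from .cohort import GH_DEFICIENCY_SUBTYPE, compute_mph
from .errors import SimulationError, ValidationError
from .pgs import DosageMatrix, WeightTable, write_dosage_csv, write_weight_table

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]
N_PCS = 10


@dataclass(frozen=True)
class DisorderModel:
    """Prevalence and height-deficit distribution (SDS) for one cause."""

    prevalence: float
    deficit_mean: float
    deficit_sd: float


@dataclass(frozen=True)
class MonogenicModel:
    carrier_freq: float = 0.01       # per parent
    effect_sds: float = -2.0         # height effect in carriers
    transmission_prob: float = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for the synthetic study.

    Defaults encode the study conditions the analysis assumes: the
    polygenic score explains 38.1% of adult-height variance
    (pgs_variance_fraction), disorder deficits are independent of the PGS,
    parental heights carry reporting error, and the cohort is ascertained
    on short stature.
    """

    n_families: int = 1500
    n_snps: int = 200
    allele_freq_range: tuple = (0.1, 0.9)
    pgs_variance_fraction: float = 0.381   # h2_pgs: adult R^2 of the true score
    familial_env_fraction: float = 0.15    # c2: family-shared environment
    primary: DisorderModel = DisorderModel(0.008, -2.0, 0.5)
    secondary: DisorderModel = DisorderModel(0.045, -1.8, 0.5)
    constitutional_delay: DisorderModel = DisorderModel(0.030, -1.2, 0.4)
    monogenic: MonogenicModel = MonogenicModel()
    gh_fraction_of_secondary: float = 0.45   # secondary cases labeled GH deficiency
    gh_misdiagnosed_fraction: float = 0.10   # of GH-labeled cases, stim max >= 10
    parental_report_sd: float = 0.2          # SDS reporting error
    visit_age_range: tuple = (4.0, 16.0)     # years
    visit_noise_sd: float = 0.2              # SDS measurement noise at the visit
    referral_height_max: float = -1.5        # refer if pediatric height SDS <= this
    referral_mph_dev_min: float | None = None  # optionally also refer if |height-MPH| >= this
    adult_height_fraction: float = 0.25      # children with adult measurements
    n_adult_reference: int = 2000
    low_r2_fraction: float = 0.0             # weight-table rows below the R^2=0.7 filter
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pgs_variance_fraction < 1.0):
            raise ValidationError("pgs_variance_fraction must be in (0, 1)")
        if not (0.0 <= self.familial_env_fraction < 1.0):
            raise ValidationError("familial_env_fraction must be in [0, 1)")
        if self.pgs_variance_fraction + self.familial_env_fraction >= 1.0:
            raise ValidationError("pgs_variance_fraction + familial_env_fraction must be < 1")
        prevs = [self.primary.prevalence, self.secondary.prevalence, self.constitutional_delay.prevalence]
        if any(not (0.0 <= p <= 1.0) for p in prevs) or sum(prevs) > 1.0:
            raise ValidationError("cause prevalences must lie in [0,1] and sum to <= 1")
        if self.n_snps < 0 or self.n_families < 1:
            raise ValidationError("n_snps must be >= 0 and n_families >= 1")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("allele_freq_range must lie strictly inside (0, 1)")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stage substream of the master seed."""
        streams = ("weights", "adults", "trios", "phenotypes")
        if stream not in streams:
            raise ValidationError(f"unknown RNG stream {stream!r}")
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(len(streams))[streams.index(stream)])


def config_to_yaml(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key, cls in (("primary", DisorderModel), ("secondary", DisorderModel),
                     ("constitutional_delay", DisorderModel), ("monogenic", MonogenicModel)):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = cls(**raw[key])
    for key in ("allele_freq_range", "visit_age_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


# ---------------------------------------------------------------------------
# Weights and genotypes
# ---------------------------------------------------------------------------

def simulate_weights(config: SimulationConfig) -> tuple[WeightTable, np.ndarray]:
    """Draw a variant weight table and allele frequencies.

    Weights are scaled so the raw-score variance under HWE is 1, which makes
    the downstream standardization numerically tame.
    """
    rng = config.rng("weights")
    m = config.n_snps
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, m)
    w = rng.normal(0.0, 1.0, m)
    var = float(np.sum(w**2 * 2.0 * freqs * (1.0 - freqs)))
    if var > 0:
        w = w / np.sqrt(var)
    pairs = [_ALLELE_PAIRS[k] for k in rng.integers(0, len(_ALLELE_PAIRS), m)]
    r2 = rng.uniform(0.8, 1.0, m)
    n_low = int(round(config.low_r2_fraction * m))
    if n_low:
        low_idx = rng.choice(m, n_low, replace=False)
        r2[low_idx] = rng.uniform(0.3, 0.69, n_low)
    frame = pd.DataFrame(
        {
            "id": [f"snp{k:05d}" for k in range(m)],
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
            "weight": w,
            "imputation_r2": r2,
        }
    )
    return WeightTable(frame), freqs


def _hwe_genotypes(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    return rng.binomial(2, freqs[None, :], (n, len(freqs))).astype(np.int8)


def _mendelian_child(rng: np.random.Generator, gm: np.ndarray, gf: np.ndarray) -> np.ndarray:
    """One allele drawn uniformly from each parent's pair, per variant."""
    am = rng.binomial(1, gm / 2.0)
    af = rng.binomial(1, gf / 2.0)
    return (am + af).astype(np.int8)


# ---------------------------------------------------------------------------
# Adult reference cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdultCohort:
    """Simulated unselected adult cohort used for PGS standardization and calibration."""

    sample_ids: list
    genotypes: np.ndarray          # n x m effect-allele dosages
    raw_scores: np.ndarray
    pgs_sds: np.ndarray            # self-standardized
    height_sds: np.ndarray
    sex: np.ndarray
    pcs: pd.DataFrame


def simulate_adult_reference(config: SimulationConfig, weights: WeightTable, freqs: np.ndarray) -> AdultCohort:
    rng = config.rng("adults")
    n = config.n_adult_reference
    if n < 2:
        raise ValidationError("n_adult_reference must be >= 2")
    G = _hwe_genotypes(rng, freqs, n)
    w = weights.frame["weight"].to_numpy(float)
    raw = G @ w
    sd = raw.std(ddof=1)
    pgs_sds = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)
    b = np.sqrt(config.pgs_variance_fraction)
    e = rng.normal(0.0, np.sqrt(1.0 - config.pgs_variance_fraction), n)
    height = b * pgs_sds + e
    sex = np.where(rng.random(n) < 0.5, refs.FEMALE, refs.MALE)
    pcs = pd.DataFrame(rng.normal(0.0, 1.0, (n, N_PCS)), columns=[f"pc{k+1}" for k in range(N_PCS)])
    ids = [f"adult{k:05d}" for k in range(n)]
    return AdultCohort(ids, G, raw, pgs_sds, height, sex, pcs)


# ---------------------------------------------------------------------------
# Trio cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrioCohort:
    """Simulated referral cohort of child-mother-father trios."""

    children: pd.DataFrame         # one row per referred child
    child_genotypes: np.ndarray    # aligned with children rows
    mother_genotypes: np.ndarray
    father_genotypes: np.ndarray
    weights: WeightTable
    freqs: np.ndarray
    adult_reference: AdultCohort
    config: SimulationConfig


def simulate_trios(config: SimulationConfig, weights: WeightTable | None = None,
                   freqs: np.ndarray | None = None,
                   adult_reference: AdultCohort | None = None) -> TrioCohort:
    """Generate the referred trio cohort (plus its adult reference, if not given)."""
    if weights is None or freqs is None:
        weights, freqs = simulate_weights(config)
    if adult_reference is None:
        adult_reference = simulate_adult_reference(config, weights, freqs)
    rng = config.rng("trios")
    n = config.n_families
    w = weights.frame["weight"].to_numpy(float)

    Gm = _hwe_genotypes(rng, freqs, n)
    Gf = _hwe_genotypes(rng, freqs, n)
    Gc = _mendelian_child(rng, Gm, Gf)

    mu, sd = adult_reference.raw_scores.mean(), adult_reference.raw_scores.std(ddof=1)
    if sd == 0:
        sd = 1.0
    z_m, z_f, z_c = ((G @ w - mu) / sd for G in (Gm, Gf, Gc))

    b = np.sqrt(config.pgs_variance_fraction)
    c = np.sqrt(config.familial_env_fraction)
    e_scale = np.sqrt(1.0 - config.pgs_variance_fraction - config.familial_env_fraction)
    F = rng.normal(0.0, 1.0, n)

    mono = config.monogenic
    carrier_m = rng.random(n) < mono.carrier_freq
    carrier_f = rng.random(n) < mono.carrier_freq
    h_mother = b * z_m + c * F + e_scale * rng.normal(0.0, 1.0, n) + mono.effect_sds * carrier_m
    h_father = b * z_f + c * F + e_scale * rng.normal(0.0, 1.0, n) + mono.effect_sds * carrier_f

    child_mono = (carrier_m & (rng.random(n) < mono.transmission_prob)) | (
        carrier_f & (rng.random(n) < mono.transmission_prob)
    )
    adult_potential = b * z_c + c * F + e_scale * rng.normal(0.0, 1.0, n)

    # cause assignment, independent of the PGS
    u = rng.random(n)
    p1 = config.primary.prevalence
    p2 = p1 + config.secondary.prevalence
    p3 = p2 + config.constitutional_delay.prevalence
    cause = np.full(n, "none", dtype=object)
    cause[u < p1] = "primary"
    cause[(u >= p1) & (u < p2)] = "secondary"
    cause[(u >= p2) & (u < p3)] = "constitutional_delay"
    subtype = np.full(n, "", dtype=object)
    subtype[cause == "primary"] = "syndromic"
    cause[child_mono] = "primary"
    subtype[child_mono] = "monogenic"

    def deficits(model: DisorderModel, mask: np.ndarray) -> np.ndarray:
        d = np.zeros(n)
        d[mask] = rng.normal(model.deficit_mean, model.deficit_sd, int(mask.sum()))
        return d

    primary_random = (cause == "primary") & ~child_mono
    adult_height = adult_potential + deficits(config.primary, primary_random)
    adult_height = adult_height + mono.effect_sds * child_mono
    transient = deficits(config.secondary, cause == "secondary") + deficits(
        config.constitutional_delay, cause == "constitutional_delay"
    )
    pediatric_height = adult_height + transient + rng.normal(0.0, config.visit_noise_sd, n)

    # secondary subtype split and GH stimulation values
    sec = cause == "secondary"
    is_gh = sec & (rng.random(n) < config.gh_fraction_of_secondary)
    subtype[sec] = "systemic_disease"
    subtype[is_gh] = GH_DEFICIENCY_SUBTYPE
    gh_stim = np.full(n, np.nan)
    n_gh = int(is_gh.sum())
    gh_vals = rng.uniform(1.0, 9.5, n_gh)
    misdx = rng.random(n_gh) < config.gh_misdiagnosed_fraction
    gh_vals[misdx] = rng.uniform(10.0, 20.0, int(misdx.sum()))
    gh_stim[is_gh] = gh_vals

    rep_sd = config.parental_report_sd
    rep_mother = h_mother + (rng.normal(0.0, rep_sd, n) if rep_sd > 0 else 0.0)
    rep_father = h_father + (rng.normal(0.0, rep_sd, n) if rep_sd > 0 else 0.0)

    sex = np.where(rng.random(n) < 0.5, refs.FEMALE, refs.MALE)
    age = rng.uniform(*config.visit_age_range, n)
    pcs = rng.normal(0.0, 1.0, (n, N_PCS))
    has_adult = rng.random(n) < config.adult_height_fraction

    label_map = {"none": "none", "primary": "primary_growth_disorder",
                 "secondary": "secondary_growth_disorder",
                 "constitutional_delay": "constitutional_delay"}
    children = pd.DataFrame(
        {
            "id": [f"child{k:05d}" for k in range(n)],
            "family": [f"fam{k:05d}" for k in range(n)],
            "sex": sex,
            "age_years": age,
            "pediatric_height_sds": pediatric_height,
            "adult_height_sds": adult_height,
            "has_adult_height": has_adult,
            "mother_height_sds_true": h_mother,
            "father_height_sds_true": h_father,
            "mother_height_sds_reported": rep_mother,
            "father_height_sds_reported": rep_father,
            "cause": cause,
            "clinical_label": [label_map[cc] for cc in cause],
            "clinical_subtype": subtype,
            "gh_stim_max": gh_stim,
            "pgs_raw": Gc @ w,
            "pgs_sds_true": z_c,
        }
    )
    for k in range(N_PCS):
        children[f"pc{k+1}"] = pcs[:, k]

    mph = np.array([compute_mph(a, bb) for a, bb in zip(rep_mother, rep_father)])
    referred = pediatric_height <= config.referral_height_max
    if config.referral_mph_dev_min is not None:
        referred |= np.abs(pediatric_height - mph) >= config.referral_mph_dev_min
    if not referred.any():
        raise SimulationError(
            f"referral rule retained 0 of {n} families "
            f"(height min {pediatric_height.min():.2f}, referral_height_max {config.referral_height_max})"
        )

    keep = np.flatnonzero(referred)
    return TrioCohort(
        children=children.iloc[keep].reset_index(drop=True),
        child_genotypes=Gc[keep],
        mother_genotypes=Gm[keep],
        father_genotypes=Gf[keep],
        weights=weights,
        freqs=freqs,
        adult_reference=adult_reference,
        config=config,
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def _dosage_matrix(genotypes: np.ndarray, ids: list, weights: WeightTable) -> DosageMatrix:
    wf = weights.frame
    dosages = pd.DataFrame(
        genotypes.astype(float), index=pd.Index(ids, name="sample_id"), columns=wf["id"].tolist()
    )
    alleles = pd.DataFrame(
        {"coded": wf["effect_allele"].to_numpy(), "other": wf["other_allele"].to_numpy()},
        index=pd.Index(wf["id"], name="id"),
    )
    return DosageMatrix(dosages, alleles)


def write_dosage_vcf(dosages: DosageMatrix, path) -> None:
    """Write a minimal VCF 4.2 carrying per-genotype DS (coded allele = ALT)."""
    samples = list(dosages.sample_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        mat = dosages.dosages.to_numpy(float)
        for k, vid in enumerate(dosages.variant_ids):
            ref = dosages.alleles.at[vid, "other"]
            alt = dosages.alleles.at[vid, "coded"]
            ds = "\t".join("." if np.isnan(v) else f"{v:g}" for v in mat[:, k])
            fh.write(f"1\t{k + 1}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tDS\t{ds}\n")


def cohort_phenotype_frame(cohort: TrioCohort, growth_ref=None, adult_ref=None) -> pd.DataFrame:
    """Phenotype table in the on-disk dialect (heights in cm)."""
    growth_ref = growth_ref or refs.synthetic_growth_reference()
    adult_ref = adult_ref or refs.synthetic_adult_reference()
    ch = cohort.children
    rng = cohort.config.rng("phenotypes")
    rows = []
    for i, row in enumerate(ch.itertuples(index=False)):
        h_cm = refs.sds_to_height(row.pediatric_height_sds, row.age_years * 12.0, row.sex, growth_ref)
        mother_cm = refs.sds_to_adult_height(row.mother_height_sds_reported, refs.FEMALE, adult_ref)
        father_cm = refs.sds_to_adult_height(row.father_height_sds_reported, refs.MALE, adult_ref)
        adult_cell = ""
        if row.has_adult_height:
            base_cm = refs.sds_to_adult_height(row.adult_height_sds, row.sex, adult_ref)
            n_meas = int(rng.integers(1, 4))
            meas = base_cm + rng.normal(0.0, 0.5, n_meas)
            adult_cell = ";".join(f"{m:.1f}" for m in meas)
        rows.append(
            {
                "id": row.id,
                "sex": row.sex,
                "age_years": round(float(row.age_years), 4),
                "initial_height_cm": round(float(h_cm), 4),
                "mother_height_cm": round(float(mother_cm), 4),
                "father_height_cm": round(float(father_cm), 4),
                "clinical_label": row.clinical_label,
                "clinical_subtype": row.clinical_subtype,
                "gh_stim_max": "" if np.isnan(row.gh_stim_max) else round(float(row.gh_stim_max), 1),
                "adult_heights_cm": adult_cell,
            }
        )
    frame = pd.DataFrame(rows)
    for k in range(N_PCS):
        frame[f"pc{k+1}"] = ch[f"pc{k+1}"].to_numpy()
    return frame


def adult_cohort_frame(adults: AdultCohort, adult_ref=None) -> pd.DataFrame:
    adult_ref = adult_ref or refs.synthetic_adult_reference()
    height_cm = [
        refs.sds_to_adult_height(z, s, adult_ref) for z, s in zip(adults.height_sds, adults.sex)
    ]
    frame = pd.DataFrame({"id": adults.sample_ids, "sex": adults.sex, "height_cm": np.round(height_cm, 2)})
    return pd.concat([frame, adults.pcs.set_index(frame.index)], axis=1)


def emit(cohort: TrioCohort, outdir, dosage_format: str = "csv") -> dict:
    """Write the full synthetic study in the dialects the pipeline reads.

    Produces weight table, child and adult dosages (CSV + allele sidecar, or
    VCF), phenotype CSV, adult-cohort CSV, both reference CSVs, the
    simulation config, and a ready-to-run pipeline config; returns the path map.
    """
    if dosage_format not in ("csv", "vcf"):
        raise ValidationError(f"unknown dosage format {dosage_format!r}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    growth_ref = refs.synthetic_growth_reference()
    adult_ref = refs.synthetic_adult_reference()

    paths = {
        "weights": out / "weights.csv",
        "phenotypes": out / "phenotypes.csv",
        "adult_cohort": out / "adult_cohort.csv",
        "growth_reference": out / "growth_reference.csv",
        "adult_reference": out / "adult_reference.csv",
        "sim_config": out / "sim_config.yaml",
        "run_config": out / "run_config.yaml",
    }
    write_weight_table(cohort.weights, paths["weights"])
    child_dos = _dosage_matrix(cohort.child_genotypes, cohort.children["id"].tolist(), cohort.weights)
    adult_dos = _dosage_matrix(cohort.adult_reference.genotypes, cohort.adult_reference.sample_ids, cohort.weights)
    if dosage_format == "csv":
        paths["child_dosages"] = out / "child_dosages.csv"
        paths["child_alleles"] = out / "child_alleles.csv"
        paths["adult_dosages"] = out / "adult_dosages.csv"
        paths["adult_alleles"] = out / "adult_alleles.csv"
        write_dosage_csv(child_dos, paths["child_dosages"], paths["child_alleles"])
        write_dosage_csv(adult_dos, paths["adult_dosages"], paths["adult_alleles"])
    else:
        paths["child_dosages"] = out / "children.vcf"
        paths["adult_dosages"] = out / "adults.vcf"
        write_dosage_vcf(child_dos, paths["child_dosages"])
        write_dosage_vcf(adult_dos, paths["adult_dosages"])

    cohort_phenotype_frame(cohort, growth_ref, adult_ref).to_csv(paths["phenotypes"], index=False)
    adult_cohort_frame(cohort.adult_reference, adult_ref).to_csv(paths["adult_cohort"], index=False)
    refs.write_growth_reference(growth_ref, paths["growth_reference"])
    refs.write_adult_reference(adult_ref, paths["adult_reference"])
    config_to_yaml(cohort.config, paths["sim_config"])

    run_cfg = {
        "weights": str(paths["weights"]),
        "child_dosages": str(paths["child_dosages"]),
        "adult_dosages": str(paths["adult_dosages"]),
        "phenotypes": str(paths["phenotypes"]),
        "adult_cohort": str(paths["adult_cohort"]),
        "growth_reference": str(paths["growth_reference"]),
        "adult_reference": str(paths["adult_reference"]),
        "out_dir": str(out / "results"),
        "n_boot": 500,
        "seed": cohort.config.seed,
    }
    if dosage_format == "csv":
        run_cfg["child_alleles"] = str(paths["child_alleles"])
        run_cfg["adult_alleles"] = str(paths["adult_alleles"])
    with open(paths["run_config"], "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
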