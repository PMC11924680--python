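"""Generative model: Mendelian transmission, variance structure, ascertainment, I/O."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import staturepgs as sp
from staturepgs.errors import SimulationError, ValidationError
from staturepgs.simulate import (
    DisorderModel,
    MonogenicModel,
    SimulationConfig,
    cohort_phenotype_frame,
    config_from_yaml,
    config_to_yaml,
    simulate_adult_reference,
    simulate_trios,
    simulate_weights,
)


def unselected(**kw) -> SimulationConfig:
    """Config whose referral rule keeps every family (no ascertainment)."""
    base = dict(n_families=2000, n_snps=60, n_adult_reference=500, referral_height_max=50.0, seed=13)
    base.update(kw)
    return SimulationConfig(**base)


def test_config_validation():
    with pytest.raises(ValidationError):
        SimulationConfig(pgs_variance_fraction=1.2)
    with pytest.raises(ValidationError):
        SimulationConfig(pgs_variance_fraction=0.7, familial_env_fraction=0.4)
    with pytest.raises(ValidationError):
        SimulationConfig(primary=DisorderModel(0.6, -2, 0.5), secondary=DisorderModel(0.5, -1, 0.5))
    with pytest.raises(ValidationError):
        SimulationConfig(allele_freq_range=(0.0, 0.5))


def test_config_yaml_round_trip(tmp_path):
    cfg = SimulationConfig(n_families=10, seed=99, monogenic=MonogenicModel(carrier_freq=0.05))
    p = tmp_path / "cfg.yaml"
    config_to_yaml(cfg, p)
    assert config_from_yaml(p) == cfg


def test_mendelian_consistency(trio_cohort):
    """Each child allele count is transmissible from the parental genotypes:
    c >= [mother==2] + [father==2] and c <= 2 - [mother==0] - [father==0]."""
    gm, gf, gc = (
        trio_cohort.mother_genotypes,
        trio_cohort.father_genotypes,
        trio_cohort.child_genotypes,
    )
    lower = (gm == 2).astype(int) + (gf == 2).astype(int)
    upper = 2 - (gm == 0).astype(int) - (gf == 0).astype(int)
    assert np.all(gc >= lower)
    assert np.all(gc <= upper)


def test_weights_scaled_to_unit_score_variance():
    cfg = unselected()
    weights, freqs = simulate_weights(cfg)
    var = np.sum(weights.frame["weight"] ** 2 * 2 * freqs * (1 - freqs))
    assert var == pytest.approx(1.0, rel=1e-10)
    # no strand-ambiguous pairs are generated
    pairs = set(map(frozenset, zip(weights.frame["effect_allele"], weights.frame["other_allele"])))
    assert frozenset("AT") not in pairs and frozenset("CG") not in pairs


def test_adult_reference_variance_structure():
    """Marginal height SDS ~ (0, 1); R^2 of height on the score ~ h2_pgs."""
    cfg = unselected(n_adult_reference=20_000)
    weights, freqs = simulate_weights(cfg)
    adults = simulate_adult_reference(cfg, weights, freqs)
    assert adults.height_sds.mean() == pytest.approx(0.0, abs=0.03)
    assert adults.height_sds.std() == pytest.approx(1.0, abs=0.03)
    r = np.corrcoef(adults.pgs_sds, adults.height_sds)[0, 1]
    assert r**2 == pytest.approx(cfg.pgs_variance_fraction, abs=0.02)


def test_per_snp_dosage_variance_binomial():
    cfg = unselected(allele_freq_range=(0.5, 0.5), n_adult_reference=30_000, n_snps=10)
    weights, freqs = simulate_weights(cfg)
    adults = simulate_adult_reference(cfg, weights, freqs)
    assert adults.genotypes.var(axis=0) == pytest.approx(0.5, abs=0.03)


def test_midparent_regression_slope_is_one():
    """Child raw score regressed on the midparent raw score has slope ~ 1."""
    cfg = unselected(n_families=20_000)
    cohort = simulate_trios(cfg)
    child = cohort.children["pgs_raw"].to_numpy()
    w = cohort.weights.frame["weight"].to_numpy()
    midparent = 0.5 * (cohort.mother_genotypes @ w + cohort.father_genotypes @ w)
    slope = np.polyfit(midparent, child, 1)[0]
    assert slope == pytest.approx(1.0, abs=0.05)


def test_child_pgs_variance_matches_parents():
    cfg = unselected(n_families=20_000)
    cohort = simulate_trios(cfg)
    w = cohort.weights.frame["weight"].to_numpy()
    v_child = cohort.children["pgs_raw"].var()
    v_parent = np.concatenate(
        [cohort.mother_genotypes @ w, cohort.father_genotypes @ w]
    ).var()
    assert v_child == pytest.approx(v_parent, rel=0.05)


def test_ascertainment_depresses_cohort_pgs(trio_cohort):
    """Referral on short stature selects for low polygenic scores."""
    assert trio_cohort.children["pgs_sds_true"].mean() < -0.3


def test_short_stature_prevalence_matches_normal_tail():
    """P(pediatric height <= -2) in the unselected population equals the
    analytic mixture of normal tails over generative causes."""
    from scipy.stats import norm

    cfg = unselected(
        n_families=50_000,
        monogenic=MonogenicModel(carrier_freq=0.0),
        visit_noise_sd=0.2,
    )
    cohort = simulate_trios(cfg)
    observed = (cohort.children["pediatric_height_sds"] <= -2.0).mean()

    base_sd = np.sqrt(1.0 + cfg.visit_noise_sd**2)
    p_causes = {
        "primary": cfg.primary,
        "secondary": cfg.secondary,
        "constitutional_delay": cfg.constitutional_delay,
    }
    p_none = 1.0 - sum(m.prevalence for m in p_causes.values())
    expected = p_none * norm.cdf(-2.0, 0.0, base_sd)
    for m in p_causes.values():
        sd = np.sqrt(base_sd**2 + m.deficit_sd**2)
        expected += m.prevalence * norm.cdf(-2.0, m.deficit_mean, sd)
    assert observed == pytest.approx(expected, abs=0.006)


def test_parental_reporting_noise_toggle():
    cfg = unselected(parental_report_sd=0.0, n_families=200)
    cohort = simulate_trios(cfg)
    ch = cohort.children
    np.testing.assert_array_equal(ch["mother_height_sds_reported"], ch["mother_height_sds_true"])
    cfg2 = unselected(parental_report_sd=0.3, n_families=200)
    ch2 = simulate_trios(cfg2).children
    assert (ch2["mother_height_sds_reported"] != ch2["mother_height_sds_true"]).all()


def test_gh_stim_values_exercise_recategorization(trio_cohort):
    ch = trio_cohort.children
    gh_cases = ch.loc[ch["clinical_subtype"] == "growth_hormone_deficiency", "gh_stim_max"]
    if len(gh_cases) >= 10:
        assert (gh_cases < 10).any() and gh_cases.notna().all()


def test_referral_rule_empty_cohort_errors():
    with pytest.raises(SimulationError, match="referral"):
        simulate_trios(unselected(n_families=50, referral_height_max=-30.0))


# ---------------------------------------------------------------------------
# Emission round trips
# ---------------------------------------------------------------------------

def test_emit_round_trip_csv(trio_cohort, study_dir):
    dosages = sp.pgs.read_dosage_csv(study_dir["child_dosages"], study_dir["child_alleles"])
    np.testing.assert_array_equal(
        dosages.dosages.to_numpy(), trio_cohort.child_genotypes.astype(float)
    )
    assert list(dosages.sample_ids) == trio_cohort.children["id"].tolist()


def test_emit_vcf_matches_csv(trio_cohort, tmp_path):
    paths = sp.simulate.emit(trio_cohort, tmp_path / "vcfstudy", dosage_format="vcf")
    from_vcf = sp.pgs.read_dosage_vcf(paths["child_dosages"])
    np.testing.assert_allclose(
        from_vcf.dosages.to_numpy(), trio_cohort.child_genotypes.astype(float), atol=1e-6
    )
    # REF/ALT carry the coding: ALT is the effect allele
    assert (from_vcf.alleles["coded"] == trio_cohort.weights.frame["effect_allele"].to_numpy()).all()


def test_phenotype_round_trip_recovers_sds(trio_cohort, study_dir, growth_ref, adult_ref):
    pheno = sp.cohort.load_phenotypes(study_dir["phenotypes"])
    participants = sp.cohort.participants_from_frame(pheno, growth_ref, adult_ref)
    got = np.array([p.initial_height_sds for p in participants])
    want = trio_cohort.children["pediatric_height_sds"].to_numpy()
    np.testing.assert_allclose(got, want, atol=5e-3)
    got_m = np.array([p.mother_height_sds for p in participants])
    np.testing.assert_allclose(got_m, trio_cohort.children["mother_height_sds_reported"], atol=5e-3)


def test_emit_deterministic(trio_cohort, tmp_path):
    a = sp.simulate.emit(trio_cohort, tmp_path / "a")
    b = sp.simulate.emit(trio_cohort, tmp_path / "b")
    assert (
        open(a["phenotypes"]).read() == open(b["phenotypes"]).read()
    )
    cfg2 = dataclasses.replace(trio_cohort.config)
    cohort2 = simulate_trios(cfg2)
    c = sp.simulate.emit(cohort2, tmp_path / "c")
    assert open(a["phenotypes"]).read() == open(c["phenotypes"]).read()
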