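# Methods

This note records the modeling choices behind `staturepgs`: the statistical
procedures, the generative model used for testing, the defaults and why
they were chosen, and what the synthetic results do and do not establish.

## Height standardization

Pediatric heights are standardized with the LMS method. The reference
table stores, per sex and age in months, the Box–Cox power *L*, median *M*
(cm) and coefficient of variation *S*; `z = ((x/M)^L − 1)/(L·S)` with the
log-limit branch at L = 0. L, M and S are **linearly interpolated in age**
between tabulated rows — the common convention among growth-reference
implementations, and the simplest rule that keeps z continuous in age.
Queries outside the tabulated age range are errors rather than
extrapolations. Ages are carried in months internally; the phenotype
reader converts years to months.

The repository does not ship official growth tables. A synthetic LMS table
(2–19 y, both sexes, smooth anchor-interpolated medians, S between 0.038
and 0.048) and a synthetic adult reference (male 176.1 ± 7.4 cm, female
162.6 ± 6.9 cm) are generated programmatically; they are deliberately
plausible but carry no claim of fidelity to CDC or NHANES values. Any
conforming CSV can be substituted.

## Polygenic score

The score is the weighted effect-allele dosage sum. Alignment policy:

- variants absent from either side are dropped (counted in the report);
- variants with imputation R² below 0.7 (configurable) are dropped;
- strand-ambiguous pairs (A/T, C/G) are dropped rather than
  frequency-matched — the in-house simulator never emits them, so
  ambiguity only arises with external inputs, where dropping is the
  conservative choice;
- dosages coded on the non-effect allele are flipped `d → 2 − d`;
- an allele pair matching neither orientation is dropped with a warning.

Missing dosages are mean-imputed per variant (equivalently, 2 × cohort
effect-allele frequency); the source data this emulates are fully imputed,
so the policy matters only for degraded inputs. Scores are standardized
against an external adult reference cohort (mean/SD with ddof = 1); the
referral cohort is never its own reference, since ascertainment on short
stature would shift the scale. Score orientation (higher = taller) is
inherited from the weight table; no re-orientation is applied.

Sample QC removes, in order: one random member of each pair with kinship
pi-hat > 0.2 (seeded RNG), samples with genotype missingness > 2%, and
samples whose heterozygote fraction (on rounded genotypes) lies more than
4 SD from the cohort mean. All thresholds are configurable.

The calibration model mapping PGS SDS to predicted adult-height SDS is
ordinary least squares with optional principal-component covariates and an
optional sex term (off by default; the pipeline's adult cohort is already
height-standardized by sex). At prediction time, missing PC values default
to 0, i.e. the reference-cohort centroid.

## Mid-parental height and classification

MPH on the SDS scale is `0.72 × mean(parental SDS)`; the 0.72 coefficient
shrinks the parental average toward the population mean to account for
imperfect parent–offspring height correlation. Missing parental heights
are an error (such participants are excluded upstream, not imputed).

Subtype precedence: clinical primary/secondary labels first, with one
exception — a secondary label of growth-hormone deficiency whose
stimulation maximum is ≥ 10 ng/ml becomes ISS-NF; then constitutional
delay (ISS-DP); then the MPH band splits label-free children into ISS-F
(|height − MPH| < 1.6) and ISS-NF. The boundary convention is chosen so
that the MPH-deviation flag (≥ 1.6) and ISS-F are exact complements for
label-free children; the band applies to the SDS-scale difference. Both
the band and the GH threshold are parameters.

Adult height is the median of available measurements (≥ 18 y), converted
to SDS on the adult reference; participants without measurements are
simply absent from adult-height analyses.

The single-variable classifier measure is *initial visit height SDS minus
PGS-predicted height SDS*: a strongly negative value means the child is
far shorter than their polygenic prediction, which flags a growth disorder
(the classification rule is "positive when ≤ threshold"). The MPH-based
analog substitutes the MPH prediction, and the averaged measure is the
unweighted mean of the two.

## Nonparametric comparisons

Wilcoxon signed-rank tests drop zero differences before ranking
(Wilcoxon's original treatment) and use the exact distribution for n ≤ 25
without ties, otherwise the normal approximation with continuity and tie
corrections; the switch point is configurable. Reported estimates are
medians of (differences from) the tested value. The paired effect size is
Cohen's d on paired differences — mean(diff)/SD(diff) — chosen as the most
common convention when d accompanies a paired test; a pooled-SD variant
would differ and neither is canonical.

Tukey's HSD uses the studentized-range distribution with the Tukey–Kramer
adjustment for unequal group sizes (via `scipy.stats.tukey_hsd`),
cross-checked in the tests against `statsmodels`' independent
implementation.

## Discrimination

Logistic models are fit by Newton/IRLS. The solver is hand-written and
deliberately small because the bootstrap machinery refits on the order of
10^5–10^6 models in a full run; it is validated against `statsmodels`
coefficients and standard errors in the test suite, and it raises on
complete separation instead of silently returning huge coefficients.

AUC is the Mann–Whitney rank statistic with ties counted one half, which
equals trapezoidal ROC integration (property-tested).

ΔAUC for a nested model pair refits **both** models inside every bootstrap
resample of participant rows (unstratified by default, matching the usual
practice; a stratified option exists). The interval is BCa: bias
correction from the bootstrap distribution's position relative to the
point estimate, acceleration from leave-one-out jackknife refits. The
two-sided p value is the smallest α at which the BCa interval excludes 0,
found by bisection. Resamples with a single outcome class or a
non-convergent fit are redrawn (at most 100 times, then an error).
Replicate counts default to B = 5000 and are reduced in tests and demos
for speed. Under a null (pure-noise added covariate) the interval is
conservative: in the packaged 200-replicate experiment it covered 0
essentially always, so the acceptance property asserts coverage ≥ 0.90.

Youden cutpoints maximize J = sensitivity + specificity − 1 over
thresholds placed midway between adjacent observed scores; ties on J break
toward the higher-specificity threshold (fewer false alarms in a referral
setting). Threshold-level metrics use percentile bootstrap CIs — BCa is
reserved for AUC quantities, percentile being the simpler default where no
convention is established. Directionality is explicit: `positive_low=True`
turns the rule into "flag when score ≤ t".

R² for adult-height prediction is plain OLS R² with a percentile bootstrap
CI over row resamples.

## Generative model (synthetic cohorts)

Per family: parental genotypes are Hardy–Weinberg draws at allele
frequencies uniform on (0.1, 0.9); the child receives one allele per
variant drawn uniformly from each parent's pair. Weights are Gaussian,
scaled so the raw score has unit variance under HWE. Adult height SDS is

```
height = √h²_pgs · PGS_sds + √c² · F + √(1 − h²_pgs − c²) · ε
```

with F shared within family and ε individual, so marginal variance is 1.
Defaults: **h²_pgs = 0.381** (the adult variance explained the analysis
assumes) and c² = 0.15, a moderate family-shared environment that makes
MPH informative beyond the genetic channel.

Disorders are assigned independently of the score: primary (prevalence
0.008, deficit N(−2.0, 0.5²), applied to adult potential), secondary
(0.045, N(−1.8, 0.5²), transient — pediatric height only), constitutional
delay (0.03, N(−1.2, 0.4²), transient). A monogenic layer (carrier
frequency 0.01 per parent, effect −2 SDS, transmission probability 0.5)
shortens carrier parents and makes transmitting children primary
(monogenic) cases. Secondary cases split into GH deficiency (45%, with
stimulation maxima drawn below 10 ng/ml except a 10% "misdiagnosed"
fraction drawn ≥ 10 to exercise the re-categorization rule) and systemic
disease. No quantitative generative model for these deficits exists in the
source literature; the values were chosen once so that the ascertained
cohort's subtype mix and height distribution resemble a published referral
cohort (≈60% ISS, median height ≈ −2 SDS), and are documented config
fields, not claims about any real population.

Reported parental heights add N(0, 0.2²) SDS noise (self-reported heights
are known to err by a few cm). Pediatric visit height is adult potential
plus transient deficits plus N(0, 0.2²) visit noise at an age uniform on
4–16 y. Referral keeps children with pediatric height ≤ −1.5 SDS (an
MPH-deviation OR-rule is available). PC covariates are independent
standard normals — population structure is deliberately not simulated.

What the simulator does **not** model: linkage disequilibrium, assortative
mating, imputation error, realistic growth curves, sex-specific genetic
effects, or correlated PC structure. Passing tests therefore demonstrate
the correctness and directional behavior of the *analysis machinery* under
the stated assumptions, not the calibration of any quantity in a real
clinic population.

## Problem sizes and numerics

Estimator-recovery checks use 30,000 synthetic adults (calibration R²) and
50,000 children (logistic odds ratio); shared test cohorts use 3,000
families with 60 variants and modest bootstrap counts, sizes at which
Monte-Carlo error is comfortably inside the asserted tolerances while the
suite stays quick. IRLS converges at step-norm < 1e−10 with a divergence
guard (|β| > 10⁴ or saturated logits) treated as separation. The LMS
transform switches to its log branch below |L| = 1e−12. Degenerate
bootstrap distributions collapse the BCa interval to a point; degenerate
Wilcoxon inputs (all values at the null) return p = 1 explicitly.

All randomness flows from seeded `numpy` Generators; simulation stages and
pipeline analysis blocks draw independent child streams from a single
master seed, so every report is byte-reproducible from config + seed.
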