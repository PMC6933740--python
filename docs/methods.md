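# Methods

## Scope

`petscreen` evaluates blood-based triage rules for amyloid-PET scanning in
clinically suspected early-stage AD (amnestic MCI and mild dementia; CDR
0.5, MMSE 20–30). Only the *analysis* layer is modeled: each subject enters
as a genotype label, a binary PET read, scalar plasma concentrations
(pg/ml) and optionally a global cortical SUVR. Image acquisition and
processing, assay chemistry and genotyping chemistry are out of scope.

## Generative model of the synthetic cohort

Subject-level data for this design are not publicly deposited, so the
package ships a generator calibrated to the published group summaries. Per
subject, in order:

1. **Genotype** from a categorical distribution over the six unordered
   APOE genotypes. Class masses are exact: P(ε4 carrier) = 14/52,
   P(ε2-only | non-carrier) = 7/38. The published material gives only class
   totals; the within-class split defaults to
   (ε3ε4 : ε4ε4 : ε2ε4) = (12 : 1 : 1) among carriers and all ε2-only mass
   on ε2ε3. The split is recorded in the config, overridable, and
   irrelevant to every class-level statistic.
2. **PET status** Bernoulli with the genotype-class rate: 12/14
   (carriers), 0 (ε2-only), 10/31 (ε3ε3).
3. **Plasma markers** from normals truncated below at `marker_floor`
   (default 1 pg/ml), with PET-conditional moments (pg/ml):

   | marker  | PET+        | PET−        |
   |---------|-------------|-------------|
   | Aβ1–42  | 16.3 ± 2.3  | 17.6 ± 3.3  |
   | Aβ1–40  | 50.9 ± 7.7  | 49.1 ± 7.3  |
   | tau     | 18.4 ± 8.5  | 22.5 ± 10.4 |

   Truncated normality is the minimal assumption consistent with the
   published mean ± SD summaries. For the two Aβ markers the floor sits
   more than 6 SD below the mean and truncation shifts the mean by
   < 0.01 pg/ml. For tau the floor is only ~2 SD below the mean, so the
   sampled tau mean exceeds the location parameter by ≈ 0.4–0.5 pg/ml;
   calibration checks for tau therefore compare against the analytic
   truncated-normal moments (the distribution actually drawn), not the
   location parameter.
4. **SUVR** jointly with Aβ1–42 through a Gaussian copula: with z₁ the
   standard-normal driver of Aβ1–42, SUVR = μ + σ(ρz₁ + √(1−ρ²)z₂). The
   within-group correlation targets are ρ = 0.387 (PET−) and −0.068
   (PET+). The SUVR marginals — PET− 1.00 ± 0.10, PET+ 1.35 ± 0.15 — are
   this package's own plumbing choice (plausible florbetapir
   whole-cerebellum-referenced values); only the correlations are
   calibration targets. Because Aβ1–42 truncation is negligible, the
   realized Pearson correlation matches the copula parameter to well
   within sampling error.
5. **Covariates** age ~ N(72.0, 8.8²) years, sex female with p = 0.423,
   education ~ N(11.4, 3.9²) years clipped at the 6-year inclusion
   minimum, MMSE ~ round(N(25.8, 2.8²)) clipped to 20–30, CDR ≡ 0.5.
   These are passthrough fields with no effect on markers: between-group
   covariate adjustment is reported in the source material without
   coefficients, so no covariate→marker dependence is identifiable.

Draw order is fixed, all randomness flows from one `numpy` Generator
seeded by the config, and the cohort CSV writer emits deterministic bytes,
so identical (seed, config) reproduces a cohort exactly. The config digest
(SHA-256 of the canonicalized config) is recorded in cohort provenance.

### Genotype–marker dependence

By default PET status fully mediates the markers: conditional on PET, a
carrier and a non-carrier have identical marker distributions. This keeps
the PET-conditional calibration exact, but it also means the two genotype
strata share one population Youden threshold, so the *ordering* of derived
stratum cut-offs is a coin flip. The observed data instead show ε4 carriers
with *higher* plasma Aβ1–42 than non-carriers (17.9 vs 16.7 pg/ml) despite
being mostly PET+ — which is exactly why the carrier cut-off (18.68 pg/ml)
exceeds the non-carrier one (15.58 pg/ml). `default_config(genotype_effects
=True)` enables additive per-class marker offsets calibrated to those class
means net of the PET mixture (Aβ1–42: +1.4 carriers, −1.1 ε2-only, −0.45
ε3ε3; analogous offsets for tau and Aβ1–40). With offsets on, the
carrier-vs-non-carrier cut-off ordering reproduces in ≳95% of seeds at
n = 2000; the marginal PET-conditional moments shift slightly, which is why
offsets are off in the calibration default. The true joint
genotype × PET × marker distribution is not identifiable from the published
marginals; the offsets are an explicit approximation.

What passing tests on these cohorts do **not** show: robustness to assay
drift or batch effects, non-Gaussian marker tails, covariate confounding,
or any longitudinal dynamics of plasma Aβ — none of which the generator
emulates.

## ROC, Youden selection and boundary conventions

Markers that fall with disease are oriented by the reciprocal transform
(1/Aβ1–42), and the ROC rule is *score ≥ threshold ⇒ screen-positive* over
every distinct observed score (ties collapse; sentinel +∞ anchors (0,0)).
AUC is trapezoidal and equals the all-pairs rank statistic exactly; this
equivalence is enforced in tests to 1e-12 against a brute-force oracle.

The Youden cut-off maximizes J = tpr − fpr with ties broken toward higher
specificity (screen-out efficiency matters most in a pre-screen), then
lower threshold; the tie-break rule is recorded in the result. Cut-offs sit
at *observed* score values, not inter-point midpoints — reproducible from
the ROC alone. Back on the pg/ml scale the replay convention is strict:
marker **<** cut-off screens positive, equality screens negative. One
consequence: a subject whose marker exactly equals a derived cut-off was
counted screen-positive by the ROC (score ≥ threshold) but screens negative
under replay. Exact ties are measure-zero in continuous data but the
behavior is deterministic and documented. Relatedly, the published
score-scale cut-off 0.064 (pg/ml)⁻¹ and marker-scale 15.58 pg/ml are not
exact reciprocals at printed precision (1/0.064 = 15.625); the marker-scale
values are treated as canonical for replay.

## Screening pathways

Pathways I–V as in the README. ε2ε4 is a carrier in all pathways (the ε2
override in pathway V applies only to ε4 non-carriers). Pathway I is kept
as the no-test baseline even though published accuracy tables begin at II:
the "prevalence → 70.4%" framing needs it. For a dichotomous rule the
report's AUC column is (SS+SP)/2 — the area under its two-point ROC. The
published per-pathway AUC row comes instead from continuous logistic-model
scores; both are computed here (cascade report vs `compare-auc`) and no
agreement is forced, since the published relationship between the two is
unspecified.

A known inconsistency the package reproduces rather than hides: the
published pathway II sensitivity (0.595) is incompatible with the printed
counts (12 of 22 PET+ subjects are carriers → 0.545);
`reconstruct_confusion(22, 30, {SS: 0.595}, 3)` returns an empty feasible
set, flagging the printed figure as a suspected typo, while all other
pathway II metrics are consistent with (tp, fp, tn, fn) = (12, 2, 28, 10).

## Confusion-matrix reconstruction

The inverse problem enumerates tp ∈ [0, n₊] × fp ∈ [0, n₋] and keeps every
table whose recomputed metrics round to the printed values at the stated
decimals. Rounding model: half-away-from-zero *or* half-to-even both count
as a match, since the source table's convention is unknown. Any subset of
{SS, SP, PPV, NPV, accuracy} may constrain the search; SS/SP prefilter
their own axes before pair-level metrics are checked. An empty feasible set
is an explicit "inconsistent" result carrying the nearest tables (minimum
max-absolute metric deviation), not an exception. At the study margins
(22, 30), over 95% of all 713 tables reconstruct uniquely from rounded
(SS, SP) at 3 decimals — uniqueness is checked, never assumed.

## Logistic models and AUC comparison

Risk models are plain maximum-likelihood logistic fits (no regularization)
of PET status on subsets of {ε4 indicator, ε2-only indicator, 1/Aβ1–42},
computed by IRLS/Newton with step-halving so the log-likelihood is
non-decreasing across iterations; convergence when the largest coefficient
change < 1e-8 (cap 100 iterations). ε2-only enters as a separate indicator
rather than an allele count, mirroring the cascade's categorical use of ε2.
Complete separation is detected (fitted probabilities pinned to the labels
without convergence) and flagged, never silently returned. Scores are
linear predictors — monotone in fitted probability, hence AUC-equivalent.

AUCs of two models on the *same* subjects are correlated; the comparison
method is DeLong's paired nonparametric test (the source material compares
correlated AUCs without naming its method): per-subject placement values
via midranks, variance/covariance of the placement means with n−1
denominators, z = (AUC_a − AUC_b)/√(var_a + var_b − 2cov), two-sided normal
p. Identical score vectors return z = 0, p = 1 by convention; a
zero-variance difference with unequal AUCs raises. A seeded paired
bootstrap (default 2000 resamples, class-degenerate resamples redrawn) is
included as a swappable sensitivity check. The exact published p-values
(0.014, 0.002, …) are not reproducible without raw data; the package
reproduces the qualitative ordering on calibrated synthetic cohorts.

## Problem sizes and tolerances in the test suite

Calibration checks use one n = 20 000 cohort (binomial/normal 3-SE bands;
correlation band ±0.03); the cut-off-ordering Monte-Carlo uses 100 seeds at
n = 2000 with genotype effects on; the DeLong null-rejection check uses
1000 replicates at 60+60 subjects against the band [0.03, 0.07] at
α = 0.05. Oracle equivalences: AUC to 1e-12 on 200 random tied instances
(n ≤ 30), Youden vs exhaustive scan including tie-breaks, IRLS vs BFGS on
the same likelihood to 1e-4, DeLong moments vs double-loop placements to
1e-12 on n ≤ 12. DeLong moment checks require ≥ 2 subjects per class — the
placement variance is undefined below that.

## Known limitations

* Marker distributions are truncated normals; heavy tails or skew in real
  IMR assay data are not represented.
* The genotype-offset mechanism is additive and class-level only; the true
  genotype × marker joint distribution is unidentified from published
  marginals.
* SUVR marginals are invented plumbing; only within-group correlations are
  calibrated.
* The no-covariate-effect assumption means covariate-adjusted analyses on
  synthetic cohorts are vacuous by construction.
* Published study AUCs (0.611/0.875/0.718/0.826) and the cut-off values
  themselves depend on the unavailable raw sample and are exercised only
  qualitatively.
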