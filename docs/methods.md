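# Methods

## Quantities and censoring

All concentrations are handled internally in mg/dl; the CSV reader rejects
malformed rows rather than guessing units.  For a patient with serum
K-FLC, CSF K-FLC, serum albumin and CSF albumin, the package computes the
albumin quotient `Q_alb = CSF alb / serum alb`, the kappa quotient
`Q_kappa = CSF K-FLC / serum K-FLC`, and the kappa index
`K-Index = Q_kappa / Q_alb`.  The index is scale-invariant in both
compartment pairs and reduces to a ratio of ratios; it is reported
unrounded internally and at 4 decimals in JSON reports.

CSF K-FLC values below the assay detection limit (default LOD
0.03 mg/dl) are censored.  The censoring policy replaces them with a
single empirical near-zero constant (default 0.0001 mg/dl) before any
downstream statistic, mirroring clinical reporting practice ("no evidence
of intrathecal synthesis").  The comparison is strictly `< LOD`: a value
of exactly 0.03 mg/dl is detectable.  With typical serum K-FLC
(0.5–3 mg/dl) and albumin quotients (0.002–0.01), an imputed record's
K-Index is at most 0.0001/(0.5·0.002) = 0.1, far below the smallest
clinical cutoff (3.045), so imputation can never create a screen
positive; this is property-tested.  Records carry an `imputed` flag so
reports can count them.

OCB positivity is ≥ 2 CSF-exclusive bands.  Band counts are stored, not
booleans, so boolean-only sources can be loaded as counts {0, 2} without
overstating information.

The hyperbolic barrier-reference curve
`Q_lim(kappa) = a·sqrt(Q_alb² + b²) − c` (intrathecal fraction positive
when `Q_kappa > Q_lim`) is implemented as a parameterised operation with
**no default constants**: the published K-FLC constants are not bundled,
and calling it without them raises a configuration error naming the
missing values.

## Accuracy statistics

Two endpoints are supported.  *MS vs non-MS* keeps only definitive
diagnoses (MS and other-disease controls; CIS, RIS and inconclusive cases
are excluded, giving n = 242 of 252 in the reference fixture).  *OCB
positive vs negative* keeps all records and requires an OCB result.

Contingency metrics use Wilson score intervals **without continuity
correction**, each on its own denominator.  This method was chosen
because it reproduces the reference intervals to four decimals
(40/45 → 0.7650–0.9516; 42/45 → 0.8214–0.9771).  One published interval
(44/45, upper bound 0.9989) is not consistent with any standard interval
we tested; Wilson gives 0.9961 and the lower bound matches exactly.
Bounds are clamped to [0, 1] against sub-epsilon numerical excursions.
LR+ at perfect specificity is reported as +infinity (rendered
`"Infinity"` in JSON), not an error; PPV/NPV with an empty predicted
class are flagged undefined rather than silently zeroed.

ROC curves use the classification rule `score > threshold`, consistent
with cutoff notation like "> 3.045".  Candidate thresholds are the
midpoints between adjacent distinct scores plus sentinels below the
minimum and above the maximum, so the (1,0) and (0,1) corners are always
present.  AUC is the tie-corrected probabilistic statistic, computed via
the midrank identity `U/(n₁·n₂)` and property-tested against brute-force
pairwise comparison.  The optimal cutoff maximises Youden
J = sensitivity + specificity − 1; ties break toward higher sensitivity
(screening favours not missing MS) and then toward the lower threshold.

Mann–Whitney comparisons are exact by full enumeration when the pooled
sample has ≤ 12 observations and no ties (validated against an
independent permutation oracle), and otherwise use the normal
approximation with midrank tie correction and continuity correction.
Study-scale cohorts always take the approximate path; the exact mode
exists to make the implementation testable against enumeration.

## Two-tier reflex algorithm

Tier 1: undetectable CSF K-FLC → stop, report no evidence of intrathecal
synthesis.  Tier 2: detectable but K-Index ≤ cutoff (default 3.045) →
stop.  Otherwise reflex to OCB, which determines the final result.  The
tier-2 rule uses `≤` so that "higher than the cutoff" is what triggers
reflex testing.

Strategy evaluation (`ocb_only`, `tier1_only`, `tier1_plus_kindex`)
counts spared tests over the **full cohort** but computes the strategy
confusion matrix on the **definitive-diagnosis subset** (MS vs OTHER),
since isolated syndromes and inconclusive cases have no reference label.
This mixed convention is what simultaneously reproduces the reference
spared fraction (173/252 = 68.7%) and the tier-1-only metrics
(specificity 0.9239, PPV 72.73%, NPV 97.33%).  A strategy is positive for
a patient only if the patient is reflexed *and* OCB-positive; reflexed
patients without an OCB result are counted as pending and excluded from
the matrix with a logged count, never imputed.  Time/cost savings are a
linear per-test model (`spared × rate`); per-test rates are required
configuration with no defaults, because the published aggregate savings
imply mutually inconsistent per-test rates (154.56 h/160 tests vs
167.56 h/173 tests).

## Deterministic count fixture

`count_fixture()` reconstructs a 252-patient cohort from the published
stratum counts of the validation cohort: 45 MS / 1 CIS / 2 RIS /
7 inconclusive / 197 other; 160 censored (157 other, 2 inconclusive,
1 MS); 92 detectable (62 OCB+, 30 OCB−); 65 OCB+ (40 MS, 2 RIS, 1 CIS,
4 inconclusive, 18 other — 3 of them censored, none MS); 44/42/41 MS and
27/25/19 non-MS above the cutoffs 3.045/6.6/12.58; 13 detectable
patients at or below 3.045; 61/59/58 OCB+ above the same cutoffs.  The
full joint table (diagnosis × censoring × OCB × K-Index stratum) was
derived by hand so that **all** of these marginals hold simultaneously;
the test suite asserts each one.  Two source statements about the same
cell conflict (3 vs 13 OCB+ non-MS patients above 6.6); the value 13 is
the one consistent with the OCB-endpoint contingency columns and is
used.  The published text also rounds 160/252 inconsistently (63.4% and
63.8%; it is 63.49%) — the fixture uses the count.

Within a stratum, individual measurement values are synthetic
representative constants (e.g. K-Index 2.0 for the detectable ≤ 3.045
stratum, 60 for MS above 12.58), back-computed into a consistent set of
serum/CSF concentrations; only stratum membership is meaningful, and
tests rely on nothing else.  The three individually reported MS patients
(censored with negative OCB; K-Index 4.48 at CSF K-FLC 0.07 mg/dl;
K-Index ≈ 3.26 at 0.12 mg/dl with positive OCB) are included as
described.

## Synthetic cohort generator

`generate(GeneratorConfig(...))` draws a suspected-MS referral cohort.
Diagnosis labels are multinomial (defaults 45/252 MS, 1/252 CIS, 2/252
RIS, 7/252 inconclusive).  A latent intrathecal-synthesis state S is
drawn per patient with diagnosis-dependent probability (defaults: MS
0.93, CIS/RIS 1.0, inconclusive 0.6, other 0.12); S selects the high or
low log-normal component for CSF K-FLC (medians 0.26 and 0.006 mg/dl,
log-sd 1.1 and 1.3) and drives OCB positivity (0.9 given S, false-band
rate 0.02, band count 2 + Poisson(3), single sub-threshold band with
probability 0.08 otherwise).  Serum K-FLC (median 1.1 mg/dl, log-sd
0.35), the albumin quotient (median 0.004, log-sd 0.45) and serum
albumin (normal 4400 ± 350 mg/dl, truncated at 2000) are independent;
CSF albumin is derived as `Q_alb × serum albumin`.  Values below the LOD
are emitted as censored.

Log-normal families were chosen because all quantities are strictly
positive with heavy right tails consistent with the reported ranges
(non-MS K-Index maximum ≈ 479 is reachable in the low-state tail).
Medians sit at the reported group medians; log-sds were set once so that
roughly ±3 sd covers the reported min–max ranges and the censored
fraction lands near the reported 160/252 ≈ 63.5%.  Routing OCB through
the latent state, rather than through the K-Index itself, produces the
observed discordant cells (OCB+ with censored K-FLC; OCB− with high
K-Index).

What the generator does *not* emulate: assay measurement error and
batch effects, age/sex structure, correlation between serum K-FLC and
barrier function, longitudinal CIS→MS conversion.  Passing calibration
tests therefore show that the pipeline recovers the parameters of this
idealised model, not that it would reproduce any particular clinical
cohort's values.  Consistent with that, the reported clinical AUCs
(0.9533 MS, 0.9622 OCB) and group medians depend on unreleased
patient-level values and are **not** point targets anywhere; the suite
instead checks the machinery against independent oracles (pairwise AUC,
coverage simulation, permutation enumeration, closed-form censoring
probability, a 10× Monte-Carlo score-distribution oracle).

## Problem sizes and numerics

The suite's stochastic checks use n = 252 cohorts for censoring-fraction
bands (tolerance ±0.07 ≈ binomial noise at that size), n = 5,000 for
median calibration (factor-of-two band, since only medians are pinned)
and a single n = 20,000 cohort for parameter recovery (censoring within
3 binomial sd of the closed-form mixture probability; AUC within 0.03 of
the Monte-Carlo oracle).  `scripts/acceptance.py` uses the same sizes.
All randomness flows through `numpy.random.default_rng` seeded from
configuration; identical config and seed give byte-identical cohorts and
CSV output.

## Known limitations

* The clinical-override pathway ("test anyway on strong suspicion") is
  representable only by the caller choosing not to screen; there is no
  modelling of it.
* The intrathecal-fraction check is inert until the caller supplies the
  hyperbolic constants; concordance with the reflex algorithm is
  therefore not validated here.
* Monetary/time savings are a linear per-test model only.
* Lambda free light chains, IgG indices and instrument-level analytics
  are out of scope.
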