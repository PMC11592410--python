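# Methods

## Problem and model

`fibrotriage` implements the non-invasive assessment of advanced liver
fibrosis (NASH CRN stage F3–F4) in metabolic dysfunction-associated
steatotic liver disease (MASLD). Three serum indices are computed from
routine labs:

- APRI = (AST / ULN) / platelets × 100, with the AST upper limit of normal
  defaulting to 40 U/L but carried as configuration (`ReferenceRanges`)
  because laboratories differ;
- FIB-4 = age × AST / (platelets × √ALT);
- NFS = −1.675 + 0.037·age + 0.094·BMI + 1.13·[IFG or diabetes]
  + 0.99·(AST/ALT) − 0.013·platelets − 0.66·albumin.

The ELF test is a proprietary combination of three matrix-turnover analytes
(TIMP-1, hyaluronic acid, PIIINP); its combination formula is not public, so
ELF is consumed as a given number on the patient record and never computed.
Likewise ARFI elastography (shear-wave speed, m/s) is consumed as a
measurement. Missing optional biomarkers are represented as `None`, never
sentinel numbers; any operation that needs one fails loudly, or excludes
the subject, per an explicit missing-data policy.

## Sequential triage

A pathway is an ordered list of stage rules. Each rule reads one marker and
has a low and a high cutoff: below the low cutoff the subject is ruled out,
at/above the high cutoff ruled in (rule-in is the biopsy/referral trigger),
and the zone in between advances to the next stage. Boundary inclusivity is
an explicit per-rule field because published thresholds mix conventions; the
defaults are:

- FIB-4 ≥ 1.30 enters the pathway (inclusive low), rule-in only strictly
  above 2.67;
- ELF ≥ 9.8 rules in (inclusive); the single-test ELF screen at 9.6 is
  exclusive (positive strictly above);
- in the three-step pathway, ELF < 7.7 rules out, 7.7 ≤ ELF < 9.8 goes to
  ARFI, and ARFI ≥ cutoff rules in.

Whether subjects with FIB-4 above 2.67 are ruled in directly or also routed
through ELF is genuinely ambiguous in practice, so both readings are
first-class variants (`elf_on_indeterminate_only`, the default, and
`elf_on_all_fib4_positive`); reports record which was used.

The ARFI cutoff has **no default**: shear-wave values vary between devices
and no consensus threshold exists, so constructing a three-step pathway
without an explicit cutoff is a configuration error.

Residual indeterminates (possible only under `keep_indeterminate`) and
subjects excluded for missing markers are kept out of the confusion matrix
and reported separately: folding them into either margin silently distorts
sensitivity or specificity. Flow accounting preserves subjects stage by
stage (rule-out + advance + rule-in = entering, always), and the
"biopsies avoided within the indeterminate zone" statistic counts rule-outs
among subjects who advanced past stage 1, divided by the stage-2 entrants.

## Diagnostic-accuracy statistics

All statistics use the empirical (nonparametric) ROC model with the
orientation fixed as "higher score = more diseased", which holds for APRI,
FIB-4, NFS and ELF. An AUROC below 0.5 is reported as-is with a warning,
never auto-flipped.

- **AUROC** is the Mann–Whitney statistic with ties counted ½, computed by
  the midrank formula; the stored operating points are the exact empirical
  step function, whose trapezoidal area equals the same number.
- **Youden cutoff** maximizes J = sensitivity + specificity − 1 over the
  observed score values with strict ">" positivity (matching the convention
  of quoting a cutoff as "positive above c"); ties in J break toward higher
  sensitivity, then the smaller cutoff. Midpoints between observed values
  are available as an option, not the default.
- **DeLong variance** uses the structural components (per-positive and
  per-negative placement values) with unbiased (n−1) sample variances — the
  original formulation is sometimes coded with n, so this is stated
  explicitly. The 95% CI is the normal approximation, clipped to [0, 1].
  Exact replication of any particular commercial package's CI method is a
  non-goal.
- **The paired DeLong test** estimates the covariance of two AUROCs from
  the paired placements; identical score vectors give p = 1 by definition,
  and a zero-variance difference with nonzero delta reports p = 0 with a
  warning rather than a division error.
- **Predictive values** follow Bayes' theorem; PPV/NPV computed from a
  confusion matrix agree exactly with the Bayes formula evaluated at that
  matrix's own prevalence, and every report row is checked for this
  consistency.
- **Spearman correlation** with ordinal stage is the Pearson correlation of
  midranks with a t-approximation p (n−2 df).
- Undefined ratios (empty margins, zero rank variance) are NaN, never 0.
  p-values are kept at full precision; truncated rendering ("p < 0.0001")
  is a display concern only.

## Synthetic cohorts

No patient-level data are deposited for the reference study, so the
generator emulates its published group structure: 28 subjects with advanced
fibrosis (stages drawn F3:F4 = 26:2) versus 125 without (F0:F1:F2 =
69:44:12), with per-group means and SDs for age, BMI, AST, ALT, platelets,
ELF and the serum indices taken from the published characteristics table
(e.g. ELF 10.11 ± 1.15 vs 8.70 ± 1.00).

Only the first two moments are published, so the distribution family per
variable is the generator's honest degree of freedom, chosen once:

- **normal** for ELF and NFS (symmetric; SD ≪ mean or unbounded sign);
- **lognormal**, matched by moment inversion, for AST, ALT, APRI and FIB-4,
  whose published SDs approach their means (right skew) and which must stay
  positive;
- **truncated normal** for age (floor 18), BMI (floor 15) and platelets
  (floor 50), near-symmetric variables with physiologic floors. The floors
  sit ≳3 SD from the means, so the truncation bias on the matched moments
  is negligible.

Albumin is not tabulated per group; physiologic values are used (3.9 ± 0.5
advanced, 4.1 ± 0.4 g/dL non-advanced). ARFI is likewise untabulated and
device-dependent; typical shear-wave values (2.2 ± 0.6 vs 1.35 ± 0.40 m/s)
are supplied so three-stage pathways are exercisable. The IFG-or-diabetes
flag prevalence (0.75 / 0.70) combines the published per-group diabetes
prevalence with the overall impaired-fasting-glucose fraction. Sex is drawn
from the published counts (10/28 and 70/125 male).

Variables are independent by default; a Gaussian-copula knob can impose an
AST–ALT rank correlation for stress tests. Scores can be *derived* from the
generated labs through the scores module (the end-to-end mode) or
*simulated directly* from the published index distributions
(`simulate_scores`, for tests that need index moments exactly); which mode
produced a result is recorded in the report metadata.

What passing tests on synthetic cohorts do **not** show: the generator has
no real-data correlation structure between indices (a subject's FIB-4 and
ELF are conditionally independent given group), no assay noise model, and
no covariate-dependent fibrosis risk — so absolute agreement with any
particular real cohort's triage flow (e.g. its indeterminate-zone fraction)
is not expected, only the distribution-level quantities (AUROCs, operating
characteristics at the published cutoffs).

The closed-form binormal AUROC Φ((μ₁−μ₀)/√(σ₁²+σ₀²)) serves as the
analytic oracle: for the ELF parameters above it equals 0.8226, and the
mean empirical AUROC of generated cohorts must recover it within
Monte-Carlo tolerance.

## Numerical and design choices

- Scores are full precision internally; rendered tables round AUROC to 3
  decimals and percentages to 2.
- Candidate Youden cutoffs and tie-breaks are as above; degenerate inputs
  (single-class label vectors, all-tied scores, fewer than 2 subjects per
  class for a DeLong variance, fewer than 3 for a rank correlation) raise
  domain errors rather than returning silent defaults.
- The default evaluation target is advanced fibrosis (F3–F4); significant
  fibrosis (F2–F4) is a flag. Subjects missing a marker are excluded from
  the affected analysis only, with counts reported.
- Problem sizes in the test suite: oracle-equivalence checks run 500 small
  random instances; bootstrap and permutation cross-checks of the DeLong
  estimators use 10,000 replicates at the study's 28+125 scale; the
  simulation-recovery check averages 1,000 cohorts. These sizes give
  Monte-Carlo error comfortably below the asserted tolerances.
- Runs are reproducible: one integer seed drives cohort generation, and the
  machine-readable outputs of a run are byte-identical across repeats of
  the same config and seed.

## Known limitations

- ELF and ARFI enter only as numbers; assay analytics and elastography
  physics are out of scope, as are VCTE/MRE, cost-effectiveness modeling
  and figure replication.
- The DeLong CI is a normal approximation; small-sample or
  near-boundary (AUROC → 1) coverage is approximate, as the collapse to a
  degenerate CI under perfect separation makes explicit.
- Several published operating characteristics of the reference study are
  internally inconsistent with their own sensitivity/specificity/prevalence
  under Bayes' theorem (its two-step PPV and accuracy, its single-ELF NPV,
  and its two biopsy-avoidance percentages, which use irreconcilable
  denominators). These are treated as known discrepancies of the source,
  not targets: the package reports raw counts so either reading can be
  inspected, and asserts only the arithmetically determined quantities.
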