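# Methods

## Data model

A patient record holds LGE scores on the standard 17-segment AHA
left-ventricular model (6 basal, 6 mid, 4 apical segments, true apex) and a
7-segment right-ventricular model numbered 18–24. Each LV segment carries at
most one dominant transmurality class — subepicardial, mid-myocardial,
subendocardial, or transmural; RV segments are presence-only, since
transmurality cannot be graded reliably in the thin RV wall. Five boolean
flags record extra-ventricular LGE (atrial, valvular, papillary muscle,
moderator band) and the Whale's Tail sign.

The RV numbering convention is: 18 basal inferior, 19 basal lateral (the
inlet), 20 RV outflow tract (the outlet), 21/22 mid inferior/lateral,
23/24 apical inferior/lateral (the apex). No universal RV segmentation
standard exists; the criterion segment set {18, 19, 20, 23, 24} is therefore
a `PaduaConfig` value rather than a constant.

Junctional (septal insertion-point) enhancement is common in healthy
subjects and is never a pathological finding here. It is handled upstream
of every rule: a record may carry the `junctional_only_septal_lge` flag,
but junctional LGE is never entered in the segment map, and validation
rejects records that set the flag while also recording septal segmental
LGE. Consequently no classifier or feature needs a special case.

Each recorded segment is assumed confirmed in two orthogonal views; an
`unconfirmed` per-segment override excludes segments from the Padua rules
when that assumption fails.

## Classifiers

Four binary classifiers target the ARVC-vs-differential question: any
RV-LGE, any LV-LGE, RV-LGE per Padua (≥1 criterion-set RV segment), LV-LGE
per Padua (≥1 subepicardial or mid-myocardial segment among LV 1–16; the
true apex never qualifies). ARVC is the positive class throughout. The
joint Padua category (both / LV only / RV only / neither) partitions any
cohort.

The fixed published decision tree ships as a JSON asset. Its split
conditions are: anteroseptal LV-LGE at the root; absent → extensive
(≥5 segments) mid-myocardial LV-LGE → myocarditis, else moderate
(≥2 segments) mid-myocardial → DCM, else ARVC; present → extensive
(≥16 segments) LV-LGE → amyloidosis, else moderate (≥2 segments) RV-LGE →
sarcoidosis, else inferolateral LV-LGE → ARVC, else DCM. Count thresholds
are inclusive (`>=`). The published flowchart names the split conditions
and the per-differential discriminators but not every leaf label; the leaf
assignment of the final inferolateral split is a reconstruction and is
flagged as such in the asset's metadata. The "moderate RV-LGE" count uses
all 7 RV segments (whether it should count only criterion segments is
unstated; this is configurable by editing the tree JSON, which is validated
on load against the feature schema).

## Diagnostic metrics and tests

Sensitivity, specificity, accuracy, PPV and NPV are computed from exact 2×2
counts; a metric whose margin is empty is reported as undefined (`None`),
never as zero. Confidence intervals use the Wilson score method, which
behaves well at extreme proportions and the small group sizes typical of
these cohorts (n = 13–55). Displayed percentages round half-up to whole
percent; full-precision proportions are always carried alongside.

2×2 comparisons offer uncorrected Pearson chi-square, Yates-corrected
chi-square, and the two-sided Fisher exact test (summation of tables no
more probable than observed); the automatic rule uses Fisher when any
expected cell is below 5. Both chi-square variants are exposed because
printed p-values in this literature are reproducible only under a specific
variant — on the cohort's RV-LGE margins, 0.027 arises from the uncorrected
Pearson statistic and 0.034 from the Yates-corrected one — and the package
records which test reproduces which value rather than asserting a single
author choice. Rank comparisons are Mann-Whitney U (two groups) and
Kruskal-Wallis (more), mid-ranks for ties, as implemented in scipy.

Bonferroni thresholds are per table: alpha divided by the number of tested
rows, displayed rounded half-up to 3 decimals (0.05/12 → 0.004, 0.05/15 →
0.003, 0.05/26 → 0.002). Cohen's kappa is computed from the agreement
table, with Altman-style qualitative bands; two constant, identical raters
give kappa = 1 by convention, with a warning.

## CART learner

The tree learner is written from first principles so that every numeric
convention is explicit:

* impurity: Gini (the canonical CART default), decrease computed from
  integer class counts as `(S_L/n_L + S_R/n_R − S/n)/n` with S the sum of
  squared counts — ties are then exact in floating point;
* split candidates: midpoints between consecutive distinct observed values
  per feature (booleans split at 0.5); exhaustive search;
* tie-breaks: lexicographically lowest feature name, then lowest threshold;
  leaf labels by majority, ties to diagnosis declaration order — builds are
  bit-reproducible;
* stopping: min node size 5, min impurity decrease 1e−9, max depth 6;
* pruning: weakest-link cost-complexity path (nested subtrees, strictly
  increasing α); candidate penalties are geometric means of consecutive
  path values; selection by minimum stratified k-fold CV misclassification
  error (ties to the smaller tree), with the 1-SE rule available but off by
  default to match selection by lowest error estimate;
* no class weighting: empirical priors.

The default predictor set is the ventricular feature vector (region
presence flags, segment counts, mid-myocardial count). The
extra-ventricular flag is excluded by default — the published analysis
evaluated RV- and LV-LGE parameters, and the published tree contains only
ventricular features — but any feature list can be passed explicitly.

## Synthetic cohorts

`generate_cohort` emulates the *marginal* structure of the study: for each
diagnosis, per-segment LGE probabilities equal to the published per-segment
rates (e.g. basal anteroseptal LGE in 100% of amyloidosis, 3.6% of ARVC
patients), transmurality mixtures with the published dominant weights
(ARVC 79% subepicardial; DCM 77% and myocarditis 66% mid-myocardial;
amyloidosis 63% transmural), and the published extra-ventricular flag
rates. Within a patient, segments are tied by a single latent severity
factor: segment s is positive iff `sqrt(ρ)·z + sqrt(1−ρ)·ε_s` falls below
the p_s-quantile of a standard normal. This Gaussian one-factor copula
preserves every marginal exactly for any ρ while concentrating enhancement
in high-severity patients; ρ defaults to 0.4 because fully independent
segments would understate the prevalence of extensively enhanced patients.
Remaining transmurality mass (beyond the published dominant weights) and
the sarcoidosis mixture are unpublished and set to clinically plausible
values; they are declared once in `_TRANSMURALITY_MIX`.

What the generator does **not** emulate: wall-level spatial contiguity of
enhancement (a real patient's LGE clusters in neighbouring segments; here
only a global severity factor correlates them), reader variability, and
any dependence between segmental LGE and ventricular function. Tests that
pass on generated cohorts therefore validate marginal behaviour and
algorithmic correctness, not the true joint distribution of disease.

Default group sizes are the study's (55/25/13/20/19). For tree
re-derivation experiments the cohort is scaled *proportionally*
(`scaled_by`), preserving the empirical class priors the CART uses — an
equal-groups design shifts the ARVC prior from 42% to 20% and materially
changes which split wins the root.

## The fixture cohort

`build_fixture_cohort` solves the printed margin equations exactly: per
diagnosis, patients are allocated to joint cells over (RV state: Padua /
non-criterion-only / none) × (LV state: Padua / non-qualifying-only / none)
× (any extra-ventricular LGE). The per-diagnosis "both Padua" cells are
bounded by Fréchet-style inequalities; within those bounds the published
cohort-level total (43) is met by a deterministic greedy in diagnosis
order. Two published counts are only available at coarser granularity and
are fixed by documented choice: the Padua-RV split across the non-ARVC
groups (set to DCM 3 / myocarditis 9 / sarcoidosis 16 / amyloidosis 15,
which also realizes the published ARVC-vs-DCM specificity of 88% for the
Padua RV rule) and the per-diagnosis "both" allocation. Infeasible
constraint edits raise an error naming the violated identity.

Each cell is realized by a canonical minimal pattern (criterion RV LGE via
segment 18; non-criterion RV via segment 21; Padua LV via a qualifying
class at basal inferolateral; non-qualifying LV via a transmural entry).
With `extended=True`, the realization instead distributes segments by a
least-loaded greedy so that per-segment marginals match the published
per-diagnosis counts wherever the cell structure allows, with a residual
report; under the default constraints all 145 per-segment/flag marginals
are met exactly. The construction is self-verifying: `check_constraints`
re-derives every count from the finished cohort through the public
classifiers.

Median segment counts are properties of the generator's mixture, not
fixture targets (medians do not decompose into margins). The patient order
is shuffled by the seed; all counts are seed-invariant.

## Problem sizes

The test suite runs the split-search oracle on 1,300 random nodes of up to
30 samples, tree re-derivation on ten simulated cohorts of ~2,500 patients,
and marginal-recovery checks at 10,000 patients per diagnosis — sizes at
which binomial standard errors make the 4·SE acceptance bands meaningful
while the full suite stays fast.

## Known limitations

* The published tree's performance on the original cohort (sensitivity
  93%, specificity 78%) cannot be recomputed here: the patient-level data
  are not public, and the fixture pins margins, not the joint feature
  distribution the tree exploits. The package instead proves the tree
  implements the published split conditions exactly (exhaustive lattice
  test) and evaluates it on synthetic cohorts.
* The RV segment numbering and the final tree leaf are documented
  conventions, not published facts (both are configurable data).
* Genotype is modelled only as a positive/unknown flag on ARVC patients
  (40 of 55), sufficient for the genotype-positive sensitivity filter but
  not for genotype-phenotype analyses.
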