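# Methods

## Overview

`neglectmap` implements a subtype analysis of visuospatial neglect (VSN): 18
behavioral variables are extracted from two touch-screen attention tasks and
the Behavioural Inattention Test (BIT), reduced by PCA on the correlation
scale, clustered with Gaussian mixtures selected by BIC/ICL, compared with
nonparametric group tests, related to lesion anatomy through overlap and
subtraction maps and voxel-based lesion–symptom mapping (VLSM), and tracked
longitudinally by projecting repeated assessments through the frozen
cross-sectional models.

## Task geometry and variables

The target grid is 5 rows × 7 columns = 35 targets, numbered row-major with
the left-top target 1 and the right-bottom target 35. Columns 1–3 form the
left hemispace (15 targets), column 4 is the midline and belongs to neither
hemispace, columns 5–7 the right hemispace. Only this layout is consistent
with the ±15 range of the left−right miss differences.

Two readings in the variable definitions deserve note:

* **Miss counts (`MSc_En`, `MSc_Ex`).** "Targets minus count of selections"
  is read as *distinct* targets selected; raw selection counts (with
  repeats) enter only the `%ReSel` denominators. Any other reading would let
  the count leave its 0–35 range.
* **Midline crossings (`CrossMid`).** Reselections are removed first (the
  sequence is deduplicated to first occurrences), midline-column targets are
  transparent, and the remaining consecutive pairs are counted when their
  hemispaces differ. A midline target can neither create nor break a
  crossing.
* **`%ReSel_L`.** The left-space reselection rate uses the left-restricted
  denominator (reselections of left targets / selections of left targets),
  the reading that parallels the global formula applied to the left
  subspace. A global-denominator variant is available via
  `resel_left_denominator="all"` since the wording admits both.

Undefined quantities — ratios over empty hemispaces, statistics of an empty
log — propagate as NaN with no silent imputation; PCA then uses complete
cases and logs what was dropped and why.

## PCA and component retention

Variables mix milliseconds, counts and ordinal scores, so the decomposition
is of the correlation matrix (z-scores, SD with one delta degree of
freedom). The sign of each loading column is fixed by making its
largest-magnitude entry positive, so a fit is bit-reproducible. Retention
combines the Kaiser rule (eigenvalue > 1) with a cumulative-variance
threshold (default 0.70): the retained count is the smallest K whose
cumulative proportion reaches the threshold while the K-th eigenvalue still
passes Kaiser; when the two criteria conflict the Kaiser count wins with a
warning, floored at one. No rotation is applied (a varimax step would break
the variance-ordering identities the tests rely on, and the unrotated
solution is what downstream clustering consumes).

## Mixture clustering

Candidates cross G = 1..10 with six covariance families (spherical,
diagonal, full × shared/free), 60 models. Each is fit by EM: k-means++
centers, hard one-hot initialization softened by 1%, relative
log-likelihood tolerance 1e-6, at most 300 iterations, 10 restarts, variance
floor 1e-6. A restart in which any component's weighted count falls below
two is rejected as degenerate — such components collapse onto the variance
floor and spike the likelihood, which otherwise drives selection toward
spurious extra clusters. With a variance floor the objective can drift
below tolerance on within-component dimensions of zero spread; the stop rule
therefore triggers on signed improvement below tolerance.

Selection: `BIC = 2·loglik − m·log N` and `ICL = BIC − 2·Σ entropy of
responsibilities` (higher is better for both, so ICL ≤ BIC always). The
selected model maximizes ICL among candidates within a BIC tolerance window
(default 10) of the best BIC; ties break toward fewer components, then the
simpler family. The policy is explicit and configurable because "use both
criteria" does not by itself resolve conflicts.

## Group statistics

Kruskal–Wallis per retained component uses the tie-corrected H with the
upper tail of χ²(k−1); the effect size is reported as r = √(H/(N−1)) and the
formula travels with the result, since several r conventions circulate.
The Steel–Dwass post hoc computes, for each pair of clusters, the
tie-corrected standardized rank-sum statistic t and refers √2·|t| to the
studentized-range distribution with k groups and infinite degrees of
freedom; for k = 2 this reduces exactly to the two-sided rank-sum test.
Totally tied data are flagged degenerate with p = 1 rather than an error.

## Lesion analyses

All volumes must share one voxel grid; spatial normalization is upstream.
Overlap maps are 100 × (lesioned count / group size) per voxel. Subtraction
maps are differences of overlap percentages, thresholded one-sidedly at a
≥50 percentage-point criterion (both directions reported) — a deliberately
conservative criterion for small groups. Region summaries report the
maximum and mean map value per atlas region with a "dominant" flag at ≥50;
a box-parcel toy atlas with perisylvian/temporal/parietal region names
supports tests and synthetic cohorts. In the pipeline, the subtraction
contrasts target the three most impaired clusters — ranked by mean
first-component score, since cluster numbering is arbitrary — as
most-impaired minus (second ∪ third) plus the two pairwise directions
between the second and third. Cosine similarity between maps is the flattened-voxel
cosine, 0 (flagged) for empty maps.

VLSM tests each voxel lesioned in ≥ 5 patients (and spared in ≥ 2),
comparing the behavioral score of lesioned vs spared patients with the
Brunner–Munzel test by default — robust to the non-normal PC-score
distributions mixtures produce — with Welch's t as an option; the default
threshold is uncorrected α = 0.05 with optional max-statistic permutation
familywise correction. Voxel coordinates are 0-based, axis order as stored
in the NIfTI header.

## Longitudinal projection

The cross-sectional PCA and mixture are frozen; later assessments are
standardized with the stored means/SDs, projected on the retained loadings,
and scored against the fixed components. Hard labels are maximum posterior
with no hysteresis; a confidence flag marks timepoints whose maximum
posterior falls below 0.5. Timepoints with missing variables are flagged
and skipped, never imputed. Freezing guarantees that adding timepoints can
never alter the cross-sectional solution or another patient's labels.

## Synthetic cohorts

The generator emulates the *statistical* structure of neglect behavior, not
its psychophysics: per-column probabilities that a target is never found
(endogenous) or a flash is missed (exogenous), an additive left reaction-time
gradient in ms per column from the right edge, a reselection probability
realized as a geometric run of repeats after each completed selection
(optionally drawn from one hemispace), a categorical initial-position
distribution, a column- or row-wise or random exploration order, truncated
rounded-normal BIT scores, and lesion probability elevated within spherical
foci over a Bernoulli background. Reaction-time noise is log-normal
(mean-preserving), keeping times positive and right-skewed so the RT
standard deviation stays meaningful. The exogenous task is simulated as 35
single-target flashes — one per target, random order, response timeout
configurable — which matches the 0–35 range of the exogenous miss count.

The default six-subtype cohort mirrors the canonical clinical contrasts:
subtype 1 is globally slow with bilateral misses, right-space-only
reselection and very low BIT (low arousal/attention); subtype 2 carries a
strong left RT gradient and left-space misses (exogenous neglect); subtype 3
reselects heavily in both hemispaces with near-normal BIT (spatial working
memory deficit); subtypes 4 and 5 show the same subtle left slowing but
opposite initial-selection bias (habitual bottom-right vs top-left start,
row- vs column-wise exploration); subtype 6 performs cleanly. Prevalences
follow the 6/20/8/50/22/16 of 122 split, and the BIT subtest means are
anchored to the published per-cluster BIT medians (≈26, 102, 122, 127, 131
and 143 of 146), which keeps the severity axis from absorbing all variance.
Start positions are concentrated (90/10) because a patient's habitual
starting corner is consistent, and the right-bias subtype starts at the
bottom-right corner: the raw initial-position index interleaves left- and
right-column targets numerically, so corner starts are needed for the bias
contrast to survive the index encoding. Lesion foci for subtypes 1–3 sit in
distinct toy-atlas regions (anterior perisylvian, temporal, parietal).

What the generator does **not** model: eye movements, motor noise,
fatigue/learning within a session, correlated miss patterns beyond the
column gradient, realistic lesion shapes, or any coupling between behavior
and lesion other than the shared subtype label. Passing recovery tests
therefore shows that the pipeline recovers planted statistical structure of
this kind — not that real neglect cohorts contain six clusters.

## Validation experiments and problem sizes

`neglectmap.validation` holds the planted-truth experiments that
`scripts/acceptance.py` and the acceptance tests re-run: subtype recovery on
20 replicate 122-patient cohorts (modal selected G and the fraction of
replicates with ARI ≥ 0.8), component retention on a 400-row four-factor
harness (18 variables in four groups, loadings √0.75), the empirical size of
the Kruskal–Wallis path over 10,000 null replicates with the 6/20/8/50/22/16
layout, VLSM false-positive rate on 1,000 independent null voxels and
sensitivity on a planted 2-SD lesion effect, and Dice recovery of a planted
locus by the ≥50-point subtraction criterion with 20 patients per group.
These sizes keep each experiment in the seconds-to-minutes range while
leaving the Monte-Carlo error well inside the decision margins.

## Numerical and design choices

* Per-stage seeds derive from the global seed via
  `SeedSequence([seed, stage_index])`, so stages rerun in isolation
  bit-identically; the run manifest records the config and SHA-256 of every
  artifact.
* The reselection process emits, after every completed new selection, a
  geometric number of repeats — hence any emitted selection is a repeat with
  exactly the configured probability, which is what makes the empirical
  `%ReSel` converge to 100·p.
* Left-column exogenous miss probabilities in the default cohort stay at
  ≤ 0.45 so that the left-end-column RT mean (and thus `EndlineL/R`) is
  almost always defined; an all-missed column would otherwise drop the
  patient from complete-case PCA.
* Known limitations: the EM is plain (no annealing or split-merge moves), so
  model selection near degenerate solutions relies on the restart guard; the
  Steel–Dwass reference is asymptotic (no exact small-sample tables); VLSM
  offers only uncorrected and max-statistic-permutation inference.
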