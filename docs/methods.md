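# Methods

This note documents the models, conventions and design choices behind
the package: what each component computes, which parameters matter and
why their defaults were chosen, and what the synthetic-data checks do
and do not demonstrate.

## The instrument

### Informant score (7-item IQCODE)

Seven ordinal ratings 1–5 ("much improved" … "much worse", 3 = "no
change"), summarised as the arithmetic mean of the non-missing items.
Up to **two** missing items are tolerated — the mean of the remaining
items is then used; with three or more the questionnaire is flagged
invalid and the combined algorithm refuses to run, directing the caller
to the patient-only path.  The mean is kept at full floating precision
internally; comparisons against cutoffs are unrounded, and only display
formatting rounds to two decimals (the precision at which the cutoffs
are quoted).  Whether the original analysis compared rounded or exact
means is not documented; exact comparison is the conservative choice
because it never moves a case across a cutoff by rounding.

### Patient-only tree

A binary decision tree over the ten yes/no items.  The published
account fixes the root (CDT-5), the middle layer (Q1–Q3 and CDT-3) and
the excluded items (Q4 never selected; Q5 dropped because removing it
changed the correct classification rate only marginally), but not the
complete leaf mapping.  The shipped tree is therefore a
*reconstruction* consistent with those constraints, tagged
`provenance="reconstructed"` in its JSON serialization, and should be
treated as a configurable artifact rather than ground truth:

```
CDT-5 perfect?
├─ yes: Q1? ── no → watchful waiting
│        └ yes: Q2? ── yes → further evaluation
│                 └ no: Q3? ── yes → further evaluation, no → watchful waiting
└─ no:  CDT-3? ── no → further evaluation
         └ yes: Q1? ── yes → further evaluation
                  └ no: Q2? ── yes → further evaluation, no → watchful waiting
```

Missing patient answers are a hard error everywhere: the instrument
defines no imputation for the yes/no items, so none is invented.

### Combined rules

Rules are evaluated in their printed order.  The safety-net rule
(abnormal patient-directed result AND informant mean ≥ 3.29) is checked
first and can refer a case whose subgroup cutoff alone would not; it
encodes the logic that deficits on *both* instruments always warrant
work-up.  Subgroup rules 2–4 apply regardless of the patient-directed
result, exactly as printed.  All cutoff comparisons are **at-or-above**
(`mean >= cutoff` refers): the one rule whose comparator is printed
uses "≥", and internal consistency demands a single convention.  Q4 and
Q5 are recorded and serialized but consulted by no shipped algorithm.

Rule sets enforce two invariants at construction: subgroup predicates
partition the full value space of the dispatch items (every
combination matches exactly one rule), and every cutoff lies in
[1, 5].  Decisions are therefore total and deterministic, and
increasing the informant mean can never revoke a referral.

## The derivation pipeline

### CART

Binary recursive partitioning with Gini impurity (entropy available),
following rpart's conventions, which the original analysis used:

* a split's **gain** is the impurity decrease weighted by node size;
  the split is kept only if the gain exceeds
  `cp x (root node risk)` — *strictly* exceeds, so `cp = 1` always
  yields a root-only tree (the maximal relative gain, a perfect root
  split, equals exactly 1);
* default `cp = 0.01` (1%), the value used to build the instrument;
* `min_node_size = 20` mirrors rpart's `minsplit` default — nodes
  smaller than this become leaves.  Toy fixtures lower it explicitly;
* each item is used at most once per root-to-leaf path; ties between
  equally good splits go to the earlier item in the supplied order, so
  fits are bit-reproducible;
* leaves carry the majority class, with ties resolved to "further
  evaluation" (the sensitive choice for a case-finding tool);
* a single-class cohort returns a root-only tree with a warning rather
  than an error.

The fit is checked two ways in the test suite: against an exhaustive
search over all depth-≤2 trees on planted two-level cohorts, and
against R's rpart (same data, same cp) for the root split.

### Contingency table, pruning, subgroups

The selected items are cross-tabulated against the group label.  An
item is pruned when, for every combination of the remaining items, its
two value-strata carry the same homogeneity class (proportion
tolerance configurable, default 0 — classes must match exactly); an
unobserved stratum imposes no constraint, so constant items are always
dropped.  This mirrors the instrument's own construction, where the
"two distinguishable hands" clock criterion had no effect on the
categorization and was removed.

Cells are classified **high** (patient proportion ≥ 0.8), **low**
(≤ 0.2) or **mixed**.  The analysis that produced the instrument never
quantifies "high or low proportion"; 0.8/0.2 are this package's
defaults and are recorded in every derivation report.  Cells differing
in exactly one item value and sharing a class merge transitively into
subgroups.  This merge rule is the only one of the variants we
examined that reproduces the instrument's published four-subgroup
structure over (Q1, Q2, Q3, CDT-5): two 4-cell Q1=no subgroups that
remain separate (different classes), one mixed singleton, and one
7-cell high region that is connected but not expressible as a single
conjunction.

### ROC cutoff optimization

Candidate cutoffs are the midpoints between consecutive distinct
sorted scores plus two extremes — the minimum score (refer everyone)
and a value just above the maximum (refer no one).  The candidate
maximizing the CCR wins; ties go to the lowest cutoff, which maximizes
sensitivity.  Subgroup optimization is unweighted (each subgroup's own
cases only); whether the original analysis weighted by subgroup
prevalence is unknowable from the published account.  Complete 7-item
means live on a 1/7 lattice, so midpoint candidates such as
43/14 ≈ 3.0714 are consistent with published two-decimal cutoffs like
3.07; ROC results carry both the exact and the 2-decimal form.

Subgroup rules are assigned as: high subgroups → unconditional
referral; mixed and low subgroups → their optimized cutoff.  Two
degeneracies are handled with warnings rather than failures, because a
valid rule set must still partition the item space: a single-class
subgroup receives the unconditional decision of its class, and item
combinations never observed in the cohort default to watchful waiting.

The safety-net referral threshold is optimized by ROC over the cases
the fitted tree already flags as abnormal; when that subset is
single-class (in the original sample the deficient/deficient case
never occurred, and perfectly separated synthetic cohorts reproduce
this), the threshold falls back to a whole-cohort ROC, with a warning.

### Bootstrap evaluation

Case resampling with replacement, non-stratified by default (the
original account does not state stratification; a stratified option
preserving the group counts is provided).  The *fixed* rules are
scored on each replicate — no refitting — and sensitivity, specificity
and CCR are summarised by their means and 25th–75th percentile
("quartile") ranges.  A replicate lacking one class leaves the
corresponding rate undefined; such replicates are excluded from that
statistic's summary and counted, never imputed.  Because each resampled
case is uniform over the cohort, the expected replicate rates equal the
full-sample rates exactly; the test suite verifies convergence within
Monte-Carlo error at 5,000 replicates, and the acceptance check uses
1,000 (the instrument's own evaluation used 10,000 — the smaller
default here is a runtime choice that does not change the expectation,
only the Monte-Carlo error of the summary).

## Synthetic cohorts

`simulate_cohort` draws items independently per subject: per-group
Bernoulli endorsement for the ten yes/no items, per-group ordinal
distributions for the seven informant items, and per-item missingness.
Default group sizes (70 controls / 113 patients) match the published
informant subsample; default endorsement and rating distributions are
*plausible placeholders* (e.g. 68% of controls draw a perfect clock,
matching the reported 32% imperfect rate; informant ratings center on
"no change" for controls and shift toward "worse" for patients) — the
true item-response distributions of the clinical cohort are
unpublished.  Informant items are independent by default; an optional
`latent_loading` adds inter-item correlation through a shared
per-subject severity factor (Gaussian copula), since no covariance
structure is documented.

`planted_cutoff_scenario` plants a known informant cutoff per
subgroup: severity targets are drawn from Gaussians centered
`separation/2` below (controls) and above (patients) the cutoff with
standard deviation `spread`, then converted to seven complete ratings
whose mean is the nearest 1/7-grid value.  Defaults — the two Q1=no
subgroups with their published cutoffs 3.07 and 3.50, patient
fractions 0.5 and 0.15, `separation = 0.5`, `spread = 0.12`,
2,000 cases per subgroup — were chosen so that the scenario exercises
the *whole* pipeline: the fractions differ so the tree fit has a
selection signal, and they straddle the low/mixed boundary so the two
subgroups are classified differently and are not merged.  At these
settings the CCR-optimal cutoff of the generated scores is within one
1/7 grid step of the planted value with high probability, which is the
parameter-recovery criterion the acceptance suite checks over 20 seeds.

**What passing these checks shows — and does not.**  They show the
pipeline is internally correct: it recovers planted structure from
data generated under its own assumptions (independent items, clean
two-group labels, no informant/patient correlation beyond the planted
one).  They do not validate the instrument clinically, and the
published operating characteristics (e.g. combined sensitivity 97.4%,
specificity 81.6%, CCR 89.4%) cannot be reproduced here because the
clinical cohort is not public; those figures are documented properties
of the original sample, not test oracles.

## Numerical and interface choices

* Grid sweeps (the acceptance thresholds) compute grid points as
  integer ratios (`i/100`), avoiding accumulated floating-point error;
  a mean of exactly 3.07 compares equal to the stored 3.07 cutoff.
* JSON artifacts are written with sorted keys and stable float
  `repr`, so repeated runs with the same seed are byte-identical;
  thresholds serialize as decimal strings whose `float()` round-trip
  is exact.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  output artifact embeds its seed and configuration.
* Cohort CSVs are UTF-8 with a required header, `yes`/`no` values
  case-insensitive, decimal points (not commas) despite the
  instrument's German/French origins; malformed rows are reported with
  file line numbers, and a blank patient answer rejects the row (no
  imputation).

## Known limitations

* The shipped patient-only tree is a reconstruction; its leaf-level
  behavior beyond the documented constraints is this package's choice.
* The derivation can overfit small noisy cohorts (many subgroups) at
  `cp = 0.01` with ten candidate items; this is a property of the
  method at that setting, visible and tunable, not hidden.
* Kappa significance testing, weighted kappa and multi-rater
  generalizations are out of scope, as are clinical diagnostic
  criteria, image-based clock scoring and the 16-item IQCODE protocol.
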