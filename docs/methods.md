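# Methods

## Model and procedure

The pipeline treats each patient as a *transaction*: the set of distinct
generalized disease items accumulated over all of their hospital visits.
Association mining over these transactions is the standard
support/confidence/lift formulation; for a directed rule A ⇒ B,
sup = P(A ∪ B) (joint frequency), conf = P(B | A), and
lift = P(A ∪ B) / (P(A)·P(B)). A lift above 1 marks positive association and
is the primary comorbidity criterion; confidence orders and weights the
network edges.

Frequent itemsets are found with FP-growth: items are ordered by descending
global frequency (ties broken lexicographically, so the tree shape does not
depend on transaction order), transactions are inserted into a shared-prefix
tree with node counts, and the tree is mined recursively via conditional
pattern bases. An exhaustive subset enumerator with the identical contract
is kept in the package as `brute_force_itemsets` and serves as the oracle in
a randomized equivalence suite (universes ≤ 12 items); it is guarded to ≤ 20
items because enumeration is exponential. Only frequent **pairs** are turned
into rules — the evaluation semantics and the network are pairwise — but
larger itemsets are still mined and available.

### Threshold semantics

The mining thresholds default to sup ≥ 0.001, conf ≥ 0, lift > 1. Support
and confidence gates are inclusive; the lift gate is strict, because lift
exactly 1 means independence and cannot indicate comorbidity. A fractional
support threshold is converted to an integer count by ceiling so that
"support ≥ s" holds exactly on counts. Both directions of a qualifying pair
are emitted whenever each passes the gates on its own (the pair's lift is
shared; the two confidences differ).

## Code generalization

Raw ICD-10 codes are mapped to items at three levels. Level 0 (verbatim)
applies to codes that are already 3-character categories, to six-digit
NOS/NEC subcategories (these encode etiology/severity detail that must not
be pooled), to the abnormal-findings range R90–R94, and to F84.2–F84.9,
which are deliberately kept apart from the autism anchor. F84.0 and F84.1
collapse to the level-1 item "F84". Any other code whose category falls in a
configured chapter block (F70–F79, G20–G26, G40–G41, G90–G99, J00–J06,
J20–J22, L20–L30, E00–E07 by default) takes the block label (level 2);
everything else collapses to its 3-character category (level 1). Range
membership uses lexicographic comparison of categories, which coincides with
ontological order for fixed-width ICD-10 categories. The exact study mapping
table is configuration, not code: users can override any assignment with a
`raw_code,level,item_label` CSV and supply their own block table and NOS/NEC
flag list.

Patients are dropped when fewer than two items remain after exclusion and
generalization. Two items *including* the autism anchor is the default
reading (anchor + ≥ 1 comorbidity); the threshold is a parameter
(`min_items`) for the stricter reading.

## Cross-validation design

Folds are stratified by disease frequency: diseases are processed rarest
first, and each disease's not-yet-assigned patients are shuffled and placed
one at a time into a uniformly random group among those currently smallest.
This realizes "rare diseases spread as evenly as possible" and guarantees a
fold-size spread of at most one (1488 patients → sizes {148, 149}). A
patient is assigned when their rarest disease is processed and never moved
afterwards.

Evaluation of a test patient walks each of their diseases d and triggers
every rule with antecedent d. A trigger is correct iff the consequent is
also one of the patient's diseases; "predicted" means appearing as a
triggered consequent, so the examined antecedent itself never counts as
predicted — a patient's rarest-cause disease can remain unpredicted even
while triggering many rules. Per fold, R1/R2 collect rules with ≥ 1 correct
(incorrect) prediction; a rule can sit in both, and Nrt/Nrf count it in
both. Rt = Pt/Nrt and Rf = Pf/Nrf are reported as tagged missing values
(not 0, not ∞) when their denominators are zero — "no correct rules" is not
"rate zero". All per-patient and per-fold ratios are computed as exact
`fractions.Fraction` values and rendered as decimals only in the output
table, which reports Avg and Std (population, over the k folds) per
confidence cutoff C. Rules are mined per training split at the standard
thresholds; the C sweep is applied as a post-hoc filter of each fold's rule
base, matching its role as an evaluation parameter rather than a mining
threshold.

## Verification

The external check consults a local co-occurrence cache keyed by truncated
ICD-10 code strings. A dotted code tries its 4-character prefix then its
3-character category; a block item is split back into the raw member codes
observed in the data, each truncated the same way; the rule is significant
if *any* candidate pair is cached with chi-square p < 0.05 (Pearson, 1 df,
no continuity correction; computed locally when the cache stores counts,
taken as stored when it stores p). No multiple-testing correction is applied
by default, for fidelity to the raw-p criterion; a Bonferroni option exists.
The cache/literature statuses map onto four final classes
(cohd+literature, cohd_only, literature_only, unverified) and a 2×2
agreement table with margins. Live database access is out of scope: the
shipped snapshot (`data/cohd_cache_synthetic.csv`) is synthetic, built to
cover the default code universe so the stage runs without any download.

## Synthetic cohort generator

The generator emulates a single-center pediatric autism cohort: 1488
patients by default, 82.66% male, 81.76% urban, first-visit age bands
weighted 59.88/34.34/5.58/0.20% (early childhood through late adolescence),
and visit counts binned 1–9/10–19/20+ with weights 96.24/2.55/1.21%. Every
patient carries the anchor (F84.0 before age 3, F84.1 after, mirroring the
diagnostic-age split between those codes). The ~44-code default universe is
long-tailed (prevalences 0.30 down to 0.005) and spans the headline
comorbidity groups plus V/Z decoy codes that exercise the exclusion path; no
per-code prevalence table exists for the real cohort, so these are free
parameters chosen once as a realistic hospital frequency profile. Planted
pairs default to a nutrient-deficiency chain (E58.x00 → E61.100/E60.x00),
epilepsy → convulsions, and intellectual disability → speech disorder.

Generation is per patient: independent Bernoulli draws per code, then each
planted (X, Y, p) re-draws Y as Bernoulli(p) when X is present — the
simplest model in which sup, conf and lift of the planted rules are
controlled exactly. Codes are scattered over the patient's visits uniformly,
with a 30% chance of a repeat at a second visit, to exercise multi-visit
deduplication. The generator does **not** model longitudinal disease
progression, code-ontology realism beyond the syntactic pattern,
demographic–disease dependence, or inter-code correlation beyond the planted
pairs; passing recovery tests therefore demonstrates correctness of the
mining and evaluation machinery under known structure, not performance on
real EHR data.

## Numerical choices and edge cases

- Seeds: a single integer seed drives `numpy.random.default_rng` in the
  generator and `random.Random` in fold assignment; identical config + seed
  reproduces every artifact byte for byte.
- Degenerate 2×2 tables (a zero marginal) raise a dedicated error rather
  than returning 0/NaN.
- Empty rule sets propagate as tagged missing Rt/Rf and fold means skip
  undefined values.
- Test problem sizes: property suites use universes ≤ 12 items; recovery and
  monotonicity checks use cohorts of 800–2500 patients, where binomial
  standard errors are small enough for 4-SE bands to be discriminating.

## Known limitations

Only single-antecedent/single-consequent rules are emitted; reciprocal
edges are kept as two distinct links in the network; the "subnetwork"
notion is operationalized as weakly connected components plus top-degree
hub flags, since visual grouping in a viewer is not algorithmically defined.
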