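# Methods

## Data model and conventions

A study is a set of classrooms, each with a roster (id, gender, age,
classroom, rural/urban setting), a square ordinal contact matrix (directed
ratings 1–5), a directed 0/1 co-drinking nomination matrix, and one 10-item
AUDIT response per student (items 1–8 score 0–4, items 9–10 score 0/2/4;
total 0–40).

Two conventions are fixed because downstream counts depend on them:

* **Rows are raters.** Entry (i, j) is i's rating of j; all ties are
  out-ties of the row actor.  Triad type frequencies are not invariant to
  transposition (the D/U types swap), so this choice is part of the method.
* **Missing ratings** (absent respondents) carry an explicit sentinel (0)
  and behave like "we never coincided" at every dichotomization level; a
  reader option drops the actor instead.  Settings are constant within a
  classroom and ids are matched case-sensitively after whitespace trimming.

## Dichotomization

Tie iff rating ≥ cut, with cuts 2/3/4 for minimum/intermediate/maximum
intensity (configurable; validation enforces non-decreasing cuts so the tie
sets always nest).  The diagonal is forced to 0.  Only the minimum layer
feeds the composition and correlation stages by default — any contact at
all marks the start of a relationship — but all three layers are censused.

## Triad census and the transitivity partition

Classification is dyad-pattern logic: count mutual/asymmetric/null dyads,
then disambiguate orientation (shared arc source → D, shared target → U,
chain/cycle → C, the transitive three-arc pattern → T).  A 64-entry lookup
over the off-diagonal bit patterns, built from that logic at import, drives
a vectorized O(n³) sweep over all C(n, 3) triples.  Classrooms have n ≤ 60,
so subquadratic census algorithms are deliberately out of scope.  The test
suite checks the classifier against an exhaustive isomorphism matcher on
all 64 labeled 3-node digraphs and against `networkx.triadic_census` on
random networks; neither oracle is a runtime dependency.

The default partition is binary: transitive = {030T, 120D, 120U, 300} (the
types containing a transitive triple and no intransitive one), everything
else intransitive — including the vacuous types 003, 012 and 102, which
contain no two-path at all.  A three-way scheme separating the vacuous
types is available for sensitivity analysis.  Guard rails on custom
schemes: 300 must be transitive; 012, 102 and 111U must not be.

Per-actor profiles count, for each student, the transitive and intransitive
triads among the C(n−1, 2) triples containing them; since each triad holds
three actors, profile columns sum to exactly three times the census totals
(asserted in tests).  Setting-level results are componentwise sums of the
classroom censuses, with the multiset of classroom sizes retained.

A note on a tempting but false invariant: adding the closing arc X→Z to an
open two-path X→Y→Z converts that 021C triple to 030T, but the *global*
transitive total can still decrease, because the new arc also retypes every
other triple containing the dyad (X, Z) — e.g. an 030T there can become
120C.  The tests therefore assert the local property only.

## Composition layers

"Composition by gender" is read as the same-gender subnetwork of the
minimum-intensity layer (tie kept iff both endpoints share the attribute) —
the homophily reading.  The alternative reading, a census stratified by the
gender multiset of each triple (FFF/FFM/FMM/MMM), is also computed and
reported; stratum censuses sum to the unstratified census by construction.
Neither reading is claimed to be uniquely correct; both appear in the
report.

The consumption layer uses the directed nominations as-is.  Flags allow
intersecting with the contact layer (`restrict_to_contact`) and union
symmetrization, both off by default: the analysis treats nomination as an
out-tie like any other.

## Inference

* **Risk**: AUDIT total ≥ threshold; the threshold defaults to 8, the
  instrument's conventional cut-off, and is a prominent config key named in
  every report since reasonable analyses use 7–10.
* **Chi-square**: Pearson test of independence on the risk × gender and
  risk × setting tables (scipy), no continuity correction by default,
  Yates' correction by flag.  Zero-margin tables raise a degenerate-input
  error that the pipeline converts to a report warning.
* **Cross-layer correlation**: Pearson r between two layers' vectors with a
  two-sided t-test p-value.  The default vectors (`node_profile`) are the
  per-actor transitive-triad participation counts, giving one r per
  classroom with n = classroom size, so power varies by classroom as in the
  study design this mirrors.  `census_vector` (16 type counts, n = 16) and
  `tie_level` (vectorized off-diagonal adjacencies, a QAP-style comparison
  without permutation inference) are selectable.  Zero-variance vectors
  raise rather than returning NaN.
* **Power**: for the two-sided test of ρ = 0 at level α, the default is the
  exact computation — integrate Hotelling's density of the sample
  correlation under bivariate normality (via `scipy.special.hyp2f1` in log
  space and `scipy.integrate.quad`) over the rejection region of the
  t-test.  This matches a Monte-Carlo estimate (10⁵ replicates, r = 0.8,
  n = 10) to three decimals, whereas the Fisher-z approximation
  (z = atanh r, SE = 1/√(n−3)), also provided as `method="fisher_z"`,
  underestimates power by ≈ 0.04 at that classroom-like n.  Exact is
  therefore the default; at ρ = 0 both return exactly α.
* **Multiple testing**: raw p-values are reported, matching common practice
  for per-classroom descriptive correlation tables; an optional
  Benjamini–Hochberg column is available and clearly an extension.

## Synthetic-data generator

Per classroom, in order: genders (Bernoulli, p_female) → base directed ties
(probability `base_tie_prob`, + `homophily_boost` if same gender,
+ `reciprocity_boost` if the reverse tie was already drawn in the row-major
sweep) → `closure_sweeps` passes in which every open two-path i→k→j is
closed with `closure_prob` (open pairs are collected before drawing, so
additions within a sweep do not cascade) → ordinal intensities (non-ties
rate 1; each tie's latent U(0,1) strength maps through `intensity_cuts` to
2/3/4/5) → risk status (Bernoulli with a rural prevalence shift) →
co-drinking nominations drawn over contact ties with probability 0.70 when
both endpoints are at risk and 0.15 otherwise → AUDIT items, drawn by
partitioning a target total (above/below the threshold according to risk
status) across the 10 items while respecting each item's range and the
even-value constraint of items 9–10.

Each classroom uses its own random substream derived from the study seed
and the classroom's position, so classroom outputs are invariant to how
many other classrooms are generated — verified by test.

The **paper_shaped** preset fixes 6 rural classrooms (17,17,17,17,16,16)
and 4 urban (24,24,24,23) — 195 students, 100 rural — p_female = 0.54,
risk prevalence 0.41 urban / 0.46 rural (overall ≈ 43.6 % at risk), base
tie probability 0.12 with reciprocity +0.35, homophily +0.15, and two
closure sweeps at 0.15.  These reproduce the survey *shape* this pipeline
targets; no claim is made that they match any particular dataset's
generating process.  `null_model` removes all structural effects (for
calibration: under it the rural/urban risk chi-square should be
non-significant at the nominal rate) and `high_closure` triples the
clustering pressure.

What the generator does **not** emulate: degree heterogeneity beyond what
the boosts induce, age structure in tie formation, inter-classroom ties,
missing respondents, and measurement error in AUDIT self-reports.  Passing
tests therefore demonstrate correctness of the pipeline's computations and
its sensitivity to reciprocity/homophily/closure/risk-linkage effects — not
that real classrooms satisfy the model.

## Problem sizes and numerical choices

Tests exercise classrooms of 8–24 students and Monte-Carlo sweeps of 30
seeds on two 14-student classrooms — sizes at which every effect the
generator injects is already detectable (one-sided Wilcoxon p < 0.01
across seeds) and the full suite runs in seconds.  The acceptance script
runs the complete 195-student study.  Proportions are exact rational
arithmetic in floating point (no rounding until display); human-readable
tables round to 2 decimals, CSVs and JSON keep full precision.  Config
hashes cover all analytic parameters but not the output directory.

## Known limitations

* No Holland–Leinhardt conditional-uniform null models or τ statistics;
  censuses are reported raw, as descriptive quantities.
* No ERGM/multilevel modelling, no longitudinal network evolution.
* The tie-level correlation mode does not do QAP permutation inference;
  its p-value assumes independent dyads and should be read descriptively.
* UCINET DL support covers the full-matrix and edgelist1 variants only.
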