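# triadscope

Triadic social-network analysis of classroom sociometric surveys, built for
studies of adolescent alcohol consumption that compare rural and urban school
settings.

In a sociometric survey every student rates how much time they spend with
each classmate (an ordinal 1–5 directed rating: 1 = "we never coincided",
5 = "we are always together") and marks the classmates they go out and drink
with.  `triadscope` turns those matrices into the quantities such studies
report:

1. **Dichotomization.** The ordinal matrix is cut into three nested binary
   contact networks — minimum (rating ≥ 2), intermediate (≥ 3) and maximum
   (≥ 4) intensity.
2. **Triad census.** Every unordered triple of students falls into one of
   the 16 Holland–Leinhardt MAN classes (counts of **M**utual,
   **A**symmetric and **N**ull dyads plus an orientation letter).  The
   census partitions into *transitive* types — those realizing the balance
   pattern "if X→Y and Y→Z then X→Z" non-vacuously, i.e. {030T, 120D, 120U,
   300} — and *intransitive* types (everything else, including the vacuous
   003/012/102).
3. **Composition layers.** Same-gender (homophilous) subnetworks,
   gender-stratified censuses (FFF/FFM/FMM/MMM triples), and the directed
   co-drinking nomination layer.
4. **Inference.** AUDIT risk classification (10-item totals, conventional
   cut-off ≥ 8), chi-square association of risk with gender and setting,
   and per-classroom Pearson correlation of each student's transitive-triad
   participation in the co-drinking layer against the contact and
   same-gender layers — each correlation annotated with the exact power of
   the two-sided test of ρ = 0 at the observed |r| and classroom size.
5. **Synthetic studies.** A generator of full multi-classroom datasets with
   controllable reciprocity, gender homophily, triadic closure, rural/urban
   risk gradients and risk-linked co-drinking, so the whole chain is
   testable without survey data.

## Worked example

Simulate a paper-shaped study (10 classrooms: 6 rural + 4 urban, 195
students) and run the full analysis:

```bash
triadscope analyze --seed 1 --out out/
triadscope report out/report.json
```

prints (abridged):

```
risk by setting:
  rural  40/100 at risk (40.00%)
  urban  42/95 at risk (44.21%)

transitive triads per setting/layer:
  rural/minimum                   372/  3840 (9.69%)
  rural/gender_homophilous        148/  3840 (3.85%)
  rural/consumption                 8/  3840 (0.21%)
  urban/minimum                   850/  7843 (10.84%)
  ...

correlations (consumption vs other layers):
  R02    rural  vs minimum              r=+0.60  power=0.77
  U03    urban  vs gender_homophilous   r=+0.64  power=0.94
  U04    urban  vs minimum              r=+0.62  power=0.91
  ...
```

Reading the numbers: 40/100 rural students score at or above the AUDIT
cut-off; of the 3 840 rural student triples, 372 (9.69 %) form transitive
contact triads at minimum intensity; in classroom U04 the students central
to transitive co-drinking triads are largely the same students central to
transitive contact triads (r = +0.62), and at n = 23 a true correlation of
that size would be detected with probability 0.91.  Classrooms whose
co-drinking layer has a constant transitive profile are reported as
warnings (undefined correlation) rather than dropped silently.

The same pipeline runs on real data laid out as `roster.csv` +
`contact_<classroom>.csv` + `nominations_<classroom>.csv`
(`triadscope analyze --input-dir DIR --out OUT`); UCINET DL (full matrix and
edge-list variants) and edge-list files are supported for networks.

Library use mirrors the CLI:

```python
from triadscope import (PipelineConfig, run_pipeline, census, dichotomize_all)

report = run_pipeline(PipelineConfig(preset="paper_shaped", seed=1))
report.setting_censuses[("urban", "minimum")].transitive_share  # 0.1084
```

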