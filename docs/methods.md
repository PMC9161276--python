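# Methods

This note documents the models, conventions and design choices behind
`tlsgrade`, in the spirit of a statistical methods appendix.

## Phenotyping

Input cells are assumed segmented and thresholded upstream: one row per
DAPI⁺ nucleated cell with binary positivity for CD3, CD4, CD20, CD21,
CD103 and BCL6. "All nucleated cells" therefore means all rows of the cell
table; no further filtering is applied.

Gates are declarative (required-positive / required-negative marker sets)
and non-exclusive. Because the panel carries no CD8 antibody, CD8 T cells
are defined by exclusion as CD3⁺CD4⁻, and the CD4 gates require CD3
co-positivity (`cd4_t` = CD3⁺CD4⁺, `cd4_trm` = CD3⁺CD4⁺CD103⁺). The
stricter CD3-gated reading was chosen because a bare CD4⁺ gate would admit
CD4⁺ myeloid cells; the rules file is editable, so the bare-CD4 reading is
one line away. Under these gates the hierarchy
`cd8_trm ≤ min(cd8_t, cd3_trm)`, `cd4_trm ≤ cd4_t`, `gc_b ≤ b_cell` holds
for every input, and is property-tested.

## TLS staging and patient grade

A TLS is staged from two counts: CD21⁺ FDCs and CD20⁺BCL6⁺ GC-B cells.
SFL if GC-B count ≥ `gc_min`; else PFL if FDC count ≥ `fdc_min`; else E.
Both thresholds default to **1 cell** — a presence/absence reading of
"FDC network present" and "GC reaction present" — and are configuration
knobs so sensitivity to stray positive cells can be probed. The GC test
runs first, so a GC⁺FDC⁻ structure is SFL; the grade-3 definition requires
only one SFL-TLS and does not require PFL co-occurrence.

Grade: 3 if any SFL, else 2 if any PFL, else 1. The rule is order-invariant
and monotone in SFL additions. Patients with zero TLSs raise an error
(the study design includes only TLS-positive tissue) rather than receiving
a fabricated grade. TLS density is the TLS count divided by the summed
tumour area (mm²) of the patient's sections. No minimum aggregate size is
imposed on what counts as a TLS; the delineation is taken from the
upstream region table as given.

## Proportions and patient aggregates

A region proportion is `100 · count / total nucleated cells`, undefined
(never zero) for empty regions; empty regions are excluded with a logged
warning. Patient aggregates average **regions with equal weight** — the
field, not the cell, is the sampling unit — separately for the inside-TLS
compartment, the outside compartment, and the overall average. The overall
average pools all regions ("pooled", primary); averaging the two
compartment means instead is available as `average_mode="mean_of_means"`,
and a cell-count-weighted mode as `cell_weighted=True`, because the
field-level description of an average over "all fields" admits both
readings. Missing compartments propagate as missing values and are dropped
from downstream stratification, never imputed.

## Survival machinery

* **Kaplan–Meier**: product-limit estimator over distinct event times;
  subjects censored at an event time remain at risk for that time's events
  (deaths-before-censorings tie rule). The median is the smallest event
  time with S(t) ≤ 0.5 and is reported as missing ("not reached") when the
  curve never crosses 0.5.
* **Log-rank**: observed/expected event counts with the hypergeometric
  variance; the k-group statistic uses the (k−1)-dimensional quadratic
  form with a pseudo-inverse guarding degenerate strata, and specialises
  exactly to U²/V at k = 2.
* **Hazard ratio**: the O/E ratio (O₁/E₁)/(O₂/E₂) with
  CI = exp(log HR ± 1.96·√(1/E₁ + 1/E₂)). This is the quantity commonly
  quoted "from the log-rank test"; no proportional-hazards regression is
  fitted anywhere in the package. The O/E estimator is known to shrink
  slightly toward the null for large effects, so its CI coverage is
  approximately — not exactly — nominal; the acceptance suite checks
  coverage within [0.90, 0.99] at a true HR of 0.25.
* **Maximally selected cutpoint**: candidate cutoffs are the observed
  feature values whose ≥/< split keeps at least `minprop` (default 0.1,
  the conventional minimum group fraction) of subjects on each side; the
  standardised log-rank statistic |U|/√V is computed for every candidate
  (vectorised over candidates) and the argmax returned, ties broken toward
  the smallest cutoff. The p-value is a seeded permutation estimate
  (default B = 1000) obtained by permuting features against outcomes —
  exact-by-simulation, with no reliance on the asymptotic distribution of
  maximally selected statistics. Dichotomisation uses the "≥ cutoff =
  high" convention.

## Group statistics

* **Wilcoxon signed-rank** (paired): zero differences dropped (Wilcoxon's
  original rule, the default of mainstream statistics software), midranks
  for tied |d|. For n ≤ 25 the exact two-sided p is 2·P(W⁺ ≤ min(W⁺,W⁻))
  computed from the full sign-assignment distribution via a
  generating-function convolution (doubled ranks keep midranks integral);
  beyond that, a normal approximation with tie correction and continuity
  correction.
* **Kruskal–Wallis**: pooled midranks with the standard tie correction,
  p from χ²(k−1).
* **Pearson χ²**: no continuity correction; zero margins are rejected with
  the offending row/column named; expected counts are returned so the
  dispatch rule is auditable.
* **Fisher exact** (2×c, c ≤ 6): two-sided p by full enumeration of tables
  with the observed margins, summing the probability of every table no
  more probable than the observed one (probability ordering, the
  convention matching commonly printed two-sided values).
* **Dispatch**: Fisher when any expected count < 5 (and the table is 2×c),
  else χ². No multiple-testing correction is applied anywhere; reported
  p-values are unadjusted.

## Synthetic cohort generator

The generator emulates the data structure of a TLS-maturity mIF study, not
any particular cohort: per-patient TLS sets of mixed maturity, 3–5 outside
fields, per-cell marker combinations drawn from a categorical distribution
over biologically possible archetypes, and exponential DFS with planted
log-hazards.

Defaults were fixed once from the study-scale aggregates the emulated
design reports: 49 TLS-positive patients; 10–23 TLSs and 3–5 outside
fields per patient (matching ~807 TLSs and ~151 outside fields in total);
grade frequencies (0.12, 0.53, 0.35); tumour areas 150–450 mm² (so
whole-section TLS densities fall on the ~0.07/mm² scale); baseline hazard
0.16/month (ln 2 / 4.3-month grade-1 median DFS); grade log-hazards
ln 0.418 and ln 0.226; T_RM-high log-hazard ln 0.433; censoring = uniform
dropout with probability 0.3 plus administrative cut-off at 60 months.
Cells per region (200–600) is not reported anywhere at this granularity
and was chosen once as realistic for 200× fields. Outside-TLS archetype
frequencies sit at the percent scale of reported outside-field subset
levels, with inside-TLS enrichment multipliers (e.g. ×3.2 for CD4⁺ T_RM)
and an additional SFL-vs-E/PFL multiplier (×2.5 for CD4⁺ T_RM) shaping the
maturity gradient.

Structural guarantees make classification recovery deterministic rather
than probabilistic: FDC cells have frequency zero in E-TLS, GC-B cells
frequency zero in E- and PFL-TLS, and PFL/SFL regions are topped up to at
least one defining cell (converting all-negative cells) when the random
draw falls short. Consequently staging + grading recover the planted truth
with 100% accuracy at the default thresholds, for every seed — an
invariant the tests assert. Grade consistency of the drawn maturity sets
is enforced the same way (a grade-2 patient is guaranteed ≥ 1 PFL, a
grade-3 patient ≥ 1 SFL), and configurations that make a requested grade
impossible (e.g. grade-3 probability > 0 with zero SFL mass) are rejected
with an error naming the clash.

Randomness uses one root `SeedSequence` with an index-keyed substream per
patient (patients → regions → cells → survival within each substream), so
extending the cohort never changes earlier patients, and identical configs
give byte-identical fixture files.

What the generator does **not** emulate — and what passing tests therefore
do not certify about real data: spatial coordinates and point patterns
(region membership is assigned directly, mirroring manual delineation),
correlated clinical covariates, between-section staining batch effects,
intensity-threshold miscalibration (marker calls are generated
post-threshold; the optional intensity mode produces lognormal intensities
consistent with the calls at a fixed threshold of 1.0, not a realistic
gating problem), non-exponential hazards, and informative censoring.
Survival draws use min(exponential event time, uniform dropout,
administrative cut-off), the simplest mechanism satisfying the
non-informative-censoring assumption of KM/log-rank.

## Numerical conventions and problem sizes

Proportions are stored at full precision; rendered contingency tables
round percentages half-away-from-zero to integers. JSON reports are
written with sorted keys and no timestamps, so a fixed config + seed
reproduces them byte for byte (the manifest carries input checksums).
Cutpoint tie-breaks go to the smallest cutoff; permutation p-values use
the add-one estimator (h+1)/(B+1).

The simulation-based checks in the test suite run at: 2000 null
replicates (log-rank type-I), 200 replicates of n = 200 (cutpoint
recovery), 200 replicates of n = 400 (O/E CI coverage), and 10 cohorts of
25 patients at ≥ 300 cells/region (enrichment recovery) — sizes at which
each property's Monte Carlo error is small relative to its acceptance
band while the whole suite completes in well under a minute of
simulation time.

## Known limitations

* The O/E hazard ratio is a crude estimator; for strong effects its CI is
  mildly anti-conservative (see above). It is used deliberately, to match
  the log-rank-based reporting convention it implements.
* Fisher enumeration is limited to 2×c tables (c ≤ 6); larger sparse
  tables fall back to χ² under the dispatch rule.
* Cutpoints are derived on the full analysed set, then reused for
  subgrouped analyses; deriving per-subgroup cutoffs would require a
  different (documented) choice.
* The permutation null for the cutpoint p-value conditions on the observed
  feature multiset and censoring pattern; it does not account for the
  cutpoint having been selected on the same data twice (selection is
  re-done inside every permutation, which is the standard remedy).
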