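# tlsgrade

Quantitative analysis of **tertiary lymphoid structure (TLS) maturity** and
**tissue-resident memory T cells (T_RM)** from cell-level multiplex
immunofluorescence (mIF) tables, with survival statistics linking both to
disease-free survival (DFS).

TLSs are ectopic lymphoid aggregates in tumour tissue. Their maturity is
staged from follicular organisation: **E-TLS** (early aggregate, no CD21⁺
follicular dendritic cell network, no germinal centre), **PFL-TLS** (primary
follicle-like, CD21⁺ FDC network but no GC reaction) and **SFL-TLS**
(secondary follicle-like, GC reaction = CD20⁺Bcl-6⁺ B cells present). The GC
test takes precedence. Patients are then scored

* **grade 1** — only E-TLSs,
* **grade 2** — at least one PFL-TLS and no SFL-TLS,
* **grade 3** — at least one SFL-TLS,

and T_RM subsets are gated from the six-marker panel (CD3, CD4, CD20, CD21,
CD103, BCL6): CD3⁺CD103⁺, CD3⁺CD4⁺CD103⁺ and CD3⁺CD4⁻CD103⁺ cells, with
subset proportions expressed as percentages of all nucleated cells per TLS
or outside field, averaged per patient within each compartment.

The package is aimed at researchers in spatial tumour immunology who have
segmented, marker-thresholded cell tables (one row per DAPI⁺ cell) and want
a reproducible path from those tables to maturity grades, compartment
proportions and survival stratification.

## What is inside

| module | contents |
| --- | --- |
| `tlsgrade.phenotyping` | marker-combination gating rules, per-region subset counting |
| `tlsgrade.tls_scoring` | E/PFL/SFL staging, patient grade, TLS density (per mm²) |
| `tlsgrade.quantification` | region proportions; inside / outside / average patient aggregates |
| `tlsgrade.survival` | Kaplan–Meier, log-rank (2- and k-group), O/E hazard ratios, maximally selected rank-statistic cutpoints, stratified analyses |
| `tlsgrade.group_stats` | exact Wilcoxon signed-rank, Kruskal–Wallis, Pearson χ², Fisher exact (enumeration), chi-square/Fisher dispatch |
| `tlsgrade.synthetic` | seeded synthetic cohorts with planted grades, maturities, T_RM strata and exponential DFS hazards |
| `tlsgrade.io` / `tlsgrade.pipeline` / `tlsgrade.cli` | CSV schemas and validation, end-to-end orchestration, reports, `tlsgrade` CLI |

The survival and nonparametric machinery is implemented from first
principles (product-limit estimator, hypergeometric log-rank moments, sign
enumeration, margin-fixed table enumeration) and is cross-checked in the
test suite against lifelines and scipy as independent oracles.

Statistical conventions: hazard ratios are the log-rank O/E ratio
(O₁/E₁)/(O₂/E₂), not Cox fits; cutpoint p-values come from seeded
permutations; medians that never cross S(t) = 0.5 are reported as
not-reached; zero differences are dropped in the Wilcoxon test; the
two-sided Fisher p uses probability ordering.

## Worked example

```sh
tlsgrade simulate --out demo/cohort --seed 7 --n-patients 20
tlsgrade run-all --input demo/cohort --out demo/run --seed 11 --permutations 200
```

The first command writes `cells.csv`, `regions.csv`, `sections.csv`,
`clinical.csv` and a `truth.json` sidecar with the planted ground truth.
The second runs the whole pipeline and prints the summary tables; the run
above starts with

```
Patient grade distribution
        grade 1 grade 2 grade 3
all patients    1 (5%)  11 (55%)        8 (40%)
```

i.e. of the 20 simulated patients, 1 carried only E-TLSs, 11 reached PFL
but not SFL maturity, 8 had at least one germinal-centre-positive TLS.
`survival_report.json` records, for every feature, the selected cutoff and
the dichotomised comparison. For the CD3⁺CD103⁺ T_RM proportion inside TLS
this run finds

```
cutoff 3.17 % of nucleated cells
HR (high vs low) 0.17, 95% CI (0.055, 0.54), log-rank p = 0.00029
median DFS: high = not reached, low = 9.8 months
```

— patients above the cutoff recur at roughly one-sixth the rate, matching
the protective T_RM effect planted by the generator. The paired Wilcoxon
block of `group_stats_report.json` shows the inside-TLS enrichment of the
same subset (mean 2.72 % inside vs 0.83 % outside, exact p ≈ 2 × 10⁻⁶).

All outputs are deterministic for a fixed input and `--seed`: re-running a
command reproduces every report byte for byte.

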