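"""End-to-end orchestration: phenotype -> stage -> grade -> quantify ->
cutpoints -> survival and group statistics, with machine-readable reports.

Outputs written to the run directory:

* ``tls_classification.csv`` — region_id, maturity, n_fdc, n_gcb
* ``patient_grades.csv``     — patient_id, grade, n_tls, tls_density
* ``proportions.csv``        — region-level subset percentages
* ``patient_summary.csv``    — one row/patient with compartment aggregates
* ``survival_report.json``   — KM/log-rank/cutpoint analyses
* ``group_stats_report.json``— Wilcoxon, Kruskal-Wallis, contingency tests
* ``summary_tables.txt``     — human-readable contingency/stratification tables
* ``manifest.json``          — config snapshot, input checksums, versions

All stochastic steps (cutpoint permutations) are seeded from the run seed,
so identical config + seed gives byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import NoCutpointError, TLSGradeError, UndefinedStatisticError
from .group_stats import (
    chi_square_test,
    choose_association_test,
    fisher_exact,
    kruskal_wallis,
    wilcoxon_signed_rank,
)
from .io import Cohort, read_cohort
from .phenotyping import default_rules, load_rules
from .quantification import build_patient_summary, region_proportions
from .survival import (
    dichotomize,
    km_curve,
    logrank_k_groups,
    logrank_test,
    max_selected_cutpoint,
    stratified_analysis,
)
from .tls_scoring import classify_regions, grade_cohort

log = logging.getLogger(__name__)

DEFAULT_FEATURES = ["cd3_trm", "cd4_trm", "cd8_trm", "cd4_t", "cd8_t", "b_cell", "fdc", "gc_b"]
TRM_FEATURES = ["cd3_trm", "cd4_trm", "cd8_trm"]
COVARIATES = ["sex", "age", "t_stage", "n_stage", "tnm_stage", "micropapillary", "egfr", "smoking"]


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    seed: int
    rules_path: str | None = None
    fdc_min: int = 1
    gc_min: int = 1
    minprop: float = 0.1
    n_permutations: int = 1000
    average_mode: str = "pooled"
    cell_weighted: bool = False
    features: list[str] = field(default_factory=lambda: list(DEFAULT_FEATURES))
    make_plots: bool = False


@dataclass
class PipelineResult:
    config: PipelineConfig
    classifications: pd.DataFrame
    grades: pd.DataFrame
    proportions: pd.DataFrame
    summary: pd.DataFrame
    survival_report: dict
    group_stats_report: dict
    paths: dict


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _km_summary(curve) -> dict:
    return {
        "n": curve.n,
        "median": curve.median,
        "times": curve.times.tolist(),
        "survival": curve.survival.tolist(),
    }


def _logrank_record(res) -> dict:
    return {
        "chi_square": res.chi_square,
        "p_value": res.p_value,
        "hazard_ratio": res.hazard_ratio,
        "hr_ci_95": list(res.hr_ci_95),
        "observed": res.observed.tolist(),
        "expected": res.expected.tolist(),
        "n": list(res.n),
    }


def _feature_analysis(
    summary: pd.DataFrame, column: str, *, minprop: float, n_permutations: int,
    rng: np.random.Generator,
) -> dict:
    """Cutpoint + dichotomised KM/log-rank for one continuous feature."""
    sub = summary[[column, "dfs_months", "event"]].dropna()
    record: dict = {"feature": column, "n": int(len(sub))}
    values = sub[column].to_numpy(float)
    time = sub["dfs_months"].to_numpy(float)
    event = sub["event"].to_numpy(int)
    try:
        cut = max_selected_cutpoint(
            values, time, event,
            minprop=minprop, n_permutations=n_permutations, random_state=rng,
        )
    except (NoCutpointError, UndefinedStatisticError) as exc:
        record["skipped"] = str(exc)
        return record
    labels = dichotomize(values, cut.cutoff)
    record["cutoff"] = cut.cutoff
    record["cutpoint_statistic"] = cut.statistic
    record["cutpoint_p_permutation"] = cut.p_value
    record["groups"] = f">={cut.cutoff:g} (high) vs <{cut.cutoff:g} (low)"
    high = labels == "high"
    try:
        res = logrank_test(time[high], event[high], time[~high], event[~high])
    except UndefinedStatisticError as exc:
        record["skipped"] = str(exc)
        return record
    record["logrank"] = _logrank_record(res)
    record["median_high"] = km_curve(time[high], event[high]).median
    record["median_low"] = km_curve(time[~high], event[~high]).median
    return record


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; see module docstring for outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(config.input_dir)
    rules = load_rules(config.rules_path) if config.rules_path else default_rules()

    classifications = classify_regions(
        cohort.cells, cohort.regions, rules, fdc_min=config.fdc_min, gc_min=config.gc_min
    )
    grades = grade_cohort(classifications, cohort.sections)
    proportions = region_proportions(cohort.cells, cohort.regions, rules)
    summary = build_patient_summary(
        proportions, grades, cohort.clinical,
        average_mode=config.average_mode, cell_weighted=config.cell_weighted,
    )

    classifications.to_csv(out / "tls_classification.csv", index=False)
    grades.to_csv(out / "patient_grades.csv", index=False)
    proportions.to_csv(out / "proportions.csv", index=False)
    summary.to_csv(out / "patient_summary.csv", index=False)

    survival_report = _survival_analyses(summary, config)
    group_report = _group_analyses(summary, cohort.clinical, config)

    _write_json(survival_report, out / "survival_report.json")
    _write_json(group_report, out / "group_stats_report.json")

    tables_text = render_tables(summary, cohort.clinical, survival_report)
    (out / "summary_tables.txt").write_text(tables_text)

    manifest = _manifest(config, cohort)
    _write_json(manifest, out / "manifest.json")

    if config.make_plots:
        _km_plots(summary, out)

    paths = {
        name: out / fname
        for name, fname in {
            "classifications": "tls_classification.csv",
            "grades": "patient_grades.csv",
            "proportions": "proportions.csv",
            "summary": "patient_summary.csv",
            "survival_report": "survival_report.json",
            "group_stats_report": "group_stats_report.json",
            "tables": "summary_tables.txt",
            "manifest": "manifest.json",
        }.items()
    }
    return PipelineResult(
        config=config,
        classifications=classifications,
        grades=grades,
        proportions=proportions,
        summary=summary,
        survival_report=survival_report,
        group_stats_report=group_report,
        paths=paths,
    )


def _survival_analyses(summary: pd.DataFrame, config: PipelineConfig) -> dict:
    report: dict = {"seed": config.seed, "minprop": config.minprop}
    time = summary["dfs_months"].to_numpy(float)
    event = summary["event"].to_numpy(int)
    grade = summary["grade"].to_numpy(int)

    # grade stratification: overall k-group test + pairwise comparisons
    groups = {g: (time[grade == g], event[grade == g]) for g in sorted(set(grade))}
    grade_block: dict = {
        "strata": {
            str(g): {"n": int(len(t)), "median": km_curve(t, e).median}
            for g, (t, e) in groups.items()
            if len(t) >= 2
        }
    }
    if len(grade_block["strata"]) >= 2:
        present = [g for g in groups if len(groups[g][0]) >= 2]
        try:
            k_res = logrank_k_groups([groups[g] for g in present])
            grade_block["k_group"] = {
                "chi_square": k_res.chi_square, "df": k_res.df, "p_value": k_res.p_value,
            }
        except UndefinedStatisticError as exc:
            grade_block["k_group"] = {"skipped": str(exc)}
        pairwise = []
        for i, ga in enumerate(present):
            for gb in present[i + 1:]:
                try:
                    res = logrank_test(*groups[gb], *groups[ga])  # later grade vs earlier
                except UndefinedStatisticError:
                    continue
                pairwise.append({"comparison": f"grade{gb}_vs_grade{ga}", **_logrank_record(res)})
        grade_block["pairwise"] = pairwise
    report["grade"] = grade_block

    # cutpoint analyses: TLS burden + each subset x compartment
    features = ["n_tls", "tls_density"]
    for subset in config.features:
        for compartment in ("inside", "outside", "average"):
            col = f"{subset}_{compartment}"
            if col in summary.columns:
                features.append(col)
    rng_root = np.random.SeedSequence(config.seed)
    feature_rngs = rng_root.spawn(len(features))
    report["features"] = [
        _feature_analysis(
            summary, col, minprop=config.minprop,
            n_permutations=config.n_permutations,
            rng=np.random.default_rng(feature_rngs[i]),
        )
        for i, col in enumerate(features)
    ]

    # combined grade x T_RM strata (grade 3 vs grade 1+2, high vs low)
    combined = {}
    feature_cutoffs = {
        rec["feature"]: rec.get("cutoff")
        for rec in report["features"]
        if rec.get("cutoff") is not None
    }
    for subset in TRM_FEATURES:
        col = f"{subset}_inside"
        cutoff = feature_cutoffs.get(col)
        if cutoff is None or col not in summary.columns:
            continue
        values = summary[col].to_numpy(float)
        hl = dichotomize(values, cutoff)
        labels = np.array(
            [
                None if h is None else f"grade{'3' if g == 3 else '1+2'}_{h}"
                for g, h in zip(grade, hl)
            ],
            dtype=object,
        )
        strat = stratified_analysis(time, event, labels)
        combined[col] = {
            "cutoff": cutoff,
            "strata": {
                name: {"n": info["n"], "median": info["median"]}
                for name, info in strat["strata"].items()
            },
            "pairwise": strat["pairwise"],
            "excluded": strat["excluded"],
        }
    report["combined_grade_trm"] = combined
    return report


def _group_analyses(summary: pd.DataFrame, clinical: pd.DataFrame, config: PipelineConfig) -> dict:
    report: dict = {}
    # paired inside-vs-outside comparisons (Wilcoxon signed-rank)
    paired = []
    for subset in config.features:
        cols = (f"{subset}_inside", f"{subset}_outside")
        if not all(c in summary.columns for c in cols):
            continue
        sub = summary[list(cols)].dropna()
        rec: dict = {"subset": subset, "n_pairs": int(len(sub))}
        try:
            res = wilcoxon_signed_rank(sub[cols[0]], sub[cols[1]])
            rec.update(
                statistic=res.statistic, p_value=res.p_value,
                n_used=res.n_used, method=res.method,
                mean_inside=float(sub[cols[0]].mean()),
                mean_outside=float(sub[cols[1]].mean()),
            )
        except (UndefinedStatisticError, TLSGradeError) as exc:
            rec["skipped"] = str(exc)
        paired.append(rec)
    report["inside_vs_outside_wilcoxon"] = paired

    # inside-TLS proportions across grades (Kruskal-Wallis)
    kw = []
    for subset in config.features:
        col = f"{subset}_inside"
        if col not in summary.columns:
            continue
        groups = [
            summary.loc[summary["grade"] == g, col].dropna().to_numpy()
            for g in sorted(summary["grade"].unique())
        ]
        rec = {"subset": subset, "grouping": "grade"}
        try:
            res = kruskal_wallis(groups)
            rec.update(H=res.statistic, df=res.df, p_value=res.p_value)
        except UndefinedStatisticError as exc:
            rec["skipped"] = str(exc)
        kw.append(rec)
    report["inside_by_grade_kruskal"] = kw

    # grade x covariate contingency tests
    merged = summary[["patient_id", "grade"]].merge(clinical, on="patient_id")
    contingency = []
    for cov in COVARIATES:
        if cov not in merged.columns or merged[cov].isna().all():
            continue
        table = pd.crosstab(merged[cov], merged["grade"])
        if table.shape[0] < 2 or table.shape[1] < 2:
            continue
        test = choose_association_test(table.to_numpy())
        rec = {
            "covariate": cov,
            "levels": [str(i) for i in table.index],
            "grades": [int(c) for c in table.columns],
            "counts": table.to_numpy().tolist(),
            "test": test,
        }
        try:
            if test == "fisher":
                rec["p_value"] = fisher_exact(table.to_numpy())
            else:
                res = chi_square_test(table.to_numpy())
                rec.update(chi_square=res.statistic, df=res.df, p_value=res.p_value)
        except TLSGradeError as exc:
            rec["skipped"] = str(exc)
        contingency.append(rec)
    report["grade_by_covariate"] = contingency
    return report


def _manifest(config: PipelineConfig, cohort: Cohort) -> dict:
    checksums = {}
    for name in ("cells", "regions", "sections", "clinical"):
        path = Path(config.input_dir) / f"{name}.csv"
        if path.exists():
            checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "input_checksums": checksums,
        "n_patients": int(cohort.clinical.shape[0]),
        "n_regions": int(cohort.regions.shape[0]),
        "n_cells": int(cohort.cells.shape[0]),
    }


# ---------------------------------------------------------------------------
# human-readable rendering


def render_percentages(counts) -> list[int]:
    """Row percentages rounded to the nearest integer (half away from zero)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot render percentages of an all-zero row")
    return [int(np.floor(100.0 * c / total + 0.5)) for c in counts]


def render_contingency(counts: np.ndarray, row_labels, col_labels, title: str) -> str:
    lines = [title, "\t" + "\t".join(str(c) for c in col_labels)]
    for label, row in zip(row_labels, counts):
        row = np.asarray(row)
        if row.sum() == 0:
            cells = ["—"] * len(row)
        else:
            pct = render_percentages(row)
            cells = [f"{int(v)} ({p}%)" for v, p in zip(row, pct)]
        lines.append(f"{label}\t" + "\t".join(cells))
    return "\n".join(lines)


def render_tables(summary: pd.DataFrame, clinical: pd.DataFrame, survival_report: dict) -> str:
    """Contingency and univariate-stratification summaries as plain text."""
    blocks = []
    merged = summary[["patient_id", "grade"]].merge(clinical, on="patient_id")
    grade_counts = merged["grade"].value_counts().sort_index()
    blocks.append(
        render_contingency(
            grade_counts.to_numpy()[None, :],
            ["all patients"],
            [f"grade {g}" for g in grade_counts.index],
            "Patient grade distribution",
        )
    )
    for cov in COVARIATES:
        if cov not in merged.columns or merged[cov].isna().all():
            continue
        table = pd.crosstab(merged[cov], merged["grade"])
        if table.shape[0] < 2:
            continue
        blocks.append(
            render_contingency(
                table.to_numpy(),
                [str(i) for i in table.index],
                [f"grade {g}" for g in table.columns],
                f"Grade by {cov}",
            )
        )
    lines = ["Univariate DFS stratification", "feature\tcutoff\tHR (95% CI)\tp"]
    for rec in survival_report.get("features", []):
        if "logrank" not in rec:
            lines.append(f"{rec['feature']}\t—\t—\t—")
            continue
        lr = rec["logrank"]
        ci = lr["hr_ci_95"]
        lines.append(
            f"{rec['feature']}\t>={rec['cutoff']:.3g}"
            f"\t{lr['hazard_ratio']:.3f} ({ci[0]:.3f}, {ci[1]:.3f})"
            f"\t{lr['p_value']:.4g}"
        )
    blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def _km_plots(summary: pd.DataFrame, out: Path) -> None:
    """Optional KM figure for the grade strata."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g in sorted(summary["grade"].dropna().unique()):
        sub = summary[summary["grade"] == g]
        curve = km_curve(sub["dfs_months"], sub["event"])
        t = np.r_[0, np.repeat(curve.times, 2)]
        s = np.r_[1.0, 1.0, np.repeat(curve.survival, 2)[:-1]]
        ax.step(t, s, where="post", label=f"grade {int(g)} (n={curve.n})")
    ax.set_xlabel("months")
    ax.set_ylabel("DFS probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "km_grade.png", dpi=120)
    plt.close(fig)
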