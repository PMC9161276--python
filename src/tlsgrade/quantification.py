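"""Subset proportions per region and patient-level compartment aggregates.

The proportion of a subset in a region (a TLS or an outside field) is the
percentage of that subpopulation among all nucleated cells of the region.
Patient-level aggregates average region proportions with equal weight per
region ("fields are the unit"), separately for the inside-TLS compartment,
the outside-TLS compartment, and the pooled average over all regions.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateRegionError, ValidationError
from .phenotyping import PhenotypeRule, default_rules, subset_masks

log = logging.getLogger(__name__)

COMPARTMENTS = ("inside", "outside", "average")


def region_proportion(counts: Mapping[str, int], total: int, subset: str) -> float:
    """Percentage of ``subset`` among the ``total`` nucleated cells."""
    if total < 1:
        raise DegenerateRegionError("proportion undefined for an empty region")
    return 100.0 * counts.get(subset, 0) / total


def region_proportions(
    cells: pd.DataFrame,
    regions: pd.DataFrame,
    rules: list[PhenotypeRule] | None = None,
) -> pd.DataFrame:
    """Long-format per-region proportions for every subset.

    Columns: patient_id, region_id, region_type, subset, proportion, n_cells.
    Regions without any cells are excluded with a logged warning (their
    proportions are undefined, never imputed zero).
    """
    rules = rules if rules is not None else default_rules()
    masks = subset_masks(cells, rules)
    by_region = masks.groupby(cells["region_id"].to_numpy()).sum()
    totals = cells.groupby("region_id").size()

    rows = []
    for rec in regions.itertuples(index=False):
        total = int(totals.get(rec.region_id, 0))
        if total == 0:
            log.warning(
                "region %s has no cells; excluded from proportions", rec.region_id
            )
            continue
        counts = by_region.loc[rec.region_id]
        for rule in rules:
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "region_id": rec.region_id,
                    "region_type": rec.region_type,
                    "subset": rule.subset,
                    "proportion": 100.0 * counts[rule.subset] / total,
                    "n_cells": total,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "region_id", "region_type", "subset", "proportion", "n_cells"],
    )


def patient_compartment_mean(proportions: Iterable[float]) -> float:
    """Unweighted arithmetic mean over region proportions; NaN if empty."""
    values = np.asarray(list(proportions), dtype=float)
    if values.size == 0:
        return float("nan")
    return float(values.mean())


def build_patient_summary(
    proportions: pd.DataFrame,
    grades: pd.DataFrame,
    clinical: pd.DataFrame,
    *,
    average_mode: str = "pooled",
    cell_weighted: bool = False,
) -> pd.DataFrame:
    """One row per patient: grade, TLS burden, and the three compartment
    aggregates for every subset.

    ``average_mode``: "pooled" (primary; mean over all regions pooled with
    equal region weight) or "mean_of_means" (mean of the two compartment
    means).  ``cell_weighted=True`` weights regions by their nucleated-cell
    count instead of equally.

    Raises :class:`ValidationError` when a patient in the cell-derived
    tables is absent from the clinical table.
    """
    if average_mode not in ("pooled", "mean_of_means"):
        raise ValidationError(f"unknown average_mode {average_mode!r}")
    missing = sorted(set(proportions["patient_id"]) - set(clinical["patient_id"]))
    if missing:
        raise ValidationError(
            "patients present in cell data but absent from clinical table",
            [str(m) for m in missing],
        )

    def agg(frame: pd.DataFrame) -> float:
        if len(frame) == 0:
            return float("nan")
        if cell_weighted:
            w = frame["n_cells"].to_numpy(float)
            return float(np.average(frame["proportion"].to_numpy(float), weights=w))
        return float(frame["proportion"].mean())

    subsets = sorted(set(proportions["subset"]))  # deterministic column order
    rows = []
    for patient_id, group in proportions.groupby("patient_id", sort=True):
        row: dict = {"patient_id": patient_id}
        for subset in subsets:
            sub = group[group["subset"] == subset]
            inside = agg(sub[sub["region_type"] == "tls"])
            outside = agg(sub[sub["region_type"] == "outside"])
            if average_mode == "pooled":
                overall = agg(sub)
            else:
                parts = [v for v in (inside, outside) if not np.isnan(v)]
                overall = float(np.mean(parts)) if parts else float("nan")
            if np.isnan(outside):
                log.warning(
                    "patient %s has no outside fields for %s; missing value recorded",
                    patient_id, subset,
                )
            row[f"{subset}_inside"] = inside
            row[f"{subset}_outside"] = outside
            row[f"{subset}_average"] = overall
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary = summary.merge(grades, on="patient_id", how="left")
    keep = [c for c in ("dfs_months", "event") if c in clinical.columns]
    summary = summary.merge(clinical[["patient_id", *keep]], on="patient_id", how="left")
    return summary
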