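"""Cohort table schemas, readers/writers and validation.

The pipeline consumes four UTF-8 comma-separated tables (header row
required, no index column, empty string = missing):

* ``cells.csv`` — patient_id, section_id, region_id, cell_id, CD3, CD4,
  CD20, CD21, CD103, BCL6 (binary 0/1 positivity; one row per nucleated
  cell).
* ``regions.csv`` — patient_id, section_id, region_id, region_type
  (``tls`` or ``outside``).
* ``sections.csv`` — patient_id, section_id, tumor_area_mm2.
* ``clinical.csv`` — patient_id, dfs_months, event (1 = recurrence
  observed, 0 = censored) plus optional covariate columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .phenotyping import MARKERS

CELL_COLUMNS = ["patient_id", "section_id", "region_id", "cell_id", *MARKERS]
REGION_COLUMNS = ["patient_id", "section_id", "region_id", "region_type"]
SECTION_COLUMNS = ["patient_id", "section_id", "tumor_area_mm2"]
CLINICAL_REQUIRED = ["patient_id", "dfs_months", "event"]

FILENAMES = {
    "cells": "cells.csv",
    "regions": "regions.csv",
    "sections": "sections.csv",
    "clinical": "clinical.csv",
}


@dataclass
class Cohort:
    """In-memory cohort: the four validated tables."""

    cells: pd.DataFrame
    regions: pd.DataFrame
    sections: pd.DataFrame
    clinical: pd.DataFrame


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the four CSVs; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, fname in FILENAMES.items():
        path = directory / fname
        getattr(cohort, name).to_csv(path, index=False)
        paths[name] = path
    return paths


def _require_columns(df: pd.DataFrame, required, table: str, problems: list[str]) -> bool:
    missing = [c for c in required if c not in df.columns]
    if missing:
        problems.append(f"{table}: missing column(s) {missing}")
        return False
    return True


def validate_cohort(cohort: Cohort) -> list[str]:
    """All schema and referential-integrity problems, as messages."""
    problems: list[str] = []
    cells, regions = cohort.cells, cohort.regions
    sections, clinical = cohort.sections, cohort.clinical

    cells_ok = _require_columns(cells, CELL_COLUMNS, "cells", problems)
    regions_ok = _require_columns(regions, REGION_COLUMNS, "regions", problems)
    sections_ok = _require_columns(sections, SECTION_COLUMNS, "sections", problems)
    clinical_ok = _require_columns(clinical, CLINICAL_REQUIRED, "clinical", problems)

    if cells_ok:
        for m in MARKERS:
            bad = ~cells[m].isin([0, 1])
            if bad.any():
                ids = cells.loc[bad, "cell_id"].head(5).tolist()
                problems.append(
                    f"cells: marker {m} has non-binary value(s); first offending cell_id(s): {ids}"
                )
        if cells["cell_id"].duplicated().any():
            dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].head(5).tolist()
            problems.append(f"cells: duplicate cell_id(s): {dup}")
    if regions_ok:
        bad = ~regions["region_type"].isin(["tls", "outside"])
        if bad.any():
            problems.append(
                "regions: region_type must be 'tls' or 'outside'; offending region_id(s): "
                f"{regions.loc[bad, 'region_id'].head(5).tolist()}"
            )
        if regions["region_id"].duplicated().any():
            problems.append("regions: duplicate region_id(s)")
    if sections_ok:
        bad = ~(pd.to_numeric(sections["tumor_area_mm2"], errors="coerce") > 0)
        if bad.any():
            problems.append(
                "sections: non-positive tumor_area_mm2 for section_id(s) "
                f"{sections.loc[bad, 'section_id'].head(5).tolist()}"
            )
    if clinical_ok:
        t = pd.to_numeric(clinical["dfs_months"], errors="coerce")
        if (t.isna() | (t < 0)).any():
            problems.append("clinical: dfs_months must be numeric and >= 0")
        if (~clinical["event"].isin([0, 1])).any():
            problems.append("clinical: event must be 0 or 1")
        if clinical["patient_id"].duplicated().any():
            problems.append("clinical: duplicate patient_id(s)")

    if cells_ok and regions_ok:
        orphans = sorted(set(cells["region_id"]) - set(regions["region_id"]))
        if orphans:
            problems.append(f"cells: region_id(s) absent from regions table: {orphans[:10]}")
    if regions_ok and sections_ok:
        orphans = sorted(set(regions["section_id"]) - set(sections["section_id"]))
        if orphans:
            problems.append(f"regions: section_id(s) absent from sections table: {orphans[:10]}")
    if cells_ok and clinical_ok:
        orphans = sorted(set(cells["patient_id"]) - set(clinical["patient_id"]))
        if orphans:
            problems.append(f"cells: patient_id(s) absent from clinical table: {orphans[:10]}")
    return problems


def read_cohort(directory: str | Path, *, validate: bool = True) -> Cohort:
    """Load and (by default) validate the four cohort CSVs from a directory."""
    directory = Path(directory)
    frames = {}
    for name, fname in FILENAMES.items():
        path = directory / fname
        if not path.exists():
            raise ValidationError(f"missing input file: {path}")
        frames[name] = pd.read_csv(path)
    cohort = Cohort(**frames)
    if validate:
        problems = validate_cohort(cohort)
        if problems:
            raise ValidationError(f"invalid cohort in {directory}", problems)
    return cohort
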