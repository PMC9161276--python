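"""TLS maturity classification, patient grade scoring, and TLS burden.

Tertiary lymphoid structures are staged by follicular organisation:

* **E-TLS** — early: dense lymphocytic aggregate, no CD21+ follicular
  dendritic cell (FDC) network, no germinal-centre (GC) reaction;
* **PFL-TLS** — primary follicle-like: CD21+ FDC network present, no GC
  reaction;
* **SFL-TLS** — secondary follicle-like: GC reaction present
  (CD20+Bcl-6+ B cells).

The GC test takes precedence: a structure with a GC reaction is SFL
regardless of its FDC count.

Patients (restricted to TLS-positive tumours) are scored from the maturity
of their TLS set: grade 1 = only E-TLS; grade 2 = at least one PFL-TLS and
no SFL-TLS; grade 3 = at least one SFL-TLS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError, DegenerateRegionError, ValidationError
from .phenotyping import PhenotypeRule, count_subsets, default_rules

E_TLS = "E_TLS"
PFL_TLS = "PFL_TLS"
SFL_TLS = "SFL_TLS"
MATURITY_STAGES = (E_TLS, PFL_TLS, SFL_TLS)

#: Subset labels used for staging under the default rules.
FDC_SUBSET = "fdc"
GCB_SUBSET = "gc_b"


@dataclass(frozen=True)
class TLSClassification:
    region_id: str
    maturity: str
    n_fdc: int
    n_gcb: int


def classify_tls_maturity(
    counts: Mapping[str, int],
    *,
    region_id: str = "",
    fdc_min: int = 1,
    gc_min: int = 1,
    fdc_subset: str = FDC_SUBSET,
    gcb_subset: str = GCB_SUBSET,
) -> TLSClassification:
    """Stage one TLS from its subset counts.

    SFL if the GC-B count reaches ``gc_min``; else PFL if the FDC count
    reaches ``fdc_min``; else E.  Defaults of one positive cell mirror a
    presence/absence reading of FDC-network and GC-reaction positivity; both
    thresholds are configurable to probe sensitivity to stray positives.
    """
    if fdc_min < 1 or gc_min < 1:
        raise ConfigurationError("fdc_min and gc_min must be >= 1")
    n_fdc = int(counts.get(fdc_subset, 0))
    n_gcb = int(counts.get(gcb_subset, 0))
    if n_gcb >= gc_min:
        maturity = SFL_TLS
    elif n_fdc >= fdc_min:
        maturity = PFL_TLS
    else:
        maturity = E_TLS
    return TLSClassification(region_id=region_id, maturity=maturity, n_fdc=n_fdc, n_gcb=n_gcb)


def grade_patient(maturities: Iterable[str]) -> int:
    """Patient grade from the maturity labels of all their TLSs.

    Order-invariant.  Raises for an empty list: the study design includes
    only TLS-positive tissue, so a patient without TLS is outside the
    inclusion criteria rather than "grade 0".
    """
    stages = list(maturities)
    if not stages:
        raise ValidationError("patient has no TLS; outside study inclusion criteria")
    unknown = set(stages) - set(MATURITY_STAGES)
    if unknown:
        raise ValidationError(f"unknown maturity label(s): {sorted(unknown)}")
    if SFL_TLS in stages:
        return 3
    if PFL_TLS in stages:
        return 2
    return 1


def tls_density(n_tls: int, tumor_area_mm2: float) -> float:
    """TLS per mm^2 of tumour tissue."""
    if n_tls < 0:
        raise ValidationError("n_tls must be >= 0")
    if not tumor_area_mm2 > 0:
        raise ValidationError(f"tumor area must be positive, got {tumor_area_mm2}")
    return n_tls / tumor_area_mm2


def classify_regions(
    cells: pd.DataFrame,
    regions: pd.DataFrame,
    rules: list[PhenotypeRule] | None = None,
    *,
    fdc_min: int = 1,
    gc_min: int = 1,
) -> pd.DataFrame:
    """Stage every TLS region of a cohort.

    Returns a frame with columns region_id, patient_id, maturity, n_fdc,
    n_gcb.  Outside fields are not staged.  TLS regions with zero cells are
    rejected (proportion and staging both undefined).
    """
    rules = rules if rules is not None else default_rules()
    tls_regions = regions[regions["region_type"] == "tls"]
    grouped = dict(tuple(cells.groupby("region_id", sort=False)))
    rows = []
    for rec in tls_regions.itertuples(index=False):
        region_cells = grouped.get(rec.region_id)
        if region_cells is None or len(region_cells) == 0:
            raise DegenerateRegionError(
                f"TLS region {rec.region_id!r} has no cells; cannot stage"
            )
        counts, _ = count_subsets(region_cells, rules)
        cls = classify_tls_maturity(
            counts, region_id=rec.region_id, fdc_min=fdc_min, gc_min=gc_min
        )
        rows.append(
            {
                "region_id": cls.region_id,
                "patient_id": rec.patient_id,
                "maturity": cls.maturity,
                "n_fdc": cls.n_fdc,
                "n_gcb": cls.n_gcb,
            }
        )
    return pd.DataFrame(
        rows, columns=["region_id", "patient_id", "maturity", "n_fdc", "n_gcb"]
    )


def grade_cohort(
    classifications: pd.DataFrame, sections: pd.DataFrame
) -> pd.DataFrame:
    """Per-patient grade, TLS count and TLS density.

    ``classifications`` is the output of :func:`classify_regions`; tumour
    area per patient is the sum over that patient's sections.
    """
    area = sections.groupby("patient_id")["tumor_area_mm2"].sum()
    rows = []
    for patient_id, group in classifications.groupby("patient_id", sort=True):
        n_tls = len(group)
        grade = grade_patient(group["maturity"])
        if patient_id not in area.index:
            raise ValidationError(f"patient {patient_id!r} missing from sections table")
        rows.append(
            {
                "patient_id": patient_id,
                "grade": grade,
                "n_tls": n_tls,
                "tls_density": tls_density(n_tls, float(area.loc[patient_id])),
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "grade", "n_tls", "tls_density"])
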