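"""Seeded synthetic cohorts with known ground truth.

The generator emulates the data structure behind a multiplex-IF TLS study:
per-patient sets of TLSs of mixed maturity, randomly sampled outside-TLS
fields, per-cell binary marker calls drawn from maturity- and
compartment-dependent frequencies, and disease-free survival times whose
hazard depends on the patient's TLS grade and T_RM stratum.  Every draw is
reproducible from the configured seed, and the planted truth (grades,
per-TLS maturities, T_RM strata, log-hazards) is returned alongside the
tables so each downstream stage can be tested by recovery.

Structural guarantees (not left to chance):

* CD21+ FDC cells never occur in E-TLS regions; CD20+Bcl6+ GC-B cells never
  occur in E- or PFL-TLS regions (frequency zero by construction).
* PFL regions contain at least one FDC cell and SFL regions at least one
  GC-B cell (all-negative cells are converted when the random draw falls
  short), so maturity classification at the default presence thresholds
  recovers the planted maturity for any region size.
* Each patient is generated from an independent, index-keyed substream of
  the root seed (patients -> regions -> cells -> survival), so extending the
  cohort never changes earlier patients.

Marker calls are generated as binary (already thresholded); an optional
intensity mode appends lognormal marker intensities consistent with the
binary calls at a fixed threshold of 1.0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import Cohort, write_cohort
from .phenotyping import MARKERS
from .tls_scoring import E_TLS, PFL_TLS, SFL_TLS

log = logging.getLogger(__name__)

# Cell archetypes: marker combination drawn per cell.  Combinations that are
# biologically impossible under the panel's gating (e.g. CD4+CD3- "T cells")
# simply do not appear in this list, giving them probability zero.
ARCHETYPES: dict[str, tuple[str, ...]] = {
    "negative": (),
    "cd4_t": ("CD3", "CD4"),
    "cd8_t": ("CD3",),
    "b_cell": ("CD20",),
    "fdc": ("CD21",),
    "gc_b": ("CD20", "BCL6"),
    "cd4_trm": ("CD3", "CD4", "CD103"),
    "cd8_trm": ("CD3", "CD103"),
    "cd103_other": ("CD103",),
}
_TRM_ARCHETYPES = ("cd4_trm", "cd8_trm")


@dataclass
class SurvivalParams:
    """Exponential DFS model: hazard = h0 * exp(b2*[grade=2] + b3*[grade=3]
    + bt*[T_RM high]); independent uniform dropout plus administrative
    censoring at max_followup_months."""

    baseline_hazard: float = 0.16          # events/month; ln2 / 4.3-month median
    log_hr_grade2: float = -0.87           # ln 0.418
    log_hr_grade3: float = -1.49           # ln 0.226
    log_hr_trm_high: float = -0.84         # ln 0.433
    censor_rate: float = 0.3
    max_followup_months: float = 60.0


def _default_maturity_mix() -> dict[int, dict[str, float]]:
    return {
        1: {E_TLS: 1.0},
        2: {E_TLS: 0.6, PFL_TLS: 0.4},
        3: {E_TLS: 0.45, PFL_TLS: 0.35, SFL_TLS: 0.2},
    }


def _default_base_freqs() -> dict[str, float]:
    # outside-TLS marker-combination frequencies (fractions of nucleated cells)
    return {
        "cd4_t": 0.037,
        "cd8_t": 0.16,
        "b_cell": 0.10,
        "fdc": 0.001,
        "gc_b": 0.0,
        "cd4_trm": 0.0026,
        "cd8_trm": 0.0055,
        "cd103_other": 0.002,
    }


def _default_enrichment() -> dict[str, float]:
    # inside-TLS multiplier per archetype
    return {
        "cd4_t": 2.0,
        "cd8_t": 1.1,
        "b_cell": 1.8,
        "cd4_trm": 3.2,
        "cd8_trm": 1.5,
        "cd103_other": 1.0,
    }


def _default_maturity_enrichment() -> dict[str, float]:
    # additional multiplier in SFL-TLS relative to E/PFL
    return {"cd4_trm": 2.5, "cd8_trm": 1.6, "b_cell": 1.4}


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults are sized to the printed aggregates of the emulated study: 49
    TLS-positive patients, ~16.5 TLSs and 3-5 outside fields per patient
    (807 TLSs + 151 outside fields in total), grade split ~6/26/17, and an
    exponential DFS model whose grade/T_RM log-hazards reproduce the
    reported univariate hazard-ratio magnitudes.
    """

    n_patients: int = 49
    grade_probs: tuple[float, float, float] = (0.12, 0.53, 0.35)
    tls_per_patient: tuple[int, int] = (10, 23)
    outside_fields_per_patient: tuple[int, int] = (3, 5)
    cells_per_region: tuple[int, int] = (200, 600)
    maturity_mix_by_grade: dict = field(default_factory=_default_maturity_mix)
    subset_base_freqs: dict = field(default_factory=_default_base_freqs)
    enrichment: dict = field(default_factory=_default_enrichment)
    maturity_enrichment: dict = field(default_factory=_default_maturity_enrichment)
    tls_fdc_freq: float = 0.006            # FDC frequency in PFL/SFL regions
    tls_gcb_freq: float = 0.004            # GC-B frequency in SFL regions
    trm_high_prob: float = 0.6
    trm_high_multiplier: float = 2.0
    tumor_area_mm2: tuple[float, float] = (150.0, 450.0)
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    intensity_mode: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        probs = np.asarray(self.grade_probs, dtype=float)
        if probs.size != 3 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigurationError("grade_probs must be a 3-vector summing to 1")
        for name in ("tls_per_patient", "outside_fields_per_patient", "cells_per_region"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ConfigurationError(f"{name} range must satisfy 0 <= min <= max")
        if self.tls_per_patient[0] < 1:
            raise ConfigurationError("every patient needs at least one TLS (inclusion criterion)")
        lo, hi = self.tumor_area_mm2
        if not (0 < lo <= hi):
            raise ConfigurationError("tumor_area_mm2 range must be positive with min <= max")
        if not self.survival.baseline_hazard > 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if not 0 <= self.survival.censor_rate <= 1:
            raise ConfigurationError("censor_rate must lie in [0, 1]")
        if self.survival.max_followup_months < 0:
            raise ConfigurationError("max_followup_months must be >= 0")
        for grade in (1, 2, 3):
            mix = self.maturity_mix_by_grade.get(grade)
            if probs[grade - 1] > 0 and mix is None:
                raise ConfigurationError(f"grade {grade} has probability > 0 but no maturity mix")
            if mix is None:
                continue
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
                raise ConfigurationError(f"maturity mix for grade {grade} must sum to 1")
            if probs[grade - 1] > 0:
                if grade == 1 and mix.get(E_TLS, 0.0) != 1.0:
                    raise ConfigurationError(
                        "grade 1 requires an all-E maturity mix (only E-TLS allowed)"
                    )
                if grade == 2 and (mix.get(SFL_TLS, 0.0) > 0 or mix.get(PFL_TLS, 0.0) == 0):
                    raise ConfigurationError(
                        "grade 2 mix must give PFL probability > 0 and SFL probability 0"
                    )
                if grade == 3 and mix.get(SFL_TLS, 0.0) == 0:
                    raise ConfigurationError("grade 3 mix must give SFL probability > 0")
        for name, freqs in (
            ("subset_base_freqs", self.subset_base_freqs),
            ("enrichment", self.enrichment),
            ("maturity_enrichment", self.maturity_enrichment),
        ):
            unknown = set(freqs) - set(ARCHETYPES)
            if unknown:
                raise ConfigurationError(f"{name} names unknown archetype(s) {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Planted truth of one simulated cohort."""

    grades: dict[str, int]
    maturities: dict[str, str]          # region_id -> maturity (TLS only)
    trm_high: dict[str, bool]
    log_hazard: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "grades": self.grades,
                    "maturities": self.maturities,
                    "trm_high": self.trm_high,
                    "log_hazard": self.log_hazard,
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            grades={k: int(v) for k, v in d["grades"].items()},
            maturities=d["maturities"],
            trm_high={k: bool(v) for k, v in d["trm_high"].items()},
            log_hazard={k: float(v) for k, v in d["log_hazard"].items()},
        )


def _archetype_probs(
    config: SimConfig, region_class: str, trm_high: bool
) -> np.ndarray:
    """Categorical distribution over archetypes for one region class.

    ``region_class`` is "outside", E_TLS, PFL_TLS or SFL_TLS.  Frequencies
    exceeding a total of 1 are proportionally clipped with a logged warning;
    the all-negative archetype absorbs the remaining mass.
    """
    names = [n for n in ARCHETYPES if n != "negative"]
    freqs = np.array([config.subset_base_freqs.get(n, 0.0) for n in names])
    if region_class != "outside":
        enr = np.array([config.enrichment.get(n, 1.0) for n in names])
        freqs = freqs * enr
        for i, n in enumerate(names):
            if n == "fdc":
                freqs[i] = config.tls_fdc_freq if region_class in (PFL_TLS, SFL_TLS) else 0.0
            if n == "gc_b":
                freqs[i] = config.tls_gcb_freq if region_class == SFL_TLS else 0.0
        if region_class == SFL_TLS:
            mat = np.array([config.maturity_enrichment.get(n, 1.0) for n in names])
            freqs = np.where(
                [n not in ("fdc", "gc_b") for n in names], freqs * mat, freqs
            )
        if trm_high:
            for i, n in enumerate(names):
                if n in _TRM_ARCHETYPES:
                    freqs[i] *= config.trm_high_multiplier
    total = freqs.sum()
    if total > 1.0:
        log.warning(
            "archetype frequencies for %s sum to %.3f > 1; proportionally clipped",
            region_class, total,
        )
        freqs = freqs / total * 0.999
    out = np.empty(len(ARCHETYPES))
    out[0] = 1.0 - freqs.sum()  # "negative" is first
    out[1:] = freqs
    return out


def simulate_survival(
    grade: int,
    trm_high: bool,
    params: SurvivalParams,
    rng: np.random.Generator,
) -> tuple[float, int, float]:
    """One (observed time, event indicator, true log-hazard) draw.

    Event time is exponential with hazard h0 * exp(b2*[g=2] + b3*[g=3] +
    bt*[high]); censoring is min(administrative follow-up, optional uniform
    dropout); observed time = min(event, censor).
    """
    if not params.baseline_hazard > 0:
        raise ConfigurationError("baseline_hazard must be positive")
    if grade not in (1, 2, 3):
        raise ConfigurationError(f"grade must be 1, 2 or 3, got {grade}")
    log_h = (
        np.log(params.baseline_hazard)
        + (params.log_hr_grade2 if grade == 2 else 0.0)
        + (params.log_hr_grade3 if grade == 3 else 0.0)
        + (params.log_hr_trm_high if trm_high else 0.0)
    )
    t_event = rng.exponential(1.0 / np.exp(log_h))
    c = params.max_followup_months
    if rng.random() < params.censor_rate:
        c = min(c, rng.uniform(0.0, params.max_followup_months))
    time = min(t_event, c)
    event = int(t_event <= c)
    return float(time), event, float(log_h)


def _covariates(rng: np.random.Generator) -> dict[str, str]:
    """Clinical covariates from baseline-table-like marginals (independent)."""
    return {
        "sex": "male" if rng.random() < 0.49 else "female",
        "age": "ge60" if rng.random() < 0.43 else "lt60",
        "t_stage": "T1" if rng.random() < 0.59 else "T2-4",
        "n_stage": "N3" if rng.random() < 0.12 else "N1-2",
        "tnm_stage": "IIIB" if rng.random() < 0.20 else "IIIA",
        "micropapillary": "positive" if rng.random() < 0.45 else "negative",
        "egfr": "positive" if rng.random() < 0.60 else "negative",
        "smoking": "smoker" if rng.random() < 0.47 else "never",
    }


def _draw_region_cells(
    config: SimConfig,
    rng: np.random.Generator,
    region_class: str,
    trm_high: bool,
    n_cells: int,
) -> np.ndarray:
    """Marker matrix (n_cells x 6) for one region, with maturity minima."""
    probs = _archetype_probs(config, region_class, trm_high)
    idx = rng.choice(len(ARCHETYPES), size=n_cells, p=probs)
    names = list(ARCHETYPES)
    # enforce presence of the defining cells for the planted maturity
    required = []
    if region_class == PFL_TLS:
        required = [("fdc", 1)]
    elif region_class == SFL_TLS:
        required = [("gc_b", 1)]
    for arch, minimum in required:
        arch_i = names.index(arch)
        short = minimum - int((idx == arch_i).sum())
        if short > 0:
            negatives = np.nonzero(idx == 0)[0]
            idx[negatives[:short]] = arch_i
    marker_idx = {m: j for j, m in enumerate(MARKERS)}
    matrix = np.zeros((n_cells, len(MARKERS)), dtype=int)
    for j, name in enumerate(names):
        rows = idx == j
        for m in ARCHETYPES[name]:
            matrix[rows, marker_idx[m]] = 1
    return matrix


def _intensities(matrix: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Lognormal intensities consistent with binary calls at threshold 1.0."""
    pos = np.exp(rng.normal(0.7, 0.4, size=matrix.shape))
    neg = np.exp(rng.normal(-0.9, 0.4, size=matrix.shape))
    return np.where(matrix == 1, np.maximum(pos, 1.0), np.minimum(neg, 0.999))


def simulate_cohort(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate one cohort (cells, regions, sections, clinical) plus truth.

    Deterministic given ``config.seed``; patient ``i`` is generated from
    substream ``i`` so earlier patients are unaffected by ``n_patients``.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_patients)

    cell_blocks: list[dict] = []  # one dict of column arrays per region
    region_rows = []
    section_rows = []
    clinical_rows = []
    truth = GroundTruth(grades={}, maturities={}, trm_high={}, log_hazard={})

    for i in range(config.n_patients):
        rng = np.random.default_rng(children[i])
        pid = f"P{i:03d}"
        sid = f"{pid}_S1"
        grade = int(rng.choice((1, 2, 3), p=config.grade_probs))
        trm_high = bool(rng.random() < config.trm_high_prob)
        n_tls = int(rng.integers(config.tls_per_patient[0], config.tls_per_patient[1] + 1))
        n_out = int(
            rng.integers(
                config.outside_fields_per_patient[0],
                config.outside_fields_per_patient[1] + 1,
            )
        )
        mix = config.maturity_mix_by_grade[grade]
        stages = list(mix)
        mix_p = np.array([mix[s] for s in stages])
        maturities = [str(rng.choice(stages, p=mix_p)) for _ in range(n_tls)]
        # enforce grade consistency on the drawn set
        if grade == 2 and PFL_TLS not in maturities:
            maturities[0] = PFL_TLS
        if grade == 3 and SFL_TLS not in maturities:
            maturities[0] = SFL_TLS

        area = float(rng.uniform(*config.tumor_area_mm2))
        section_rows.append({"patient_id": pid, "section_id": sid, "tumor_area_mm2": area})

        region_specs = [(f"{pid}_TLS{j:02d}", "tls", maturities[j]) for j in range(n_tls)]
        region_specs += [(f"{pid}_OUT{j:02d}", "outside", "outside") for j in range(n_out)]
        for region_id, region_type, region_class in region_specs:
            region_rows.append(
                {
                    "patient_id": pid,
                    "section_id": sid,
                    "region_id": region_id,
                    "region_type": region_type,
                }
            )
            if region_type == "tls":
                truth.maturities[region_id] = region_class
            n_cells = int(
                rng.integers(config.cells_per_region[0], config.cells_per_region[1] + 1)
            )
            if n_cells == 0:
                continue
            matrix = _draw_region_cells(config, rng, region_class, trm_high, n_cells)
            block = {
                "patient_id": np.full(n_cells, pid, dtype=object),
                "section_id": np.full(n_cells, sid, dtype=object),
                "region_id": np.full(n_cells, region_id, dtype=object),
                "cell_id": np.array(
                    [f"{region_id}_C{c:04d}" for c in range(n_cells)], dtype=object
                ),
            }
            for j, m in enumerate(MARKERS):
                block[m] = matrix[:, j]
            if config.intensity_mode:
                intensities = _intensities(matrix, rng)
                for j, m in enumerate(MARKERS):
                    block[f"{m}_intensity"] = intensities[:, j]
            cell_blocks.append(block)

        time, event, log_h = simulate_survival(grade, trm_high, config.survival, rng)
        clinical_rows.append(
            {"patient_id": pid, "dfs_months": time, "event": event, **_covariates(rng)}
        )
        truth.grades[pid] = grade
        truth.trm_high[pid] = trm_high
        truth.log_hazard[pid] = log_h

    cell_cols = ["patient_id", "section_id", "region_id", "cell_id", *MARKERS]
    if config.intensity_mode:
        cell_cols += [f"{m}_intensity" for m in MARKERS]
    if cell_blocks:
        cells = pd.DataFrame(
            {col: np.concatenate([b[col] for b in cell_blocks]) for col in cell_cols}
        )
    else:
        cells = pd.DataFrame(columns=cell_cols)
    cohort = Cohort(
        cells=cells,
        regions=pd.DataFrame(
            region_rows, columns=["patient_id", "section_id", "region_id", "region_type"]
        ),
        sections=pd.DataFrame(
            section_rows, columns=["patient_id", "section_id", "tumor_area_mm2"]
        ),
        clinical=pd.DataFrame(
            clinical_rows,
            columns=[
                "patient_id", "dfs_months", "event", "sex", "age", "t_stage",
                "n_stage", "tnm_stage", "micropapillary", "egfr", "smoking",
            ],
        ),
    )
    return cohort, truth


def simulate_clinical(
    n_patients: int,
    grade_probs: tuple[float, float, float],
    survival: SurvivalParams,
    *,
    trm_high_prob: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Fast clinical-only cohort (grade, T_RM stratum, DFS) without cells.

    Shares the survival model of :func:`simulate_cohort`; intended for
    large survival-statistics simulations where cell tables are not needed.
    """
    probs = np.asarray(grade_probs, dtype=float)
    if probs.size != 3 or abs(probs.sum() - 1.0) > 1e-12 or np.any(probs < 0):
        raise ConfigurationError("grade_probs must be a 3-vector summing to 1")
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root)
    grades = rng.choice((1, 2, 3), size=n_patients, p=probs)
    highs = rng.random(n_patients) < trm_high_prob
    rows = []
    for i in range(n_patients):
        time, event, log_h = simulate_survival(int(grades[i]), bool(highs[i]), survival, rng)
        rows.append(
            {
                "patient_id": f"P{i:03d}",
                "grade": int(grades[i]),
                "trm_high": bool(highs[i]),
                "dfs_months": time,
                "event": event,
                "log_hazard": log_h,
            }
        )
    return pd.DataFrame(rows)


def write_fixture(cohort: Cohort, truth: GroundTruth, directory: str | Path) -> dict[str, Path]:
    """Write the four cohort CSVs plus the ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = write_cohort(cohort, directory)
    truth_path = directory / "truth.json"
    truth.to_json(truth_path)
    paths["truth"] = truth_path
    return paths
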