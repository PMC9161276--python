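"""Marker-based phenotyping of multiplex-IF cell tables.

Every row of a cell table is one DAPI+ nucleated cell with binary positivity
calls for the six-marker panel (CD3, CD4, CD20, CD21, CD103, BCL6).  A
:class:`PhenotypeRule` maps required-positive / required-negative marker sets
to an immune-subset label.  Labels are non-exclusive: a CD3+CD4-CD103+ cell
is simultaneously a CD8 T cell, a CD3+ T_RM and a CD8+ T_RM.

The default gates ship in ``data/default_rules.yaml`` and implement the
standard reading of the panel:

====== ===========================
subset gate
====== ===========================
cd4_t   CD3+ CD4+
cd8_t   CD3+ CD4-
b_cell  CD20+
fdc     CD21+
cd3_trm CD3+ CD103+
cd4_trm CD3+ CD4+ CD103+
cd8_trm CD3+ CD4- CD103+
gc_b    CD20+ BCL6+
====== ===========================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import ConfigurationError, DegenerateRegionError

#: The six-marker panel, in canonical column order.
MARKERS: tuple[str, ...] = ("CD3", "CD4", "CD20", "CD21", "CD103", "BCL6")


@dataclass(frozen=True)
class PhenotypeRule:
    """One immune-subset gate over the six-marker panel."""

    subset: str
    positive: frozenset = field(default_factory=frozenset)
    negative: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "positive", frozenset(self.positive))
        object.__setattr__(self, "negative", frozenset(self.negative))
        unknown = (self.positive | self.negative) - set(MARKERS)
        if unknown:
            raise ConfigurationError(
                f"rule {self.subset!r} references unknown marker(s) "
                f"{sorted(unknown)}; panel is {list(MARKERS)}"
            )
        if self.positive & self.negative:
            raise ConfigurationError(
                f"rule {self.subset!r} lists marker(s) "
                f"{sorted(self.positive & self.negative)} as both positive and negative"
            )
        if not self.positive:
            raise ConfigurationError(f"rule {self.subset!r} has no positive markers")

    def matches(self, cell: Mapping[str, int]) -> bool:
        return all(cell[m] == 1 for m in self.positive) and all(
            cell[m] == 0 for m in self.negative
        )


def _rules_from_records(records: Iterable[Mapping]) -> list[PhenotypeRule]:
    rules = []
    for rec in records:
        rules.append(
            PhenotypeRule(
                subset=rec["subset"],
                positive=frozenset(rec.get("positive") or ()),
                negative=frozenset(rec.get("negative") or ()),
            )
        )
    names = [r.subset for r in rules]
    if len(names) != len(set(names)):
        raise ConfigurationError("duplicate subset names in rules")
    return rules


def load_rules(path: str | Path) -> list[PhenotypeRule]:
    """Load gating rules from a YAML file (list of subset/positive/negative)."""
    with open(path) as fh:
        records = yaml.safe_load(fh)
    if not records:
        raise ConfigurationError(f"no rules found in {path}")
    return _rules_from_records(records)


def default_rules() -> list[PhenotypeRule]:
    """The packaged default gates (see module docstring)."""
    text = resources.files("tlsgrade.data").joinpath("default_rules.yaml").read_text()
    return _rules_from_records(yaml.safe_load(text))


def assign_phenotypes(cell: Mapping[str, int], rules: Iterable[PhenotypeRule]) -> set[str]:
    """Return every subset label whose gate the cell satisfies.

    ``cell`` is any mapping with the six marker keys (a dict, a pandas row).
    The result does not depend on rule order.
    """
    rules = list(rules)
    if not rules:
        raise ConfigurationError("empty rule list")
    return {r.subset for r in rules if r.matches(cell)}


def subset_masks(cells: pd.DataFrame, rules: Iterable[PhenotypeRule]) -> pd.DataFrame:
    """Boolean membership matrix (cells x subsets), vectorised over the table."""
    rules = list(rules)
    if not rules:
        raise ConfigurationError("empty rule list")
    missing = set(MARKERS) - set(cells.columns)
    if missing:
        raise ConfigurationError(f"cell table lacks marker column(s) {sorted(missing)}")
    out = {}
    for rule in rules:
        mask = pd.Series(True, index=cells.index)
        for m in rule.positive:
            mask &= cells[m].to_numpy() == 1
        for m in rule.negative:
            mask &= cells[m].to_numpy() == 0
        out[rule.subset] = mask
    return pd.DataFrame(out, index=cells.index)


def count_subsets(
    cells: pd.DataFrame, rules: Iterable[PhenotypeRule]
) -> tuple[dict[str, int], int]:
    """Per-subset cell counts and the total nucleated count for one region.

    All rows must belong to a single region.  Every row counts as one
    nucleated cell (DAPI positivity is the upstream segmentation criterion),
    so ``total == len(cells)`` and ``counts[s] <= total`` for every subset.
    """
    if "region_id" in cells.columns and cells["region_id"].nunique() > 1:
        raise ConfigurationError(
            "count_subsets expects cells of a single region; got "
            f"{sorted(cells['region_id'].unique())}"
        )
    if len(cells) == 0:
        raise DegenerateRegionError("region has no nucleated cells")
    masks = subset_masks(cells, rules)
    counts = {s: int(masks[s].sum()) for s in masks.columns}
    return counts, len(cells)
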