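"""Rare-biosphere classification into six abundance categories.

Every OTU is assigned exactly one label from its per-sample relative
abundances, using two thresholds: ``rare`` (default 0.01% = 1e-4) and
``abundant`` (default 1% = 1e-2).  "Abundant" is an inclusive comparison
(>= threshold); "rare" is strict (< threshold), so an OTU sitting exactly
at 0.01% is not rare.

Categories
----------
AAT   always abundant: >= abundant in every sample
ART   always rare: < rare in every sample
MT    moderate: within [rare, abundant) in every sample
CRAT  conditionally rare and abundant: < rare somewhere and >= abundant somewhere
CAT   conditionally abundant: >= rare everywhere, >= abundant somewhere
CRT   conditionally rare: < abundant everywhere, < rare somewhere (not everywhere)

AAT + CAT + CRAT pool into the "dominant" subcommunity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .otu import OtuTable, RelAbundTable

CATEGORIES = ("AAT", "CAT", "MT", "ART", "CRT", "CRAT")
DOMINANT = ("AAT", "CAT", "CRAT")

RARE_THRESHOLD = 1e-4
ABUNDANT_THRESHOLD = 1e-2


@dataclass
class RarityAssignment:
    """Per-OTU category labels plus the thresholds that produced them."""

    category: pd.Series  # index = otu id, values in CATEGORIES
    rare_threshold: float
    abundant_threshold: float

    def otus(self, *categories: str) -> list[str]:
        bad = set(categories) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")
        mask = self.category.isin(categories)
        return list(self.category.index[mask])

    @property
    def dominant_otus(self) -> list[str]:
        return self.otus(*DOMINANT)

    def counts(self) -> pd.Series:
        return self.category.value_counts().reindex(CATEGORIES, fill_value=0)


def classify_taxa(
    rel: RelAbundTable,
    rare_threshold: float = RARE_THRESHOLD,
    abundant_threshold: float = ABUNDANT_THRESHOLD,
) -> RarityAssignment:
    """Assign each OTU one of the six rarity categories.

    The rules are mutually exclusive and exhaustive over the lattice of
    (any sample rare, any sample moderate, any sample abundant) states.
    """
    if not (0 < rare_threshold < abundant_threshold < 1):
        raise ValueError(
            "thresholds must satisfy 0 < rare < abundant < 1, got "
            f"{rare_threshold} and {abundant_threshold}"
        )
    vals = rel.values.to_numpy(dtype=float)
    below_rare = vals < rare_threshold
    at_least_abund = vals >= abundant_threshold

    any_rare = below_rare.any(axis=0)
    all_rare = below_rare.all(axis=0)
    any_abund = at_least_abund.any(axis=0)
    all_abund = at_least_abund.all(axis=0)

    labels = np.empty(vals.shape[1], dtype=object)
    labels[:] = "MT"  # within [rare, abundant) everywhere
    labels[all_abund] = "AAT"
    labels[all_rare] = "ART"
    labels[any_rare & any_abund] = "CRAT"
    labels[~any_rare & any_abund & ~all_abund] = "CAT"
    labels[any_rare & ~all_rare & ~any_abund] = "CRT"

    return RarityAssignment(
        category=pd.Series(labels, index=rel.otu_ids, name="category"),
        rare_threshold=rare_threshold,
        abundant_threshold=abundant_threshold,
    )


def _check_same_otus(assign: RarityAssignment, table: OtuTable) -> None:
    if set(assign.category.index) != set(table.otu_ids):
        raise ValueError("assignment and table cover different OTU sets")


def pool_dominant(assign: RarityAssignment, table: OtuTable) -> OtuTable:
    """Subtable of the pooled dominant (AAT + CAT + CRAT) OTUs."""
    _check_same_otus(assign, table)
    otus = assign.dominant_otus
    if not otus:
        warnings.warn("dominant pool is empty (no AAT/CAT/CRAT OTUs)", stacklevel=2)
    return table.subset_otus(otus)


def select_category(assign: RarityAssignment, table: OtuTable, *categories: str) -> OtuTable:
    """Subtable restricted to the OTUs of the given categories."""
    _check_same_otus(assign, table)
    otus = assign.otus(*categories)
    if not otus:
        warnings.warn(f"selection {categories} is empty", stacklevel=2)
    return table.subset_otus(otus)


def write_assignment(assign: RarityAssignment, path) -> None:
    """Two-column TSV (otu_id, category)."""
    out = assign.category.rename_axis("otu_id")
    out.to_frame().to_csv(path, sep="\t", lineterminator="\n")
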