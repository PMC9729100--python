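"""Biallelic editing-outcome tabulation across single cells.

Because InDel repair is far more efficient than knock-in, most cells with
a knock-in on one allele carry a disruptive edit on the other — a built-in
loss of heterozygosity that lets recessive loss-of-function variants show
a phenotype without a second engineered hit.  This module tabulates
unordered allele-pair counts from per-cell genotype calls and quantifies
that conditional structure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .quant import AlleleCategory

__all__ = [
    "SingleCellGenotype",
    "ZygosityTable",
    "tabulate_zygosity",
    "loh_assessment",
    "LohAssessment",
]

DEFAULT_DISRUPTIVE = (
    AlleleCategory.FRAMESHIFT_INDEL,
    AlleleCategory.VARIANT_KI,
    AlleleCategory.INFRAME_INDEL,
)


@dataclass(frozen=True)
class SingleCellGenotype:
    """Allele-category calls for one diploid cell (unordered pair)."""

    cell_id: str
    allele_1: AlleleCategory
    allele_2: AlleleCategory
    confident: bool = True

    @property
    def pair(self) -> tuple[AlleleCategory, AlleleCategory]:
        a, b = sorted((self.allele_1, self.allele_2), key=lambda c: c.value)
        return (a, b)


@dataclass
class ZygosityTable:
    """Counts over unordered allele-category pairs, with conditionals."""

    pair_counts: Counter
    n_cells: int

    def cells_with(self, category: AlleleCategory) -> int:
        return sum(n for (a, b), n in self.pair_counts.items() if category in (a, b))

    def conditional(self, category: AlleleCategory) -> dict[AlleleCategory, float]:
        """P(other allele = c | one allele = category).

        A homozygous pair contributes one cell to the conditioning set with
        the other allele equal to the same category.
        """
        denom = self.cells_with(category)
        if denom == 0:
            return {}
        out: dict[AlleleCategory, float] = {}
        for (a, b), n in self.pair_counts.items():
            if category not in (a, b):
                continue
            other = b if a == category else a
            out[other] = out.get(other, 0.0) + n / denom
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"allele_1": a.value, "allele_2": b.value, "cells": n}
            for (a, b), n in sorted(self.pair_counts.items(), key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows)


def tabulate_zygosity(genotypes: list[SingleCellGenotype]) -> ZygosityTable:
    """Unordered-pair counts over single-cell genotype calls."""
    if not genotypes:
        raise ValueError("no genotypes supplied")
    counts = Counter(g.pair for g in genotypes)
    return ZygosityTable(pair_counts=counts, n_cells=len(genotypes))


@dataclass(frozen=True)
class LohAssessment:
    """Fraction of knock-in cells with overall gene loss, with breakdown."""

    fraction: float | None
    breakdown: dict = field(default_factory=dict)
    n_knockin_cells: int = 0
    undefined: bool = False


def loh_assessment(
    table: ZygosityTable,
    knockin_category: AlleleCategory = AlleleCategory.VARIANT_KI,
    disruptive: tuple[AlleleCategory, ...] = DEFAULT_DISRUPTIVE,
) -> LohAssessment:
    """Built-in loss-of-heterozygosity fraction among knock-in cells.

    Sums the conditional second-allele mass over the configured disruptive
    categories (by default frameshift InDels, biallelic knock-in of the
    variant itself, and in-frame InDels — which at a typical target site
    remove the residue under test).
    """
    n_ki = table.cells_with(knockin_category)
    if n_ki == 0:
        return LohAssessment(fraction=None, undefined=True)
    cond = table.conditional(knockin_category)
    breakdown = {c: cond.get(c, 0.0) for c in disruptive}
    return LohAssessment(
        fraction=sum(breakdown.values()),
        breakdown=breakdown,
        n_knockin_cells=n_ki,
    )


def read_genotype_table(path) -> list[SingleCellGenotype]:
    """Load a TSV with columns cell_id, allele_1, allele_2."""
    df = pd.read_csv(path, sep="\t")
    return [
        SingleCellGenotype(
            cell_id=str(r["cell_id"]),
            allele_1=AlleleCategory(r["allele_1"]),
            allele_2=AlleleCategory(r["allele_2"]),
        )
        for _, r in df.iterrows()
    ]
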