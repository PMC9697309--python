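"""Threshold filter cascade on per-locus group-mean dN/dS values.

Loci are classified by the first matching rule, in fixed order:

1. parent-parent mean omega > 1.0        -> ``parental_divergence``
   (divergent between the parental species; would segregate in the F2 and
   produce false positive substitutions in parent-hybrid comparisons)
2. parental intraspecific mean > 1.0     -> ``intraspecific_polymorphism``
3. hybrid-hybrid mean > 4.0              -> ``hybrid_hybrid_divergence``
   (not shared by both hybrids, so not a candidate for a shared trait)
4. parent-hybrid mean <= 1.0             -> ``parent_hybrid_purifying``
5. otherwise (parent-hybrid mean > 1.0)  -> ``diversifying_annotated`` or
   ``diversifying_not_annotated`` depending on the annotation flag.

The boundary of rule 4 is inclusive: a mean of exactly 1.0 counts as
purifying, so selection requires a strictly elevated ratio.  Categories are
mutually exclusive and partition the input; a locus with a missing group
mean (e.g. all pairs of a group saturated) is reported as ``unscored``
outside the partition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping, Sequence

from .sample_design import PairGroup


@dataclass(frozen=True)
class FilterThresholds:
    parent_parent_max: float = 1.0
    intraspecific_max: float = 1.0
    hybrid_hybrid_max: float = 4.0
    parent_hybrid_select_min: float = 1.0  # strict: select iff mean > this

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be > 0, got {value}")


class FilterCategory(str, Enum):
    PARENTAL_DIVERGENCE = "parental_divergence"
    INTRASPECIFIC_POLYMORPHISM = "intraspecific_polymorphism"
    HYBRID_HYBRID_DIVERGENCE = "hybrid_hybrid_divergence"
    PARENT_HYBRID_PURIFYING = "parent_hybrid_purifying"
    DIVERSIFYING_NOT_ANNOTATED = "diversifying_not_annotated"
    DIVERSIFYING_ANNOTATED = "diversifying_annotated"


DIVERSIFYING_CATEGORIES = frozenset(
    {FilterCategory.DIVERSIFYING_ANNOTATED, FilterCategory.DIVERSIFYING_NOT_ANNOTATED}
)

UNSCORED = "unscored"


def classify_locus(
    group_means: Mapping[PairGroup, float | None],
    annotated: bool,
    thresholds: FilterThresholds = FilterThresholds(),
) -> FilterCategory | str:
    """Apply the cascade to one locus; first matching rule wins.

    Returns :data:`UNSCORED` when any required group mean is missing.
    """
    needed = (
        PairGroup.PARENT_PARENT,
        PairGroup.PARENT_INTRA,
        PairGroup.HYBRID_HYBRID,
        PairGroup.PARENT_HYBRID,
    )
    if any(group_means.get(g) is None for g in needed):
        return UNSCORED
    if group_means[PairGroup.PARENT_PARENT] > thresholds.parent_parent_max:
        return FilterCategory.PARENTAL_DIVERGENCE
    if group_means[PairGroup.PARENT_INTRA] > thresholds.intraspecific_max:
        return FilterCategory.INTRASPECIFIC_POLYMORPHISM
    if group_means[PairGroup.HYBRID_HYBRID] > thresholds.hybrid_hybrid_max:
        return FilterCategory.HYBRID_HYBRID_DIVERGENCE
    if group_means[PairGroup.PARENT_HYBRID] <= thresholds.parent_hybrid_select_min:
        return FilterCategory.PARENT_HYBRID_PURIFYING
    if annotated:
        return FilterCategory.DIVERSIFYING_ANNOTATED
    return FilterCategory.DIVERSIFYING_NOT_ANNOTATED


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to two decimals."""
    return float(
        (Decimal(100 * count) / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class FilterReport:
    """Category accounting for the cascade: counts, percentages, total."""

    counts: dict[FilterCategory, int]
    percentages: dict[FilterCategory, float]
    total: int
    unscored: int = 0

    @property
    def removed_by_divergence_filters(self) -> int:
        """Loci removed by the three upstream divergence filters."""
        return (
            self.counts[FilterCategory.PARENTAL_DIVERGENCE]
            + self.counts[FilterCategory.INTRASPECIFIC_POLYMORPHISM]
            + self.counts[FilterCategory.HYBRID_HYBRID_DIVERGENCE]
        )

    @property
    def above_selection_boundary(self) -> int:
        """Loci with parent-hybrid mean above the selection boundary."""
        return (
            self.counts[FilterCategory.DIVERSIFYING_ANNOTATED]
            + self.counts[FilterCategory.DIVERSIFYING_NOT_ANNOTATED]
        )

    def to_rows(self) -> list[dict[str, object]]:
        rows = [
            {
                "category": cat.value,
                "count": self.counts[cat],
                "percent": self.percentages[cat],
            }
            for cat in FilterCategory
        ]
        rows.append({"category": "total", "count": self.total, "percent": 100.0 if self.total else 0.0})
        return rows


def build_report(
    classifications: Sequence[FilterCategory | str],
) -> FilterReport:
    """Tally classified loci into the category accounting.

    ``unscored`` loci are counted separately and excluded from the
    percentage base (they never entered the partition).
    """
    tally = Counter(classifications)
    unscored = tally.pop(UNSCORED, 0)
    total = sum(tally.values())
    counts = {cat: tally.get(cat, 0) for cat in FilterCategory}
    if total == 0:
        import logging

        logging.getLogger(__name__).warning("empty classification input")
        percentages = {cat: 0.0 for cat in FilterCategory}
    else:
        percentages = {cat: _pct(counts[cat], total) for cat in FilterCategory}
    return FilterReport(
        counts=counts, percentages=percentages, total=total, unscored=unscored
    )


def report_from_counts(counts: Mapping[FilterCategory, int]) -> FilterReport:
    """Build the accounting directly from per-category counts."""
    classifications: list[FilterCategory] = []
    for cat, n in counts.items():
        classifications.extend([cat] * n)
    return build_report(classifications)
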