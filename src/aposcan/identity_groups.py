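"""Within-group sequence identity classification.

For each trimmed locus this asks whether the sequences are 100% identical
within the hybrid group and within the parental group, and -- when they are
not identical within the parents -- whether the variability comes from
divergence between the two parental species or from polymorphism within a
parental species (the study had two individuals of one species).  The
counts of flag combinations are what a Venn diagram of these sets renders.

Identity is assessed on the trimmed dN/dS block so that the identity and
selection analyses describe the same sequence region.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

from .sample_design import PARENTAL_ROLES, SampleDesign, SampleRole


@dataclass(frozen=True)
class IdentityProfile:
    """Per-locus identity flags; ``None`` marks a group absent from the design."""

    locus_id: str
    identical_within_hybrids: bool | None
    identical_within_parents: bool | None
    parental_variability_between_species: bool | None
    parental_variability_within_species: bool | None


def _all_equal(seqs: list[str]) -> bool:
    return all(s == seqs[0] for s in seqs[1:])


def profile_locus(
    sequences: Mapping[str, str], design: SampleDesign, locus_id: str = ""
) -> IdentityProfile:
    """Exact-string identity flags for one trimmed locus alignment."""
    hybrids = [sequences[s] for s in design.samples_with_role(SampleRole.HYBRID)]
    parents_a = [sequences[s] for s in design.samples_with_role(SampleRole.PARENT_A)]
    parents_b = [sequences[s] for s in design.samples_with_role(SampleRole.PARENT_B)]
    parents = parents_a + parents_b

    ident_hyb = _all_equal(hybrids) if len(hybrids) >= 2 else None
    ident_par = _all_equal(parents) if len(parents) >= 2 else None

    between = None
    if parents_a and parents_b:
        between = any(a != b for a in parents_a for b in parents_b)

    within = None
    intra_pairs = [
        (x, y)
        for group in (parents_a, parents_b)
        if len(group) >= 2
        for x, y in combinations(group, 2)
    ]
    if intra_pairs:
        within = any(x != y for x, y in intra_pairs)

    return IdentityProfile(
        locus_id=locus_id,
        identical_within_hybrids=ident_hyb,
        identical_within_parents=ident_par,
        parental_variability_between_species=between,
        parental_variability_within_species=within,
    )


def summarize_profiles(profiles: Iterable[IdentityProfile]) -> dict[str, int]:
    """Counts of identity categories over a locus set (for Venn rendering)."""
    counts: Counter[str] = Counter()
    n = 0
    for p in profiles:
        n += 1
        if p.identical_within_hybrids and p.identical_within_parents:
            counts["all_identical"] += 1
        if p.identical_within_hybrids:
            counts["hybrids_identical"] += 1
        elif p.identical_within_hybrids is False:
            counts["hybrids_variable"] += 1
        if p.identical_within_parents:
            counts["parents_identical"] += 1
        elif p.identical_within_parents is False:
            counts["parents_variable"] += 1
        if p.parental_variability_between_species:
            counts["parental_variability_between_species"] += 1
        if p.parental_variability_within_species:
            counts["parental_variability_within_species"] += 1
    result = {
        key: counts.get(key, 0)
        for key in (
            "all_identical",
            "hybrids_identical",
            "hybrids_variable",
            "parents_identical",
            "parents_variable",
            "parental_variability_between_species",
            "parental_variability_within_species",
        )
    }
    result["n_loci"] = n
    return result
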