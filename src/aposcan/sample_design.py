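"""Sample roles and pairwise comparison groups.

The study design behind this pipeline contrasts sexual parental plants with
aposporous F2 hybrids.  Every downstream statistic (pairwise dN/dS, the
filter cascade, identity profiles) is organised around the four kinds of
unordered sample pair this design induces:

* ``parent_parent_interspecific`` -- one individual of each parental species,
* ``parent_intraspecific``        -- two individuals of the same parental species,
* ``hybrid_hybrid``               -- two F2 hybrids,
* ``parent_hybrid``               -- a parent (either species) with a hybrid.

Roles are always supplied in configuration; they are never inferred from
sample names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping


class SampleRole(str, Enum):
    """Role of one sequenced individual in the crossing design."""

    PARENT_A = "parent_species_a"
    PARENT_B = "parent_species_b"
    HYBRID = "hybrid"

    @classmethod
    def parse(cls, label: str) -> "SampleRole":
        try:
            return cls(label)
        except ValueError:
            valid = ", ".join(r.value for r in cls)
            raise ValueError(
                f"unknown sample role {label!r}; expected one of: {valid}"
            ) from None


PARENTAL_ROLES = frozenset({SampleRole.PARENT_A, SampleRole.PARENT_B})


class PairGroup(str, Enum):
    """Comparison group of an unordered sample pair."""

    PARENT_PARENT = "parent_parent_interspecific"
    PARENT_INTRA = "parent_intraspecific"
    HYBRID_HYBRID = "hybrid_hybrid"
    PARENT_HYBRID = "parent_hybrid"


@dataclass(frozen=True)
class SampleDesign:
    """Ordered sample -> role assignment.

    Parameters
    ----------
    samples
        Sequence of ``(sample_id, role)`` tuples.  Sample ids must be unique.
    """

    samples: tuple[tuple[str, SampleRole], ...]

    def __init__(self, samples: Iterable[tuple[str, SampleRole | str]]):
        normalised = []
        seen: set[str] = set()
        for sample_id, role in samples:
            if sample_id in seen:
                raise ValueError(f"duplicate sample_id {sample_id!r} in design")
            seen.add(sample_id)
            if not isinstance(role, SampleRole):
                role = SampleRole.parse(role)
            normalised.append((sample_id, role))
        object.__setattr__(self, "samples", tuple(normalised))

    @classmethod
    def from_config(cls, entries: Iterable[Mapping[str, str]]) -> "SampleDesign":
        """Build from a config block ``[{"id": ..., "role": ...}, ...]``."""
        return cls((e["id"], e["role"]) for e in entries)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.samples)

    def role_of(self, sample_id: str) -> SampleRole:
        for sid, role in self.samples:
            if sid == sample_id:
                return role
        raise KeyError(f"sample {sample_id!r} not in design")

    def samples_with_role(self, role: SampleRole) -> tuple[str, ...]:
        return tuple(s for s, r in self.samples if r == role)

    def require_all_roles(self) -> None:
        """Cascade filtering needs at least one sample of every role."""
        missing = [r.value for r in SampleRole if not self.samples_with_role(r)]
        if missing:
            raise ValueError(
                "cascade filtering requires every role to be present; "
                f"missing: {', '.join(missing)}"
            )

    def __len__(self) -> int:
        return len(self.samples)


def classify_pair(role_a: SampleRole, role_b: SampleRole) -> PairGroup:
    """Group of an unordered pair, symmetric in argument order."""
    roles = {role_a, role_b}
    if roles == PARENTAL_ROLES:
        return PairGroup.PARENT_PARENT
    if roles == {SampleRole.HYBRID}:
        return PairGroup.HYBRID_HYBRID
    if SampleRole.HYBRID in roles:
        return PairGroup.PARENT_HYBRID
    # same parental role on both sides (either species)
    return PairGroup.PARENT_INTRA


def enumerate_pairs(design: SampleDesign) -> dict[tuple[str, str], PairGroup]:
    """Map every unordered sample pair to its :class:`PairGroup`.

    Keys are ``(sample_a, sample_b)`` in design order; the grouping itself
    does not depend on that order.  For the five-sample study design
    (1 parent A, 2 parent B, 2 hybrids) this yields 10 pairs: 2
    parent-parent, 1 intraspecific, 1 hybrid-hybrid and 6 parent-hybrid.
    """
    if len(design) < 2:
        raise ValueError("need at least two samples to enumerate pairs")
    return {
        (a, b): classify_pair(design.role_of(a), design.role_of(b))
        for a, b in combinations(design.sample_ids, 2)
    }
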