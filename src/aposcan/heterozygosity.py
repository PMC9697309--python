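"""Per-position heterozygosity from read pileups.

A position is called heterozygous when the minor base call (the
second-most-frequent base) reaches at least ``minor_fraction_min`` of the
read depth (default 10%, boundary inclusive) -- a simple diploid rule that
excludes erroneous base calls without a genotype-likelihood model.
Per-locus summaries are the percentage of heterozygous positions among
positions with data; per-sample averages are unweighted means across loci.

Input is SAMtools-mpileup text (6 columns); read-start (``^`` + mapping
quality), read-end (``$``), indel spans, deletion placeholders (``*``) and
reference skips are stripped before counting, and ``.``/``,`` resolve to
the reference base given on the line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from statistics import fmean
from typing import Iterable, Iterator, Mapping, Sequence

_BASES = ("A", "C", "G", "T")
_INDEL_RE = re.compile(r"[+-](\d+)")


@dataclass(frozen=True)
class HetParams:
    minor_fraction_min: float = 0.10  # inclusive boundary
    min_depth: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.minor_fraction_min <= 0.5:
            raise ValueError("minor_fraction_min must be in (0, 0.5]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class PileupColumn:
    locus_id: str
    position: int  # 0-based
    depth: int
    base_counts: dict[str, int]

    def __post_init__(self) -> None:
        if sum(self.base_counts.values()) > self.depth:
            raise ValueError(
                f"{self.locus_id}:{self.position}: base counts exceed depth"
            )


def _parse_bases(bases: str, ref: str, line_no: int) -> dict[str, int]:
    counts = {b: 0 for b in _BASES}
    i = 0
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":
            i += 2  # caret + mapping quality char
            continue
        if ch in "$*><":
            i += 1
            continue
        if ch in "+-":
            m = _INDEL_RE.match(bases, i)
            if not m:
                raise ValueError(f"line {line_no}: malformed indel in {bases!r}")
            length = int(m.group(1))
            i = m.end() + length
            continue
        if ch in ".,":
            base = ref.upper()
        else:
            base = ch.upper()
        if base in counts:
            counts[base] += 1
        elif base != "N":
            raise ValueError(f"line {line_no}: unexpected base char {ch!r}")
        i += 1
    return counts


def parse_mpileup(source: str | Path | Iterable[str]) -> Iterator[PileupColumn]:
    """Parse mpileup text into :class:`PileupColumn` records.

    ``source`` may be a path or an iterable of lines.  Positions in the
    file are 1-based; emitted columns are 0-based.
    """
    if isinstance(source, (str, Path)):
        with Path(source).open() as fh:
            yield from parse_mpileup(list(fh))
        return
    for line_no, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(
                f"line {line_no}: expected >=5 mpileup columns, got {len(fields)}"
            )
        locus, pos, ref, depth, bases = fields[:5]
        try:
            position = int(pos) - 1
            depth_i = int(depth)
        except ValueError:
            raise ValueError(f"line {line_no}: non-integer position/depth") from None
        yield PileupColumn(
            locus_id=locus,
            position=position,
            depth=depth_i,
            base_counts=_parse_bases(bases, ref, line_no),
        )


def call_position(col: PileupColumn, params: HetParams = HetParams()) -> str:
    """Call one pileup column: ``heterozygous``, ``homozygous`` or ``no_data``."""
    if col.depth < params.min_depth or sum(col.base_counts.values()) == 0:
        return "no_data"
    ordered = sorted(col.base_counts.values(), reverse=True)
    minor = ordered[1] if len(ordered) > 1 else 0
    if minor / col.depth >= params.minor_fraction_min:
        return "heterozygous"
    return "homozygous"


def locus_het_percentage(
    columns: Iterable[PileupColumn], params: HetParams = HetParams()
) -> float | None:
    """Percentage of heterozygous positions among positions with data.

    Returns ``None`` (missing) when no position has data.
    """
    het = scored = 0
    for col in columns:
        call = call_position(col, params)
        if call == "no_data":
            continue
        scored += 1
        het += call == "heterozygous"
    if scored == 0:
        return None
    return 100.0 * het / scored


def sample_average(per_locus_percentages: Sequence[float]) -> float:
    """Unweighted mean heterozygosity percentage across loci."""
    if not per_locus_percentages:
        raise ValueError("no per-locus percentages to average")
    return fmean(per_locus_percentages)


def summarize_pileup(
    source: str | Path | Iterable[str], params: HetParams = HetParams()
) -> dict[str, float | None]:
    """Per-locus heterozygosity percentages for one sample's pileup."""
    by_locus: dict[str, list[PileupColumn]] = {}
    for col in parse_mpileup(source):
        by_locus.setdefault(col.locus_id, []).append(col)
    return {
        locus: locus_het_percentage(cols, params)
        for locus, cols in by_locus.items()
    }
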