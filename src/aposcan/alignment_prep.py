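"""Codon-alignment preparation: stop stripping, consensus, block trimming.

dN/dS counting needs an in-frame block with no gaps, no ambiguity and no
stop codons shared across all samples.  The reading frame is anchored at
alignment column 0; all operations work on codon columns (triplets of
alignment columns).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dnds import STOP_CODONS

_GAPLIKE = frozenset("-N")
ALIGN_ALPHABET = frozenset("ACGTN-")


@dataclass
class CodonAlignment:
    """Per-locus aligned nucleotide sequences keyed by sample id."""

    locus_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"locus {self.locus_id}: unequal sequence lengths {sorted(lengths)}"
            )
        for sid, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - ALIGN_ALPHABET
            if bad:
                raise ValueError(
                    f"locus {self.locus_id}, sample {sid}: "
                    f"invalid characters {sorted(bad)}"
                )
            self.sequences[sid] = seq

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    @property
    def n_codon_columns(self) -> int:
        return self.length // 3

    def codon_column(self, idx: int) -> dict[str, str]:
        return {s: seq[3 * idx : 3 * idx + 3] for s, seq in self.sequences.items()}

    @classmethod
    def read_fasta(cls, path: str | Path, locus_id: str | None = None) -> "CodonAlignment":
        path = Path(path)
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls(locus_id=locus_id or path.stem, sequences=records)

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=sid, description="")
            for sid, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class TrimParams:
    """Minimum length (in amino acids = codons) of the retained block."""

    min_block_aa: int = 30

    def __post_init__(self) -> None:
        if self.min_block_aa < 1:
            raise ValueError("min_block_aa must be >= 1")


def strip_stop_codons(alignment: CodonAlignment) -> tuple[CodonAlignment, list[int]]:
    """Remove every codon column where any sample holds a stop codon.

    Returns the shortened alignment and the list of removed codon-column
    indices (in the input frame).  The alignment length must be a multiple
    of 3.
    """
    if alignment.length % 3 != 0:
        raise ValueError(
            f"locus {alignment.locus_id}: length {alignment.length} not in frame"
        )
    removed: list[int] = []
    keep: list[int] = []
    for idx in range(alignment.n_codon_columns):
        codons = alignment.codon_column(idx).values()
        if any(c in STOP_CODONS for c in codons):
            removed.append(idx)
        else:
            keep.append(idx)
    sequences = {
        sid: "".join(seq[3 * i : 3 * i + 3] for i in keep)
        for sid, seq in alignment.sequences.items()
    }
    return CodonAlignment(alignment.locus_id, sequences), removed


def build_consensus(alignment: CodonAlignment) -> str:
    """Majority-rule consensus excluding gaps.

    Per column the most frequent base among {A, C, G, T} is taken (``-`` and
    ``N`` are excluded); ties break to the alphabetically smallest base.
    Columns with no called base are omitted.
    """
    if not alignment.sequences:
        raise ValueError("consensus of an empty alignment")
    out: list[str] = []
    seqs = list(alignment.sequences.values())
    for col in range(alignment.length):
        counts = Counter(seq[col] for seq in seqs)
        for gap in _GAPLIKE:
            counts.pop(gap, None)
        if not counts:
            continue  # all-gap column omitted
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        out.append(best[0])
    return "".join(out)


@dataclass
class TrimResult:
    """Outcome of :func:`trim_to_block` for one locus."""

    locus_id: str
    verdict: str  # "trimmed" or "below_min_block"
    block_start_codon: int | None = None
    block_len_codons: int = 0
    alignment: CodonAlignment | None = None


def _clean_codon_runs(alignment: CodonAlignment) -> list[tuple[int, int]]:
    """(start, length) runs of codon columns free of gaps and N in all samples."""
    runs: list[tuple[int, int]] = []
    start = None
    for idx in range(alignment.n_codon_columns):
        clean = all(
            not (set(codon) & _GAPLIKE)
            for codon in alignment.codon_column(idx).values()
        )
        if clean:
            if start is None:
                start = idx
        elif start is not None:
            runs.append((start, idx - start))
            start = None
    if start is not None:
        runs.append((start, alignment.n_codon_columns - start))
    return runs


def trim_to_block(
    alignment: CodonAlignment, params: TrimParams = TrimParams()
) -> TrimResult:
    """Trim to the single longest gap-free in-frame block across all samples.

    Block boundaries snap to codon columns of the frame anchored at column
    0; ``N`` counts as a gap.  If the longest clean run is shorter than
    ``params.min_block_aa`` codons the locus is dropped with verdict
    ``below_min_block``.  Ties between equally long runs go to the leftmost.
    """
    runs = _clean_codon_runs(alignment)
    if not runs:
        return TrimResult(alignment.locus_id, "below_min_block")
    start, length = max(runs, key=lambda r: (r[1], -r[0]))
    if length < params.min_block_aa:
        return TrimResult(
            alignment.locus_id, "below_min_block",
            block_start_codon=start, block_len_codons=length,
        )
    sequences = {
        sid: seq[3 * start : 3 * (start + length)]
        for sid, seq in alignment.sequences.items()
    }
    return TrimResult(
        alignment.locus_id,
        "trimmed",
        block_start_codon=start,
        block_len_codons=length,
        alignment=CodonAlignment(alignment.locus_id, sequences),
    )


def prepare_locus(
    alignment: CodonAlignment, params: TrimParams = TrimParams()
) -> TrimResult:
    """Stop stripping followed by block trimming (the standard preparation)."""
    stripped, _ = strip_stop_codons(alignment)
    return trim_to_block(stripped, params)
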