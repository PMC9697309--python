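"""Pairwise Nei-Gojobori dN/dS with Jukes-Cantor correction.

The counting method works codon by codon on an in-frame, gap-free alignment
block:

* **Sites.**  Each codon position contributes a synonymous-site fraction
  equal to the share of its three single-base neighbours that preserve the
  amino acid; neighbours that would create a stop codon count as
  nonsynonymous, which keeps ``S + N = 3 * codons`` exact.  Per pair, S and
  N are the means of the two sequences' counts.
* **Differences.**  For a codon pair differing at ``k`` positions, observed
  synonymous/nonsynonymous differences are averaged over all ``k!``
  substitution orderings.  Orderings that pass through a stop codon are
  excluded from the average; if every ordering does, the codon contributes
  ``k`` nonsynonymous differences (flagged per pair).
* **Distances.**  Proportions ``pS = Sd/S`` and ``pN = Nd/N`` are corrected
  with the Jukes-Cantor formula ``d = -(3/4) ln(1 - (4/3) p)``, and the
  ratio reported is ``omega = (dN + c)/(dS + c)`` with pseudo-count
  ``c = 0.01`` so loci without synonymous (or nonsynonymous) change remain
  comparable.

Only the standard genetic code (translation table 1) is supported, matching
the conservative counting approach this pipeline is built around; no
model-based (ML) estimation is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations, product
from statistics import fmean
from typing import Mapping

from Bio.Data import CodonTable

from .sample_design import PairGroup, SampleDesign, enumerate_pairs

PSEUDO_COUNT = 0.01

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
_BASES = "ACGT"


class SaturationError(ValueError):
    """Observed proportion of differences >= 3/4: Jukes-Cantor undefined."""


def codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts ``(s, n)`` for one codon.

    ``s`` sums, over the three positions, the fraction of single-base
    neighbours coding the same amino acid; stop-codon neighbours count as
    nonsynonymous.  ``n = 3 - s`` always.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    if codon not in GENETIC_CODE:
        raise ValueError(f"ambiguous or invalid codon {codon!r}")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            if neighbour not in STOP_CODONS and GENETIC_CODE[neighbour] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _codon_diff_contrib(c1: str, c2: str) -> tuple[float, float, bool]:
    """(Sd, Nd, stop_fallback) contribution of one differing codon pair.

    Averages over all orderings of the differing positions, skipping
    orderings whose intermediate codons are stops.  When no ordering
    survives, all ``k`` differences are scored nonsynonymous.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0, False
    path_sd: list[float] = []
    path_nd: list[float] = []
    for order in permutations(diff_pos):
        current = c1
        sd = nd = 0.0
        valid = True
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                valid = False
                break
            if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        if valid:
            path_sd.append(sd)
            path_nd.append(nd)
    if not path_sd:
        return 0.0, float(k), True
    return fmean(path_sd), fmean(path_nd), False


# Lookup tables over the 61 sense codons; the pairwise table has 61*61
# entries and makes long-alignment scans a dict lookup per codon.
SITE_COUNTS: dict[str, tuple[float, float]] = {
    c: codon_site_counts(c)
    for c in ("".join(p) for p in product(_BASES, repeat=3))
    if c not in STOP_CODONS
}
# integer count of synonymous single-base neighbours (0..9) per codon;
# keeps the S + N = 3L identity exact in floating point
_SYN_NINTHS: dict[str, int] = {
    c: round(s * 3) for c, (s, _) in SITE_COUNTS.items()
}
_DIFF_TABLE: dict[tuple[str, str], tuple[float, float, bool]] = {
    (a, b): _codon_diff_contrib(a, b)
    for a in SITE_COUNTS
    for b in SITE_COUNTS
}


@dataclass(frozen=True)
class PairCounts:
    """Nei-Gojobori counts for one sequence pair over the trimmed block."""

    S: float
    N: float
    Sd: float
    Nd: float
    stop_fallback_codons: int = 0


@dataclass(frozen=True)
class DnDsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float
    stop_fallback_codons: int = 0


def _validate_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence length mismatch: {len(seq_a)} vs {len(seq_b)}"
        )
    if len(seq_a) % 3 != 0:
        raise ValueError(f"sequence length {len(seq_a)} is not a multiple of 3")
    return seq_a, seq_b


def pairwise_counts(seq_a: str, seq_b: str) -> PairCounts:
    """Per-pair site and difference counts over an in-frame gap-free block.

    ``S``/``N`` are means of the two sequences' per-codon site counts;
    ``Sd + Nd`` always equals the nucleotide Hamming distance of the pair.
    """
    seq_a, seq_b = _validate_pair(seq_a, seq_b)
    syn_ninths = 0  # integer accumulator over both sequences
    sd = nd = 0.0
    fallback = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        try:
            syn_ninths += _SYN_NINTHS[ca] + _SYN_NINTHS[cb]
        except KeyError:
            bad = ca if ca not in SITE_COUNTS else cb
            raise ValueError(
                f"codon {bad!r} at position {i} is a stop or contains an "
                "ambiguous/gap character; trim the alignment first"
            ) from None
        if ca != cb:
            d_s, d_n, fell = _DIFF_TABLE[(ca, cb)]
            sd += d_s
            nd += d_n
            fallback += fell
    n_codons = len(seq_a) // 3
    S = syn_ninths / 6.0  # pair mean of per-sequence synonymous sites
    return PairCounts(
        S=S,
        N=3.0 * n_codons - S,
        Sd=sd,
        Nd=nd,
        stop_fallback_codons=fallback,
    )


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance ``d = -(3/4) ln(1 - (4/3) p)``.

    Raises :class:`SaturationError` for ``p >= 3/4`` where the correction
    is undefined.
    """
    if p < 0:
        raise ValueError(f"proportion of differences must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(
            f"proportion of differences p={p:.4f} >= 3/4: "
            "Jukes-Cantor distance saturated"
        )
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def omega(dN: float, dS: float, pseudo_count: float = PSEUDO_COUNT) -> float:
    """Pseudo-counted ratio ``(dN + c)/(dS + c)``; equals 1.0 when both are 0."""
    if dN < 0 or dS < 0:
        raise ValueError(f"distances must be non-negative, got dN={dN}, dS={dS}")
    return (dN + pseudo_count) / (dS + pseudo_count)


def compare_pair(seq_a: str, seq_b: str) -> DnDsResult:
    """Full Nei-Gojobori + Jukes-Cantor comparison of one sequence pair."""
    counts = pairwise_counts(seq_a, seq_b)
    pS = counts.Sd / counts.S if counts.S > 0 else 0.0
    pN = counts.Nd / counts.N if counts.N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    return DnDsResult(
        S=counts.S,
        N=counts.N,
        Sd=counts.Sd,
        Nd=counts.Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        omega=omega(dN, dS),
        stop_fallback_codons=counts.stop_fallback_codons,
    )


@dataclass
class LocusMatrix:
    """All pairwise results for one locus plus group and overall means."""

    locus_id: str
    pairwise: dict[tuple[str, str], DnDsResult]
    pair_groups: dict[tuple[str, str], PairGroup]
    saturated_pairs: list[tuple[str, str]]
    group_means: dict[PairGroup, float | None]
    overall_mean: float | None

    @property
    def saturated(self) -> bool:
        return bool(self.saturated_pairs)


def locus_matrix(
    sequences: Mapping[str, str],
    design: SampleDesign,
    locus_id: str = "",
    average: str = "mean_of_ratios",
) -> LocusMatrix:
    """Pairwise dN/dS for every sample pair of a trimmed locus alignment.

    Group means are arithmetic means of the pairwise omega values within
    each :class:`PairGroup` (``average="mean_of_ratios"``, the default), or
    pseudo-counted ratios of summed-count distances (``average="pooled"``).
    Pairs whose pS or pN saturates the Jukes-Cantor correction are excluded
    from all means and reported in ``saturated_pairs``.
    """
    if average not in ("mean_of_ratios", "pooled"):
        raise ValueError(f"unknown averaging mode {average!r}")
    groups = enumerate_pairs(design)
    pairwise: dict[tuple[str, str], DnDsResult] = {}
    saturated: list[tuple[str, str]] = []
    for pair in groups:
        a, b = pair
        try:
            pairwise[pair] = compare_pair(sequences[a], sequences[b])
        except SaturationError:
            saturated.append(pair)
    group_means: dict[PairGroup, float | None] = {}
    for grp in PairGroup:
        members = [p for p, g in groups.items() if g == grp and p in pairwise]
        if not members:
            group_means[grp] = None
        elif average == "mean_of_ratios":
            group_means[grp] = fmean(pairwise[p].omega for p in members)
        else:
            dn = fmean(pairwise[p].dN for p in members)
            ds = fmean(pairwise[p].dS for p in members)
            group_means[grp] = omega(dn, ds)
    overall = (
        fmean(r.omega for r in pairwise.values()) if pairwise else None
    )
    return LocusMatrix(
        locus_id=locus_id,
        pairwise=pairwise,
        pair_groups=groups,
        saturated_pairs=saturated,
        group_means=group_means,
        overall_mean=overall,
    )
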