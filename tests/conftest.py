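import random
from itertools import permutations

import pytest

from aposcan.dnds import SITE_COUNTS
from aposcan.sample_design import SampleDesign, SampleRole
from aposcan.synthetic_data import DEFAULT_DESIGN

SENSE_CODONS = tuple(sorted(SITE_COUNTS))
STOPS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TO_AA = {}


def translate_codon(codon: str) -> str:
    """Independent translation via Biopython, memoised."""
    if codon not in _CODON_TO_AA:
        from Bio.Seq import Seq

        _CODON_TO_AA[codon] = str(Seq(codon).translate())
    return _CODON_TO_AA[codon]


def brute_force_codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Oracle: recursively enumerate substitution orderings between codons.

    Branches are pruned at the first stop-codon intermediate; surviving
    complete paths are averaged.  When every ordering hits a stop, all
    differences count as nonsynonymous.
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    complete: list[tuple[int, int]] = []

    def recurse(current, remaining, sd, nd):
        if not remaining:
            complete.append((sd, nd))
            return
        for pos in remaining:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOPS:
                continue
            syn = translate_codon(current) == translate_codon(nxt)
            recurse(
                nxt,
                [p for p in remaining if p != pos],
                sd + syn,
                nd + (not syn),
            )

    recurse(c1, diffs, 0, 0)
    if not complete:
        return 0.0, float(len(diffs))
    n = len(complete)
    return sum(s for s, _ in complete) / n, sum(d for _, d in complete) / n


def brute_force_pair_diffs(seq_a: str, seq_b: str) -> tuple[float, float]:
    sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        s, d = brute_force_codon_diffs(seq_a[i : i + 3], seq_b[i : i + 3])
        sd += s
        nd += d
    return sd, nd


def random_codon_pair(rng: random.Random, max_codons: int = 30) -> tuple[str, str]:
    """A random sense-codon sequence and a mutated copy."""
    n = rng.randint(1, max_codons)
    a = "".join(rng.choice(SENSE_CODONS) for _ in range(n))
    b = list(a)
    for _ in range(rng.randint(0, max(1, n))):
        i = rng.randrange(n)
        b[3 * i : 3 * i + 3] = rng.choice(SENSE_CODONS)
    return a, "".join(b)


@pytest.fixture
def paper_design() -> SampleDesign:
    """Five samples: 1 parent A, 2 parent B, 2 hybrids."""
    return DEFAULT_DESIGN


@pytest.fixture
def three_sample_design() -> SampleDesign:
    return SampleDesign(
        [
            ("a", SampleRole.PARENT_A),
            ("b", SampleRole.PARENT_B),
            ("h", SampleRole.HYBRID),
        ]
    )
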