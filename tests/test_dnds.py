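import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aposcan.dnds import (
    SITE_COUNTS,
    SaturationError,
    codon_site_counts,
    compare_pair,
    jukes_cantor,
    locus_matrix,
    omega,
    pairwise_counts,
)
from aposcan.sample_design import PairGroup

from .conftest import (
    SENSE_CODONS,
    brute_force_pair_diffs,
    random_codon_pair,
    translate_codon,
)

codon_seqs = st.lists(
    st.sampled_from(SENSE_CODONS), min_size=1, max_size=25
).map("".join)


class TestSiteCounts:
    @pytest.mark.parametrize(
        "codon, s",
        [("TTT", 1 / 3), ("ATG", 0.0), ("CTT", 1.0), ("TGG", 0.0)],
    )
    def test_known_codons(self, codon, s):
        got_s, got_n = codon_site_counts(codon)
        assert got_s == pytest.approx(s, abs=1e-12)
        assert got_s + got_n == pytest.approx(3.0, abs=0)

    def test_all_sense_codons_against_neighbour_enumeration(self):
        """Oracle: count synonymous single-base neighbours directly from the
        translation table, scoring stop neighbours as nonsynonymous."""
        for codon in SENSE_CODONS:
            syn = 0
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    nb = codon[:pos] + base + codon[pos + 1 :]
                    if translate_codon(nb) not in ("*",) and translate_codon(
                        nb
                    ) == translate_codon(codon):
                        syn += 1
            s, n = codon_site_counts(codon)
            assert s == pytest.approx(syn / 3, abs=1e-12)
            assert s + n == 3.0

    @pytest.mark.parametrize("codon", ["TAA", "TGA", "TNG", "AT-"])
    def test_stop_and_ambiguous_codons_rejected(self, codon):
        with pytest.raises(ValueError, match=codon):
            codon_site_counts(codon)


class TestPairwiseCounts:
    def test_identical_sequences_have_zero_differences(self):
        pc = pairwise_counts("ATGAAA", "ATGAAA")
        assert pc.Sd == 0.0 and pc.Nd == 0.0

    def test_single_synonymous_difference(self):
        pc = pairwise_counts("TTT", "TTC")  # both Phe
        assert pc.Sd == 1.0 and pc.Nd == 0.0

    def test_two_step_pathway_averaging(self):
        # TTT -> GTA: via GTT gives 1 syn + 1 nonsyn, via TTA gives 2 nonsyn
        pc = pairwise_counts("TTT", "GTA")
        assert pc.Sd == pytest.approx(0.5)
        assert pc.Nd == pytest.approx(1.5)

    def test_stop_blocked_pathway_excluded_from_averaging(self):
        # TAC (Tyr) -> TCA (Ser): the ordering through TAA (stop) is
        # excluded, leaving only TAC -> TCC -> TCA (1 nonsyn + 1 syn)
        # instead of an average over both orderings.
        pc = pairwise_counts("TAC", "TCA")
        assert pc.Sd == 1.0 and pc.Nd == 1.0
        assert pc.stop_fallback_codons == 0

    def test_every_sense_codon_pair_has_a_stop_free_ordering(self):
        """Under the standard code the all-orderings-blocked fallback is
        never reachable: some ordering always avoids stop intermediates."""
        from aposcan.dnds import _DIFF_TABLE

        assert not any(fell for _, _, fell in _DIFF_TABLE.values())

    def test_length_mismatch_and_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pairwise_counts("ATG", "ATGATG")
        with pytest.raises(ValueError, match="multiple of 3"):
            pairwise_counts("ATGA", "ATGC")

    @settings(derandomize=True, max_examples=150)
    @given(codon_seqs, st.randoms(use_true_random=False))
    def test_sites_sum_exact_and_diffs_match_hamming(self, seq, rnd):
        other = list(seq)
        for _ in range(rnd.randint(0, len(seq) // 3)):
            i = rnd.randrange(len(seq) // 3)
            other[3 * i : 3 * i + 3] = rnd.choice(SENSE_CODONS)
        other = "".join(other)
        pc = pairwise_counts(seq, other)
        L = len(seq) // 3
        assert pc.S + pc.N == pytest.approx(3 * L, abs=0)
        hamming = sum(a != b for a, b in zip(seq, other))
        assert pc.Sd + pc.Nd == pytest.approx(hamming, abs=1e-9)

    def test_symmetry_of_pair_order(self):
        rng = random.Random(11)
        for _ in range(50):
            a, b = random_codon_pair(rng)
            ab, ba = pairwise_counts(a, b), pairwise_counts(b, a)
            assert ab.S == pytest.approx(ba.S)
            assert ab.Sd == pytest.approx(ba.Sd)
            assert ab.Nd == pytest.approx(ba.Nd)

    def test_matches_brute_force_pathway_enumerator(self):
        rng = random.Random(202)
        for _ in range(200):
            a, b = random_codon_pair(rng)
            pc = pairwise_counts(a, b)
            sd, nd = brute_force_pair_diffs(a, b)
            assert pc.Sd == pytest.approx(sd, abs=1e-9)
            assert pc.Nd == pytest.approx(nd, abs=1e-9)

    def test_matches_biopython_ng86_on_stop_path_free_pairs(self):
        """Independent library cross-check where the two stop-pathway
        policies coincide (no mutational ordering passes through a stop)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        from itertools import permutations

        from .conftest import STOPS

        def stop_path_free(a, b):
            for i in range(0, len(a), 3):
                c1, c2 = a[i : i + 3], b[i : i + 3]
                for order in permutations([p for p in range(3) if c1[p] != c2[p]]):
                    cur = c1
                    for pos in order:
                        cur = cur[:pos] + c2[pos] + cur[pos + 1 :]
                        if cur in STOPS:
                            return False
            return True

        rng = random.Random(3)
        checked = 0
        while checked < 40:
            a, b = random_codon_pair(rng)
            if not stop_path_free(a, b):
                continue
            try:
                mine = compare_pair(a, b)
            except SaturationError:
                continue
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            assert mine.dN == pytest.approx(dn, abs=1e-9)
            assert mine.dS == pytest.approx(ds, abs=1e-9)
            checked += 1


class TestJukesCantor:
    def test_closed_form_values(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.0598) == pytest.approx(0.062321, abs=1e-5)

    def test_monotone_in_p(self):
        grid = [i / 100 for i in range(0, 75)]
        values = [jukes_cantor(p) for p in grid]
        assert all(b > a for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("p", [0.75, 0.8, 1.0])
    def test_saturation_error_at_three_quarters(self, p):
        with pytest.raises(SaturationError):
            jukes_cantor(p)

    def test_negative_p_rejected(self):
        with pytest.raises(ValueError):
            jukes_cantor(-0.01)


class TestOmega:
    @pytest.mark.parametrize(
        "dN, dS, expected",
        [(0.0, 0.0, 1.0), (0.09, 0.01, 5.0), (0.0, 0.99, 0.01)],
    )
    def test_pseudo_counted_ratio(self, dN, dS, expected):
        assert omega(dN, dS) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            omega(-0.1, 0.0)


class TestLocusMatrix:
    def test_five_samples_give_ten_pairwise_results(self, paper_design):
        seqs = {s: "ATGAAACCCGGG" for s in paper_design.sample_ids}
        lm = locus_matrix(seqs, paper_design)
        assert len(lm.pairwise) == 10

    def test_identical_sequences_give_omega_one_everywhere(self, paper_design):
        seqs = {s: "ATGAAACCCGGGTTA"[:12] for s in paper_design.sample_ids}
        lm = locus_matrix(seqs, paper_design)
        assert all(r.omega == pytest.approx(1.0) for r in lm.pairwise.values())
        assert all(
            m == pytest.approx(1.0) for m in lm.group_means.values() if m is not None
        )
        assert lm.overall_mean == pytest.approx(1.0)

    def test_group_mean_is_arithmetic_mean_of_pairwise_omegas(self, paper_design):
        rng = random.Random(5)
        seqs = {}
        base = "".join(rng.choice(SENSE_CODONS) for _ in range(60))
        for s in paper_design.sample_ids:
            mutated = list(base)
            for _ in range(6):
                i = rng.randrange(60)
                mutated[3 * i : 3 * i + 3] = rng.choice(SENSE_CODONS)
            seqs[s] = "".join(mutated)
        lm = locus_matrix(seqs, paper_design)
        ph = [
            lm.pairwise[p].omega
            for p, g in lm.pair_groups.items()
            if g == PairGroup.PARENT_HYBRID
        ]
        assert lm.group_means[PairGroup.PARENT_HYBRID] == pytest.approx(
            sum(ph) / len(ph)
        )

    def test_saturated_pair_excluded_and_reported(self, paper_design):
        seqs = {s: "ATGAAACCCGGGAAATTTCCC" for s in paper_design.sample_ids}
        # make one hybrid saturate against everything: all codons replaced
        seqs["hybrid_2"] = "TGTGGGAAATTTCGAGCGGGG"
        lm = locus_matrix(seqs, paper_design)
        assert lm.saturated
        for pair in lm.saturated_pairs:
            assert "hybrid_2" in pair
            assert pair not in lm.pairwise
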