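"""TSD detection, nicking-site contexts and consensus profiles."""

import numpy as np
import pytest

from retrokit.sequences import GenomeSequence, revcomp
from retrokit.tables import load_tsd_sites, reconstruct_tsd_locus
from retrokit.tsd import (FlankTooShortError, NickContext, TsdCall, TsdParams,
                          build_site_consensus, extract_nick_contexts, find_tsd)


def brute_force_tsd(seq, element_span, params):
    """Exhaustive enumeration over all (left_start, right_start, length)
    triples, sorted by the contract's tie-break key."""
    estart, eend = element_span
    slack = params.boundary_slack
    candidates = []
    for length in range(params.min_len, params.max_len + 1):
        for left_end in range(estart - slack, estart + slack + 1):
            left_start = left_end - length
            if left_start < 0 or left_end > eend:
                continue
            for right_start in range(eend - slack, eend + slack + 1):
                if right_start < estart or right_start + length > len(seq):
                    continue
                left = seq[left_start:left_end]
                right = seq[right_start:right_start + length]
                mm = sum(a != b for a, b in zip(left, right))
                if mm > params.max_mismatch:
                    continue
                offset = abs(left_end - estart) + abs(right_start - eend)
                candidates.append(
                    ((-length, mm, offset, left_start),
                     TsdCall((left_start, left_end),
                             (right_start, right_start + length), left, mm)))
    if not candidates:
        return None
    return min(candidates, key=lambda c: c[0])[1]


def random_tprt_locus(rng, flank=60, tsd_len=None):
    """A short locus with a planted TPRT insertion; returns (genome, span, tsd)."""
    from retrokit.simulate import random_dna, simulate_tprt_insertion
    if tsd_len is None:
        tsd_len = int(rng.integers(7, 17))
    pre = GenomeSequence("locus", random_dna(2 * flank, rng))
    element = "CAATCGTTGC" + random_dna(80, rng) + "A" * 12
    filled, truth = simulate_tprt_insertion(pre, element, flank, tsd_len)
    return filled, truth.span, truth.tsd


class TestFindTsd:
    def test_catalogued_locus_exact_repeat(self):
        table = load_tsd_sites()
        row = table[table["element"] == "Sadhu5-1"].iloc[0]
        locus, span = reconstruct_tsd_locus(row)
        call = find_tsd(locus, span)
        assert call.repeat_seq == "AGTACTACTACT"
        assert call.mismatches == 0

    def test_unrelated_flanks_give_none(self):
        seq = "G" * 30 + "CAATCGTTGC" + "T" * 50 + "C" * 30
        g = GenomeSequence("g", seq)
        assert find_tsd(g, (30, 90)) is None

    def test_flank_too_short_names_side(self):
        g = GenomeSequence("g", "ACGTACGTACGTACGTACGTACGTACGT")
        with pytest.raises(FlankTooShortError, match="left"):
            find_tsd(g, (2, 20))

    def test_matches_brute_force_on_planted_loci(self, rng):
        params = TsdParams()
        for _ in range(120):
            genome, span, tsd = random_tprt_locus(rng)
            got = brute = None
            got = find_tsd(genome, span, params)
            brute = brute_force_tsd(genome.residues, span, params)
            assert got == brute
            assert tsd in got.repeat_seq  # containment guarantee

    def test_mismatch_tolerance(self, rng):
        genome, span, tsd = random_tprt_locus(rng, tsd_len=12)
        # corrupt one base of the right TSD copy
        seq = list(genome.residues)
        pos = span[1] + 5
        seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        broken = GenomeSequence("g", "".join(seq))
        exact = find_tsd(broken, span, TsdParams(max_mismatch=0))
        fuzzy = find_tsd(broken, span, TsdParams(max_mismatch=1))
        assert fuzzy.length >= 12
        assert exact is None or exact.length < fuzzy.length


class TestNickContexts:
    def _locus(self, element):
        table = load_tsd_sites()
        row = table[table["element"] == element].iloc[0]
        genome, span = reconstruct_tsd_locus(row)
        k = len(row["tsd"])
        call = TsdCall((span[0] - k, span[0]), (span[1], span[1] + k),
                       row["tsd"].upper())
        return genome, span, call, row

    def test_catalogued_windows(self):
        genome, span, call, row = self._locus("Sadhu1-1")
        ctx = extract_nick_contexts(genome, span, call)
        assert ctx == NickContext("TACAAAAGT", "AAATGAC", "TAATAAACA")

    def test_all_catalogued_loci_reproduce_printed_columns(self):
        for _, row in load_tsd_sites().iterrows():
            genome, span = reconstruct_tsd_locus(row)
            k = len(row["tsd"])
            call = TsdCall((span[0] - k, span[0]), (span[1], span[1] + k),
                           row["tsd"].upper())
            ctx = extract_nick_contexts(genome, span, call)
            assert ctx.five_prime_nick == row["five_prime_nick"].upper()
            assert ctx.tsd_prefix == row["tsd"].upper()[:7]
            assert ctx.three_prime_nick == row["three_prime_nick"].upper()

    def test_minus_strand_windows_are_mirrored(self):
        genome, span, call, _ = self._locus("Sadhu5-1")
        rc = genome.reverse_complement()
        n = len(genome)
        flip = lambda s: (n - s[1], n - s[0])
        rc_call = TsdCall(flip(call.right_span), flip(call.left_span),
                          revcomp(call.repeat_seq))
        rc_span = flip(span)
        plus = extract_nick_contexts(genome, span, call, "+")
        minus = extract_nick_contexts(rc, rc_span, rc_call, "-")
        assert plus == minus

    def test_short_flank_raises(self):
        g = GenomeSequence("g", "ACAAAAGT" + "AGT" * 20 + "TAATAAACA")
        call = TsdCall((5, 12), (40, 47), g.residues[5:12])
        with pytest.raises(FlankTooShortError):
            extract_nick_contexts(g, (12, 40), call)


class TestSiteConsensus:
    @pytest.fixture
    def table_contexts(self):
        return [
            NickContext(row["five_prime_nick"].upper(),
                        row["tsd"].upper()[:7],
                        row["three_prime_nick"].upper())
            for _, row in load_tsd_sites().iterrows()
        ]

    def test_modal_bases_from_catalogue(self, table_contexts):
        five, prefix, three = build_site_consensus(table_contexts)
        # the duplicated target begins with adenines ...
        assert prefix.modal_base(0) == ("A", 12)
        # ... and the 5' nicking site favors a thymine at the cut position
        assert five.modal_base(8) == ("T", 7)

    def test_column_sums_equal_n(self, table_contexts):
        for profile in build_site_consensus(table_contexts):
            assert (profile.counts.sum(axis=1) == profile.n_sequences).all()

    def test_order_invariance(self, table_contexts):
        fwd = build_site_consensus(table_contexts)
        rev = build_site_consensus(table_contexts[::-1])
        for a, b in zip(fwd, rev):
            assert a.counts.equals(b.counts)

    def test_single_sequence_full_information(self):
        ctx = NickContext("AAAAAAAAA", "AAAAAAA", "AAAAAAAAA")
        five, _, _ = build_site_consensus([ctx])
        assert np.allclose(five.information_bits, 2.0)

    def test_mixed_lengths_rejected(self):
        contexts = [NickContext("AAAAAAAAA", "AAAAAAA", "AAAAAAAAA"),
                    NickContext("AAAAAAAAA", "AAAA", "AAAAAAAAA")]
        with pytest.raises(ValueError, match="length"):
            build_site_consensus(contexts)
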