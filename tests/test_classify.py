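"""Pairwise identity, subfamily relations, nomenclature, consensus."""

import numpy as np
import pytest

from retrokit.classify import (SubfamilyAssignment,
                               assign_names, classify_element,
                               pairwise_identity, parse_name,
                               subfamily_consensus)
from retrokit.simulate import (SimParams, derive_element,
                               make_ancestral_element, mutate, random_dna)

NEG_INF = float("-inf")


def gotoh_score(a, b, match=1.0, mismatch=-1.0, open_=-5.0, extend=-1.0):
    """Affine-gap global alignment score with free terminal gaps.

    Independent dynamic-programming oracle: a gap of length n scores
    open + (n-1)*extend; leading/trailing gaps are free.
    """
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        M[i][0] = 0.0  # free leading gap
    for j in range(1, m + 1):
        M[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend)
    best = max(max(M[n][j], X[n][j], Y[n][j]) for j in range(m + 1))
    best = max(best, max(max(M[i][m], X[i][m], Y[i][m]) for i in range(n + 1)))
    return best


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGT", "ACGT") == (1.0, 4)

    def test_three_quarters(self):
        identity, cols = pairwise_identity("ACGT", "ACGA")
        assert identity == 0.75 and cols == 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_symmetry(self, rng):
        for _ in range(20):
            a = random_dna(int(rng.integers(10, 40)), rng)
            b = random_dna(int(rng.integers(10, 40)), rng)
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_alignment_score_matches_dp_oracle(self, rng):
        from retrokit.classify import align_stats
        for _ in range(40):
            a = random_dna(int(rng.integers(5, 31)), rng)
            b = random_dna(int(rng.integers(5, 31)), rng)
            _, _, alignment = align_stats(a, b)
            assert alignment.score == pytest.approx(gotoh_score(a, b))


class TestClassifyElement:
    @pytest.fixture
    def panel(self, rng):
        params = SimParams()
        return {f"Sadhu{i + 1}-1": make_ancestral_element(params, rng)
                for i in range(4)}

    def test_self_is_member_at_full_identity(self, panel):
        name = "Sadhu2-1"
        a = classify_element(name, panel[name], "full_length", panel)
        assert a.relation == "member_full_length"
        assert a.nearest_full_length == name
        assert a.identity == 1.0

    def test_truncated_copy_is_derived_from_parent(self, rng, panel):
        trunc = mutate(derive_element(panel["Sadhu3-1"],
                                      "five_prime_truncation", rng), 0.05, rng)
        a = classify_element("cand", trunc, "partial", panel)
        assert a.relation == "derived"
        assert a.nearest_full_length == "Sadhu3-1"
        assert a.identity > 0.75

    def test_distant_fragment_is_like_nearest(self, rng, panel):
        distant = mutate(panel["Sadhu1-1"][300:700], 0.45, rng)
        a = classify_element("cand", distant, "fragment", panel)
        assert a.relation == "like"
        assert a.identity <= 0.75

    def test_identity_exactly_at_threshold_is_not_derived(self):
        # the derivative rule is a strict inequality; mismatches are spread
        # internally so gaps cannot pay for themselves
        base = "ACGT" * 25
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        cand = "".join(flip[c] if i % 4 == 1 else c
                       for i, c in enumerate(base))
        a = classify_element("cand", cand, "partial", {"Sadhu1-1": base})
        assert a.identity == pytest.approx(0.75)
        assert a.relation == "like"

    def test_empty_reference_panel_rejected(self, panel):
        with pytest.raises(ValueError):
            classify_element("c", panel["Sadhu1-1"], "partial", {})

    def test_permutation_invariance(self, rng, panel):
        cand = mutate(panel["Sadhu4-1"], 0.2, rng)
        shuffled = dict(reversed(list(panel.items())))
        a = classify_element("c", cand, "partial", panel)
        b = classify_element("c", cand, "partial", shuffled)
        assert (a.relation, a.nearest_full_length, a.identity) == \
               (b.relation, b.nearest_full_length, b.identity)


class TestAssignNames:
    def _assignment(self, ref, relation, nearest):
        return SubfamilyAssignment(ref, relation, nearest, 0.9, 500)

    def test_derivative_and_like_numbering(self):
        batch = [
            self._assignment("e1", "derived", "Sadhu5-1"),
            self._assignment("e2", "derived", "Sadhu5-1"),
            self._assignment("e3", "like", "Sadhu3-1"),
        ]
        named = assign_names(batch)
        assert [a.assigned_name for a in named] == [
            "Sadhu5-1d1", "Sadhu5-1d2", "Sadhu3L1"]

    def test_members_numbered_in_input_order(self):
        batch = [
            self._assignment("a", "member_full_length", "Sadhu7-1"),
            self._assignment("b", "member_full_length", "Sadhu7-1"),
        ]
        named = assign_names(batch, family_prefix="AlSadhu",
                             subfamily_of={"Sadhu7-1": "7"})
        assert [a.assigned_name for a in named] == ["AlSadhu7-1", "AlSadhu7-2"]

    def test_empty_batch(self):
        assert assign_names([]) == []

    def test_names_parse_back_losslessly(self):
        for name, expect in [
            ("Sadhu5-1", ("Sadhu", 5, "member_full_length", 1)),
            ("Sadhu5-1d2", ("Sadhu", 5, "derived", 2)),
            ("Sadhu3L1", ("Sadhu", 3, "like", 1)),
            ("AlSadhu10-2", ("AlSadhu", 10, "member_full_length", 2)),
        ]:
            parsed = parse_name(name)
            assert (parsed["family"], parsed["subfamily"], parsed["relation"],
                    parsed["index"]) == expect


class TestSubfamilyConsensus:
    def test_single_member_is_itself(self):
        assert subfamily_consensus(["ACGTACGT"]) == "ACGTACGT"

    def test_plurality_per_column(self):
        assert subfamily_consensus(["ACGT", "ACGT", "ACTT"],
                                   anchor="ACGT") == "ACGT"

    def test_recovers_ancestor_from_diverged_members(self, rng):
        params = SimParams()
        ancestor = make_ancestral_element(params, rng)
        members = [mutate(ancestor, 0.05, rng) for _ in range(9)]
        consensus = subfamily_consensus(members)
        mismatch = sum(x != y for x, y in zip(consensus, ancestor))
        assert len(consensus) == len(ancestor)
        assert mismatch / len(ancestor) <= 0.02
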