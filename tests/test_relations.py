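"""Pairwise relation classification, enumeration, and segment decomposition."""

import itertools

import pytest

from circuitchain import (
    RelationLabel,
    UnknownContactError,
    canonical,
    classify_pair,
    count_strings,
    decompose_segments,
    enumerate_strings,
    parse_chain,
    reduce_by_reversal,
    relation_matrix,
    reverse_chain,
    serialize_chain,
)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "text,label",
        [
            ("AABB", RelationLabel.S),
            ("ABBA", RelationLabel.P),
            ("ABAB", RelationLabel.X),
            ("Nt A B D B A D Ct", None),  # placeholder, handled below
        ],
    )
    def test_basic_patterns(self, text, label):
        if label is None:
            assert classify_pair(parse_chain(text), "A", "D") is RelationLabel.X
        else:
            assert classify_pair(parse_chain(text), "A", "B") is label

    def test_parallel_orientation(self):
        chain = parse_chain("ABBA")
        assert classify_pair(chain, "A", "B") is RelationLabel.P
        assert classify_pair(chain, "B", "A") is RelationLabel.Pinv

    def test_concerted_series_and_parallel(self):
        assert classify_pair(parse_chain("A (A B) B"), "A", "B") is RelationLabel.CS
        assert classify_pair(parse_chain("(A B) B A"), "A", "B") is RelationLabel.CP

    def test_unknown_contact(self):
        with pytest.raises(UnknownContactError):
            classify_pair(parse_chain("AABB"), "A", "Z")

    def test_threads_do_not_affect_classification(self):
        plain = parse_chain("ABAB")
        threaded = parse_chain("A _{+B} B A B _{-A}")
        assert classify_pair(plain, "A", "B") is classify_pair(threaded, "A", "B")

    def test_partition_property_over_all_five_contact_strings(self):
        """Every 2-contact restriction gets exactly one of S/P/Pinv/X."""
        base = {RelationLabel.S, RelationLabel.P, RelationLabel.Pinv, RelationLabel.X}
        for chain in enumerate_strings(5):
            for a, b in itertools.combinations(chain.contact_names, 2):
                assert classify_pair(chain, a, b) in base

    def test_reversal_invariance(self):
        """Nesting is orientation-independent (reverse of abba is abba), so
        every pair label, P and P⁻¹ included, survives chain reversal."""
        for chain in enumerate_strings(4):
            rev = reverse_chain(chain)
            for a, b in itertools.combinations(chain.contact_names, 2):
                assert classify_pair(rev, a, b) is classify_pair(chain, a, b)


class TestRelationMatrix:
    def test_all_series(self):
        summary = relation_matrix(parse_chain("AABBCC"))
        assert set(summary.labels.values()) == {RelationLabel.S}
        assert summary.frequencies == {"S": 1.0}

    def test_all_cross(self):
        summary = relation_matrix(parse_chain("ABCABC"))
        assert set(summary.labels.values()) == {RelationLabel.X}

    def test_single_contact_empty(self):
        summary = relation_matrix(parse_chain("AA"))
        assert summary.labels == {}
        assert summary.frequencies == {}

    def test_frequencies_sum_to_one(self, random_chain_pool):
        for chain in random_chain_pool:
            if chain.n_contacts < 2:
                continue
            summary = relation_matrix(chain)
            assert sum(summary.frequencies.values()) == pytest.approx(1.0)


class TestEnumeration:
    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 3), (3, 15), (4, 105),
                                            (5, 945), (6, 10395)])
    def test_count_matches_closed_form(self, n, expected):
        assert count_strings(n) == expected

    def test_count_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            count_strings(0)

    def test_two_contact_strings(self):
        assert {str(s) for s in enumerate_strings(2)} == {"AABB", "ABBA", "ABAB"}

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_enumeration_cardinality_and_distinctness(self, n):
        strings = enumerate_strings(n)
        assert len(strings) == count_strings(n)
        assert len({str(s) for s in strings}) == len(strings)

    def test_bound_enforced(self):
        with pytest.raises(ValueError):
            enumerate_strings(8)


class TestReversalReduction:
    def test_single_contact(self):
        assert len(reduce_by_reversal(enumerate_strings(1))) == 1

    @pytest.mark.parametrize(
        "a,b",
        [("AABCBC", "ABABCC"), ("AABCCB", "ABBACC"), ("ABACCB", "ABBCAC")],
    )
    def test_documented_symmetric_pairs(self, a, b):
        classes = reduce_by_reversal([parse_chain(a), parse_chain(b)])
        assert len(classes) == 1

    def test_three_contact_classes_against_brute_force(self):
        """Orbit counting with explicit letter bijections as the oracle.

        The class count for three contacts is 11: seven strings are their own
        reversal and four pairs merge (AABCBC/ABABCC, AABCCB/ABBACC,
        ABACCB/ABBCAC, and ABCACB/ABCBAC).
        """
        strings = [str(s) for s in enumerate_strings(3)]

        def equivalent(s1, s2):
            for perm in itertools.permutations("ABC"):
                mapping = dict(zip("ABC", perm))
                for cand in (s2, s2[::-1]):
                    if "".join(mapping[c] for c in cand) == s1:
                        return True
            return False

        orbits = []
        for s in strings:
            for orbit in orbits:
                if equivalent(orbit[0], s):
                    orbit.append(s)
                    break
            else:
                orbits.append([s])
        assert len(orbits) == 11
        assert len(reduce_by_reversal(enumerate_strings(3))) == len(orbits)
        merged = sorted(sorted(o) for o in orbits if len(o) == 2)
        assert merged == [
            ["AABCBC", "ABABCC"],
            ["AABCCB", "ABBACC"],
            ["ABACCB", "ABBCAC"],
            ["ABCACB", "ABCBAC"],
        ]


class TestSegments:
    def test_two_blobs_in_series(self):
        segments = decompose_segments(parse_chain("ABABCDCD"))
        assert [serialize_chain(s) for s in segments] == ["ABAB", "CDCD"]

    def test_threaded_interaction_segments(self):
        chain = parse_chain("A _{+B} A B _{+A} B C _{+D} C D _{+C} D")
        segments = decompose_segments(chain)
        assert len(segments) == 2
        assert [s.contact_names for s in segments] == [("A", "B"), ("C", "D")]

    def test_irreducible_chain(self):
        segments = decompose_segments(parse_chain("ABAB"))
        assert len(segments) == 1

    def test_cross_segment_relations_are_series(self, random_chain_pool):
        for chain in random_chain_pool:
            segments = decompose_segments(chain)
            if len(segments) < 2:
                continue
            for s1, s2 in itertools.combinations(segments, 2):
                for a in s1.contact_names:
                    for b in s2.contact_names:
                        assert classify_pair(chain, a, b) is RelationLabel.S

    def test_concatenation_reproduces_chain(self, random_chain_pool):
        for chain in random_chain_pool:
            segments = decompose_segments(chain)
            rebuilt = sum((list(s.events) for s in segments), [])
            assert tuple(rebuilt) == chain.events
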