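"""Parsing, serialization, matrix conversion, and editing of chain strings."""

import numpy as np
import pytest

from circuitchain import (
    ConcertedOrderError,
    MatrixFormatError,
    NotationError,
    SoftAttributeError,
    UnknownContactError,
    UnknownThreadTargetError,
    UnpairedContactError,
    break_contact,
    canonical,
    chain_from_json,
    chain_to_json,
    from_connectivity_matrix,
    merge_chains,
    parse_chain,
    reverse_chain,
    serialize_chain,
    to_connectivity_matrix,
)
from circuitchain.notation import Group, Site, Thread


class TestParsing:
    def test_two_hard_contacts_in_series(self):
        chain = parse_chain("AABB")
        assert chain.site_sequence == ("A", "A", "B", "B")
        a, b = chain.contacts
        assert (a.name, a.kind, a.sites) == ("A", "hard", (1, 2))
        assert (b.name, b.kind, b.sites) == ("B", "hard", (3, 4))

    def test_slip_knot_soft_contact_with_thread(self):
        chain = parse_chain("A^{+o} A _{+A}")
        (rec,) = chain.contacts
        assert rec.kind == "soft"
        assert rec.chirality == "+"
        assert rec.parity == "odd"
        assert chain.events[-1] == Thread("+", "A")

    def test_compact_and_spaced_dialects_agree(self):
        assert parse_chain("NtABDBADCt") == parse_chain("Nt A B D B A D Ct")
        assert parse_chain("AABB") == parse_chain("A A B B")

    def test_termini_recorded(self):
        chain = parse_chain("NtABDBADCt")
        assert chain.termini == ("Nt", "Ct")

    def test_concerted_groups_take_consecutive_site_indices(self, yibk_chain):
        assert yibk_chain.n_contacts == 10
        assert yibk_chain.contact("B").sites == (2, 4)
        assert yibk_chain.contact("S").sites == (12, 19)

    @pytest.mark.parametrize(
        "text,err",
        [
            ("ABA", UnpairedContactError),
            ("AAA", UnpairedContactError),
            ("A A B^{+e} B^{+e}", SoftAttributeError),
            ("A^{+e} A^{+o}", SoftAttributeError),
            ("A A _{+B}", UnknownThreadTargetError),
            ("A B (D B) A D", ConcertedOrderError),
            ("A ^{+e} ;", NotationError),
            ("A (B", NotationError),
        ],
    )
    def test_validation_errors(self, text, err):
        with pytest.raises(err):
            parse_chain(text)

    def test_attribute_on_second_occurrence_rejected(self):
        with pytest.raises(SoftAttributeError):
            parse_chain("A A^{+e}")


class TestSerialization:
    def test_round_trip_plain(self):
        assert serialize_chain(parse_chain("AABB")) == "AABB"

    def test_reverse_reading_reattaches_attributes(self):
        chain = parse_chain("A C^{+e} _{+B} A B _{+A} B C")
        assert serialize_chain(chain, "reverse") == "C^{+e} B _{+A} B A _{+B} C A"

    def test_reverse_of_series_of_cross(self):
        rev = canonical(reverse_chain(parse_chain("AABCBC")))
        assert serialize_chain(rev) == "ABABCC"

    def test_reverse_is_involution(self, random_chain_pool):
        for chain in random_chain_pool:
            back = canonical(reverse_chain(reverse_chain(chain)))
            assert back == canonical(chain)

    def test_parse_serialize_round_trip(self, random_chain_pool):
        for chain in random_chain_pool:
            assert parse_chain(serialize_chain(chain)) == chain

    def test_json_round_trip(self, random_chain_pool):
        for chain in random_chain_pool[:30]:
            assert chain_from_json(chain_to_json(chain)) == chain


class TestConnectivityMatrix:
    def test_cross_structure_matrix(self):
        S = to_connectivity_matrix(parse_chain("ABAB"))
        expected = np.zeros((4, 4), dtype=int)
        expected[0, 2] = expected[2, 0] = 1
        expected[1, 3] = expected[3, 1] = 1
        assert np.array_equal(S, expected)

    def test_single_contact_antidiagonal(self):
        assert np.array_equal(
            to_connectivity_matrix(parse_chain("AA")), np.array([[0, 1], [1, 0]])
        )

    def test_matrix_to_string_worked_example(self):
        S = np.array(
            [[0, 0, 0, 1], [0, 0, 1, 0], [0, 1, 0, 0], [1, 0, 0, 0]]
        )
        assert serialize_chain(from_connectivity_matrix(S)) == "ABBA"

    def test_round_trip_through_matrix(self, random_chain_pool):
        for chain in random_chain_pool:
            S = to_connectivity_matrix(chain)
            back = from_connectivity_matrix(S)
            assert np.array_equal(to_connectivity_matrix(back), S)

    @pytest.mark.parametrize(
        "S",
        [
            np.array([[0, 1], [0, 0]]),  # not symmetric
            np.array([[1, 1], [1, 1]]),  # nonzero diagonal
            np.eye(4, dtype=int)[::-1] + np.eye(4, dtype=int),  # diag violation
            np.ones((2, 2), dtype=int) - np.eye(2, dtype=int) + 1,  # entries > 1
        ],
    )
    def test_invalid_matrices_rejected(self, S):
        with pytest.raises(MatrixFormatError):
            from_connectivity_matrix(S)


class TestEditing:
    def test_break_removes_letter_and_threads(self):
        chain = parse_chain("A C^{+e} _{+B} A B _{+A} B C")
        after = break_contact(chain, "A")
        assert serialize_chain(after) == "C^{+e} _{+B} B B C"
        final = break_contact(after, "B")
        assert serialize_chain(final) == "C^{+e} C"

    def test_break_last_contact_gives_empty_chain(self):
        after = break_contact(parse_chain("AA"), "A")
        assert after.n_contacts == 0
        assert serialize_chain(after) == ""

    def test_break_bookkeeping(self, random_chain_pool):
        for chain in random_chain_pool:
            name = chain.contact_names[0]
            n_threads_hit = sum(1 for th in chain.threads if th.target == name)
            after = break_contact(chain, name)
            assert len(after.site_sequence) == len(chain.site_sequence) - 2
            assert len(after.threads) == len(chain.threads) - n_threads_hit

    def test_break_unknown_contact(self):
        with pytest.raises(UnknownContactError):
            break_contact(parse_chain("AA"), "Z")

    def test_merge_concatenates(self):
        merged = merge_chains(parse_chain("AA"), parse_chain("BB"))
        assert serialize_chain(merged) == "AABB"

    def test_merge_renames_collisions(self):
        merged = merge_chains(parse_chain("AA"), parse_chain("AA"))
        assert serialize_chain(merged) == "AABB"

    def test_merge_then_decompose_recovers_parts(self):
        from circuitchain import decompose_segments

        a, b = parse_chain("ABAB"), parse_chain("ABBA")
        merged = merge_chains(a, b)
        seg1, seg2 = decompose_segments(merged)
        assert canonical(seg1) == canonical(a)
        assert canonical(seg2) == canonical(b)


class TestFiles:
    def test_ctstr_round_trip(self, tmp_path, random_chain_pool):
        from circuitchain.notation import read_ctstr, write_ctstr

        path = tmp_path / "chains.ctstr"
        chains = random_chain_pool[:10]
        write_ctstr(path, chains)
        path.write_text("# comment line\n" + path.read_text())
        assert read_ctstr(path) == chains

    def test_matrix_tsv_with_sidecar(self, tmp_path):
        from circuitchain.notation import read_matrix_tsv, write_matrix_tsv
        import json
        import numpy as np

        chain = parse_chain("A^{+e} B A B _{+A}")
        path = tmp_path / "m.tsv"
        write_matrix_tsv(path, chain)
        S = read_matrix_tsv(path)
        assert np.array_equal(S, to_connectivity_matrix(chain))
        sidecar = json.loads((tmp_path / "m.tsv.json").read_text())
        assert chain_from_json(sidecar) == chain
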