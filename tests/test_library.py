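"""Library enumeration, annotation and rule-based classification."""

import itertools

import pytest
from hypothesis import given, strategies as st

from g4screen.library import (
    InvalidReferenceError,
    MalformedSequenceError,
    PatternError,
    ReferenceTopology,
    SpectralClass,
    annotate,
    assign_rule_class,
    count_by_tetrad_mutations,
    enumerate_library,
    match_tetrad_pattern,
)

REF_SEQ = "GGGTGGGTTGGGTGGGA"


def brute_force_raw_enumeration():
    """Independent string-surgery oracle for the raw (pre-dedup) library."""
    raw = []
    for bases in itertools.product("ACGT", repeat=4):
        s = list(REF_SEQ)
        for p, b in zip((2, 6, 11, 15), bases):
            s[p - 1] = b
        raw.append("".join(s))
    for tet in ("GGGG", "AGGG", "GGAG"):
        base = list(REF_SEQ)
        for p, b in zip((2, 6, 11, 15), tet):
            base[p - 1] = b
        for bases in itertools.product("ACT", repeat=4):
            s = list(base)
            for p, b in zip((4, 8, 9, 13), bases):
                s[p - 1] = b
            raw.append("".join(s))
    return raw


class TestEnumeration:
    def test_unique_count_and_sublibrary_sizes(self, library):
        assert len(library) == 496
        assert sum(1 for r in library if "tetrad" in r.sublibraries) == 256
        for sub in ("loop_17_3", "loop_17_4", "loop_17_10"):
            assert sum(1 for r in library if sub in r.sublibraries) == 81

    def test_raw_enumeration_has_three_duplicates(self, library):
        raw = brute_force_raw_enumeration()
        assert len(raw) == 499
        assert len(raw) - len(set(raw)) == 3
        assert set(raw) == {r.sequence for r in library}

    def test_duplicates_keep_all_sublibrary_tags(self, library):
        merged = [r for r in library if len(r.sublibraries) > 1]
        assert len(merged) == 3
        for r in merged:
            assert r.sublibraries[0] == "tetrad"  # tetrad id is canonical
            assert r.loop_pattern == "TTTT"
        assert {r.tetrad_pattern for r in merged} == {"GGGG", "AGGG", "GGAG"}

    def test_all_sequences_pairwise_distinct(self, library):
        seqs = [r.sequence for r in library]
        assert len(seqs) == len(set(seqs))

    def test_invalid_reference_rejected(self):
        # position 2 is a tetrad position and must be G
        bad = "GA" + REF_SEQ[2:]
        with pytest.raises(InvalidReferenceError):
            ReferenceTopology(sequence=bad)


class TestAnnotate:
    def test_reference_is_unmutated(self, ref):
        rec = annotate(REF_SEQ, ref)
        assert rec.n_tetrad_mutations == 0
        assert rec.tetrad_pattern == "GGGG"
        assert rec.loop_pattern == "TTTT"

    def test_single_mutation_at_position_2(self, ref):
        seq = REF_SEQ[:1] + "A" + REF_SEQ[2:]
        rec = annotate(seq, ref)
        assert rec.n_tetrad_mutations == 1
        assert rec.mutated_tetrad_positions == frozenset({2})
        assert rec.tetrad_pattern == "AGGG"

    def test_fully_mutated_tetrad(self, ref):
        s = list(REF_SEQ)
        for p in (2, 6, 11, 15):
            s[p - 1] = "A"
        rec = annotate("".join(s), ref)
        assert rec.n_tetrad_mutations == 4

    @pytest.mark.parametrize("bad", ["GGG", REF_SEQ + "A", REF_SEQ[:-1] + "X"])
    def test_malformed_sequences_rejected(self, ref, bad):
        with pytest.raises(MalformedSequenceError):
            annotate(bad, ref)

    @given(
        st.text(alphabet="ACGT", min_size=17, max_size=17),
    )
    def test_mutation_count_matches_non_g_tetrad_bases(self, seq):
        rec = annotate(seq)
        assert rec.n_tetrad_mutations == sum(
            1 for b in rec.tetrad_pattern if b != "G"
        )
        assert len(rec.mutated_tetrad_positions) == rec.n_tetrad_mutations


class TestMutationCounts:
    @pytest.mark.parametrize(
        "k,expected",
        [({0}, 81), ({1}, 172), ({2}, 54), ({3, 4}, 189)],
    )
    def test_partition_counts(self, library, k, expected):
        assert count_by_tetrad_mutations(library, k) == expected

    def test_partition_sums_to_library_size(self, library):
        total = sum(
            count_by_tetrad_mutations(library, k)
            for k in ({0}, {1}, {2}, {3, 4})
        )
        assert total == 496

    def test_two_mutation_brute_force(self, library):
        # C(4,2) position pairs x 3^2 substitutions, reference loops only
        expected = sum(
            1
            for bases in itertools.product("ACGT", repeat=4)
            if sum(b != "G" for b in bases) == 2
        )
        assert expected == 54
        assert count_by_tetrad_mutations(library, {2}) == expected


class TestPatternMatching:
    def test_naaa_or_aaan_selects_seven(self, library):
        assert len(match_tetrad_pattern(library, "NAAA", "AAAN")) == 7

    def test_gggg_equals_zero_mutation_count(self, library):
        assert len(match_tetrad_pattern(library, "GGGG")) == count_by_tetrad_mutations(
            library, {0}
        )

    def test_yyyy_on_tetrad_sublibrary(self, library):
        tetrad_only = [r for r in library if "tetrad" in r.sublibraries]
        assert len(match_tetrad_pattern(tetrad_only, "YYYY")) == 2**4

    @pytest.mark.parametrize("bad", ["GGG", "GGGX", "BGGG"])
    def test_bad_patterns_rejected(self, library, bad):
        with pytest.raises(PatternError):
            match_tetrad_pattern(library, bad)


class TestRuleClassifier:
    def test_unmutated_tetrad_is_17_3_biconditional(self, library):
        for rec in library:
            is_c3 = rec.class_label.major is SpectralClass.C17_3
            assert is_c3 == (rec.tetrad_pattern == "GGGG")

    def test_second_half_mutations_give_17_63(self, ref):
        seq = "".join(
            "A" if i == 10 else b for i, b in enumerate(REF_SEQ)
        )  # G->A at position 11
        rec = annotate(seq, ref)
        assert rec.tetrad_pattern == "GGAG"
        assert assign_rule_class(rec).major is SpectralClass.C17_63

    def test_dimer_background_with_three_loop_adenosines_is_17_4(self, library):
        cands = [
            r
            for r in library
            if r.sublibraries[0] == "loop_17_4" and r.n_loop_adenosines_489 == 3
        ]
        assert cands
        for r in cands:
            assert r.class_label.major is SpectralClass.C17_4

    def test_loop_adenosine_refinement_partitions_loop_17_4(self, library):
        for r in library:
            if r.sublibraries[0] != "loop_17_4":
                continue
            expected = {
                0: SpectralClass.C17_4s26,
                1: SpectralClass.C17_4s26,
                2: SpectralClass.C17_4_plus_17_4s26,
                3: SpectralClass.C17_4,
            }[r.n_loop_adenosines_489]
            assert r.class_label.major is expected

    def test_all_mutated_to_a_is_17_180(self, ref):
        s = list(REF_SEQ)
        for p in (2, 6, 11, 15):
            s[p - 1] = "A"
        rec = annotate("".join(s), ref)
        assert assign_rule_class(rec).major is SpectralClass.C17_180

    def test_tggt_override(self, library):
        tggt = [r for r in library if r.tetrad_pattern == "TGGT"]
        assert len(tggt) == 1
        assert tggt[0].class_label.major is SpectralClass.C17_36
        # with the override off, TGGT stays in 17.28 like the rest of HGGH
        off = assign_rule_class(tggt[0], tggt_to_17_36=False)
        assert off.major is SpectralClass.C17_28
        assert SpectralClass.C17_36 in off.ambiguous_alternatives

    def test_hggh_ambiguity_recorded_not_dropped(self, library):
        hggh = [
            r
            for r in library
            if r.class_label.major is SpectralClass.C17_28
        ]
        assert len(hggh) == 8  # nine HGGH patterns minus the TGGT override
        for r in hggh:
            assert SpectralClass.C17_36 in r.class_label.ambiguous_alternatives

    def test_classifier_is_total_and_deterministic(self, library):
        again = enumerate_library()
        for a, b in zip(library, again):
            assert a.class_label == b.class_label

    def test_rule_domains_mutually_exclusive(self, library):
        # a sequence cannot have both halves intact and be non-GGGG, so the
        # 17.3 / 17.63 / 17.4-family domains partition by construction
        for rec in library:
            tet = rec.tetrad_pattern
            first = tet[:2] == "GG"
            second = tet[2:] == "GG"
            cls = rec.class_label.major
            if first and second:
                assert cls is SpectralClass.C17_3
            elif first:
                assert cls is SpectralClass.C17_63
            elif second:
                assert cls in {
                    SpectralClass.C17_4,
                    SpectralClass.C17_4s26,
                    SpectralClass.C17_4_plus_17_4s26,
                }
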