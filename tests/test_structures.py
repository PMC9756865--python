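"""Structure types, WUSS parsing, consensus projection and family splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from predpair.structures import (
    FamilyRecord,
    SecondaryStructure,
    WussParseError,
    filter_families,
    pairs_to_dotbracket,
    parse_wuss,
    project_consensus,
    split_by_family,
)


def oracle_parse(notation):
    """Independent per-symbol-type stack oracle."""
    import string

    pairs = set()
    openers = {"(": ")", "<": ">", "[": "]", "{": "}"}
    openers.update({u: u.lower() for u in string.ascii_uppercase})
    close_of = {v: k for k, v in openers.items()}
    stacks = {}
    for pos, ch in enumerate(notation):
        if ch in openers:
            stacks.setdefault(ch, []).append(pos)
        elif ch in close_of:
            pairs.add((stacks[close_of[ch]].pop(), pos))
    return pairs


class TestParseWuss:
    @pytest.mark.parametrize(
        "notation,expected",
        [
            ("<<..>>", {(0, 5), (1, 4)}),
            (".....", set()),
            ("((..AA..))..aa", {(0, 9), (1, 8), (4, 13), (5, 12)}),
            ("((..[[..))..]]", {(0, 9), (1, 8), (4, 13), (5, 12)}),
            (",,::__~~--", set()),
        ],
    )
    def test_examples(self, notation, expected):
        assert parse_wuss(notation) == expected

    @pytest.mark.parametrize("bad", ["((.)", ".>", "Aa.a", "(]"])
    def test_unbalanced_raises_with_position(self, bad):
        with pytest.raises(WussParseError, match="position"):
            parse_wuss(bad)

    def test_matches_stack_oracle_on_random_balanced_strings(self):
        rng = np.random.default_rng(7)
        symbol_sets = ["()", "<>", "[]", "{}", "Aa", "Bb"]
        for _ in range(1000):
            n_pairs = int(rng.integers(0, 12))
            s = ["."] * (2 * n_pairs + int(rng.integers(0, 6)))
            free = list(range(len(s)))
            for _ in range(n_pairs):
                if len(free) < 2:
                    break
                i, j = sorted(rng.choice(len(free), size=2, replace=False))
                sym = symbol_sets[int(rng.integers(0, len(symbol_sets)))]
                # nested within one symbol type by construction: use fresh
                # type for crossing pairs is not needed for oracle equality
                s[free[i]], s[free[j]] = sym[0], sym[1]
                del free[j], free[i]
            notation = "".join(s)
            try:
                got = parse_wuss(notation)
            except WussParseError:
                # oracle agrees it is unbalanced (same-type crossing order)
                continue
            assert got == oracle_parse(notation)


class TestSecondaryStructure:
    def test_normalises_t_and_case(self):
        s = SecondaryStructure("x", "acgt")
        assert s.sequence == "ACGU"

    def test_rejects_base_triples(self):
        with pytest.raises(ValueError, match="triple"):
            SecondaryStructure("x", "GCGC", {(0, 1), (1, 2)})

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            SecondaryStructure("x", "GC", {(0, 5)})

    def test_canonical_filtering(self):
        s = SecondaryStructure("x", "GCAA", {(0, 1), (2, 3)})
        assert s.canonical_pairs() == {(0, 1)}  # G-C kept, A-A dropped


class TestProjectConsensus:
    def test_wobble_kept_noncanonical_dropped(self):
        s = project_consensus("m", "GC-AU", "<<.>>")
        assert s.sequence == "GCAU"
        # column pair (0,4)=G:U wobble kept -> (0,3); (1,3)=C:A dropped
        assert s.pairs == {(0, 3)}

    def test_all_unpaired(self):
        assert project_consensus("m", "ACGU", "....").pairs == set()

    def test_gap_in_unpaired_column_only(self):
        s = project_consensus("m", "A-U", "<.>")
        assert s.sequence == "AU"
        assert s.pairs == {(0, 1)}

    def test_gap_in_paired_column_drops_pair(self):
        s = project_consensus("m", "C-GG", "<<>>")
        # outer C:G kept and remapped, inner pair touches a gap -> dropped
        assert s.sequence == "CGG"
        assert s.pairs == {(0, 2)}

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            project_consensus("m", "ACGU", "...")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_pairs_canonical_and_in_bounds(self, seed):
        rng = np.random.default_rng(seed)
        L = 20
        cols = rng.choice(list("ACGU-"), size=L, p=[0.22, 0.22, 0.22, 0.22, 0.12])
        consensus = list("." * L)
        for i, j in [(0, 19), (1, 18), (4, 10)]:
            consensus[i], consensus[j] = "<", ">"
        s = project_consensus("m", "".join(cols), "".join(consensus))
        from predpair.structures import is_canonical

        for i, j in s.pairs:
            assert 0 <= i < j < len(s.sequence)
            assert is_canonical(s.sequence[i], s.sequence[j])


class TestDotBracket:
    def test_nested_single_layer(self, hairpin):
        db = pairs_to_dotbracket(len(hairpin), hairpin.pairs)
        assert db == "(((((....)))))"

    def test_crossing_uses_second_layer(self):
        # pseudoknot: (0,6) crosses (3,9)
        db = pairs_to_dotbracket(10, {(0, 6), (3, 9)})
        assert db.count("(") == 1 and db.count("<") == 1
        assert parse_wuss(db) == {(0, 6), (3, 9)}

    def test_roundtrip_random_crossing_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            L = 30
            pairs = set()
            used = set()
            for _ in range(8):
                i, j = sorted(rng.choice(L, size=2, replace=False).tolist())
                if i != j and not {i, j} & used:
                    pairs.add((i, j))
                    used |= {i, j}
            assert parse_wuss(pairs_to_dotbracket(L, pairs)) == pairs


class TestFamilyFilterAndSplit:
    def _family(self, fid, paired_fraction):
        # one member of length 10 with the requested paired fraction
        n_pairs = int(round(paired_fraction * 10 / 2))
        pairs = {(k, 9 - k) for k in range(n_pairs)}
        seq = "G" * 5 + "C" * 5
        return FamilyRecord(fid, [SecondaryStructure(fid, seq, pairs)])

    def test_threshold_strictness(self):
        below = self._family("below", 0.19)  # rounds to 1 pair -> 0.2? use counts
        below = FamilyRecord(
            "below", [SecondaryStructure("b", "G" * 100, set())],
            annotated_pair_count=9,
        )
        at = FamilyRecord(
            "at", [SecondaryStructure("a", "G" * 100, set())],
            annotated_pair_count=10,
        )
        kept = filter_families([below, at], 0.20)
        assert [f.family_id for f in kept] == ["at"]

    def test_empty_input(self):
        assert filter_families([], 0.2) == []

    def test_split_sizes_and_disjointness(self):
        fams = [self._family(f"f{k}", 0.4) for k in range(10)]
        split = split_by_family(fams, (0.6, 0.2, 0.2), seed=1)
        assert (len(split.train), len(split.validation), len(split.test)) == (6, 2, 2)
        assert split.all_families == {f"f{k}" for k in range(10)}

    def test_split_deterministic(self):
        ids = [f"fam{k}" for k in range(17)]
        a = split_by_family(ids, seed=42)
        b = split_by_family(ids, seed=42)
        assert (a.train, a.validation, a.test) == (b.train, b.validation, b.test)
        c = split_by_family(ids, seed=43)
        assert (a.train, a.validation, a.test) != (c.train, c.validation, c.test)

    def test_too_few_families(self):
        with pytest.raises(ValueError, match="3 families"):
            split_by_family(["a", "b"])

    def test_bad_ratios(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_by_family(["a", "b", "c"], (0.5, 0.2, 0.2))
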