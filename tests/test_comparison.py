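"""Heteroplasmy-aware pairwise comparison and the three-tier counting rule."""

import pytest
from hypothesis import given, settings, strategies as st

from mitokin import (MitoHaplotype, Mode, Outcome, PositionCall, Variant,
                     VariantKind, build_two_family_fixture, call_at, classify,
                     compare_all, count_differences, enumerate_pairs,
                     normalize, parse_haplotype, position_differs)
from mitokin.comparison import ComparisonError, results_to_frame


def call(position, alleles):
    return PositionCall(position=position, alleles=frozenset(alleles))


class TestPositionDiffers:
    @pytest.mark.parametrize("a,b,isfg,strict", [
        ("A", "A", False, False),          # identical homoplasmic
        ("A", "G", True, True),            # homoplasmic mismatch
        ("AG", "G", False, True),          # het shares the homoplasmic base
        ("AG", "AG", False, False),        # identical heteroplasmy
        ("AG", "CT", True, True),          # disjoint allele sets
        ("AG", "AT", False, True),         # overlapping heteroplasmies
    ])
    def test_mode_semantics(self, a, b, isfg, strict):
        c1, c2 = call(100, a), call(100, b)
        assert position_differs(c1, c2, Mode.ISFG) is isfg
        assert position_differs(c1, c2, Mode.STRICT) is strict
        # symmetry
        assert position_differs(c2, c1, Mode.ISFG) is isfg
        assert position_differs(c2, c1, Mode.STRICT) is strict

    def test_different_positions_rejected(self):
        with pytest.raises(ComparisonError):
            position_differs(call(1, "A"), call(2, "A"), Mode.ISFG)


class TestClassify:
    @pytest.mark.parametrize("n,outcome", [
        (0, Outcome.CANNOT_EXCLUDE), (1, Outcome.INCONCLUSIVE),
        (2, Outcome.EXCLUDE), (5, Outcome.EXCLUDE),
    ])
    def test_counting_rule(self, n, outcome):
        assert classify(n) is outcome

    def test_negative_rejected(self):
        with pytest.raises(ComparisonError):
            classify(-1)


class TestCountDifferences:
    def test_single_substitution_counts_in_both_modes(self, ref):
        h1 = parse_haplotype("", ref, "a")
        h2 = parse_haplotype("A16247G", ref, "b")
        for mode in Mode:
            res = count_differences(h1, h2, mode, ref)
            assert res.n_diff == 1 and res.outcome is Outcome.INCONCLUSIVE
            assert res.differing_positions == ("A16247G",)

    def test_heteroplasmy_vs_reference(self, ref):
        h1 = parse_haplotype("A2833R", ref, "a")
        h2 = parse_haplotype("", ref, "b")
        assert count_differences(h1, h2, Mode.ISFG, ref).n_diff == 0
        assert count_differences(h1, h2, Mode.STRICT, ref).n_diff == 1

    def test_two_heteroplasmies_exclude_in_strict_only(self, ref):
        h1 = parse_haplotype("T9012Y A16280R", ref, "a")
        h2 = parse_haplotype("", ref, "b")
        assert count_differences(h1, h2, Mode.ISFG, ref).outcome is Outcome.CANNOT_EXCLUDE
        res = count_differences(h1, h2, Mode.STRICT, ref)
        assert res.n_diff == 2 and res.outcome is Outcome.EXCLUDE

    def test_symmetry(self, ref):
        h1 = parse_haplotype("A16247G T146Y", ref, "a")
        h2 = parse_haplotype("T9012Y", ref, "b")
        for mode in Mode:
            r12 = count_differences(h1, h2, mode, ref)
            r21 = count_differences(h2, h1, mode, ref)
            assert r12.n_diff == r21.n_diff
            assert r12.differing_positions == r21.differing_positions

    def test_reference_mismatch_rejected(self, ref):
        h1 = parse_haplotype("", ref, "a")
        h2 = MitoHaplotype("b", (), reference_name="other")
        with pytest.raises(ComparisonError):
            count_differences(h1, h2, Mode.ISFG, ref)

    def test_no_call_positions_excluded(self, ref):
        h1 = parse_haplotype("A16247G", ref, "a")
        h2 = MitoHaplotype("b", (), ref.name, no_call=frozenset({16247}))
        for mode in Mode:
            assert count_differences(h1, h2, mode, ref).n_diff == 0

    def test_indel_in_one_sample_differs_in_both_modes(self, ref):
        h1 = parse_haplotype("315.1C", ref, "a")
        h2 = parse_haplotype("", ref, "b")
        for mode in Mode:
            assert count_differences(h1, h2, mode, ref).n_diff == 1

    def test_length_heteroplasmy_vs_concordant_insertion(self, ref):
        h1 = parse_haplotype("315.1C+", ref, "a")
        h2 = parse_haplotype("315.1C", ref, "b")
        assert count_differences(h1, h2, Mode.ISFG, ref).n_diff == 0
        assert count_differences(h1, h2, Mode.STRICT, ref).n_diff == 1


# random haplotype pairs over the small reference
def _random_haplotype(draw, small_ref, sample_id):
    n = draw(st.integers(0, 6))
    variants = {}
    for _ in range(n):
        position = draw(st.integers(1, small_ref.length))
        if small_ref.is_masked(position) or position in variants:
            continue
        ref_base = small_ref.base(position)
        others = [b for b in "ACGT" if b != ref_base]
        if draw(st.booleans()):
            alt = draw(st.sampled_from(others))
            variants[position] = Variant(
                kind=VariantKind.SUBSTITUTION, position=position,
                call=call(position, alt))
        else:
            alt = draw(st.sampled_from(others))
            variants[position] = Variant(
                kind=VariantKind.POINT_HETEROPLASMY, position=position,
                call=call(position, ref_base + alt))
    return MitoHaplotype(sample_id, tuple(variants.values()), small_ref.name)


class TestInvariants:
    @given(data=st.data())
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_isfg_differences_subset_of_strict(self, small_ref, data):
        h1 = _random_haplotype(data.draw, small_ref, "a")
        h2 = _random_haplotype(data.draw, small_ref, "b")
        isfg = count_differences(h1, h2, Mode.ISFG, small_ref)
        strict = count_differences(h1, h2, Mode.STRICT, small_ref)
        assert set(isfg.differing_positions) <= set(strict.differing_positions)

    @given(data=st.data())
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_matches_full_reference_scan(self, small_ref, data):
        """Brute-force oracle: compare the effective call at every unmasked
        position of the reference instead of only the variant positions."""
        h1 = _random_haplotype(data.draw, small_ref, "a")
        h2 = _random_haplotype(data.draw, small_ref, "b")
        for mode in Mode:
            expected = sum(
                position_differs(call_at(h1, p, small_ref),
                                 call_at(h2, p, small_ref), mode)
                for p in range(1, small_ref.length + 1)
                if not small_ref.is_masked(p))
            assert count_differences(h1, h2, mode, small_ref).n_diff == expected

    def test_masked_variants_never_reported(self, small_ref):
        inside = 52  # masked range 50-55
        h1 = normalize(MitoHaplotype("a", (
            Variant(kind=VariantKind.SUBSTITUTION, position=inside,
                    call=call(inside, "A" if small_ref.base(inside) != "A" else "G")),),
            small_ref.name), small_ref)
        h2 = parse_haplotype("", small_ref, "b")
        for mode in Mode:
            assert count_differences(h1, h2, mode, small_ref).n_diff == 0


class TestCompareAll:
    def test_identical_haplotypes_all_cannot_exclude(self, ref):
        _, haplotypes, _ = build_two_family_fixture(ref)
        empty = {s: MitoHaplotype(s, (), ref.name) for s in haplotypes}
        from mitokin import Pedigree
        pedigree, _, _ = build_two_family_fixture(ref)
        pairs, _ = enumerate_pairs(pedigree)
        table, _, _ = compare_all(pairs, empty, Mode.ISFG, ref)
        assert table.count(Outcome.CANNOT_EXCLUDE) == table.n_pairs == len(pairs)

    def test_fixture_outcome_counts(self, ref):
        pedigree, haplotypes, _ = build_two_family_fixture(ref)
        pairs, _ = enumerate_pairs(pedigree)
        table, results, matrix = compare_all(pairs, haplotypes, Mode.ISFG, ref)
        assert table.n_pairs == 1732
        assert table.count(Outcome.INCONCLUSIVE) == 64
        assert table.count(Outcome.EXCLUDE) == 0
        assert matrix.to_numpy().sum() == 1732
        frame = results_to_frame(results)
        assert (frame["n_diff"] == 1).sum() == 64

    def test_missing_haplotype_raises(self, ref):
        pedigree, haplotypes, _ = build_two_family_fixture(ref)
        pairs, _ = enumerate_pairs(pedigree)
        haplotypes = dict(haplotypes)
        haplotypes.pop("FAM8-7")
        with pytest.raises(ComparisonError, match="FAM8-7"):
            compare_all(pairs, haplotypes, Mode.ISFG, ref)
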