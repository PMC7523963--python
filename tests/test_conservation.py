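"""Conservation profile, region variation rates, and the disorder index."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arctail.conservation import (
    AlignedFamily,
    RegionSpec,
    build_family,
    conservation_profile,
    disorder_index,
    family_from_alignment,
    region_summary,
    region_variation_rate,
)
from arctail.io_formats import ProteinSequence


def _family(rows, reference_id="s1"):
    seqs = [ProteinSequence(f"s{i+1}", "", row) for i, row in enumerate(rows)]
    return build_family(seqs, reference_id)


class TestBuildFamily:
    def test_equal_length_is_positional_identity_map(self):
        fam = _family(["ACDEFGHIK"] * 9)
        assert fam.metadata["engine"] == "positional"
        assert fam.column_map == list(range(1, 10))

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            _family(["ACDE"])

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            _family(["ACDE", "ACDE"], reference_id="nope")

    def test_internal_deletion_maps_reference_gap_column(self):
        # reference lacks one residue present in the other sequence: the
        # alignment must contain exactly one reference-gap column
        ref = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        other = ref[:15] + "A" + ref[15:]
        fam = build_family(
            [ProteinSequence("ref", "", ref), ProteinSequence("oth", "", other)], "ref"
        )
        assert fam.metadata["engine"] == "mafft"
        gaps = [c for c, p in enumerate(fam.column_map) if p is None]
        assert len(gaps) == 1
        mapped = [p for p in fam.column_map if p is not None]
        assert mapped == list(range(1, len(ref) + 1))

    def test_prealigned_input(self):
        fam = family_from_alignment([("a", "AC-E"), ("b", "ACDE")], "a")
        assert fam.column_map == [1, 2, None, 3]


class TestConservationProfile:
    def test_identity_family_has_no_variants(self):
        prof = conservation_profile(_family(["ACDEF"] * 4))
        assert prof.variant_positions() == []
        assert all(prof.majority[p] == "ACDEF"[p - 1] for p in prof.positions)

    def test_single_minority_residue_is_variant_majority_kept(self):
        prof = conservation_profile(_family(["AAAA", "AAAA", "AAAA", "GAAA"]))
        assert prof.variant[1] and prof.majority[1] == "A"
        assert prof.counts[1] == {"A": 3, "G": 1}

    def test_tie_broken_toward_reference_then_alphabetical(self):
        # column 1: {A,A,G,G} with reference A -> majority A
        prof = conservation_profile(_family(["AC", "AC", "GC", "GC"]))
        assert prof.variant[1] and prof.majority[1] == "A"
        # reference not among tied symbols -> alphabetical
        prof2 = conservation_profile(_family(["TC", "GC", "GC", "AC", "AC"]))
        assert prof2.majority[1] == "A"

    def test_x_and_gap_count_as_disagreement(self):
        prof = conservation_profile(_family(["XA", "XA"]))
        assert prof.variant[1] and not prof.variant[2]
        fam = family_from_alignment([("a", "A-C"), ("b", "AAC")], "b")
        assert conservation_profile(fam).variant[2]


class TestRegionVariationRate:
    def test_toy_family_two_variant_columns_in_ten(self):
        rows = ["ACDEFGHIKL", "ACDEFGHIKL", "ACDQFGHIKV"]  # variants at 4 and 10
        prof = conservation_profile(_family(rows))
        rr = region_variation_rate(prof, RegionSpec("all", 1, 10))
        assert (rr.variant_count, rr.length) == (2, 10)
        assert rr.rate == pytest.approx(0.2)

    def test_identical_sequences_rate_zero(self):
        prof = conservation_profile(_family(["ACDEFGHIKL"] * 5))
        assert region_variation_rate(prof, RegionSpec("r", 3, 7)).rate == 0.0

    def test_region_outside_reference_rejected(self):
        prof = conservation_profile(_family(["ACDE"] * 2))
        with pytest.raises(ValueError, match="exceeds reference"):
            region_variation_rate(prof, RegionSpec("r", 2, 9))

    def test_invalid_region_spec(self):
        with pytest.raises(ValueError):
            RegionSpec("r", 5, 4)
        with pytest.raises(ValueError):
            RegionSpec("r", 0, 4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_permutation_invariance_and_additivity(self, data):
        rng = random.Random(data.draw(st.integers(0, 10_000)))
        length = 30
        rows = []
        for _ in range(5):
            rows.append("".join(rng.choice("ACDG") for _ in range(length)))
        prof = conservation_profile(_family(rows))
        # permutation invariance
        perm = rows[:]
        rng.shuffle(perm)
        ids = [f"s{i}" for i in range(5)]
        fam2 = AlignedFamily(list(zip(ids, perm)), ids[perm.index(rows[0])],
                             list(range(1, length + 1)))
        prof2 = conservation_profile(fam2)
        whole = RegionSpec("w", 1, length)
        assert (
            region_variation_rate(prof, whole).variant_count
            == region_variation_rate(prof2, whole).variant_count
        )
        # additivity over a random split
        cut = data.draw(st.integers(1, length - 1))
        left = region_variation_rate(prof, RegionSpec("l", 1, cut))
        right = region_variation_rate(prof, RegionSpec("r", cut + 1, length))
        assert left.variant_count + right.variant_count == region_variation_rate(prof, whole).variant_count

    def test_region_summary_schema(self):
        prof = conservation_profile(_family(["ACDEFGHIKL"] * 3))
        frame = region_summary(prof, [RegionSpec("a", 1, 5), RegionSpec("b", 6, 10)])
        assert list(frame.columns) == ["region", "length", "variant_count", "variation_rate"]
        assert frame["length"].tolist() == [5, 5]


class TestDisorderIndex:
    def test_charged_homopolymer_scores_disordered(self):
        scores = disorder_index("E" * 30, window=5)
        assert all(s > 0 for s in scores)

    def test_hydrophobic_homopolymer_scores_ordered(self):
        scores = disorder_index("I" * 30, window=5)
        assert all(s < 0 for s in scores)

    def test_interior_value_matches_hand_arithmetic(self):
        # window 5 centred on position 3 of KEDIVA: fragment KEDIV,
        # |net charge|/5 = 0.2, mean normalised KD hydropathy evaluated by
        # hand; d = (0.2 + 1.151)/2.785 - <H> = 0.033988
        scores = disorder_index("KEDIVA", window=5)
        assert scores[2] == pytest.approx(0.033988, abs=1e-6)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            disorder_index("ACDEF", window=4)
        with pytest.raises(ValueError, match="larger than sequence"):
            disorder_index("ACD", window=5)
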