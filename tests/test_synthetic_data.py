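"""Generators: determinism, planted truths, and downstream recovery."""

import numpy as np
import pytest

from arctail.chemshift import delta_ca, detect_tail_start, segment_secondary_structure
from arctail.conservation import RegionSpec, conservation_profile, region_variation_rate
from arctail.csp import csp_profile, match_residues, perturbed_residues
from arctail.io_formats import ProteinSequence
from arctail.pest import pest_profile
from arctail.synthetic_data import (
    CspConfig,
    FamilyConfig,
    ShiftConfig,
    implant_pest,
    simulate_csp_pair,
    simulate_family,
    simulate_shift_table,
    synthetic_arc_sequence,
)


class TestDeterminism:
    def test_family_byte_identical_under_fixed_seed(self):
        a, truth_a = simulate_family(seed=42)
        b, truth_b = simulate_family(seed=42)
        assert a.members == b.members and truth_a == truth_b
        c, _ = simulate_family(seed=43)
        assert c.members != a.members

    def test_shift_table_and_csp_pair_reproducible(self):
        t1, _ = simulate_shift_table(seed=7)
        t2, _ = simulate_shift_table(seed=7)
        assert t1.entries == t2.entries
        a1, b1, _ = simulate_csp_pair(seed=7)
        a2, b2, _ = simulate_csp_pair(seed=7)
        assert a1.entries == a2.entries and b1.entries == b2.entries


class TestFamilyGenerator:
    def test_zero_probability_identical_members(self):
        cfg = FamilyConfig(regions=[(RegionSpec("all", 1, 396), 0.0)])
        family, truth = simulate_family(cfg, seed=0)
        assert truth == set()
        rows = {row for _, row in family.members}
        assert len(rows) == 1

    def test_probability_one_region_fully_variant(self):
        cfg = FamilyConfig(regions=[(RegionSpec("hot", 10, 20), 1.0)])
        family, truth = simulate_family(cfg, seed=0)
        profile = conservation_profile(family)
        rr = region_variation_rate(profile, RegionSpec("hot", 10, 20))
        assert rr.rate == 1.0
        assert truth == set(range(10, 21))

    def test_truth_labels_match_recovered_variant_columns(self):
        family, truth = simulate_family(seed=5)
        profile = conservation_profile(family)
        assert set(profile.variant_positions()) == truth

    def test_too_few_members_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_family(FamilyConfig(n_members=1), seed=0)

    def test_binomial_sampling_calibration(self):
        # 500 replicate draws of a 46-column region at p = 0.39: the mean
        # estimated rate must fall in the exact binomial 95% interval of
        # the pooled draw count
        from scipy.stats import binom

        p, ncols, reps = 0.39, 46, 500
        cfg = FamilyConfig(n_members=9, reference_length=46,
                           regions=[(RegionSpec("r", 1, 46), p)])
        total = 0
        for s in range(reps):
            family, truth = simulate_family(cfg, seed=s)
            total += len(truth)
        lo, hi = binom.ppf([0.025, 0.975], ncols * reps, p)
        assert lo <= total <= hi


class TestShiftGenerator:
    def test_noiseless_coil_recovers_exact_zero(self):
        cfg = ShiftConfig(
            helices=[], coil_band=0.0, coil_outlier_prob=0.0,
            noise_sigma={"helix": 0.0, "strand": 0.0, "coil": 0.0},
        )
        table, truth = simulate_shift_table(cfg, seed=0)
        profile = delta_ca(table)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in profile.values.values())
        assert [s.state for s in truth.segments] == ["coil"]

    def test_noiseless_five_helix_pattern_recovered_exactly(self):
        cfg = ShiftConfig(
            coil_band=0.0, coil_outlier_prob=0.0,
            noise_sigma={"helix": 0.0, "strand": 0.0, "coil": 0.0},
            missing=[],
        )
        table, truth = simulate_shift_table(cfg, seed=0)
        seg = segment_secondary_structure(delta_ca(table), 0.05, -0.05, 4)
        assert [(s.start, s.end, s.state) for s in seg.segments] == [
            (s.start, s.end, s.state) for s in truth.segments
        ]

    def test_missing_positions_absent_from_table(self, arc_sequence):
        table, _ = simulate_shift_table(seed=1, sequence=arc_sequence)
        numbers = {e.residue_number for e in table.entries}
        assert 280 not in numbers and 281 not in numbers  # first two unassigned
        prolines = {r for r in range(280, 397) if arc_sequence.residue(r) == "P"}
        assert prolines and not (prolines & numbers)

    def test_planted_tail_position_recovered(self):
        # plant the tail at a non-default position and recover it
        cfg = ShiftConfig(helices=[(281, 300), (305, 330)], coil_outlier_prob=0.0)
        table, truth = simulate_shift_table(cfg, seed=3)
        seg = segment_secondary_structure(delta_ca(table), 0.05, -0.05, 4)
        tail = detect_tail_start(seg, table.residue_types())
        assert tail.residue == 331


class TestCspGenerator:
    def test_empty_truth_sigma_zero_identical_tables(self):
        cfg = CspConfig(perturbed=frozenset(), noise_sigma_h=0.0, noise_sigma_n=0.0)
        a, b, truth = simulate_csp_pair(cfg, seed=0)
        profile = csp_profile(match_residues(a, b)[0])
        assert truth == set()
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in profile.csp.values())

    def test_planted_truth_recovered_exactly(self):
        cfg = CspConfig(
            construct_range=(1, 40), perturbed=frozenset({10, 11}),
            offset_h=0.05, offset_n=0.25,  # 5x the noise scale
            noise_sigma_h=0.01, noise_sigma_n=0.05,
        )
        seq = ProteinSequence("s", "", "A" * 40)
        a, b, truth = simulate_csp_pair(cfg, seed=11, sequence=seq)
        flagged, _ = perturbed_residues(csp_profile(match_residues(a, b)[0]))
        assert truth == {10, 11} and flagged == truth

    def test_noiseless_offsets_give_hand_oracle_csp(self):
        cfg = CspConfig(
            construct_range=(1, 20), perturbed=frozenset({5}),
            offset_h=0.1, offset_n=0.5, noise_sigma_h=0.0, noise_sigma_n=0.0,
        )
        seq = ProteinSequence("s", "", "A" * 20)
        a, b, _ = simulate_csp_pair(cfg, seed=0, sequence=seq)
        profile = csp_profile(match_residues(a, b)[0])
        assert profile.csp[5] == pytest.approx(0.244949, abs=1e-6)
        assert profile.csp[6] == pytest.approx(0.0, abs=1e-12)


class TestImplantPest:
    def test_implant_places_flanks_and_content(self, arc_sequence):
        assert arc_sequence.residue(350) == "K" and arc_sequence.residue(393) == "K"
        frag = arc_sequence.residues[350:392]
        assert "P" in frag and set(frag) & set("DE") and set(frag) & set("ST")
        assert not set(frag) & set("KRH")

    def test_implant_into_all_k_sequence_flank_rule(self):
        seq = ProteinSequence("k", "", "K" * 30)
        implanted = implant_pest(seq, RegionSpec("i", 5, 20))
        regions = pest_profile(implanted)
        assert [(r.start, r.end) for r in regions] == [(5, 20)]
        assert (regions[0].flank_left, regions[0].flank_right) == ("K", "K")

    def test_recipe_validation(self):
        seq = ProteinSequence("s", "", "A" * 30)
        with pytest.raises(ValueError, match="at least one P"):
            implant_pest(seq, RegionSpec("i", 5, 20), recipe="ESTDA")
        with pytest.raises(ValueError, match="D/E"):
            implant_pest(seq, RegionSpec("i", 5, 20), recipe="PSTA")
        with pytest.raises(ValueError, match="S/T"):
            implant_pest(seq, RegionSpec("i", 5, 20), recipe="PDEA")
        with pytest.raises(ValueError, match="positively charged"):
            implant_pest(seq, RegionSpec("i", 5, 20), recipe="PESTK")
        with pytest.raises(ValueError, match="beyond the sequence"):
            implant_pest(seq, RegionSpec("i", 20, 40))
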