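"""ReDCaT design series, masses, %Rmax normalization and footprinting."""

import math

import numpy as np
import pytest
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

from bindscan.spr import (
    REDCAT_OVERHANG,
    SPRCycle,
    analyze_cycles,
    dna_strand_mw,
    duplex_mw,
    infer_footprint,
    make_redcat_duplex,
    percent_rmax,
    protein_mw,
    protein_pi,
    substitution_series,
    theoretical_rmax,
    tile_region,
    truncation_series,
)
from bindscan.synthetic import SprSimConfig, make_genome, simulate_spr_cycles

from conftest import annotate_intact


def revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestDuplexDesign:
    def test_bottom_strand_definition(self):
        d = make_redcat_duplex("ATGC", "d1")
        assert d.bottom_strand == "GCAT" + REDCAT_OVERHANG
        assert len(d.bottom_strand) == 24

    def test_forty_mer_gives_sixty_nt_bottom_strand(self):
        d = make_redcat_duplex("A" * 40, "d1")
        assert len(d.bottom_strand) == 60

    def test_over_forty_rejected(self):
        with pytest.raises(ValueError, match="40"):
            make_redcat_duplex("A" * 41, "d1")

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            make_redcat_duplex("ATGU", "d1")


class TestTiling:
    def test_single_oligo_spans_whole_region(self):
        region = make_genome(40, 0.6, seed=3).sequence
        (d,) = tile_region(region, 40, 1)
        assert d.test_seq == region
        assert (d.region_start, d.region_end) == (0, 40)

    def test_six_oligo_placement(self):
        region = make_genome(130, 0.6, seed=3).sequence
        designs = tile_region(region, 40, 6)
        starts = [d.region_start for d in designs]
        assert starts == [0, 18, 36, 54, 72, 90]
        for a, b in zip(designs, designs[1:]):
            assert a.region_end - b.region_start == 22
        assert designs[-1].region_end == 130
        for d in designs:
            assert d.test_seq == region[d.region_start : d.region_end]

    def test_impossible_coverage_rejected(self):
        region = make_genome(300, 0.6, seed=3).sequence
        with pytest.raises(ValueError, match="cover"):
            tile_region(region, 40, 6)


class TestTruncation:
    def test_left_series_lengths_and_suffixes(self):
        region = make_genome(40, 0.6, seed=5).sequence
        designs = truncation_series(region, "left", step=2, min_len=30)
        assert [len(d.test_seq) for d in designs] == [40, 38, 36, 34, 32, 30]
        for d in designs:
            assert region.endswith(d.test_seq)
            assert d.test_seq in region

    def test_min_len_equal_length_gives_identity(self):
        region = make_genome(36, 0.6, seed=5).sequence
        designs = truncation_series(region, "right", step=2, min_len=36)
        assert len(designs) == 1 and designs[0].test_seq == region

    def test_right_mirrors_left_on_reversed_sequence(self):
        region = make_genome(40, 0.6, seed=5).sequence
        right = truncation_series(region, "right", step=2, min_len=30)
        left_rev = truncation_series(region[::-1], "left", step=2, min_len=30)
        assert [d.test_seq for d in right] == [d.test_seq[::-1] for d in left_rev]

    def test_min_len_beyond_region_rejected(self):
        with pytest.raises(ValueError, match="min_len"):
            truncation_series("ACGTACGT", "left", min_len=9)


class TestSubstitution:
    spans = [("DR1", 2, 12), ("DR2", 14, 24), ("DR3", 26, 36)]

    def test_three_repeats_give_seven_designs(self):
        region = make_genome(40, 0.6, seed=7).sequence
        designs = substitution_series(region, self.spans, seed=11)
        assert len(designs) == 7
        kept = {d.intact_repeats for d in designs}
        assert len(kept) == 7 and all(1 <= len(k) <= 3 for k in kept)

    def test_keep_all_design_is_original(self):
        region = make_genome(40, 0.6, seed=7).sequence
        designs = substitution_series(region, self.spans, seed=11)
        full = next(d for d in designs if len(d.intact_repeats) == 3)
        assert full.test_seq == region

    def test_lengths_unchanged_and_edits_confined_to_replaced_spans(self):
        region = make_genome(40, 0.6, seed=7).sequence
        for d in substitution_series(region, self.spans, seed=11):
            assert len(d.test_seq) == len(region)
            replaced = [s for s in self.spans if s[0] not in d.intact_repeats]
            for pos, (a, b) in enumerate(zip(region, d.test_seq)):
                inside = any(s <= pos < e for _, s, e in replaced)
                if not inside:
                    assert a == b

    def test_overlapping_spans_rejected(self):
        region = make_genome(40, 0.6, seed=7).sequence
        with pytest.raises(ValueError, match="overlap"):
            substitution_series(region, [("DR1", 2, 12), ("DR2", 10, 20)], seed=1)


class TestMasses:
    def test_acgt_strand_mass(self):
        assert dna_strand_mw("ACGT") == pytest.approx(1173.84, abs=1e-9)

    def test_single_base(self):
        assert dna_strand_mw("A") == pytest.approx(251.25, abs=1e-9)

    def test_duplex_mass_additivity(self):
        d = make_redcat_duplex("ATGC", "d1")
        assert duplex_mw(d) == pytest.approx(
            dna_strand_mw(d.test_seq) + dna_strand_mw(d.bottom_strand)
        )

    def test_glycine_mw(self):
        assert protein_mw("G") == pytest.approx(75.07, abs=0.01)

    def test_unknown_letters_rejected(self):
        with pytest.raises(ValueError, match="amino-acid"):
            protein_mw("GZ")
        with pytest.raises(ValueError, match="amino-acid"):
            protein_pi("GB")

    def test_pi_matches_independent_bjellqvist_implementation(self):
        sequences = [
            "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEK",
            "MSTNPKPQRKTKRNTNRRPQDVKFPGG",
            "MAEGEITTFTALTEKFNLPPGNYKKPKLLYCSNGGHFLRILPDGTVDGT",
        ]
        for seq in sequences:
            assert protein_pi(seq) == pytest.approx(
                IsoelectricPoint(seq).pi(), abs=0.05
            )

    def test_polyglycine_pi_between_terminal_pkas(self):
        # only the termini ionize, so pI must sit between their pKa values
        assert 3.55 < protein_pi("GGGGGG") < 7.5


class TestRmax:
    def test_unit_mass_ratio(self):
        assert theoretical_rmax(24700, 24700, 100) == pytest.approx(100.0)

    def test_hand_arithmetic(self):
        assert theoretical_rmax(30000, 24700, 100) == pytest.approx(121.457, abs=1e-3)

    def test_stoichiometry_linearity(self):
        one = theoretical_rmax(30000, 24700, 100, 1)
        assert theoretical_rmax(30000, 24700, 100, 2) == pytest.approx(2 * one)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            theoretical_rmax(0, 24700, 100)

    def test_percent_rmax_endpoints(self):
        assert percent_rmax(121.457, 121.457) == pytest.approx(100.0)
        assert percent_rmax(0.0, 121.457) == 0.0
        assert percent_rmax(60, 121.457) == pytest.approx(49.40, abs=0.005)

    def test_percent_rmax_linearity(self):
        rmax = 87.3
        values = [percent_rmax(r, rmax) for r in (10.0, 20.0, 40.0)]
        assert values[1] == pytest.approx(2 * values[0])
        assert values[2] == pytest.approx(4 * values[0])

    def test_above_120_percent_warns(self):
        with pytest.warns(UserWarning, match="120"):
            percent_rmax(200.0, 100.0)

    def test_zero_rmax_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            percent_rmax(10.0, 0.0)


class TestAnalyzeCycles:
    def test_identical_replicates_have_zero_sem(self):
        d = make_redcat_duplex("ATGCATGCAT", "d1")
        cycles = [SPRCycle("d1", 100.0, 50.0)] * 3
        (res,) = analyze_cycles(cycles, [d], analyte_mw=30000)
        assert res.sem == 0.0 and res.n_cycles == 3
        expected = 100 * 50.0 / theoretical_rmax(30000, duplex_mw(d), 100.0)
        assert res.percent_rmax == pytest.approx(expected)

    def test_unknown_design_rejected(self):
        d = make_redcat_duplex("ATGC", "d1")
        with pytest.raises(ValueError, match="unknown design_id"):
            analyze_cycles([SPRCycle("nope", 100, 10)], [d], analyte_mw=30000)

    def test_zero_noise_recovers_occupancy_closed_form(self):
        designs = [
            annotate_intact(d, TestSubstitution.spans)
            for d in substitution_series(
                make_genome(40, 0.6, seed=7).sequence, TestSubstitution.spans, seed=11
            )
        ]
        config = SprSimConfig(
            repeat_energies={"DR1": -1.0, "DR2": -2.0, "DR3": -3.0},
            baseline_kd=1e-6,
            protein_conc=5e-8,
            noise_sd=0.0,
            seed=1,
        )
        cycles = simulate_spr_cycles(designs, config, n_replicates=2)
        results = analyze_cycles(cycles, designs, analyte_mw=config.analyte_mw)
        by_id = {d.design_id: d for d in designs}
        for res in results:
            d = by_id[res.design_id]
            ddg = sum(config.repeat_energies[r] for r in d.intact_repeats)
            kd = config.baseline_kd * math.exp(ddg / 0.593)
            theta = config.protein_conc / (config.protein_conc + kd)
            assert res.percent_rmax == pytest.approx(100 * theta, abs=1e-6)
            assert res.sem == pytest.approx(0.0, abs=1e-9)


class TestFootprint:
    spans = [("DR1", 2, 12), ("DR2", 14, 24), ("DR3", 26, 36)]

    def _series(self, region, side):
        designs = [
            annotate_intact(d, self.spans)
            for d in truncation_series(region, side, step=2, min_len=20)
        ]
        # every repeat contributes strongly: damaging the outermost one
        # drops occupancy well below the 20% loss threshold
        config = SprSimConfig(
            repeat_energies={"DR1": -2.5, "DR2": -2.5, "DR3": -2.5},
            baseline_kd=1e-3,
            protein_conc=1e-8,
            noise_sd=0.0,
            seed=99,
        )
        cycles = simulate_spr_cycles(designs, config, n_replicates=3)
        results = analyze_cycles(cycles, designs, analyte_mw=config.analyte_mw)
        order = {d.design_id: i for i, d in enumerate(designs)}
        return sorted(results, key=lambda r: order[r.design_id]), designs

    def test_threshold_semantics_on_monotone_series(self):
        region = make_genome(40, 0.6, seed=13).sequence
        designs = truncation_series(region, "left", step=2, min_len=20)
        percents = [100, 90, 80, 70, 60, 50, 40, 30, 10, 5, 1]
        from bindscan.spr import BindingResult

        left = [
            BindingResult(d.design_id, 100.0, p, 0.0, 1, p >= 20)
            for d, p in zip(designs, percents)
        ]
        full = [BindingResult(designs[0].design_id, 100.0, 100, 0.0, 1, True)]
        fp = infer_footprint(left, full, designs, loss_fraction=0.2)
        # loss at the first value < 20 (index 8); last retained start = 7*2
        assert fp.start == 14 and fp.left_lost

    def test_simulated_footprint_covers_planted_repeats(self):
        region = make_genome(40, 0.6, seed=13).sequence
        left, l_designs = self._series(region, "left")
        right, r_designs = self._series(region, "right")
        fp = infer_footprint(left, right, l_designs + r_designs, loss_fraction=0.2)
        assert fp.left_lost and fp.right_lost
        # covers all repeats, erring by at most one 2-bp truncation step per side
        assert 0 <= fp.start <= 2
        assert 36 <= fp.end <= 38

    def test_binding_never_lost_returns_full_region_with_warnings(self):
        region = make_genome(40, 0.6, seed=13).sequence
        designs = truncation_series(region, "left", step=2, min_len=30)
        from bindscan.spr import BindingResult

        series = [
            BindingResult(d.design_id, 100.0, 95.0, 0.0, 1, True) for d in designs
        ]
        rdesigns = truncation_series(region, "right", step=2, min_len=30)
        rseries = [
            BindingResult(d.design_id, 100.0, 95.0, 0.0, 1, True) for d in rdesigns
        ]
        fp = infer_footprint(series, rseries, designs + rdesigns)
        assert (fp.start, fp.end) == (0, 40)
        assert not fp.left_lost and not fp.right_lost
        assert len(fp.warnings) == 2

    def test_no_full_length_binding_rejected(self):
        region = make_genome(40, 0.6, seed=13).sequence
        designs = truncation_series(region, "left", step=2, min_len=30)
        from bindscan.spr import BindingResult

        series = [BindingResult(d.design_id, 100.0, 0.0, 0.0, 1, False) for d in designs]
        with pytest.raises(ValueError, match="no binding"):
            infer_footprint(series, series, designs)
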