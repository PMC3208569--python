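"""Protein edits, codon/splice arithmetic, hydropathy and transfer energetics,
nonparametric group comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as stn

from ancl_exome.protein_physchem import (
    RECORDED_SEGMENT,
    RECORDED_WINDOW,
    SCALES,
    GroupComparison,
    ProteinEdit,
    ProteinSequence,
    apply_edit,
    calibrate_profile_convention,
    codon_of_cds_position,
    compare_variant_profiles,
    hydropathy_profile,
    inframe_check,
    load_reference,
    octanol_minus_interface,
    segment_stats,
    splice_cv_reduction,
    transfer_dG,
)


@pytest.fixture(scope="module")
def wt():
    return load_reference()


class TestProteinSequence:
    def test_reference_is_198_residues_with_domains(self, wt):
        assert len(wt) == 198
        assert wt.domains["cysteine_string"] == (113, 136)
        assert wt.domains["membrane_segment"] == (108, 139)

    def test_dileucine_and_anchor_residues(self, wt):
        assert wt.residue(115) == "L" and wt.residue(116) == "L"
        assert wt.residue(108) == "A" and wt.residue(139) == "K"
        assert all(wt.residue(p) == "C" for p in (121, 122, 123, 124))
        assert sum(wt.residue(p) == "C" for p in range(113, 120)) == 3

    def test_rejects_noncanonical_residues(self):
        with pytest.raises(ValueError, match="non-canonical"):
            ProteinSequence("x", "ACDEFGBZ")

    def test_fasta_roundtrip(self, wt, tmp_path):
        path = tmp_path / "seq.fa"
        wt.to_fasta(path)
        back = ProteinSequence.from_fasta(path)
        assert back.residues == wt.residues


class TestEdits:
    def test_L115R_substitutes_in_place(self, wt):
        mut = apply_edit(wt, "L115R")
        assert len(mut) == 198
        assert mut.residue(115) == "R"
        assert mut.residues[:114] == wt.residues[:114]
        assert mut.residues[115:] == wt.residues[115:]

    def test_L116del_shifts_downstream_numbering(self, wt):
        mut = apply_edit(wt, "L116del")
        assert len(mut) == 197
        for i in range(117, 199):  # former residue i now at i-1
            assert mut.residue(i - 1) == wt.residue(i)

    def test_multisite_cysteine_substitution(self, wt):
        mut = apply_edit(wt, "C113-119S")
        changed = [p for p in range(113, 120) if mut.residue(p) != wt.residue(p)]
        assert len(changed) == 3
        assert all(mut.residue(p) == "S" for p in changed)
        assert all(wt.residue(p) == "C" for p in changed)

    def test_range_deletion_with_reference_check(self, wt):
        mut = apply_edit(wt, "KPK137-139del")
        assert len(mut) == 195

    def test_reference_mismatch_cites_position(self, wt):
        with pytest.raises(ValueError, match="115"):
            apply_edit(wt, "A115R")

    def test_substitution_reversal_restores_sequence(self, wt):
        mut = apply_edit(wt, "L115R")
        back = apply_edit(mut, "R115L")
        assert back.residues == wt.residues

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            ProteinEdit.parse("notanedit")


class TestCodonArithmetic:
    def test_c344_maps_to_codon_115_offset_2(self):
        cp = codon_of_cds_position(344)
        assert (cp.codon, cp.offset) == (115, 2)

    def test_codon_boundary(self):
        assert codon_of_cds_position(3) == codon_of_cds_position(3).__class__(1, 3)
        assert codon_of_cds_position(4).codon == 2

    def test_c346_348_single_codon_inframe(self):
        res = inframe_check(346, 348)
        assert res.kind == "inframe_single_codon"
        assert res.n_codons_removed == 1
        assert res.codon_start == res.codon_end == 116

    def test_two_base_deletion_frameshifts(self):
        assert inframe_check(346, 347).kind == "frameshift"

    def test_unaligned_six_base_deletion_spans_codons(self):
        res = inframe_check(344, 349)
        assert res.kind == "inframe_multi_codon"
        assert res.n_codons_removed == 2
        assert (res.codon_start, res.codon_end) == (115, 117)

    @given(stn.integers(min_value=1, max_value=10_000))
    def test_codon_offset_inverts(self, pos):
        cp = codon_of_cds_position(pos)
        assert (cp.codon - 1) * 3 + cp.offset == pos
        assert 1 <= cp.offset <= 3


class TestSpliceCv:
    @pytest.mark.parametrize(
        "wt_cv,mut_cv,expected",
        [(69.84, 36.0, 48.45), (50.0, 50.0, 0.0), (50.0, 0.0, 100.0)],
    )
    def test_percent_reduction(self, wt_cv, mut_cv, expected):
        assert splice_cv_reduction(wt_cv, mut_cv) == pytest.approx(expected, abs=0.005)

    def test_requires_positive_wt(self):
        with pytest.raises(ValueError):
            splice_cv_reduction(0.0, 1.0)


class TestHydropathyProfile:
    def test_window_one_returns_raw_scale_values(self):
        seq = ProteinSequence("rr", "RR")
        prof = hydropathy_profile(seq, "kd", window=1)
        assert prof.values.tolist() == [-4.5, -4.5]

    def test_window_three_matches_hand_moving_average(self):
        seq = ProteinSequence("p", "ARNDC")
        prof = hydropathy_profile(seq, "kd", window=3)
        kd = SCALES["kd"]
        vals = [kd[a] for a in "ARNDC"]
        expected = [
            (vals[0] + vals[1]) / 2,          # truncated left edge
            sum(vals[0:3]) / 3,
            sum(vals[1:4]) / 3,
            sum(vals[2:5]) / 3,
            (vals[3] + vals[4]) / 2,          # truncated right edge
        ]
        assert prof.values == pytest.approx(expected)

    def test_profile_bounded_by_scale_extremes(self, wt, rng):
        for window in (1, 5, 9, 16):
            prof = hydropathy_profile(wt, "kd", window)
            assert prof.values.min() >= -4.5 and prof.values.max() <= 4.5

    def test_kd_extremes_are_ile_and_arg(self):
        kd = SCALES["kd"]
        assert kd["I"] == 4.5 == max(kd.values())
        assert kd["R"] == -4.5 == min(kd.values())

    def test_L115R_lowers_any_window_mean_containing_115(self, wt):
        mut = apply_edit(wt, "L115R")
        for window in (1, 7, 11):
            pw = hydropathy_profile(wt, "kd", window)
            pm = hydropathy_profile(mut, "kd", window)
            back = (window - 1) // 2
            fwd = window - back - 1
            for i in range(115 - fwd, 115 + back + 1):
                assert pm.values[i - 1] < pw.values[i - 1]

    def test_segment_stats_constant_profile(self):
        seq = ProteinSequence("a", "AAAAAAAA")
        prof = hydropathy_profile(seq, "kd", 3)
        mean, sd = segment_stats(prof, 2, 7)
        assert mean == pytest.approx(1.8)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_segment_stats_matches_two_pass_oracle(self, wt, rng):
        prof = hydropathy_profile(wt, "kd", 9)
        lo, hi = 50, 90
        mean, sd = segment_stats(prof, lo, hi)
        seg = prof.values[lo - 1:hi]
        mu = sum(seg) / len(seg)
        var = sum((x - mu) ** 2 for x in seg) / (len(seg) - 1)
        assert mean == pytest.approx(mu) and sd == pytest.approx(math.sqrt(var))

    def test_calibration_recovers_recorded_convention(self, wt):
        conv = calibrate_profile_convention(wt)
        assert conv.window == RECORDED_WINDOW
        assert conv.segment == RECORDED_SEGMENT
        assert conv.rms < 0.005


class TestTransferEnergies:
    def test_tripeptide_hand_sum(self):
        seq = ProteinSequence("awl", "AWL")
        te = transfer_dG(seq, 1, 3, "ww_interface")
        assert te.total == pytest.approx(0.17 - 1.85 - 0.56)
        oc = transfer_dG(seq, 1, 3, "ww_octanol")
        assert oc.total == pytest.approx(0.50 - 2.09 - 1.25)

    def test_empty_segment_zero(self, wt):
        assert transfer_dG(wt, 10, 9).total == 0.0

    def test_total_equals_sum_of_contributions(self, wt):
        te = transfer_dG(wt, 108, 139)
        assert te.total == pytest.approx(sum(c for _, _, c in te.contributions))

    def test_additive_over_concatenation(self, wt):
        whole = transfer_dG(wt, 108, 139).total
        parts = transfer_dG(wt, 108, 120).total + transfer_dG(wt, 121, 139).total
        assert whole == pytest.approx(parts)

    def test_octanol_minus_interface_definitional(self, wt):
        lo, hi = 108, 139
        assert octanol_minus_interface(wt, lo, hi) == pytest.approx(
            transfer_dG(wt, lo, hi, "ww_octanol").total
            - transfer_dG(wt, lo, hi, "ww_interface").total
        )

    def test_deletion_renumbers_domains(self, wt):
        d116 = apply_edit(wt, "L116del")
        assert d116.domains["membrane_segment"] == (108, 138)
        assert d116.domains["cysteine_string"] == (113, 135)
        assert apply_edit(wt, "L115R").domains == wt.domains

    def test_membrane_avidity_ordering_of_mutants(self, wt):
        """WT binds best: interface dG(WT) < dG(L116del) < dG(L115R)."""
        r115 = apply_edit(wt, "L115R")
        d116 = apply_edit(wt, "L116del")
        dg = lambda s: transfer_dG(s, *s.domains["membrane_segment"], "ww_interface").total
        ddg = lambda s: octanol_minus_interface(s, *s.domains["membrane_segment"])
        assert dg(wt) < dg(d116) < dg(r115)
        assert ddg(wt) < ddg(d116) < ddg(r115)


class TestGroupComparison:
    def test_identical_groups_h_near_zero_nothing_significant(self):
        g = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0],
             "c": [1.0, 2.0, 3.0, 4.0]}
        res = compare_variant_profiles(g)
        assert res.h_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.significant_pairs() == []

    def test_h_matches_hand_rank_formula_without_ties(self):
        g = {"a": [1.0, 3.0, 5.0], "b": [2.0, 4.0, 6.0], "c": [7.0, 8.0, 9.0]}
        res = compare_variant_profiles(g)
        # ranks: a {1,3,5}, b {2,4,6}, c {7,8,9}; H = 12/(N(N+1)) sum ni Ri^2 - 3(N+1)
        r = {"a": 3.0, "b": 4.0, "c": 8.0}
        h = 12 / (9 * 10) * sum(3 * rr ** 2 for rr in r.values()) - 3 * 10
        assert res.h_statistic == pytest.approx(h)

    def test_clear_separation_flagged_by_dunn(self):
        g = {"lo": list(range(10)), "hi": [x + 100 for x in range(10)],
             "mid": [x + 50 for x in range(10)]}
        res = compare_variant_profiles(g)
        assert ("lo", "hi") in res.significant_pairs()

    def test_requires_two_groups_of_two(self):
        with pytest.raises(ValueError):
            compare_variant_profiles({"a": [1, 2]})
        with pytest.raises(ValueError):
            compare_variant_profiles({"a": [1, 2], "b": [3]})

    def test_mutant_profile_comparison_flags_L115R_only(self, wt):
        """The arginine substitution significantly lowers the hydropathy of the
        membrane-proximal segment; the single-leucine deletion does not."""
        lo, hi = RECORDED_SEGMENT
        groups = {}
        for name, seq in [
            ("wt", wt),
            ("L115R", apply_edit(wt, "L115R")),
            ("L116del", apply_edit(wt, "L116del")),
        ]:
            prof = hydropathy_profile(seq, "kd", RECORDED_WINDOW)
            groups[name] = prof.segment(lo, hi)
        res = compare_variant_profiles(groups)
        flagged = res.significant_pairs()
        assert ("wt", "L115R") in flagged
        assert ("wt", "L116del") not in flagged
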