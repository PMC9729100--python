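"""Cassette designer: guide placement, off-targets, WT', ssODNs, primers."""

import numpy as np
import pytest

from crisprselect import (
    DesignConfig,
    DesignError,
    ReferenceLocus,
    VariantSpec,
    build_ssodn,
    design_primers,
    design_wtprime,
    enumerate_guides,
    reverse_complement,
    screen_offtargets,
    translate_coding,
)
from crisprselect.design import _classify_position, _scan_sites
from crisprselect.fixtures import random_locus


def _locus_without_pam(length=60):
    # alternating AT carries no GG/CC on either strand
    return ReferenceLocus("nopam", "AT" * (length // 2))


class TestEnumerateGuides:
    def test_no_pam_returns_empty(self):
        locus = _locus_without_pam()
        variant = VariantSpec(30, locus.sequence[30], "C" if locus.sequence[30] != "C" else "G")
        assert enumerate_guides(locus, variant) == []

    def test_short_locus_raises(self):
        locus = ReferenceLocus("short", "ACGT" * 10)  # 40 nt
        with pytest.raises(DesignError):
            enumerate_guides(locus, VariantSpec(20, locus.sequence[20], "A" if locus.sequence[20] != "A" else "C"))

    def test_single_constructed_site_seed_offset(self):
        # 80-nt AT background with one embedded protospacer+PAM; variant
        # 2 nt from the PAM-proximal protospacer end.
        proto = "ATATATATATATATATATAT"
        seq = "AT" * 15 + proto + "AGG" + "AT" * 14 + "A"
        locus = ReferenceLocus("one", seq)
        var_pos = 30 + 18  # protospacer position 19 -> seed offset 2
        variant = VariantSpec(var_pos, seq[var_pos], "C")
        guides = enumerate_guides(locus, variant)
        assert len(guides) == 1
        g = guides[0]
        assert g.strand == "+"
        assert g.disruption_positions[var_pos] == 2
        assert g.cut_position == 30 + 17

    def test_variant_beyond_seed_rejected(self):
        proto = "ATATATATATATATATATAT"
        seq = "AT" * 15 + proto + "AGG" + "AT" * 14 + "A"
        locus = ReferenceLocus("one", seq)
        var_pos = 30 + 8  # protospacer position 9 -> seed offset 12 > 10
        variant = VariantSpec(var_pos, seq[var_pos], "C")
        assert enumerate_guides(locus, variant) == []

    def test_sorted_by_distance_to_cut(self, design_battery):
        for locus, variant, _ in design_battery[:5]:
            guides = enumerate_guides(locus, variant)
            dists = [abs(g.variant_distance_to_cut) for g in guides]
            assert dists == sorted(dists)

    def test_every_guide_disrupted_in_pam_or_seed(self, design_battery):
        for locus, variant, _ in design_battery:
            for g in enumerate_guides(locus, variant):
                assert all(
                    v == "PAM" or 1 <= v <= 10
                    for v in g.disruption_positions.values()
                )


def _naive_offtarget_scan(protospacer, sequences, max_mm):
    """Brute-force sliding-window mismatch counter (independent oracle)."""
    hits = []
    for ref_id, seq in sequences.items():
        seq = seq.upper()
        for i in range(len(seq) - 22):
            # plus strand
            if seq[i + 21 : i + 23] == "GG":
                window = seq[i : i + 20]
                mm = [20 - j for j in range(20) if window[j] != protospacer[j]]
                if len(mm) <= max_mm:
                    hits.append((ref_id, i, "+", len(mm), tuple(mm)))
            if seq[i : i + 2] == "CC":
                window = reverse_complement(seq[i + 3 : i + 23])
                mm = [20 - j for j in range(20) if window[j] != protospacer[j]]
                if len(mm) <= max_mm:
                    hits.append((ref_id, i, "-", len(mm), tuple(mm)))
    return hits


class TestOffTargets:
    def test_on_target_only_passes(self, one_cassette):
        locus, _, cassette = one_cassette
        report = screen_offtargets(cassette.guide, {locus.locus_id: locus.sequence})
        for h in report.hits:
            assert h.mismatch_count > 0

    def test_seed_mismatch_decoy_passes(self, one_cassette):
        locus, _, cassette = one_cassette
        g = cassette.guide
        site = list(g.protospacer)
        site[15] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[15]]  # seed offset 5
        decoy = "TTTT" + "".join(site) + "TGG" + "TTTT"
        report = screen_offtargets(g, {"decoy": decoy})
        assert report.passes
        decoy_hits = [h for h in report.hits if h.reference_id == "decoy"]
        assert len(decoy_hits) == 1 and decoy_hits[0].mismatch_count == 1

    def test_pam_distal_mismatches_fail(self, one_cassette):
        _, _, cassette = one_cassette
        g = cassette.guide
        site = list(g.protospacer)
        for idx in (2, 5):  # seed offsets 18 and 15: PAM-distal
            site[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[idx]]
        decoy = "TTTT" + "".join(site) + "TGG" + "TTTT"
        report = screen_offtargets(g, {"decoy": decoy})
        assert not report.passes

    def test_agrees_with_naive_scan(self, design_battery):
        rng = np.random.default_rng(3)
        for locus, _, cassette in design_battery[:5]:
            decoys = {
                "bg": "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
            }
            report = screen_offtargets(cassette.guide, decoys, max_mismatches=3)
            expected = _naive_offtarget_scan(cassette.guide.protospacer, decoys, 3)
            got = {(h.reference_id, h.position, h.strand, h.mismatch_count) for h in report.hits}
            assert got == {(r, p, s, m) for r, p, s, m, _ in expected}


class TestDesignWtprime:
    def test_candidates_are_synonymous_and_near(self, design_battery):
        for locus, variant, cassette in design_battery:
            wt = translate_coding(locus)
            cands, _ = design_wtprime(locus, variant, cassette.guide)
            assert cands, "battery fixtures must admit a WT'"
            for c in cands:
                from crisprselect import apply_edit

                assert translate_coding(locus, apply_edit(locus, c)) == wt
                assert abs(c.position - variant.position) <= 3

    def test_met_codon_has_no_synonymous_option(self):
        # coding = ATG ATG ATG ...: every codon is Met (single-codon family),
        # so no synonymous substitution exists anywhere in the window.
        seq = "AT" * 12 + "ATG" * 12 + "TAT" + "AGG" + "AT" * 12
        locus = ReferenceLocus("met", seq, coding_segments=((24, 60, 0),))
        variant = VariantSpec(40, seq[40], "C" if seq[40] != "C" else "A")
        guides = enumerate_guides(locus, variant)
        if guides:
            cands, rejections = design_wtprime(locus, variant, guides[0])
            assert cands == []
            assert any("not synonymous" in r for r in rejections.values())

    def test_ranked_by_distance_first(self, design_battery):
        locus, variant, cassette = design_battery[1]
        cands, _ = design_wtprime(locus, variant, cassette.guide)
        dists = [
            0 if c.position == variant.position else abs(c.position - variant.position)
            for c in cands
        ]
        assert dists == sorted(dists)

    def test_rare_codon_rejection_reason_reported(self, design_battery):
        cfg = DesignConfig(rare_codon_threshold=1000.0)  # everything is "rare"
        locus, variant, cassette = design_battery[0]
        cands, rejections = design_wtprime(locus, variant, cassette.guide, config=cfg)
        assert cands == []
        assert any("rare codon" in r for r in rejections.values())


class TestBuildSsodn:
    def test_snv_total_length_91(self, design_battery):
        for locus, variant, cassette in design_battery[:5]:
            ss = build_ssodn(locus, cassette.guide, variant)
            assert len(ss.sequence) == 45 + len(variant.alt_bases) + 45 == 91

    def test_polarity_rule_and_revcomp_consistency(self):
        locus = random_locus(5, length=400)
        guides_pos = 200
        # synthetic guide objects: place cut at 200 via a real enumeration
        variant_left = VariantSpec(190, locus.sequence[190], "A" if locus.sequence[190] != "A" else "C")
        variant_right = VariantSpec(210, locus.sequence[210], "A" if locus.sequence[210] != "A" else "C")
        from crisprselect.design import GuideCandidate

        guide = GuideCandidate(
            protospacer="A" * 20, pam="AGG", strand="+",
            site_start=183, cut_position=200, variant_distance_to_cut=-10,
        )
        left = build_ssodn(locus, guide, variant_left)
        right = build_ssodn(locus, guide, variant_right)
        assert left.polarity == "sense"
        assert right.polarity == "antisense"
        assert right.sequence == reverse_complement(right.sense_sequence)

    def test_edit_close_to_cut_defaults_sense(self):
        locus = random_locus(6, length=400)
        from crisprselect.design import GuideCandidate

        guide = GuideCandidate(
            protospacer="A" * 20, pam="AGG", strand="+",
            site_start=183, cut_position=200, variant_distance_to_cut=2,
        )
        variant = VariantSpec(201, locus.sequence[201], "A" if locus.sequence[201] != "A" else "C")
        assert build_ssodn(locus, guide, variant).polarity == "sense"

    def test_arms_out_of_bounds_raise(self):
        locus = random_locus(7, length=60)
        variant = VariantSpec(5, locus.sequence[5], "A" if locus.sequence[5] != "A" else "C")
        with pytest.raises(DesignError):
            build_ssodn(locus, None, variant)


class TestDesignPrimers:
    def test_constraints_hold_on_battery(self, design_battery):
        for _, _, cassette in design_battery:
            p = cassette.primers
            assert 40 <= p.forward_offset <= 120
            assert 40 <= p.reverse_offset <= 120
            assert 230 <= p.product_length <= 350
            assert 18 <= len(p.forward) <= 25
            assert 18 <= len(p.reverse) <= 25
            # primers anneal entirely outside the ssODN-covered region
            r0, r1 = cassette.ssodn_region
            assert p.forward_region[1] <= r0
            assert p.reverse_region[0] >= r1

    def test_too_short_locus_raises_offset_error(self):
        locus = random_locus(8, length=300)
        with pytest.raises(DesignError, match="offset window unsatisfiable"):
            design_primers(locus, (10, 120))  # only 10 nt left of the region

    def test_deterministic(self, design_battery):
        locus, _, cassette = design_battery[2]
        again = design_primers(locus, cassette.ssodn_region)
        assert again == cassette.primers


class TestAssembledCassettes:
    def test_templates_identical_except_edits(self, design_battery):
        for _, _, cassette in design_battery:
            assert cassette.templates_identical_except_edits()

    def test_wtprime_synonymous_invariant(self, design_battery):
        from crisprselect import apply_edit

        for locus, _, cassette in design_battery:
            assert translate_coding(locus, apply_edit(locus, cassette.wtprime_spec)) == translate_coding(locus)

    def test_design_report_all_pass(self, design_battery):
        for _, _, cassette in design_battery:
            assert all(ok for _, ok, _ in cassette.design_report)

    def test_variant_killing_only_pam_fails_at_guide_stage(self):
        from crisprselect import assemble_cassette

        locus = _locus_without_pam(80)
        variant = VariantSpec(40, locus.sequence[40], "C" if locus.sequence[40] != "C" else "G")
        with pytest.raises(DesignError) as err:
            assemble_cassette(locus, variant)
        assert err.value.stage == "guide"


class TestSiteGeometry:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_scan_and_classify_consistency(self, strand):
        rng = np.random.default_rng(11)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))
        for start, s in _scan_sites(seq):
            if s != strand:
                continue
            # PAM GG positions classify as PAM
            if s == "+":
                assert _classify_position(start + 21, start, s) == "PAM"
                assert _classify_position(start + 19, start, s) == 1
                assert _classify_position(start, start, s) == 20
            else:
                assert _classify_position(start, start, s) == "PAM"
                assert _classify_position(start + 3, start, s) == 1
                assert _classify_position(start + 22, start, s) == 20
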