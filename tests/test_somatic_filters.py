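"""Somatic filter criteria: detector thresholds, the four SNV screens
against the enumeration oracle, indel normalization and orchestration."""

import random

import pytest

from xenosift import (
    FilterThresholds,
    PutativeVariant,
    SimulationConfig,
    apply_all,
    call_somatic,
    detect_putative_snvs,
    filter_base_quality,
    filter_germline_contingency,
    filter_indel,
    filter_mapping_quality,
    filter_strand_bias,
    left_align_indel,
    simulate_cohort,
    simulate_pileups,
)
from xenosift.pileup import PileupSite
from xenosift.somatic_filters import (
    detect_putative_indels,
    germline_indels_from_pileup,
    homopolymer_run_length,
    write_vcf,
)

from conftest import fisher_two_sided_oracle


def make_variant(
    ref="A",
    alt="T",
    tumor_alt=(5, 5),
    tumor_ref=(10, 10),
    normal_alt=(0, 0),
    normal_ref=(15, 15),
    alt_bq=36,
    ref_bq=36,
    alt_mq=60,
    position=100,
):
    tumor = PileupSite("hs_chrT", position, ref)
    tumor.add(ref, fwd=tumor_ref[0], rev=tumor_ref[1], base_quality=ref_bq)
    if sum(tumor_alt):
        tumor.add(alt, fwd=tumor_alt[0], rev=tumor_alt[1],
                  base_quality=alt_bq, mapping_quality=alt_mq)
    normal = PileupSite("hs_chrT", position, ref)
    if sum(normal_ref):
        normal.add(ref, fwd=normal_ref[0], rev=normal_ref[1])
    if sum(normal_alt):
        normal.add(alt, fwd=normal_alt[0], rev=normal_alt[1])
    return PutativeVariant("hs_chrT", position, ref, alt, tumor, normal)


class TestDetector:
    def test_site_without_alt_reads_not_emitted(self, deep_cohort):
        config, _, truth, pileups = deep_cohort
        found = detect_putative_snvs(pileups["normal"], pileups["normal"],
                                     min_alt_reads=1, min_vaf=0.0)
        truth_keys = {(m.contig, m.position) for m in truth.mutations}
        # the normal carries no somatic alt evidence at true sites
        assert not [v for v in found if (v.contig, v.position) in truth_keys]

    def test_error_free_tumor_recovers_ledger_exactly(self):
        config = SimulationConfig(seed=31, purity_primary=1.0, depth=100.0,
                                  n_common=60, n_primary_only=0, n_pdx_only=0)
        _, truth = simulate_cohort(config)
        pileups = simulate_pileups(truth, config)
        found = detect_putative_snvs(pileups["primary"], pileups["normal"])
        assert {v.key for v in found} == {
            (m.contig, m.position, m.ref, m.alt) for m in truth.mutations
        }

    def test_single_read_boundary(self):
        v = make_variant(tumor_alt=(1, 0), tumor_ref=(5, 5))
        tumor = {v.tumor.key: v.tumor}
        normal = {v.normal.key: v.normal}
        assert detect_putative_snvs(tumor, normal, min_alt_reads=1, min_vaf=0.0)
        assert not detect_putative_snvs(tumor, normal, min_alt_reads=2, min_vaf=0.0)

    def test_mismatched_loci_is_hard_error(self):
        v = make_variant()
        with pytest.raises(ValueError, match="different loci"):
            detect_putative_snvs({v.tumor.key: v.tumor}, {})


class TestGermlineContingency:
    def test_no_normal_evidence_passes(self):
        v = make_variant(tumor_alt=(6, 6), tumor_ref=(9, 9), normal_alt=(0, 0))
        assert filter_germline_contingency(v).passed

    def test_similar_proportions_fail_with_oracle_pvalue(self):
        v = make_variant(tumor_alt=(3, 2), tumor_ref=(8, 7),
                         normal_alt=(2, 2), normal_ref=(8, 8))
        rec = filter_germline_contingency(v, alpha=0.05)
        assert not rec.passed
        assert rec.p_value == pytest.approx(
            fisher_two_sided_oracle(5, 15, 4, 16), abs=1e-10
        )

    def test_identical_proportions_fail_with_p_one(self):
        v = make_variant(tumor_alt=(25, 25), tumor_ref=(25, 25),
                         normal_alt=(25, 25), normal_ref=(25, 25))
        rec = filter_germline_contingency(v)
        assert not rec.passed and rec.p_value == pytest.approx(1.0)

    def test_normal_enrichment_fails_even_when_significant(self):
        v = make_variant(tumor_alt=(1, 1), tumor_ref=(30, 30),
                         normal_alt=(20, 20), normal_ref=(10, 10))
        rec = filter_germline_contingency(v)
        assert rec.p_value < 0.05 and not rec.passed

    def test_zero_coverage_not_assessable(self):
        v = make_variant(normal_alt=(0, 0), normal_ref=(0, 0))
        rec = filter_germline_contingency(v)
        assert not rec.passed and not rec.assessable


class TestStrandBias:
    def test_one_sided_significant_fails(self):
        v = make_variant(tumor_alt=(10, 0), tumor_ref=(50, 50))
        rec = filter_strand_bias(v, alpha=0.05)
        assert not rec.passed
        assert rec.p_value == pytest.approx(
            fisher_two_sided_oracle(10, 0, 50, 50), abs=1e-10
        )
        assert rec.p_value < 0.05

    def test_balanced_alt_passes_regardless_of_ref_split(self):
        v = make_variant(tumor_alt=(5, 5), tumor_ref=(40, 0))
        assert filter_strand_bias(v).passed

    def test_single_alt_read_not_significant(self):
        v = make_variant(tumor_alt=(1, 0), tumor_ref=(1, 1))
        rec = filter_strand_bias(v)
        assert rec.passed
        assert rec.p_value == pytest.approx(
            fisher_two_sided_oracle(1, 0, 1, 1), abs=1e-10
        )


class TestBaseQuality:
    def test_extreme_separation_fails(self):
        v = make_variant(tumor_alt=(8, 8), alt_bq=10, ref_bq=35)
        assert not filter_base_quality(v, delta_bq=10).passed

    def test_identical_quality_lists_pass(self):
        v = make_variant(tumor_alt=(8, 8), alt_bq=35, ref_bq=35)
        assert filter_base_quality(v).passed

    def test_insufficient_observations_pass_flagged(self):
        v = make_variant(tumor_alt=(1, 0))
        rec = filter_base_quality(v)
        assert rec.passed and rec.review


class TestMappingQuality:
    @pytest.mark.parametrize(
        "alt_mq, min_mq, expected",
        [(0, 20, False), (60, 20, True), (20, 20, True), (19, 20, False)],
    )
    def test_mean_mq_threshold(self, alt_mq, min_mq, expected):
        v = make_variant(tumor_alt=(2, 1), alt_mq=alt_mq)
        assert filter_mapping_quality(v, min_mean_mq=min_mq).passed is expected


class TestIndel:
    REF = "ACGTACGT" + "A" * 8 + "CGTACGTACGTACGTACG"

    def _indel_variant(self, position, alt, ref_base):
        tumor = PileupSite("hs_chrT", position, ref_base)
        tumor.add(ref_base, fwd=20, rev=20)
        tumor.add(alt, fwd=5, rev=5)
        normal = PileupSite("hs_chrT", position, ref_base)
        normal.add(ref_base, fwd=30, rev=30)
        return PutativeVariant("hs_chrT", position, ref_base, alt, tumor, normal)

    def test_deletion_in_long_homopolymer_fails(self):
        # run of 8 As starts at 1-based position 9; deletion anchored before it
        v = self._indel_variant(8, "-A", self.REF[7])
        rec = filter_indel(v, self.REF, max_homopolymer=6)
        assert not rec.passed and rec.statistic == 8.0

    def test_proximal_germline_indel_fails(self):
        v = self._indel_variant(30, "-T", self.REF[29])
        rec = filter_indel(v, self.REF, germline_indels={("hs_chrT", 27)},
                           germline_window=25)
        assert not rec.passed

    def test_isolated_indel_passes(self):
        v = self._indel_variant(4, "-A", self.REF[3])
        assert filter_indel(v, self.REF, max_homopolymer=6).passed

    def test_left_and_right_aligned_encodings_agree(self):
        # deleting any single A of the run is the same left-aligned event
        left = left_align_indel(self.REF, 8, "-A")
        right = left_align_indel(self.REF, 15, "-A")
        assert left == right
        v_l = self._indel_variant(8, "-A", self.REF[7])
        v_r = self._indel_variant(15, "-A", self.REF[14])
        rec_l = filter_indel(v_l, self.REF)
        rec_r = filter_indel(v_r, self.REF)
        assert rec_l.passed == rec_r.passed == False  # noqa: E712

    def test_left_alignment_is_idempotent(self):
        pos, alt = left_align_indel(self.REF, 12, "-A")
        assert left_align_indel(self.REF, pos, alt) == (pos, alt)

    def test_insertion_left_alignment(self):
        # inserting an A anywhere inside the run normalizes to the run start
        pos_a, alt_a = left_align_indel(self.REF, 12, "+A")
        pos_b, alt_b = left_align_indel(self.REF, 16, "+A")
        assert (pos_a, alt_a) == (pos_b, alt_b)
        assert alt_a == "+A" and pos_a == 8

    def test_homopolymer_run_length_clips_at_ends(self):
        assert homopolymer_run_length("AAAA", 0) == 4
        assert homopolymer_run_length("AAAA", 3) == 4
        assert homopolymer_run_length("CAAAC", 2) == 3


class TestApplyAll:
    def test_empty_input(self):
        kept, verdicts, tally = apply_all([])
        assert kept == [] and verdicts == [] and not tally

    def test_order_invariance(self):
        variants = [
            make_variant(position=p, tumor_alt=(a, a), normal_alt=(n, n))
            for p, a, n in [(10, 5, 0), (20, 6, 4), (30, 8, 0), (40, 3, 3)]
        ]
        kept1, verd1, _ = apply_all(variants)
        shuffled = variants[::-1]
        kept2, verd2, _ = apply_all(shuffled)
        assert {v.key for v in kept1} == {v.key for v in kept2}
        by_key1 = {v.variant.key: v.kept for v in verd1}
        by_key2 = {v.variant.key: v.kept for v in verd2}
        assert by_key1 == by_key2

    def test_relaxing_strand_alpha_never_rejects_kept_variant(self):
        variants = [
            make_variant(position=p, tumor_alt=(a, 0), tumor_ref=(r, r))
            for p, a, r in [(1, 4, 30), (2, 8, 30), (3, 2, 5), (4, 12, 40)]
        ]
        kept_strict = {
            v.key for v in apply_all(variants, FilterThresholds(alpha=0.05))[0]
        }
        kept_loose = {
            v.key for v in apply_all(variants, FilterThresholds(alpha=0.20))[0]
        }
        assert kept_loose <= kept_strict  # larger alpha rejects more, never fewer

    def test_raising_min_mq_never_keeps_rejected_variant(self):
        variants = [
            make_variant(position=p, tumor_alt=(4, 4), alt_mq=mq)
            for p, mq in [(1, 10), (2, 25), (3, 40), (4, 60)]
        ]
        kept_low = {v.key for v in apply_all(variants, FilterThresholds(min_mean_mq=20))[0]}
        kept_high = {v.key for v in apply_all(variants, FilterThresholds(min_mean_mq=30))[0]}
        assert kept_high <= kept_low

    def test_all_artifact_input_rejected(self):
        config = SimulationConfig(
            seed=33, n_common=0, n_primary_only=0, n_pdx_only=0, depth=150.0,
            artifact_spec={"germline_leak": 8, "strand_bias": 8,
                           "low_bq": 8, "low_mq": 8},
        )
        refs, truth = simulate_cohort(config)
        pileups = simulate_pileups(truth, config)
        kept, _, tally = call_somatic(pileups["primary"], pileups["normal"],
                                      reference=refs.human)
        assert kept == []
        assert sum(tally.values()) == len(truth.mutations)

    def test_indel_detection_and_filtering(self):
        config = SimulationConfig(
            seed=35, n_common=5, depth=150.0,
            artifact_spec={"homopolymer_indel": 3},
        )
        refs, truth = simulate_cohort(config)
        pileups = simulate_pileups(truth, config)
        indels = detect_putative_indels(pileups["primary"], pileups["normal"])
        assert len(indels) == 3
        germline = germline_indels_from_pileup(pileups["normal"])
        _, verdicts, tally = apply_all(indels, reference=refs.human,
                                       germline_indels=germline)
        assert tally["indel_realignment"] == 3

    def test_vcf_output_tags(self, tmp_path):
        variants = [
            make_variant(position=10, tumor_alt=(6, 6)),           # PASS
            make_variant(position=20, tumor_alt=(10, 0), tumor_ref=(50, 50)),
        ]
        _, verdicts, _ = apply_all(variants)
        out = tmp_path / "out.vcf"
        write_vcf(verdicts, out, {"hs_chrT": 1000})
        text = out.read_text()
        assert "##fileformat=VCFv4.2" in text
        body = [l for l in text.splitlines() if not l.startswith("#")]
        filters = [l.split("\t")[6] for l in body]
        assert filters == ["PASS", "STRAND"]
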