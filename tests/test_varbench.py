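"""Haplotype alignment, variant calling, and benchmark metric formulas."""

import math

import numpy as np
import pytest

from dipeval import synthio, varbench
from dipeval.varbench import BenchmarkCounts, VariantRecord

from conftest import random_dna


class TestAlignHaplotype:
    def test_identical_sequences_single_match_block(self, rng):
        ref = {"c": random_dna(rng, 20_000)}
        alns, un = varbench.align_haplotype(ref, ref)
        assert not un
        assert alns[0].ops == [("=", 20_000)]

    def test_single_insertion_recovered_as_one_op(self, rng):
        seq = random_dna(rng, 20_000)
        ins = random_dna(rng, 100)
        q = seq[:10_000] + ins + seq[10_000:]
        alns, _ = varbench.align_haplotype({"q": q}, {"c": seq})
        non_match = [(o, n) for o, n in alns[0].ops if o != "="]
        assert non_match == [("I", 100)]

    def test_unanchorable_contig_reported(self, rng):
        ref = {"c": random_dna(rng, 5_000)}
        other = {"q": random_dna(np.random.default_rng(999), 5_000)}
        alns, un = varbench.align_haplotype(other, ref)
        # a random 5-kb pair shares no unique 31-mers: reported unaligned
        assert un == ["q"] and not alns


class TestLeftNormalize:
    def test_indel_shifts_through_repeat_run(self):
        #      0123456789
        ref = "GCAAAATTGC"
        # deleting one A anywhere in the run normalizes to position 1
        pos, r, a = varbench.left_normalize(4, "AA", "A", ref)
        assert (pos, r, a) == (1, "CA", "C")

    def test_snv_untouched(self):
        assert varbench.left_normalize(3, "G", "T", "AAAGAAA") == (3, "G", "T")

    def test_parsimony_trims_shared_context(self):
        pos, r, a = varbench.left_normalize(2, "CAT", "CGT", "AACATAA")
        assert (pos, r, a) == (3, "A", "G")


class TestCallVariants:
    def test_het_snv_phased_by_haplotype_order(self, rng):
        ref = {"c": random_dna(rng, 20_000)}
        seq = ref["c"]
        alt = "A" if seq[9_000] != "A" else "G"
        h1 = {"h1": seq[:9_000] + alt + seq[9_001:]}
        h2 = {"h2": seq}
        a1, _ = varbench.align_haplotype(h1, ref)
        a2, _ = varbench.align_haplotype(h2, ref)
        recs, conf = varbench.call_variants(a1, a2, ref, h1, h2)
        (rec,) = recs
        assert (rec.pos, rec.ref, rec.alts) == (9_000, seq[9_000], (alt,))
        assert rec.gt == "1|0" and rec.filter == "PASS"

    def test_single_haplotype_coverage_promoted_to_gap2(self, rng):
        ref = {"c": random_dna(rng, 30_000)}
        seq = ref["c"]
        alt = "A" if seq[5_000] != "A" else "G"
        h1 = {"h1": seq[:5_000] + alt + seq[5_001:15_000]}  # covers first half only
        h2 = {"h2": seq[15_000:]}  # covers second half only
        a1, _ = varbench.align_haplotype(h1, ref)
        a2, _ = varbench.align_haplotype(h2, ref)
        a1[0].ref_start, a1[0].ref_end = 0, 15_000
        a2[0].ref_start, a2[0].ref_end = 15_000, 30_000
        recs, conf = varbench.call_variants(a1, a2, ref, h1, h2)
        gap2 = [r for r in recs if r.filter == "GAP2"]
        assert gap2 and all(r.gt == "1|1" for r in gap2)
        assert any(r.pos == 5_000 for r in gap2)

    def test_round_trip_equals_truth_vcf(self, small_trio):
        t = small_trio
        ref = t.ancestor
        a1, _ = varbench.align_haplotype(t.child_pat, ref)
        a2, _ = varbench.align_haplotype(t.child_mat, ref)
        recs, conf = varbench.call_variants(a1, a2, ref, t.child_pat, t.child_mat)
        truth = synthio.child_truth_vcf(t)
        assert [(r.key(), r.gt) for r in recs] == [(r.key(), r.gt) for r in truth]


class TestCompare:
    CONF = {"c": [(0, 100_000)]}

    def _rec(self, pos, ref="A", alt="T", gt="0|1"):
        return VariantRecord("c", pos, ref, (alt,), gt)

    def test_identical_sets_all_tp(self):
        recs = [self._rec(10), self._rec(20, "AC", "A", "1|1")]
        c = varbench.compare_to_truth(recs, recs, self.CONF)
        assert c.snp_truth_tp == c.snp_truth_total == 1
        assert c.indel_truth_tp == c.indel_truth_total == 1
        assert c.snp_query_fp == c.indel_query_fp == 0
        assert varbench.f1_score(c) == 1.0

    def test_genotype_flip_counts_as_fp_gt(self):
        truth = [self._rec(10, gt="0|1")]
        query = [self._rec(10, gt="1|1")]
        c = varbench.compare_to_truth(query, truth, self.CONF)
        assert c.snp_fp_gt == 1 and c.snp_truth_tp == 0
        m = varbench.benchmark_metrics(c)
        assert m["SNP.Recall_ignoreGT"] == 1.0 and m["SNP.Recall"] == 0.0

    def test_counts_match_per_site_oracle(self, rng):
        truth = [self._rec(int(p), gt="0|1") for p in sorted(rng.choice(5000, 50, replace=False))]
        query = []
        flip = set(rng.choice(50, 10, replace=False))
        drop = set(rng.choice(50, 5, replace=False)) - flip
        for i, r in enumerate(truth):
            if i in drop:
                continue
            query.append(self._rec(r.pos, gt="1|1") if i in flip else r)
        novel = [self._rec(int(p) + 6000) for p in sorted(rng.choice(1000, 7, replace=False))]
        query = sorted(query + novel, key=lambda r: r.pos)
        c = varbench.compare_to_truth(query, truth, {"c": [(0, 10_000)]})
        assert c.snp_truth_total == 50
        assert c.snp_fp_gt == len(flip)
        assert c.snp_truth_tp == 50 - len(flip) - len(drop)
        assert c.snp_query_fp == len(flip) + len(novel)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            varbench.compare_to_truth(
                [self._rec(20), self._rec(10)], [self._rec(10)], self.CONF
            )

    def test_outside_confident_regions_ignored(self):
        truth = [self._rec(10)]
        query = [self._rec(10), self._rec(99_999_0)]
        c = varbench.compare_to_truth(query, truth, self.CONF)
        assert c.snp_query_fp == 0 and c.snp_truth_tp == 1


class TestMetrics:
    def test_recall_formulas(self):
        c = BenchmarkCounts(snp_truth_tp=90, snp_truth_total=100, snp_fp_gt=5,
                            snp_query_fp=5, conf_size=1_000_000)
        m = varbench.benchmark_metrics(c)
        assert m["SNP.Recall_ignoreGT"] == pytest.approx(0.95)
        assert m["SNP.Recall"] == pytest.approx(0.90)

    def test_qv_dip_closed_form(self):
        c = BenchmarkCounts(snp_query_fp=1, indel_query_fp=1, conf_size=1_000_000)
        m = varbench.benchmark_metrics(c)
        assert m["QV_dip_snp_indel"] == pytest.approx(
            -10 * math.log10(2 / (2 * 1_000_000))
        )
        assert m["QV_dip_snp_indel"] == pytest.approx(60.0)

    def test_zero_fp_infinite_sentinel(self):
        c = BenchmarkCounts(conf_size=1000)
        m = varbench.benchmark_metrics(c)
        assert m["QV_dip_infinite"] == 1.0

    def test_log_linearity_in_fp_count(self):
        qs = []
        for fp in (2, 20, 200):
            c = BenchmarkCounts(snp_query_fp=fp, conf_size=1_000_000)
            qs.append(varbench.benchmark_metrics(c)["QV_dip_snp_indel"])
        assert qs[0] - qs[1] == pytest.approx(10.0)
        assert qs[1] - qs[2] == pytest.approx(10.0)

    def test_recall_ignoregt_dominates_recall(self, rng):
        for _ in range(20):
            tp = int(rng.integers(0, 50))
            gt = int(rng.integers(0, 20))
            c = BenchmarkCounts(snp_truth_tp=tp, snp_fp_gt=gt,
                                snp_truth_total=tp + gt + int(rng.integers(0, 30)) + 1,
                                conf_size=1000)
            m = varbench.benchmark_metrics(c)
            assert m["SNP.Recall_ignoreGT"] >= m["SNP.Recall"]
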