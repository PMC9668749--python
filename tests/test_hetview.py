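"""Haplotype diversity catalogs, coding effects, heteroplasmy."""

import numpy as np
import pytest

from dipeval import hetview
from dipeval._codes import revcomp
from dipeval.hetview import HetRecord

from conftest import random_dna


class TestHapVsHap:
    def test_identical_haplotypes_empty_catalog(self, rng):
        h = {"c": random_dna(rng, 30_000)}
        assert len(hetview.hap_vs_hap(h, dict(h))) == 0

    def test_49bp_and_50bp_deletions_classified_across_boundary(self, rng):
        base = random_dna(rng, 60_000)
        h2 = {"c": base}
        h1seq = base[:20_000] + base[20_049:]  # 49-bp deletion
        h1seq = h1seq[:40_000] + h1seq[40_050:]  # 50-bp deletion
        catalog = hetview.hap_vs_hap({"c": h1seq}, h2)
        assert len(catalog.small_indels) == 1
        assert catalog.small_indels[0].affected_bp == 49
        assert len(catalog.svs) == 1
        assert catalog.svs[0].affected_bp == 50

    def test_implanted_features_recovered_exactly(self, rng):
        base = random_dna(rng, 100_000)
        h2 = {"c": base}
        # SNV at 10k, 10-bp del at 30k, 80-bp ins at 50k, 200-bp inversion at 70k
        snv_alt = "A" if base[10_000] != "A" else "C"
        ins = random_dna(rng, 80)
        inv = revcomp(base[70_000:70_200])
        h1seq = (
            base[:10_000] + snv_alt + base[10_001:30_000] + base[30_010:50_000]
            + ins + base[50_000:70_000] + inv + base[70_200:]
        )
        catalog = hetview.hap_vs_hap({"c": h1seq}, h2)
        assert [(r.pos, r.alt) for r in catalog.snvs] == [(10_000, snv_alt)]
        assert len(catalog.small_indels) == 1 and catalog.small_indels[0].vclass == "DEL"
        sv_classes = sorted(r.vclass for r in catalog.svs)
        assert sv_classes == ["INS", "INV"]
        inv_rec = next(r for r in catalog.svs if r.vclass == "INV")
        # chance base matches at the inversion's edges may trim the span
        assert abs(inv_rec.pos - 70_000) <= 5
        assert abs(len(inv_rec.ref) - 200) <= 10

    def test_gap_majority_feature_excluded(self, rng):
        base = random_dna(rng, 40_000)
        h2 = {"c": base}
        h1seq = base[:20_000] + "N" * 120 + base[20_000:]  # mostly-N insertion
        catalog = hetview.hap_vs_hap({"c": h1seq}, h2)
        assert not catalog.svs

    def test_swap_inverts_polarity_preserves_totals(self, rng):
        base = random_dna(rng, 50_000)
        h2 = {"c": base}
        h1seq = base[:25_000] + random_dna(rng, 70) + base[25_000:]
        a = hetview.hap_vs_hap({"c": h1seq}, h2)
        b = hetview.hap_vs_hap(h2, {"c": h1seq})
        assert len(a) == len(b)
        assert [r.vclass for r in a.svs] == ["INS"]
        assert [r.vclass for r in b.svs] == ["DEL"]


class TestWindowDensity:
    def test_single_variant_first_window(self):
        cat = hetview.HetCatalog(snvs=[HetRecord("c", 0, "A", "T", "SNV")])
        tracks = hetview.window_density(cat, {"c": 1_000_000}, snv_window=500_000)
        assert tracks["c"]["snv"].tolist() == [1, 0]

    def test_counts_match_brute_force(self, rng):
        pos = sorted(int(p) for p in rng.integers(0, 2_000_000, size=300))
        cat = hetview.HetCatalog(snvs=[HetRecord("c", p, "A", "T", "SNV") for p in pos])
        tracks = hetview.window_density(cat, {"c": 2_000_000}, snv_window=500_000)
        expect = [sum(w * 500_000 <= p < (w + 1) * 500_000 for p in pos) for w in range(4)]
        assert tracks["c"]["snv"].tolist() == expect

    def test_truncated_last_window_percentage_uses_true_span(self):
        cat = hetview.HetCatalog(snvs=[HetRecord("c", 1_200_000, "A", "T", "SNV")])
        tracks = hetview.window_density(cat, {"c": 1_250_000}, snv_window=500_000)
        assert tracks["c"]["snv_pct"][2] == pytest.approx(100.0 / 250_000)


class TestClassifyCoding:
    def _setup(self, cds="ATGGGATAA", strand="+"):
        ref = {"c": "TTTT" + cds + "TTTT"}
        ann = [("c", 4, 4 + len(cds), "gene1", strand)]
        return ref, ann

    def test_synonymous_third_position(self):
        ref, ann = self._setup()
        # GGA -> GGG, both glycine (positions 4..12; codon 2 third base at 9)
        snv = HetRecord("c", 9, "A", "G", "SNV")
        summary = hetview.classify_coding([snv], ann, ref)
        assert [e.effect for e in summary.effects] == ["synonymous"]

    def test_non_synonymous_second_codon(self):
        ref, ann = self._setup()
        # GGA -> GAA: Gly -> Glu
        snv = HetRecord("c", 8, "G", "A", "SNV")
        summary = hetview.classify_coding([snv], ann, ref)
        assert [e.effect for e in summary.effects] == ["non-synonymous"]

    def test_minus_strand_gene(self):
        cds = revcomp("ATGGGATAA")
        ref = {"c": "TTTT" + cds + "TTTT"}
        ann = [("c", 4, 13, "gene1", "-")]
        # third base of GGA codon on the minus strand
        pos = 4 + (len(cds) - 1 - 5)
        snv = HetRecord("c", pos, ref["c"][pos], revcomp("G"), "SNV")
        summary = hetview.classify_coding([snv], ann, ref)
        assert [e.effect for e in summary.effects] == ["synonymous"]

    def test_frame_broken_gene_skipped(self):
        ref = {"c": "TTTTATGGGATAATTTT"}
        ann = [("c", 4, 12, "broken", "+")]  # length 8, not divisible by 3
        summary = hetview.classify_coding([], ann, ref)
        assert summary.skipped_genes == ["broken"]

    def test_percentages_sum_to_hundred_within_rounding(self, rng):
        for _ in range(30):
            n_syn = int(rng.integers(1, 10_000))
            n_non = int(rng.integers(1, 10_000))
            a, b = hetview.coding_percentages(n_syn, n_non)
            assert 99.9 <= a + b <= 100.1

    def test_exclusively_non_synonymous_gene_rollup(self):
        ref = {"c": "TTTT" + "ATGGGAGGATAA" + "TTTT"}
        ann = [("c", 4, 16, "g1", "+")]
        snvs = [HetRecord("c", 8, "G", "A", "SNV"),  # non-syn
                HetRecord("c", 12, "A", "G", "SNV")]  # syn (GGA->GGG)
        summary = hetview.classify_coding(snvs, ann, ref)
        assert "g1" not in summary.genes_exclusively_non_synonymous
        only_non = hetview.classify_coding(snvs[:1], ann, ref)
        assert "g1" in only_non.genes_exclusively_non_synonymous


class TestHetSummary:
    def test_empty_catalog_zero_percent(self):
        s = hetview.het_summary(hetview.HetCatalog(), genome_bp=1_000_000)
        assert s.pct == 0.0

    def test_single_insertion_arithmetic(self):
        ins = HetRecord("c", 50_000, "A", "A" + "G" * 1000, "INS")
        s = hetview.het_summary(hetview.HetCatalog(svs=[ins]), genome_bp=100_000)
        assert s.pct == pytest.approx(1.0)

    def test_matches_brute_force_bp_tally(self, rng):
        records = []
        for p in sorted(int(x) for x in rng.integers(0, 900_000, size=40)):
            records.append(HetRecord("c", p, "A", "T", "SNV"))
        svs = [HetRecord("c", 950_000, "A", "A" + "C" * 500, "INS")]
        cat = hetview.HetCatalog(snvs=records, svs=svs)
        s = hetview.het_summary(cat, genome_bp=1_000_000)
        assert s.het_bp == 40 + 500

    def test_exclusion_bed_subtracts_both_sides(self):
        snvs = [HetRecord("c", p, "A", "T", "SNV") for p in range(0, 100_000, 1000)]
        cat = hetview.HetCatalog(snvs=snvs)
        full = hetview.het_summary(cat, genome_bp=1_000_000)
        excl = hetview.het_summary(cat, 1_000_000, exclude={"c": [(0, 50_000)]})
        assert excl.het_bp == 50
        assert excl.genome_bp == 950_000

    def test_oversized_exclusion_rejected(self):
        with pytest.raises(ValueError):
            hetview.het_summary(hetview.HetCatalog(), 1000, exclude={"c": [(0, 2000)]})


class TestHeteroplasmy:
    def test_printed_mt_example_rounds_to_two_percent(self):
        sites = {100: {"T": (4186, 3847), "C": (94, 108)}}
        alleles = hetview.heteroplasmy(sites)
        minor = next(a for a in alleles if not a.is_major)
        assert minor.base == "C" and minor.count == 202
        assert (minor.plus, minor.minus) == (94, 108)
        assert minor.pct == 2

    def test_balanced_site_reports_both(self):
        alleles = hetview.heteroplasmy({5: {"A": 50, "G": 50}})
        assert {a.base for a in alleles} == {"A", "G"}

    def test_exactly_one_percent_not_reported(self):
        alleles = hetview.heteroplasmy({5: {"A": 990, "G": 10}})
        assert [a.base for a in alleles] == ["A"]  # strict > threshold

    def test_zero_coverage_site_skipped(self):
        assert hetview.heteroplasmy({5: {"A": 0}}) == []
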