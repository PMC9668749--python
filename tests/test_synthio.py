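"""Synthetic trio generator: determinism, realized rates, truth integrity."""

import math

import numpy as np
import pytest

from dipeval import mapbin, synthio

from conftest import random_dna


class TestGenTrio:
    def test_zero_rates_yield_identical_haplotypes(self):
        cfg = synthio.TrioConfig(seed=1, chrom_lengths=(5_000,), snv_rate=0, indel_rate=0)
        t = synthio.gen_trio(cfg)
        assert t.child_mat == t.child_pat == t.ancestor

    def test_snv_count_within_poisson_band_by_exhaustive_diff(self):
        cfg = synthio.TrioConfig(seed=1, chrom_lengths=(1_000_000,), snv_rate=1e-3, indel_rate=0)
        t = synthio.gen_trio(cfg)
        mat, pat = t.child_mat["chr1"], t.child_pat["chr1"]
        assert len(mat) == len(pat)  # SNV-only: same coordinates
        diffs = sum(a != b for a, b in zip(mat, pat))
        lam = 1000
        assert abs(diffs - lam) <= 3 * math.sqrt(lam)

    def test_same_seed_byte_identical(self):
        cfg = synthio.TrioConfig(seed=9, chrom_lengths=(20_000,), snv_rate=1e-3, indel_rate=1e-4, sv_rate=1e-5)
        a, b = synthio.gen_trio(cfg), synthio.gen_trio(cfg)
        assert a.haplotypes == b.haplotypes
        assert a.variants == b.variants

    def test_children_are_recombinants(self):
        cfg = synthio.TrioConfig(seed=4, chrom_lengths=(50_000,), snv_rate=2e-3, indel_rate=0)
        t = synthio.gen_trio(cfg)
        x = t.crossovers["child_mat"]["chr1"][0]
        child_vars = {(v.pos, v.alt) for v in t.variants["child_mat"]["chr1"]}
        h1 = {(v.pos, v.alt) for v in t.variants["mother_hap1"]["chr1"]}
        h2 = {(v.pos, v.alt) for v in t.variants["mother_hap2"]["chr1"]}
        # every child variant comes from one mother haplotype, segment-wise
        for pos, alt in child_vars:
            assert (pos, alt) in (h1 | h2)
        left = {pv for pv in child_vars if pv[0] < x}
        right = {pv for pv in child_vars if pv[0] >= x}
        assert left <= h1 or left <= h2
        assert right <= h1 or right <= h2

    def test_too_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            synthio.TrioConfig(chrom_lengths=(100,), k=21)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            synthio.TrioConfig(snv_rate=1.5)


class TestLongReads:
    def test_error_free_reads_are_exact_substrings(self, small_trio):
        t = small_trio
        reads = synthio.sim_long_reads(
            {"MAT": t.child_mat["chr1"]}, coverage=2, mean_len=2_000, err_rate=0, seed=1
        )
        from dipeval._codes import revcomp

        src = t.child_mat["chr1"]
        for name, seq in reads.reads[:50]:
            assert seq in src or revcomp(seq) in src

    def test_total_bases_within_five_percent_of_coverage(self, small_trio):
        t = small_trio
        haps = {"MAT": t.child_mat["chr1"], "PAT": t.child_pat["chr1"]}
        genome = sum(len(s) for s in haps.values())
        reads = synthio.sim_long_reads(haps, coverage=10, mean_len=5_000, err_rate=0, seed=2)
        total = sum(len(s) for _, s in reads.reads)
        assert abs(total - 10 * genome) <= 0.05 * 10 * genome

    def test_same_seed_identical_reads(self, small_trio):
        t = small_trio
        kw = dict(coverage=1, mean_len=3_000, err_rate=0.01, seed=5)
        r1 = synthio.sim_long_reads({"m": t.child_mat["chr1"]}, **kw)
        r2 = synthio.sim_long_reads({"m": t.child_mat["chr1"]}, **kw)
        assert r1.reads == r2.reads

    def test_origin_recoverable_from_read_name(self, small_trio):
        t = small_trio
        reads = synthio.sim_long_reads(
            {"hapA": t.child_mat["chr1"]}, coverage=0.5, mean_len=2_000, seed=3,
            origins={"hapA": "MAT"},
        )
        for name, _ in reads.reads[:10]:
            assert synthio.parse_read_origin(name) == "MAT"

    def test_long_mean_warns_and_truncates(self, rng):
        seq = random_dna(rng, 3_000)
        with pytest.warns(UserWarning, match="truncated"):
            reads = synthio.sim_long_reads({"s": seq}, coverage=2, mean_len=10_000, seed=1)
        assert max(len(s) for _, s in reads.reads) <= 3_000


class TestMolecules:
    MOTIF = "CTTAAG"

    def test_zero_noise_reproduces_digestion(self, rng):
        seq = random_dna(rng, 400_000)
        ms = synthio.sim_molecules(
            {"c": seq}, self.MOTIF, n_molecules=5, min_len=150_000, seed=3
        )
        for mol in ms.molecules:
            contig, start, strand = mol.origin
            sub = seq[start : start + mol.length]
            if strand == "-":
                from dipeval._codes import revcomp

                sub = revcomp(sub)
            truth = mapbin.digest_to_map(sub, self.MOTIF).labels
            # '-' strand mirrors label sites by molecule coordinates; allow
            # the motif-length offset introduced by mirroring site starts
            assert mol.labels.size == truth.size
            assert np.abs(mol.labels - truth).max() <= len(self.MOTIF)

    def test_min_length_honoured(self, rng):
        seq = random_dna(rng, 500_000)
        ms = synthio.sim_molecules({"c": seq}, self.MOTIF, n_molecules=20, min_len=150_000, seed=4)
        assert ms.min_length() >= 150_000

    def test_label_dropout_matches_binomial(self, rng):
        seq = random_dna(rng, 800_000)
        fn = 0.1
        noisy = synthio.sim_molecules(
            {"c": seq}, self.MOTIF, n_molecules=60, min_len=150_000, fn_rate=fn, seed=7
        )
        sites = mapbin.digest_to_map(seq, self.MOTIF).labels
        # truth label count per molecule from its recorded origin interval
        n_true = sum(
            int(((sites >= m.origin[1]) & (sites < m.origin[1] + m.length)).sum())
            for m in noisy.molecules
        )
        n_kept = sum(m.labels.size for m in noisy.molecules)
        mean = n_true * (1 - fn)
        sd = math.sqrt(n_true * fn * (1 - fn))
        assert abs(n_kept - mean) <= 3 * sd

    def test_short_motif_rejected(self, rng):
        with pytest.raises(ValueError):
            synthio.sim_molecules({"c": random_dna(rng, 200_000)}, "GAT", n_molecules=1)


class TestExpandMotif:
    def test_hic_cut_sites_expand_to_ten(self):
        assert len(synthio.expand_motif(["GATC", "GANTC", "CTNAG", "TTAA"])) == 10

    def test_concrete_motif_identity(self):
        assert synthio.expand_motif(["GATC"]) == {"GATC"}

    def test_single_n_equals_brute_force(self):
        expect = {f"G{b}TC" for b in "ACGT"}
        assert synthio.expand_motif(["GNTC"]) == expect

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            synthio.expand_motif(["GAXC"])


class TestCoverage:
    def test_flat_track_without_noise(self):
        track = synthio.sim_coverage({"c": 100_000}, 30, noise_sd=0, seed=1)
        assert np.all(track.depths["c"] == 30)

    def test_collapse_ratio_recomputed_from_track(self):
        ct = [("c", 40_000, 60_000, 3)]
        track = synthio.sim_coverage({"c": 200_000}, 30, ct, noise_sd=2.0, seed=2)
        d = track.depths["c"]
        inside = d[40:60].mean()
        outside = np.concatenate([d[:40], d[60:]]).mean()
        assert inside / outside == pytest.approx(3.0, rel=0.05)

    def test_deterministic_under_seed(self):
        t1 = synthio.sim_coverage({"c": 50_000}, 20, noise_sd=5, seed=9)
        t2 = synthio.sim_coverage({"c": 50_000}, 20, noise_sd=5, seed=9)
        assert np.array_equal(t1.depths["c"], t2.depths["c"])

    def test_negative_depth_clipped(self):
        track = synthio.sim_coverage({"c": 100_000}, 1, noise_sd=50, seed=3)
        assert (track.depths["c"] >= 0).all()
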