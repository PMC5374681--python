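"""Synthetic-data generator: catalog structure, Hardy-Weinberg genotype
sampling, haplotype construction and the read error model."""

import numpy as np
import pytest

from panelfilter import (
    Amplicon,
    ErrorModel,
    assign_genotypes,
    build_catalog,
    make_diploid_sequences,
    normalize_variant,
    random_panel,
    simulate_reads,
)
from panelfilter.panel import ConfigurationError, homopolymer_runs
from panelfilter.simulate import CapacityError


def one_amplicon(seq=None, length=100, seed=0):
    if seq is None:
        seq = "".join("ACGT"[i] for i in np.random.default_rng(seed).integers(0, 4, length))
    return [Amplicon(id="a1", chrom="chr1", start=1, sequence=seq)]


class TestBuildCatalog:
    def test_zero_case(self):
        with pytest.raises(ConfigurationError):
            build_catalog([], 1, 0, seed=0)
        cat = build_catalog(one_amplicon(), 0, 0, seed=0)
        assert cat.variants == []

    def test_structure(self):
        panel = one_amplicon()
        cat = build_catalog(panel, n_snv=5, n_indel=2, seed=3)
        assert len(cat.variants) == 7
        snvs = [v for v in cat.variants if v.type == "SNV"]
        indels = [v for v in cat.variants if v.type == "INDEL"]
        assert len(snvs) == 5 and len(indels) == 2
        positions = [(v.chrom, v.pos) for v in cat.variants]
        assert len(set(positions)) == 7
        amp = panel[0]
        for v in cat.variants:
            assert amp.start <= v.pos <= amp.end
            assert v.ref[0] == amp.ref_base(v.pos)
            assert 0 < v.af <= 1
            if v.type == "SNV":
                assert len(v.ref) == len(v.alt) == 1 and v.ref != v.alt
            else:
                assert len(v.ref) != len(v.alt) and v.ref[0] == v.alt[0]

    def test_determinism(self):
        panel = one_amplicon()
        a = build_catalog(panel, 5, 2, seed=9)
        b = build_catalog(panel, 5, 2, seed=9)
        assert a.variants == b.variants

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            build_catalog(one_amplicon(length=40), 100, 0, seed=0)


class TestAssignGenotypes:
    def test_af_one_forces_hom_alt(self):
        panel = one_amplicon()
        cat = build_catalog(panel, 3, 0, af_sampler=[1.0], seed=1)
        truth = assign_genotypes(cat, ["s1", "s2"], seed=2)
        for s in ("s1", "s2"):
            for v in cat.variants:
                assert truth.genotype(s, v) == "hom_alt"

    def test_hwe_recovery_at_half(self):
        # 10,000 diploid samples at af=0.5: genotype fractions within
        # 3 binomial standard errors of (0.25, 0.5, 0.25)
        panel = one_amplicon()
        cat = build_catalog(panel, 1, 0, af_sampler=[0.5], seed=4)
        samples = [f"s{i}" for i in range(10_000)]
        truth = assign_genotypes(cat, samples, seed=5)
        v = cat.variants[0]
        counts = {"hom_ref": 0, "het": 0, "hom_alt": 0}
        for s in samples:
            counts[truth.genotype(s, v)] += 1
        n = len(samples)
        for gt, p in (("hom_ref", 0.25), ("het", 0.5), ("hom_alt", 0.25)):
            se = (p * (1 - p) / n) ** 0.5
            assert abs(counts[gt] / n - p) <= 3 * se

    def test_determinism(self):
        panel = one_amplicon()
        cat = build_catalog(panel, 4, 1, seed=6)
        a = assign_genotypes(cat, ["x", "y"], seed=7)
        b = assign_genotypes(cat, ["x", "y"], seed=7)
        assert a.genotypes == b.genotypes


class TestNormalizeVariant:
    SEQ = "ACGTAAAAGTC"  # A run at positions 5-8 (1-based)

    def test_snv_untouched(self):
        assert normalize_variant(3, "G", "C", self.SEQ, 1) == (3, "G", "C")

    def test_deletion_left_aligns_through_run(self):
        # deleting any single A of the run is the same canonical variant
        reps = [
            normalize_variant(p, self.SEQ[p - 1] + "A", self.SEQ[p - 1], self.SEQ, 1)
            for p in (5, 6, 7)
        ]
        assert len(set(reps)) == 1
        pos, ref, alt = reps[0]
        assert pos == 4 and ref == "TA" and alt == "T"

    def test_insertion_left_aligns_through_run(self):
        a = normalize_variant(8, "A", "AA", self.SEQ, 1)
        b = normalize_variant(5, "A", "AA", self.SEQ, 1)
        assert a == b

    def test_shared_suffix_trimmed(self):
        assert normalize_variant(2, "CGT", "CT", self.SEQ, 1) == (2, "CG", "C")


class TestDiploidSequences:
    def test_no_alt_identity(self, small_panel):
        cat = build_catalog(small_panel, 2, 1, seed=20)
        truth = assign_genotypes(cat, ["s"], seed=21)
        truth.genotypes.clear()  # force hom_ref everywhere
        dip = make_diploid_sequences(small_panel, truth, "s", seed=22)
        for amp in small_panel:
            d = dip[amp.id]
            assert d.hap_seqs == (amp.sequence, amp.sequence)

    def test_het_snv_on_exactly_one_haplotype(self):
        panel = one_amplicon()
        cat = build_catalog(panel, 1, 0, seed=23)
        truth = assign_genotypes(cat, ["s"], seed=24)
        v = cat.variants[0]
        truth.genotypes[("s", v.key)] = "het"
        dip = make_diploid_sequences(panel, truth, "s", seed=25)
        d = dip["a1"]
        diffs = [h != panel[0].sequence for h in d.hap_seqs]
        assert sorted(diffs) == [False, True]
        mutated = d.hap_seqs[diffs.index(True)]
        mismatches = [
            i for i, (a, b) in enumerate(zip(mutated, panel[0].sequence)) if a != b
        ]
        assert mismatches == [v.pos - panel[0].start]

    def test_hom_deletion_shortens_both_haplotypes(self):
        panel = one_amplicon()
        amp = panel[0]
        pos = 50
        ref = amp.sequence[pos - 1 : pos + 2]  # anchor + 2 deleted bases
        from panelfilter.simulate import CatalogVariant, TruthCatalog

        npos, nref, nalt = normalize_variant(pos, ref, ref[0], amp.sequence, amp.start)
        v = CatalogVariant(chrom="chr1", pos=npos, ref=nref, alt=nalt, type="INDEL", af=0.5)
        truth = TruthCatalog(variants=[v], genotypes={("s", v.key): "hom_alt"},
                             sample_ids=["s"])
        dip = make_diploid_sequences(panel, truth, "s", seed=26)
        for h in (0, 1):
            assert len(dip["a1"].hap_seqs[h]) == len(amp.sequence) - 2

    def test_coordinate_map_tracks_indel_shift(self, small_panel, small_truth):
        dip = make_diploid_sequences(small_panel, small_truth, "A", seed=27)
        for d in dip.values():
            for h in (0, 1):
                seq, hmap = d.hap_seqs[h], d.hap_maps[h]
                assert len(seq) == len(hmap)
                mapped = hmap[hmap >= 0]
                # reference positions strictly increasing along the haplotype
                assert np.all(np.diff(mapped) > 0)
                for i, p in enumerate(hmap):
                    planted = {a for _, a in d.applied[h]}
                    if p >= 0 and all(
                        not (a <= i < a + len(v.alt)) for v, a in d.applied[h]
                    ):
                        assert seq[i] == d.amplicon.ref_base(int(p))


class TestSimulateReads:
    def test_no_error_reads_are_haplotype_substrings(self, small_diploid):
        em = ErrorModel(sub_rate=0.0, indel_rate=0.0)
        batches = simulate_reads(small_diploid, depth=20, read_length=120,
                                 error_model=em, seed=30)
        for amp_id, batch in batches.items():
            for read in batch.to_reads():
                hap = small_diploid[amp_id].hap_seqs[read.haplotype - 1]
                expected = hap[read.offset : read.offset + len(read.bases)]
                if read.strand == "reverse":
                    from panelfilter.panel import reverse_complement
                    expected = reverse_complement(expected)
                assert read.bases == expected

    def test_mean_coverage_near_requested_depth(self):
        panel = one_amplicon(length=200, seed=31)
        from panelfilter.simulate import TruthCatalog
        truth = TruthCatalog(variants=[], sample_ids=["s"])
        dip = make_diploid_sequences(panel, truth, "s", seed=32)
        batches = simulate_reads(dip, depth=100, read_length=100, seed=33)
        cov = np.zeros(200)
        for read in batches["a1"].to_reads():
            n_del = sum(1 for _, k in read.indel_errors if k == "del")
            n_ins = sum(1 for _, k in read.indel_errors if k == "ins")
            span = len(read.bases) + n_del - n_ins
            cov[read.offset : read.offset + span] += 1
        assert 90 <= cov.mean() <= 110

    def test_strand_balance(self, small_diploid):
        batches = simulate_reads(small_diploid, depth=600, read_length=120, seed=34)
        strands = np.concatenate([b.strand for b in batches.values()])
        assert len(strands) >= 1000
        fwd = (strands == 0).mean()
        assert 0.45 <= fwd <= 0.55

    def test_homopolymer_multiplier_concentrates_indel_errors(
        self, homopolymer_amplicon
    ):
        from panelfilter.simulate import TruthCatalog
        truth = TruthCatalog(variants=[], sample_ids=["s"])
        dip = make_diploid_sequences([homopolymer_amplicon], truth, "s", seed=35)
        em = ErrorModel(sub_rate=0.0, indel_rate=0.002,
                        homopolymer_multiplier=50, homopolymer_min_run=4)
        batches = simulate_reads(dip, depth=2000, read_length=32,
                                 error_model=em, seed=36)
        batch = batches["hp"]
        runs = homopolymer_runs(homopolymer_amplicon.sequence)
        run_pos = set(np.flatnonzero(runs >= 4))
        in_run = sum(1 for p in batch.ind_pos if int(p) in run_pos)
        out_run = len(batch.ind_pos) - in_run
        # 5 in-run positions vs 27 others at 50x the rate
        assert in_run > out_run

    def test_determinism_and_seed_sensitivity(self, small_diploid):
        a = simulate_reads(small_diploid, 20, 120, seed=37)
        b = simulate_reads(small_diploid, 20, 120, seed=37)
        c = simulate_reads(small_diploid, 20, 120, seed=38)
        for amp_id in a:
            assert np.array_equal(a[amp_id].offset, b[amp_id].offset)
            assert np.array_equal(a[amp_id].quals, b[amp_id].quals)
        assert any(
            not np.array_equal(a[k].hap, c[k].hap) for k in a
        )

    def test_depth_validation(self, small_diploid):
        with pytest.raises(ConfigurationError):
            simulate_reads(small_diploid, 0, 100, seed=39)
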