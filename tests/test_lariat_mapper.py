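"""Lariat-read pipeline: filters, 5'SS search, branch alignment, calls, quant."""

import math

import pytest

from lariatfold.alu_catalog import GenomicInterval
from lariatfold.lariat_mapper import (
    BranchpointCall,
    GenomeAligner,
    Intron,
    LariatQuant,
    MapperConfig,
    ReadRecord,
    build_fiveprime_index,
    filter_ambiguous,
    fold_changes,
    genome_prefilter,
    lariat_dsrna_sites,
    locate_fiveprime,
    map_lariats,
    quantify,
    revcomp,
    trim_for_branchpoint,
)
from lariatfold.structure_stats import MaxPairFolder
from lariatfold.synthetic_data import random_sequence, simulate_lariat_reads


class TestFilterAmbiguous:
    def test_five_percent_boundary_retained(self):
        read = ReadRecord("r", "N" * 5 + "A" * 95)
        assert filter_ambiguous([read]) == [read]

    def test_above_boundary_removed(self):
        assert filter_ambiguous([ReadRecord("r", "N" * 6 + "A" * 94)]) == []

    def test_all_ambiguous_removed(self):
        assert filter_ambiguous([ReadRecord("r", "N" * 50)]) == []


class TestFivePrimeIndex:
    def test_plus_strand_key_is_leading_slice(self, plain_ledger):
        genome = plain_ledger.genome
        idx = build_fiveprime_index(plain_ledger.introns, genome)
        for intron in plain_ledger.introns:
            iv = intron.interval
            expected = (
                genome[iv.chrom][iv.start : iv.start + 20]
                if iv.strand == "+"
                else revcomp(genome[iv.chrom][iv.end - 20 : iv.end])
            )
            assert idx.entries[intron.intron_id].key == expected

    def test_short_intron_skipped(self):
        genome = {"c": "ACGT" * 20}
        short = Intron("i1", "g1", GenomicInterval("c", 10, 25, "+"))
        idx = build_fiveprime_index([short], genome)
        assert "i1" not in idx.entries


class TestLocateFiveprime:
    def _index(self):
        genome = {
            "c": random_sequence(40, seed=1, alphabet="ACGT")
            + random_sequence(40, seed=2, alphabet="ACGT")
        }
        introns = [
            Intron("i1", "g1", GenomicInterval("c", 0, 40, "+")),
            Intron("i2", "g2", GenomicInterval("c", 40, 80, "+")),
        ]
        return genome, build_fiveprime_index(introns, genome)

    def test_unique_hit_located(self):
        genome, idx = self._index()
        key = idx.entries["i1"].key
        read = ReadRecord("r", "TTTTTTTTTTTTTTTTTTTTTTTTTTTTTT" + key)
        assert locate_fiveprime(read, idx) == ("i1", 30)

    def test_two_intron_keys_disqualify(self):
        genome, idx = self._index()
        read = ReadRecord("r", idx.entries["i1"].key + idx.entries["i2"].key)
        assert locate_fiveprime(read, idx) is None

    def test_mismatched_key_not_found(self):
        genome, idx = self._index()
        key = list(idx.entries["i1"].key)
        key[10] = {"A": "C"}.get(key[10], "A")
        read = ReadRecord("r", "T" * 30 + "".join(key))
        assert locate_fiveprime(read, idx) is None

    def test_same_key_twice_disqualifies(self):
        genome, idx = self._index()
        key = idx.entries["i1"].key
        read = ReadRecord("r", key + key)
        assert locate_fiveprime(read, idx) is None


class TestTrim:
    def test_long_prefix_retained(self):
        read = ReadRecord("r", "A" * 100)
        assert trim_for_branchpoint(read, ("i", 50)) == "A" * 50

    @pytest.mark.parametrize("offset", [0, 12, 19])
    def test_short_prefix_discarded(self, offset):
        read = ReadRecord("r", "A" * 100)
        assert trim_for_branchpoint(read, ("i", offset)) is None


class TestGenomePrefilter:
    def test_genomic_reads_discarded_junction_reads_kept(self, plain_ledger):
        genome = plain_ledger.genome
        aligner = GenomeAligner(genome)
        chrom_seq = genome[plain_ledger.chrom]
        genomic = ReadRecord("g", chrom_seq[500:620])
        reverse = ReadRecord("rc", revcomp(chrom_seq[1000:1120]))
        junction, _ = simulate_lariat_reads(plain_ledger, "gene1.intron1", n=1, seed=3)
        out = genome_prefilter([genomic, reverse, junction[0]], aligner)
        assert [r.id for r in out] == [junction[0].id]

    def test_foreign_sequence_retained(self, plain_ledger):
        aligner = GenomeAligner(plain_ledger.genome)
        foreign = ReadRecord("f", random_sequence(120, seed=777, alphabet="ACGT"))
        assert [r.id for r in genome_prefilter([foreign], aligner)] == ["f"]


class TestEndToEnd:
    def test_noise_free_recovery_exact(self, plain_ledger):
        reads = []
        for intron in plain_ledger.introns:
            rs, _ = simulate_lariat_reads(plain_ledger, intron.intron_id, n=5, seed=13)
            reads.extend(rs)
        res = map_lariats(reads, plain_ledger.genome, plain_ledger.introns, plain_ledger.genes)
        assert len(res.per_read) == len(reads)
        for read_id, (intron_id, bp) in res.per_read.items():
            assert read_id.startswith(intron_id)
            assert bp == plain_ledger.branchpoints[intron_id]

    @pytest.mark.parametrize(
        "noise,expect_calls,tolerance",
        [
            (dict(mismatches=5), True, 0),
            (dict(indel=("del", 3)), True, 3),
            (dict(indel=("ins", 3)), True, 3),
            (dict(mismatches=6), False, 0),
            (dict(indel=("del", 4)), False, 0),
            (dict(indel=("ins", 4)), False, 0),
            (dict(prefix_length=19), False, 0),
        ],
    )
    def test_constraint_sharpness(self, plain_ledger, noise, expect_calls, tolerance):
        reads, _ = simulate_lariat_reads(
            plain_ledger, "gene2.intron1", n=8, seed=17, **noise
        )
        res = map_lariats(reads, plain_ledger.genome, plain_ledger.introns, plain_ledger.genes)
        bp = plain_ledger.branchpoints["gene2.intron1"]
        if expect_calls:
            assert len(res.per_read) == len(reads)
            assert all(abs(v[1] - bp) <= tolerance for v in res.per_read.values())
        else:
            assert res.per_read == {}

    def test_filter_monotonicity(self, plain_ledger):
        reads, _ = simulate_lariat_reads(plain_ledger, "gene1.intron1", n=5, seed=19)
        reads.append(ReadRecord("amb", "N" * 120))
        chrom = plain_ledger.chrom
        reads.append(ReadRecord("genomic", plain_ledger.genome[chrom][100:220]))
        res = map_lariats(reads, plain_ledger.genome, plain_ledger.introns, plain_ledger.genes)
        c = res.stage_counts
        assert (
            c["input"]
            >= c["ambiguity_filtered"]
            >= c["genome_unaligned"]
            >= c["unique_fiveprime_hit"]
            >= c["prefix_retained"]
            >= c["called"]
        )
        assert c["ambiguity_filtered"] == c["input"] - 1
        assert c["genome_unaligned"] == c["ambiguity_filtered"] - 1

    def test_determinism(self, plain_ledger):
        reads, _ = simulate_lariat_reads(plain_ledger, "gene3.intron1", n=4, seed=29)
        a = map_lariats(reads, plain_ledger.genome, plain_ledger.introns, plain_ledger.genes)
        b = map_lariats(reads, plain_ledger.genome, plain_ledger.introns, plain_ledger.genes)
        assert a.calls == b.calls and a.per_read == b.per_read


class TestQuantification:
    def test_per_million_normalization(self):
        calls = [BranchpointCall("i1", 100, tuple(f"r{i}" for i in range(10)))]
        q = quantify(calls, total_mapped=10**6)
        assert q.normalized["i1"] == pytest.approx(10.0)

    def test_branchpoint_count_mode(self):
        calls = [
            BranchpointCall("i1", 100, ("a", "b")),
            BranchpointCall("i1", 105, ("c",)),
        ]
        assert quantify(calls, 1000, count_mode="reads").counts["i1"] == 3
        assert quantify(calls, 1000, count_mode="branchpoints").counts["i1"] == 2

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            quantify([], total_mapped=0)

    def test_fold_change_arithmetic(self):
        wt = LariatQuant({"i1": 2}, 10**6, {"i1": 2.0})
        ko = LariatQuant({"i1": 86}, 10**6, {"i1": 86.0})
        fc, flagged = fold_changes(wt, ko)["i1"]
        assert fc == pytest.approx(43.0) and not flagged

    def test_zero_denominator_flagged(self):
        wt = LariatQuant({}, 10**6, {})
        ko = LariatQuant({"i1": 5}, 10**6, {"i1": 5.0})
        fc, flagged = fold_changes(wt, ko)["i1"]
        assert math.isinf(fc) and flagged
        both_zero = fold_changes(
            LariatQuant({"i1": 0}, 10, {"i1": 0.0}), LariatQuant({"i1": 0}, 10, {"i1": 0.0})
        )["i1"]
        assert math.isnan(both_zero[0]) and both_zero[1]


class TestLariatDsrnaSites:
    def _mini(self, intron_seq):
        pad5 = random_sequence(30, seed=41, alphabet="ACGT")
        pad3 = random_sequence(30, seed=43, alphabet="ACGT")
        genome = {"c": pad5 + intron_seq + pad3}
        intron = Intron("i1", "g1", GenomicInterval("c", 30, 30 + len(intron_seq), "+"))
        return genome, {"i1": intron}

    def test_stem_intron_tally_per_million(self):
        genome, introns = self._mini("G" * 33 + "AAAA" + "C" * 33)
        calls = [BranchpointCall("i1", 60, ("r1",))]
        tallies = lariat_dsrna_sites(calls, genome, introns, MaxPairFolder(), total_mapped=10**6)
        assert tallies["PKR"] == pytest.approx(1.0)
        halved = lariat_dsrna_sites(calls, genome, introns, MaxPairFolder(), total_mapped=2 * 10**6)
        assert halved["PKR"] == pytest.approx(0.5)

    def test_ir_alu_intron_has_pkr_sites(self, mixed_ledger):
        intron_id = "gene4.intron1"  # planted IR
        introns = {i.intron_id: i for i in mixed_ledger.introns}
        calls = [BranchpointCall(intron_id, mixed_ledger.branchpoints[intron_id], ("r1",))]
        tallies = lariat_dsrna_sites(
            calls, mixed_ledger.genome, introns, MaxPairFolder(), total_mapped=10**6
        )
        assert tallies["PKR"] > 0
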