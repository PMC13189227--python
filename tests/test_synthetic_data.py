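"""Ground-truth guarantees of the synthetic-data generator."""

import pytest

from lariatfold.alu_catalog import AluCategory
from lariatfold.lariat_mapper import map_lariats, revcomp
from lariatfold.synthetic_data import (
    ALU_CONSENSUS,
    SyntheticLedger,
    make_genome,
    simulate_counts,
    simulate_lariat_reads,
    validate_unique_kmers,
)


class TestMakeGenome:
    def test_deterministic_under_seed(self):
        a = make_genome(seed=2, n_genes=2, intron_length_range=(400, 500))
        b = make_genome(seed=2, n_genes=2, intron_length_range=(400, 500))
        assert a.genome == b.genome and a.to_json() == b.to_json()

    def test_background_kmers_unique(self, mixed_ledger):
        dups = validate_unique_kmers(
            mixed_ledger.genome, mask=[a.interval for a in mixed_ledger.alus]
        )
        assert dups == []

    def test_ir_intron_contains_perfect_complement_pair(self, mixed_ledger):
        intron = next(i for i in mixed_ledger.introns if i.intron_id == "gene4.intron1")
        iv = intron.interval
        seq = mixed_ledger.genome[iv.chrom][iv.start : iv.end]
        if iv.strand == "-":
            seq = revcomp(seq)
        assert ALU_CONSENSUS in seq and revcomp(ALU_CONSENSUS) in seq

    def test_planted_alu_strands_match_category(self, mixed_ledger):
        strands = {
            iid: [a.element_strand for a in alus]
            for iid, alus in mixed_ledger.alus_by_intron.items()
        }
        assert strands["gene1.intron1"] == []
        assert len(strands["gene2.intron1"]) == 1
        assert len(set(strands["gene3.intron1"])) == 1 and len(strands["gene3.intron1"]) == 2
        assert set(strands["gene4.intron1"]) == {"+", "-"}

    def test_branchpoints_inside_introns_away_from_start(self, mixed_ledger):
        for intron in mixed_ledger.introns:
            bp = mixed_ledger.branchpoints[intron.intron_id]
            iv = intron.interval
            assert iv.start <= bp < iv.end
            tx_pos = bp - iv.start if iv.strand == "+" else iv.end - 1 - bp
            assert tx_pos >= 20

    def test_infeasible_plan_rejected(self):
        with pytest.raises(ValueError, match="cannot hold"):
            make_genome(seed=1, n_genes=1, alu_plan=AluCategory.IR, intron_length_range=(300, 300))

    def test_ledger_roundtrip(self, plain_ledger):
        text = plain_ledger.to_json()
        assert SyntheticLedger.from_json(text).to_json() == text


class TestSimulateLariatReads:
    def test_read_layout_prefix_then_key(self, plain_ledger):
        reads, truth = simulate_lariat_reads(plain_ledger, "gene1.intron1", n=2, seed=1)
        intron = next(i for i in plain_ledger.introns if i.intron_id == "gene1.intron1")
        iv = intron.interval
        tx = plain_ledger.genome[iv.chrom][iv.start : iv.end]
        if iv.strand == "-":
            tx = revcomp(tx)
        key = tx[:20]
        for read in reads:
            assert read.sequence.endswith(key)
            assert len(read.sequence) == 120
        assert (truth["branchpoint"] == plain_ledger.branchpoints["gene1.intron1"]).all()

    def test_prefix_is_genomic_context_of_branchpoint(self, plain_ledger):
        reads, _ = simulate_lariat_reads(plain_ledger, "gene2.intron1", n=1, seed=2)
        intron = next(i for i in plain_ledger.introns if i.intron_id == "gene2.intron1")
        iv = intron.interval
        tx = plain_ledger.genome[iv.chrom][iv.start : iv.end]
        if iv.strand == "-":
            tx = revcomp(tx)
        bp = plain_ledger.branchpoints["gene2.intron1"]
        bp_tx = bp - iv.start if iv.strand == "+" else iv.end - 1 - bp
        assert reads[0].sequence[:100] == tx[bp_tx - 99 : bp_tx + 1]

    def test_infeasible_geometry_rejected(self, plain_ledger):
        intron = plain_ledger.introns[0]
        with pytest.raises(ValueError, match="infeasible|outside"):
            simulate_lariat_reads(
                plain_ledger,
                intron.intron_id,
                branchpoint=intron.interval.start + 5,
                read_length=120,
            )

    def test_determinism(self, plain_ledger):
        a, _ = simulate_lariat_reads(plain_ledger, "gene1.intron1", n=3, seed=9, mismatches=2)
        b, _ = simulate_lariat_reads(plain_ledger, "gene1.intron1", n=3, seed=9, mismatches=2)
        assert [r.sequence for r in a] == [r.sequence for r in b]


class TestSimulateCounts:
    def test_zero_dispersion_deterministic_limit(self, mixed_ledger):
        total, ip = simulate_counts(
            mixed_ledger, ip_enrichment=2.2, dispersion=0.0, ip_noise_dispersion=0.0, seed=3
        )
        merged = total.merge(ip, on="region_id", suffixes=("_t", "_i"))
        ir = merged[merged.category_t == "IR"]
        non_ir = merged[merged.category_t != "IR"]
        assert not ir.empty and not non_ir.empty
        assert (abs(ir["count_i"] - ir["count_t"] * 2.2) < 1e-9).all()
        assert (abs(non_ir["count_i"] - non_ir["count_t"]) < 1e-9).all()

    def test_parameters_recorded_in_ledger(self, mixed_ledger):
        simulate_counts(mixed_ledger, ip_enrichment=1.5, seed=4)
        assert mixed_ledger.count_params["ip_enrichment"] == 1.5
        assert mixed_ledger.count_params["seed"] == 4
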