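"""Gene tables, operon chaining and upstream-region extraction."""

import numpy as np
import pytest
from Bio.Seq import Seq

from togaregulon.genome_model import (
    GeneRecord,
    GenomeAnnotation,
    OrthologGroup,
    extract_upstream,
    load_genome,
    neighborhood_training_set,
    predict_operons,
    write_gene_table,
)

from conftest import random_dna


def _write_fasta(path, contigs):
    with open(path, "w") as fh:
        for cid, seq in contigs.items():
            fh.write(f">{cid}\n{seq}\n")


class TestLoadGenome:
    def test_empty_gene_table_is_valid(self, tmp_path):
        (tmp_path / "g.tsv").write_text(
            "gene_id\tgenome_id\tcontig\tstart\tend\tstrand\tname\trole\tpathway\n"
        )
        _write_fasta(tmp_path / "g.fna", {"c1": "ACGTACGT"})
        genome = load_genome(tmp_path / "g.tsv", tmp_path / "g.fna", genome_id="g")
        assert genome.genes == []

    def test_round_trip(self, tmp_path, toy_genome):
        write_gene_table(toy_genome, tmp_path / "out.tsv")
        _write_fasta(tmp_path / "g.fna", toy_genome.contigs)
        back = load_genome(tmp_path / "out.tsv", tmp_path / "g.fna")
        assert back.genes == toy_genome.genes
        assert back.genome_id == toy_genome.genome_id

    def test_named_gene_fields_survive(self, tmp_path):
        rows = (
            "gene_id\tgenome_id\tcontig\tstart\tend\tstrand\tname\trole\tpathway\n"
            "TM0439\tTmar\tc1\t11\t40\t+\tuxaR\tTF\tUxa\n"
        )
        (tmp_path / "g.tsv").write_text(rows)
        _write_fasta(tmp_path / "g.fna", {"c1": "A" * 60})
        genome = load_genome(tmp_path / "g.tsv", tmp_path / "g.fna")
        gene = genome.gene("TM0439")
        assert gene.name == "uxaR" and gene.role == "TF"
        assert (gene.start1, gene.end1) == (11, 40)

    def test_coordinate_outside_contig_names_gene(self, tmp_path):
        rows = (
            "gene_id\tgenome_id\tcontig\tstart\tend\tstrand\tname\trole\tpathway\n"
            "bad1\tg\tc1\t5\t500\t+\t\tother\t\n"
        )
        (tmp_path / "g.tsv").write_text(rows)
        _write_fasta(tmp_path / "g.fna", {"c1": "A" * 60})
        with pytest.raises(ValueError, match="bad1"):
            load_genome(tmp_path / "g.tsv", tmp_path / "g.fna")

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            GeneRecord("x", "g", "c1", 0, 10, "*")


class TestPredictOperons:
    def test_single_gene_singleton(self):
        genome = GenomeAnnotation(
            "g", {"c1": "A" * 100}, [GeneRecord("x", "g", "c1", 10, 40, "+")]
        )
        ops = predict_operons(genome)
        assert len(ops) == 1 and ops[0].gene_ids == ["x"]

    def test_gap_rule_and_strand_break(self, toy_genome):
        ops = predict_operons(toy_genome, max_gap=100)
        assert [op.gene_ids for op in ops] == [["gA", "gB"], ["gC"]]

    def test_divergent_pair_never_merges(self):
        genome = GenomeAnnotation(
            "g",
            {"c1": "A" * 300},
            [
                GeneRecord("L", "g", "c1", 10, 100, "-"),
                GeneRecord("R", "g", "c1", 101, 200, "+"),
            ],
        )
        assert len(predict_operons(genome, max_gap=10_000)) == 2

    def test_partition_and_order_independence(self):
        rng = np.random.default_rng(4)
        genes = []
        pos = 0
        for i in range(30):
            pos += int(rng.integers(20, 200))
            end = pos + int(rng.integers(30, 100))
            genes.append(
                GeneRecord(f"g{i}", "g", "c1", pos, end, "+" if rng.random() < 0.5 else "-")
            )
            pos = end
        genome = GenomeAnnotation("g", {"c1": "A" * (pos + 10)}, genes)
        ops = predict_operons(genome)
        covered = [gid for op in ops for gid in op.gene_ids]
        assert sorted(covered) == sorted(g.gene_id for g in genes)
        shuffled = list(genes)
        rng.shuffle(shuffled)
        ops2 = predict_operons(GenomeAnnotation("g", genome.contigs, shuffled))
        assert {frozenset(op.gene_ids) for op in ops} == {
            frozenset(op.gene_ids) for op in ops2
        }

    def test_minus_strand_transcription_order(self):
        genome = GenomeAnnotation(
            "g",
            {"c1": "A" * 500},
            [
                GeneRecord("m1", "g", "c1", 100, 200, "-"),
                GeneRecord("m2", "g", "c1", 220, 320, "-"),
            ],
        )
        (op,) = predict_operons(genome)
        assert op.gene_ids == ["m2", "m1"]  # rightmost first
        assert op.promoter_anchor == 320


class TestExtractUpstream:
    def test_contig_edge_truncates(self):
        genome = GenomeAnnotation(
            "g", {"c1": "ACGT" * 50}, [GeneRecord("x", "g", "c1", 0, 30, "+")]
        )
        (op,) = predict_operons(genome)
        region = extract_upstream(op, genome, window=(300, 20), min_length=1)
        assert region.truncated
        assert region.interval == (0, 20)
        assert len(region.sequence) == 20

    def test_minus_strand_coordinates_and_revcomp(self):
        rng = np.random.default_rng(11)
        contig = random_dna(rng, 1000)
        # gene at 1-based [201, 500] on minus strand
        genome = GenomeAnnotation(
            "g", {"c1": contig}, [GeneRecord("x", "g", "c1", 200, 500, "-")]
        )
        (op,) = predict_operons(genome)
        region = extract_upstream(op, genome, window=(300, 20))
        assert region.interval == (480, 800)
        assert region.sequence == str(Seq(contig[480:800]).reverse_complement())

    def test_sequence_matches_genome_substring(self, toy_genome):
        ops = predict_operons(toy_genome)
        for op in ops:
            region = extract_upstream(op, toy_genome, window=(150, 20), min_length=1)
            lo, hi = region.interval
            expected = toy_genome.sequence("c1", lo, hi, op.strand)
            assert region.sequence == expected

    def test_divergent_pair_cross_reference(self):
        rng = np.random.default_rng(5)
        contig = random_dna(rng, 800)
        genome = GenomeAnnotation(
            "g",
            {"c1": contig},
            [
                GeneRecord("gloR", "g", "c1", 100, 250, "-"),
                GeneRecord("gloE", "g", "c1", 400, 600, "+"),
            ],
        )
        ops = predict_operons(genome)
        regions = {
            op.gene_ids[0]: extract_upstream(op, genome, window=(300, 20), operons=ops)
            for op in ops
        }
        assert regions["gloR"].shared_divergent_with is not None
        assert regions["gloE"].shared_divergent_with is not None
        # both cover the shared intergenic segment
        lo = max(regions["gloR"].interval[0], regions["gloE"].interval[0])
        hi = min(regions["gloR"].interval[1], regions["gloE"].interval[1])
        assert hi > lo

    def test_neighbor_truncation(self, toy_genome):
        ops = predict_operons(toy_genome)
        op_c = next(op for op in ops if op.gene_ids == ["gC"])
        region = extract_upstream(op_c, toy_genome, window=(300, 20))
        # upstream of gC (minus strand) is clipped at the contig end
        assert region.interval[1] == 1000

    def test_bad_window_rejected(self, toy_genome):
        ops = predict_operons(toy_genome)
        with pytest.raises(ValueError):
            extract_upstream(ops[0], toy_genome, window=(0, 20))


class TestNeighborhoodTrainingSet:
    def _community(self):
        rng = np.random.default_rng(7)
        genomes = {}
        orthologs = {"tf": OrthologGroup("tf", {})}
        for gid in ("g1", "g2"):
            genes = []
            pos = 0
            for i in range(5):
                pos += 200
                genes.append(GeneRecord(f"{gid}_x{i}", gid, "c1", pos, pos + 90, "+"))
                pos += 90
            genomes[gid] = GenomeAnnotation(
                gid, {"c1": random_dna(rng, pos + 300)}, genes
            )
            orthologs["tf"].members[gid] = [f"{gid}_x2"]
        return genomes, orthologs

    def test_radius_zero_is_own_operon(self):
        genomes, orthologs = self._community()
        regions = neighborhood_training_set(orthologs["tf"], genomes, radius_genes=0)
        assert len(regions) == 2  # one operon per genome

    def test_radius_selects_flanking_operons(self):
        genomes, orthologs = self._community()
        regions = neighborhood_training_set(orthologs["tf"], genomes, radius_genes=1)
        assert len(regions) == 6  # TF operon + one on each side, per genome

    def test_absent_genome_contributes_nothing(self):
        genomes, orthologs = self._community()
        orthologs["tf"].members.pop("g2")
        regions = neighborhood_training_set(orthologs["tf"], genomes, radius_genes=0)
        assert {r.genome_id for r in regions} == {"g1"}

    def test_absent_everywhere_is_error(self):
        genomes, _ = self._community()
        with pytest.raises(ValueError):
            neighborhood_training_set(OrthologGroup("nope", {}), genomes)
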