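"""Genome data model: genes, operons, ortholog groups, upstream regions.

Input files use 1-based inclusive coordinates (GFF3 convention).  Internally
all coordinates are 0-based half-open; the TSV/GFF readers and writers convert
at the boundary.

The training set for motif discovery is assembled by gene-neighborhood
analysis: upstream regions of operons lying close (in gene rank) to a TF
ortholog on the chromosome.  Bacterial sugar-catabolism TFs are typically
encoded inside their own regulated loci and autoregulated, so the TF's operon
is always part of its training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = [
    "gene_id",
    "genome_id",
    "contig",
    "start",
    "end",
    "strand",
    "name",
    "role",
    "pathway",
]

VALID_ROLES = {"enzyme", "transporter", "TF", "regulator-RNA", "hypothetical", "other"}

#: Minimum upstream-region length kept after truncation at a coding neighbor.
MIN_REGION_LENGTH = 30


@dataclass(frozen=True)
class GeneRecord:
    """A single annotated gene.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    contig (so ``end - start`` is the gene length), regardless of ``strand``.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    name: str = ""
    role: str = "other"
    pathway: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def start1(self) -> int:
        """1-based inclusive start, as written in gene tables."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """1-based inclusive end."""
        return self.end


@dataclass
class GenomeAnnotation:
    """Contig sequences plus the ordered gene list of one genome."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id} in {self.genome_id}")
            seen.add(g.gene_id)
            if g.contig_id not in self.contigs:
                raise ValueError(f"gene {g.gene_id}: unknown contig {g.contig_id}")
            if g.end > len(self.contigs[g.contig_id]):
                raise ValueError(
                    f"gene {g.gene_id}: end {g.end} beyond contig "
                    f"{g.contig_id} length {len(self.contigs[g.contig_id])}"
                )

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def sequence(self, contig_id: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.contigs[contig_id][start:end]
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class OrthologGroup:
    """One ortholog group: per-genome lists of member gene ids.

    A genome may be absent entirely (ortholog loss)."""

    group_id: str
    members: dict[str, list[str]]

    def genomes(self) -> set[str]:
        return {g for g, ids in self.members.items() if ids}


@dataclass
class Operon:
    """A run of co-transcribed same-strand genes, in transcription order."""

    operon_id: str
    genome_id: str
    contig_id: str
    gene_ids: list[str]
    strand: str
    promoter_anchor: int  # genomic coordinate of the first gene's start (0-based)

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class UpstreamRegion:
    """Promoter-proximal sequence of an operon, oriented 5'→3' toward the gene.

    ``interval`` is the forward-strand genomic interval (0-based half-open);
    for minus-strand operons ``sequence`` is its reverse complement.
    """

    operon_id: str
    genome_id: str
    contig_id: str
    sequence: str
    interval: tuple[int, int]
    strand: str
    truncated: bool = False
    shared_divergent_with: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# I/O


def _read_contigs(fasta_path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def _genes_from_tsv(path: str | Path, default_genome: str | None) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path} missing columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneRecord(
                gene_id=row.gene_id,
                genome_id=row.genome_id or (default_genome or ""),
                contig_id=row.contig,
                start=int(row.start) - 1,
                end=int(row.end),
                strand=row.strand,
                name=row.name,
                role=row.role or "other",
                pathway=row.pathway,
            )
        )
    return genes


def _genes_from_gff3(path: str | Path, default_genome: str | None) -> list[GeneRecord]:
    # gffutils builds an in-memory sqlite db; fine at bacterial-genome scale.
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(("gene", "CDS"), order_by=("seqid", "start")):
        attrs = feat.attributes
        gid = (attrs.get("ID") or attrs.get("locus_tag") or [feat.id])[0]
        genes.append(
            GeneRecord(
                gene_id=gid,
                genome_id=default_genome or "",
                contig_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                name=(attrs.get("Name") or attrs.get("gene") or [""])[0],
                role=(attrs.get("role") or ["other"])[0],
                pathway=(attrs.get("pathway") or [""])[0],
            )
        )
    return genes


def load_genome(
    gene_table: str | Path,
    contig_fasta: str | Path,
    genome_id: str | None = None,
) -> GenomeAnnotation:
    """Load one genome from a gene table (TSV or GFF3) plus a contig FASTA.

    The TSV dialect is tab-separated with a header row
    ``gene_id genome_id contig start end strand name role pathway`` and
    1-based inclusive coordinates.  GFF3 files are accepted too; ``role`` and
    ``pathway`` are read from the attribute column when present.
    """
    contigs = _read_contigs(contig_fasta)
    path = Path(gene_table)
    if path.suffix.lower() in (".gff", ".gff3"):
        genes = _genes_from_gff3(path, genome_id)
    else:
        genes = _genes_from_tsv(path, genome_id)
    if genome_id is None:
        ids = {g.genome_id for g in genes if g.genome_id}
        genome_id = ids.pop() if len(ids) == 1 else path.stem
    genes = [
        g if g.genome_id else GeneRecord(**{**g.__dict__, "genome_id": genome_id})
        for g in genes
    ]
    return GenomeAnnotation(genome_id=genome_id, contigs=contigs, genes=genes)


def write_gene_table(genome: GenomeAnnotation, path: str | Path) -> None:
    """Write the TSV gene-table dialect (1-based inclusive coordinates)."""
    rows = [
        {
            "gene_id": g.gene_id,
            "genome_id": g.genome_id,
            "contig": g.contig_id,
            "start": g.start1,
            "end": g.end1,
            "strand": g.strand,
            "name": g.name,
            "role": g.role,
            "pathway": g.pathway,
        }
        for g in genome.genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def load_ortholog_table(path: str | Path) -> dict[str, OrthologGroup]:
    """Read a TSV ortholog table with columns group_id, genome_id, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    groups: dict[str, OrthologGroup] = {}
    for row in df.itertuples(index=False):
        grp = groups.setdefault(row.group_id, OrthologGroup(row.group_id, {}))
        grp.members.setdefault(row.genome_id, []).append(row.gene_id)
    return groups


def write_ortholog_table(groups: Iterable[OrthologGroup], path: str | Path) -> None:
    rows = [
        {"group_id": grp.group_id, "genome_id": genome, "gene_id": gid}
        for grp in groups
        for genome, ids in sorted(grp.members.items())
        for gid in ids
    ]
    pd.DataFrame(rows, columns=["group_id", "genome_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Operon prediction


def predict_operons(
    genome: GenomeAnnotation,
    max_gap: int = 100,
    require_same_strand: bool = True,
) -> list[Operon]:
    """Chain adjacent genes into operons.

    Adjacent genes on the same contig and (by default) the same strand whose
    intergenic gap is at most ``max_gap`` nucleotides are merged transitively.
    Every gene ends up in exactly one operon; isolated genes become singleton
    operons.  For minus-strand operons the gene list is reported in
    transcription order (rightmost gene first) and the promoter anchor is the
    transcription start (the rightmost coordinate).
    """
    operons: list[Operon] = []
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genome.genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    counter = 0
    for contig_id in sorted(by_contig):
        genes = sorted(by_contig[contig_id], key=lambda g: (g.start, g.end))
        run: list[GeneRecord] = []
        for g in genes:
            if run and (
                (require_same_strand and g.strand != run[-1].strand)
                or g.start - run[-1].end > max_gap
            ):
                operons.append(_make_operon(genome.genome_id, contig_id, run, counter))
                counter += 1
                run = []
            run.append(g)
        if run:
            operons.append(_make_operon(genome.genome_id, contig_id, run, counter))
            counter += 1
    return operons


def _make_operon(
    genome_id: str, contig_id: str, genes: list[GeneRecord], idx: int
) -> Operon:
    strand = genes[0].strand
    ordered = genes if strand == "+" else genes[::-1]
    anchor = genes[0].start if strand == "+" else genes[-1].end
    return Operon(
        operon_id=f"{genome_id}.op{idx:04d}",
        genome_id=genome_id,
        contig_id=contig_id,
        gene_ids=[g.gene_id for g in ordered],
        strand=strand,
        promoter_anchor=anchor,
    )


# ---------------------------------------------------------------------------
# Upstream-region extraction


def extract_upstream(
    operon: Operon,
    genome: GenomeAnnotation,
    window: tuple[int, int] = (300, 20),
    truncate_at_neighbor: bool = True,
    operons: Sequence[Operon] | None = None,
    min_length: int = MIN_REGION_LENGTH,
) -> UpstreamRegion | None:
    """Extract the candidate regulatory region upstream of an operon.

    ``window = (upstream_nt, downstream_nt)`` counts from the first gene's
    translation start in transcription orientation.  With
    ``truncate_at_neighbor`` the region is clipped so it never overlaps the
    coding span of the adjacent upstream gene.  Regions shorter than
    ``min_length`` after clipping are dropped (returns None, with a warning).

    When ``operons`` is given, divergently transcribed neighbors whose
    promoter windows overlap the same intergenic segment are cross-linked via
    ``shared_divergent_with``.
    """
    up, down = window
    if up <= 0 or down < 0:
        raise ValueError("window sizes must be positive (upstream) / non-negative")
    contig_len = len(genome.contigs[operon.contig_id])
    first_gene = genome.gene(operon.gene_ids[0])
    truncated = False

    if operon.strand == "+":
        lo, hi = operon.promoter_anchor - up, operon.promoter_anchor + down
        if lo < 0:
            lo, truncated = 0, True
        hi = min(hi, contig_len)
    else:
        lo, hi = operon.promoter_anchor - down, operon.promoter_anchor + up
        if hi > contig_len:
            hi, truncated = contig_len, True
        lo = max(lo, 0)

    if truncate_at_neighbor:
        for g in genome.genes:
            if g.contig_id != operon.contig_id or g.gene_id in operon.gene_ids:
                continue
            if operon.strand == "+" and g.end <= first_gene.start and g.end > lo:
                lo, truncated = g.end, True
            elif operon.strand == "-" and g.start >= first_gene.end and g.start < hi:
                hi, truncated = g.start, True

    if hi - lo < min_length:
        logger.warning(
            "upstream region of %s is %d nt (< %d); skipped",
            operon.operon_id,
            hi - lo,
            min_length,
        )
        return None

    shared = None
    if operons is not None:
        for other in operons:
            if (
                other.operon_id != operon.operon_id
                and other.contig_id == operon.contig_id
                and other.strand != operon.strand
            ):
                o_lo, o_hi = _promoter_interval(other, window, contig_len)
                if max(lo, o_lo) < min(hi, o_hi):
                    shared = other.operon_id
                    break

    return UpstreamRegion(
        operon_id=operon.operon_id,
        genome_id=operon.genome_id,
        contig_id=operon.contig_id,
        sequence=genome.sequence(operon.contig_id, lo, hi, operon.strand),
        interval=(lo, hi),
        strand=operon.strand,
        truncated=truncated,
        shared_divergent_with=shared,
    )


def _promoter_interval(
    operon: Operon, window: tuple[int, int], contig_len: int
) -> tuple[int, int]:
    up, down = window
    if operon.strand == "+":
        return max(0, operon.promoter_anchor - up), min(
            contig_len, operon.promoter_anchor + down
        )
    return max(0, operon.promoter_anchor - down), min(
        contig_len, operon.promoter_anchor + up
    )


def neighborhood_training_set(
    tf_group: OrthologGroup,
    genomes: dict[str, GenomeAnnotation],
    radius_genes: int = 5,
    window: tuple[int, int] = (300, 20),
    max_gap: int = 100,
    operons_by_genome: dict[str, list[Operon]] | None = None,
) -> list[UpstreamRegion]:
    """Upstream regions of operons near a TF ortholog, across genomes.

    For each genome carrying the TF, returns the regions of every operon whose
    gene-rank distance from the TF gene is at most ``radius_genes`` (the TF's
    own operon is at distance 0 — sugar-catabolism TFs are autoregulated, so
    the true site is expected in the training set).  Genomes without the TF
    contribute nothing; if the TF is absent everywhere, raises ValueError.
    """
    if not any(
        tf_group.members.get(gid) for gid in genomes
    ):
        raise ValueError(f"TF group {tf_group.group_id} absent from all genomes")
    regions: list[UpstreamRegion] = []
    for genome_id, genome in genomes.items():
        tf_ids = tf_group.members.get(genome_id, [])
        if not tf_ids:
            continue
        if operons_by_genome is not None and genome_id in operons_by_genome:
            operons = operons_by_genome[genome_id]
        else:
            operons = predict_operons(genome, max_gap=max_gap)
        rank = {
            g.gene_id: i
            for i, g in enumerate(sorted(genome.genes, key=lambda x: (x.contig_id, x.start)))
        }
        selected: list[Operon] = []
        for tf_id in tf_ids:
            tf_rank = rank[tf_id]
            tf_contig = genome.gene(tf_id).contig_id
            for op in operons:
                if op.contig_id != tf_contig or op in selected:
                    continue
                if any(abs(rank[gid] - tf_rank) <= radius_genes for gid in op.gene_ids):
                    selected.append(op)
        for op in selected:
            region = extract_upstream(op, genome, window=window, operons=operons)
            if region is not None:
                regions.append(region)
    return regions
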