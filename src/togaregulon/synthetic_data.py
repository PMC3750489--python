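"""Multi-genome communities with planted motifs, regulons and expression.

The generator emulates the statistical structure the comparative pipeline
assumes: several related "genomes" share ortholog groups; intergenic regions
are i.i.d. background of configurable GC content (default 46%, roughly the
Thermotoga maritima genomic average); each regulon has a ground-truth weight
matrix from which one binding site is sampled column-wise and planted in the
upstream region of every regulated operon in a designated subset of genomes;
the TF gene sits adjacent to one of its regulated operons in every genome
that carries it (sugar TFs are typically encoded inside their cognate loci).
Expression matrices induce regulon genes on their cognate condition with
Gaussian log2 effects and replicate noise.

One top-level seed drives named per-artifact RNG streams (sequences, sites,
expression), so any stage can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from togaregulon.expression_validation import ExpressionMatrix
from togaregulon.genome_model import (
    GeneRecord,
    GenomeAnnotation,
    OrthologGroup,
    write_gene_table,
    write_ortholog_table,
)
from togaregulon.motif_discovery import (
    ALPHABET,
    COMPLEMENT_INDEX,
    MotifProfile,
    decode,
    symmetrize_counts,
)

_STREAMS = ("pwm", "sequences", "sites", "layout", "expression")

CODONS_START = "ATG"
CODONS_STOP = "TAA"


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named RNG stream derived from the top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS.index(name),))
    )


@dataclass
class PlantedSite:
    tf: str
    genome_id: str
    operon_id: str
    offset: int  # 0-based within the upstream region (region orientation)
    strand: str
    sequence: str


@dataclass
class SyntheticTruth:
    """Ground truth for a generated community."""

    profiles: dict[str, MotifProfile]
    sites: list[PlantedSite]
    regulon_members: dict[str, dict[str, list[str]]]
    # tf -> genome_id -> operon ids
    regulon_genes: dict[str, dict[str, list[str]]]
    induced: dict[str, list[str]] = field(default_factory=dict)
    # condition -> gene names with true induction
    true_log2fc: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0
    params: dict = field(default_factory=dict)

    def site_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "tf": s.tf,
                    "genome_id": s.genome_id,
                    "operon_id": s.operon_id,
                    "offset": s.offset,
                    "strand": s.strand,
                    "sequence": s.sequence,
                }
                for s in self.sites
            ]
        )


# ---------------------------------------------------------------------------
# Ground-truth PWM sampling


def sample_pwm(
    L: int,
    target_ic_per_column: float,
    seed: int | np.random.Generator = 0,
    palindrome: bool = False,
    n_pseudo_sites: int = 200,
    tol: float = 0.1,
) -> MotifProfile:
    """Sample a random profile whose mean per-column IC matches a target.

    Columns are drawn from a sparse Dirichlet and each column is sharpened or
    flattened (exponent bisection on the consensus-leaning distribution)
    until its information content equals the target, so the mean per-column
    IC lands within ``tol`` bits of ``target_ic_per_column``.
    """
    if not 0 < target_ic_per_column <= 2:
        raise ValueError("target IC per column must be in (0, 2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pseudocount = 0.25
    cols: list[np.ndarray | None] = [None] * L
    complement = [3, 2, 1, 0]
    for i in range(L):
        if palindrome and cols[L - 1 - i] is not None:
            # mirror-complement of the already-tuned partner column, so the
            # matrix is exactly self-reverse-complementary at full IC
            partner = cols[L - 1 - i]
            cols[i] = partner[complement]
            continue
        base = rng.dirichlet(np.full(4, 0.5))
        if palindrome and i == L - 1 - i:
            # centre column of an odd-width palindrome must pair with
            # itself: enforce f(A)=f(T), f(C)=f(G) before tuning
            base = 0.5 * (base + base[complement])
        cols[i] = _tune_column(base, target_ic_per_column, n_pseudo_sites, pseudocount)
    freqs = np.array(cols).T  # 4 x L
    counts = freqs * n_pseudo_sites
    if palindrome:
        counts = symmetrize_counts(counts)  # exact symmetry despite rounding
    profile = MotifProfile(counts=counts, palindromic=palindrome, profile_id="truth")
    achieved = _mean_ic(profile)
    if abs(achieved - target_ic_per_column) > tol:
        raise RuntimeError("IC tuning failed")  # pragma: no cover
    return profile


def _column_ic(f: np.ndarray) -> float:
    nz = f[f > 0]
    return float(2.0 + (nz * np.log2(nz)).sum())


def _tune_column(
    f: np.ndarray,
    target: float,
    n_sites: int,
    pseudocount: float,
    iters: int = 60,
) -> np.ndarray:
    """Sharpen/flatten a frequency column so its *pseudocounted* IC hits the
    target (the IC measured on the resulting profile, with counts
    ``f * n_sites`` plus the pseudocount)."""
    f = np.clip(f, 1e-9, None)
    f /= f.sum()

    def effective_ic(g: np.ndarray) -> float:
        g = g / g.sum()
        smoothed = (g * n_sites + pseudocount) / (n_sites + 4 * pseudocount)
        return _column_ic(smoothed)

    def sharpen(t: float) -> np.ndarray:
        g = f ** (1.0 + t)
        return g / g.sum()

    if effective_ic(f) >= target:  # flatten instead: mix with uniform
        lo_m, hi_m = 0.0, 1.0
        for _ in range(iters):
            mid = 0.5 * (lo_m + hi_m)
            g = (1 - mid) * f + mid * 0.25
            if effective_ic(g) > target:
                lo_m = mid
            else:
                hi_m = mid
        g = (1 - lo_m) * f + lo_m * 0.25
        return g / g.sum()
    lo, hi = 0.0, 400.0
    if effective_ic(sharpen(hi)) < target:
        # near-degenerate column capped by the pseudocount; return the cap
        return sharpen(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if effective_ic(sharpen(mid)) < target:
            lo = mid
        else:
            hi = mid
    return sharpen(hi)


def _mean_ic(profile: MotifProfile) -> float:
    from togaregulon.motif_discovery import information_content

    per_col, total = information_content(profile)
    return total / profile.width


def sample_site(profile: MotifProfile, rng: np.random.Generator) -> str:
    """Draw one site column-wise from the profile's frequencies."""
    f = profile.frequencies
    return decode(
        np.array([rng.choice(4, p=f[:, i] / f[:, i].sum()) for i in range(profile.width)])
    )


def generate_planted_regions(
    n_regions: int = 10,
    length: int = 240,
    motif_len: int = 17,
    target_ic: float = 1.2,
    palindrome: bool = False,
    background_gc: float = 0.46,
    seed: int = 0,
):
    """Background regions with exactly one planted motif instance each.

    The single-motif benchmark: returns (regions, truth_profile, planted)
    where ``planted`` maps region operon_id -> (offset, strand, sequence).
    Sites are placed on a random strand at a uniform-random offset.
    """
    from togaregulon.genome_model import UpstreamRegion

    rng_pwm = _stream(seed, "pwm")
    rng_seq = _stream(seed, "sequences")
    rng_sites = _stream(seed, "sites")
    profile = sample_pwm(motif_len, target_ic, seed=rng_pwm, palindrome=palindrome)
    regions = []
    planted: dict[str, tuple[int, str, str]] = {}
    for i in range(n_regions):
        seq = _random_dna(rng_seq, length, background_gc)
        site = sample_site(profile, rng_sites)
        off = int(rng_sites.integers(0, length - motif_len + 1))
        strand = "+" if rng_sites.random() < 0.5 else "-"
        placed = site if strand == "+" else _revcomp(site)
        seq = seq[:off] + placed + seq[off + motif_len :]
        region_id = f"r{i:02d}"
        regions.append(
            UpstreamRegion(
                operon_id=region_id,
                genome_id="sim",
                contig_id="sim",
                sequence=seq,
                interval=(0, length),
                strand="+",
            )
        )
        planted[region_id] = (off, strand, site)
    return regions, profile, planted


# ---------------------------------------------------------------------------
# Community generation


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=n, p=p))


def _coding_sequence(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    body = _random_dna(rng, 3 * (n_codons - 2), gc)
    return CODONS_START + body + CODONS_STOP


@dataclass
class CommunityFiles:
    """Paths of everything written by :func:`generate_community`."""

    out_dir: Path
    fasta: dict[str, Path]
    gene_tables: dict[str, Path]
    ortholog_table: Path
    truth_sites: Path


def generate_community(
    n_genomes: int = 5,
    n_ortholog_groups: int = 40,
    regulon_design: list[tuple[str, int, int]] | None = None,
    background_gc: float = 0.46,
    intergenic_len: int = 250,
    motif_len: int = 17,
    target_ic: float = 1.2,
    gene_codons: int = 100,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, GenomeAnnotation], dict[str, OrthologGroup], SyntheticTruth]:
    """Generate a community of related genomes with planted regulons.

    ``regulon_design`` lists (tf_name, n_operons, n_genomes_with_regulon);
    default: 3 regulons of 6 operons each, planted in at least 3 genomes.
    Each genome is one contig: ortholog-group genes laid out in a fixed
    order, one gene per group per genome, separated by intergenic spacers of
    ``intergenic_len`` nt.  Regulated operons of a TF get exactly one site
    sampled from the TF's ground-truth profile planted at a uniform-random
    offset in their upstream spacer in the designated genomes; the TF gene of
    each regulon is placed immediately next to one of its regulated operons.

    With ``out_dir`` set, FASTA + gene-table TSVs per genome, the ortholog
    table, and the truth site table are also written (byte-identical for a
    fixed seed).
    """
    if regulon_design is None:
        regulon_design = [("tfA", 6, 4), ("tfB", 6, 4), ("tfC", 6, 3)]
    if intergenic_len < motif_len + 10:
        raise ValueError("intergenic_len must be at least motif length + 10")
    n_regulated = sum(n_ops for _, n_ops, _ in regulon_design)
    n_tfs = len(regulon_design)
    if n_regulated + n_tfs > n_ortholog_groups:
        raise ValueError("regulon operons + TFs exceed ortholog groups")

    rng_pwm = _stream(seed, "pwm")
    rng_seq = _stream(seed, "sequences")
    rng_sites = _stream(seed, "sites")
    rng_layout = _stream(seed, "layout")

    genome_ids = [f"g{i+1}" for i in range(n_genomes)]

    profiles: dict[str, MotifProfile] = {}
    tf_genomes: dict[str, list[str]] = {}
    regulon_groups: dict[str, list[str]] = {}
    group_names = [f"og{i:03d}" for i in range(n_ortholog_groups)]
    cursor = 0
    tf_group_of: dict[str, str] = {}
    for tf, n_ops, n_gen in regulon_design:
        profiles[tf] = sample_pwm(motif_len, target_ic, seed=rng_pwm)
        profiles[tf].profile_id = tf
        chosen = sorted(
            rng_layout.choice(n_genomes, size=n_gen, replace=False).tolist()
        )
        tf_genomes[tf] = [genome_ids[i] for i in chosen]
        regulon_groups[tf] = group_names[cursor : cursor + n_ops]
        cursor += n_ops
        tf_group_of[tf] = group_names[cursor]
        cursor += 1
    background_groups = group_names[cursor:]

    # Gene layout per genome: for each TF, its regulated groups with the TF
    # gene inserted next to the first one; then background groups.
    genomes: dict[str, GenomeAnnotation] = {}
    orthologs: dict[str, OrthologGroup] = {
        name: OrthologGroup(name, {}) for name in group_names
    }
    truth_sites: list[PlantedSite] = []
    regulon_members: dict[str, dict[str, list[str]]] = {tf: {} for tf, _, _ in regulon_design}
    regulon_genes: dict[str, dict[str, list[str]]] = {tf: {} for tf, _, _ in regulon_design}

    # Background buffers between regulon blocks keep the gene-rank
    # neighborhoods of different TFs disjoint.
    n_buffer = min(4, len(background_groups) // max(1, len(regulon_design)))

    for genome_id in genome_ids:
        order: list[tuple[str, str]] = []  # (group, tf-if-site-planted or "")
        bg_iter = iter(background_groups)
        for tf, n_ops, _ in regulon_design:
            carries = genome_id in tf_genomes[tf]
            groups = regulon_groups[tf]
            half = len(groups) // 2
            # TF gene sits in the middle of its regulated locus (present
            # only in genomes that carry the TF ortholog)
            for grp in groups[:half]:
                order.append((grp, tf if carries else ""))
            if carries:
                order.append((tf_group_of[tf], ""))
            for grp in groups[half:]:
                order.append((grp, tf if carries else ""))
            for _ in range(n_buffer):
                nxt = next(bg_iter, None)
                if nxt is not None:
                    order.append((nxt, ""))
        for grp in bg_iter:
            order.append((grp, ""))

        seq_parts: list[str] = []
        genes: list[GeneRecord] = []
        pos = 0
        op_counter = 0
        for grp, planted_tf in order:
            spacer = _random_dna(rng_seq, intergenic_len, background_gc)
            if planted_tf:
                site = sample_site(profiles[planted_tf], rng_sites)
                # keep the site inside the default (300, 20) scan window and
                # clear of the downstream gene start
                off = int(rng_sites.integers(0, intergenic_len - motif_len - 5))
                strand = "+" if rng_sites.random() < 0.5 else "-"
                placed = site if strand == "+" else _revcomp(site)
                spacer = spacer[:off] + placed + spacer[off + motif_len :]
            seq_parts.append(spacer)
            pos += len(spacer)
            cds = _coding_sequence(rng_seq, gene_codons, background_gc)
            gene_id = f"{genome_id}_{grp}"
            gene = GeneRecord(
                gene_id=gene_id,
                genome_id=genome_id,
                contig_id=f"{genome_id}_c1",
                start=pos,
                end=pos + len(cds),
                strand="+",
                name=grp,
                role="TF" if grp in tf_group_of.values() else "other",
                pathway="",
            )
            genes.append(gene)
            orthologs[grp].members.setdefault(genome_id, []).append(gene_id)
            operon_id = f"{genome_id}.op{op_counter:04d}"
            if planted_tf:
                # upstream region orientation == + strand here; offset within
                # the default window (300, 20): region covers
                # [gene_start-300, gene_start+20); spacer is the 250 nt just
                # before the gene, so region offset = off + (300 - 250)... but
                # regions are neighbor-truncated to the spacer itself, making
                # the planted offset equal to `off` directly.
                truth_sites.append(
                    PlantedSite(
                        tf=planted_tf,
                        genome_id=genome_id,
                        operon_id=operon_id,
                        offset=off,
                        strand=strand,
                        sequence=site,
                    )
                )
                regulon_members[planted_tf].setdefault(genome_id, []).append(operon_id)
                regulon_genes[planted_tf].setdefault(genome_id, []).append(gene_id)
            seq_parts.append(cds)
            pos += len(cds)
            op_counter += 1
        seq_parts.append(_random_dna(rng_seq, intergenic_len, background_gc))
        contig = "".join(seq_parts)
        genomes[genome_id] = GenomeAnnotation(
            genome_id=genome_id,
            contigs={f"{genome_id}_c1": contig},
            genes=genes,
        )

    truth = SyntheticTruth(
        profiles=profiles,
        sites=truth_sites,
        regulon_members=regulon_members,
        regulon_genes=regulon_genes,
        seed=seed,
        params={
            "n_genomes": n_genomes,
            "n_ortholog_groups": n_ortholog_groups,
            "regulon_design": regulon_design,
            "background_gc": background_gc,
            "intergenic_len": intergenic_len,
            "motif_len": motif_len,
            "target_ic": target_ic,
            "tf_group_of": tf_group_of,
        },
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for genome_id, genome in genomes.items():
            with open(out / f"{genome_id}.fna", "w") as fh:
                for contig_id, seq in genome.contigs.items():
                    fh.write(f">{contig_id}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i : i + 70] + "\n")
            write_gene_table(genome, out / f"{genome_id}.genes.tsv")
        write_ortholog_table(orthologs.values(), out / "orthologs.tsv")
        truth.site_table().to_csv(out / "truth_sites.tsv", sep="\t", index=False)

    return genomes, orthologs, truth


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Expression generation


def generate_expression(
    truth: SyntheticTruth,
    conditions: list[str] | None = None,
    reference: str = "ribose",
    mu_log2fc: float = 4.0,
    sigma: float = 0.3,
    baseline_mu: float = 8.0,
    baseline_sigma: float = 1.0,
    n_replicates: int = 2,
    genome_id: str | None = None,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Simulate a log2 expression matrix for one genome of the community.

    Each TF's regulon genes are induced on that TF's cognate condition
    (condition name = TF name unless ``conditions`` maps otherwise) by a
    per-gene shift drawn from Normal(mu_log2fc, sigma); all samples add
    independent replicate noise of the same sigma.  The reference condition
    induces nothing.
    """
    rng = _stream(seed if seed is not None else truth.seed, "expression")
    tfs = list(truth.regulon_genes)
    if conditions is None:
        conditions = [reference] + tfs
    if reference not in conditions:
        raise ValueError("conditions must include the reference")
    if genome_id is None:
        genome_id = next(
            iter(next(iter(truth.regulon_genes.values())).keys())
        )
    genes = sorted(
        {
            g
            for tf in tfs
            for g in truth.regulon_genes[tf].get(genome_id, [])
        }
    )
    # add unregulated background genes from the same genome
    n_background = truth.params.get("n_ortholog_groups", 40)
    background = [
        f"{genome_id}_og{i:03d}"
        for i in range(n_background)
        if f"{genome_id}_og{i:03d}" not in genes
    ]
    all_genes = genes + background
    baseline = rng.normal(baseline_mu, baseline_sigma, size=len(all_genes))
    data = {}
    for cond in conditions:
        shift = np.zeros(len(all_genes))
        if cond in truth.regulon_genes:
            member = set(truth.regulon_genes[cond].get(genome_id, []))
            idx = [i for i, g in enumerate(all_genes) if g in member]
            shift[idx] = rng.normal(mu_log2fc, sigma, size=len(idx))
            for i in idx:
                truth.true_log2fc[(cond, all_genes[i])] = float(shift[i])
            truth.induced[cond] = [all_genes[i] for i in idx]
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, sigma, size=len(all_genes))
            data[f"{cond}_{rep}"] = baseline + shift + noise
    df = pd.DataFrame(data, index=all_genes)
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# Recovery metrics


def recovery_metrics(
    predicted_sites: list,
    predicted_genes: dict[str, list[str]] | set,
    truth: SyntheticTruth,
    tf: str | None = None,
    offset_tolerance: int = 1,
) -> dict[str, float | None]:
    """Site- and gene-level precision/recall of predictions against truth.

    A predicted site matches a planted one when it is in the same operon and
    within ``offset_tolerance`` of the planted offset, either strand.  Gene
    sets are compared as (genome, gene) pairs.  Empty prediction sets give
    recall 0 and precision None (reported as NA).
    """
    tfs = [tf] if tf else list(truth.regulon_members)
    true_sites = {
        (s.genome_id, s.operon_id, s.offset)
        for s in truth.sites
        if s.tf in tfs
    }
    pred_sites = set()
    for h in predicted_sites:
        pred_sites.add((h.genome_id, h.operon_id, h.offset))
    matched_true = set()
    matched_pred = set()
    for p in pred_sites:
        for t in true_sites:
            if (
                p[0] == t[0]
                and p[1] == t[1]
                and abs(p[2] - t[2]) <= offset_tolerance
            ):
                matched_true.add(t)
                matched_pred.add(p)
    site_precision = len(matched_pred) / len(pred_sites) if pred_sites else None
    site_recall = len(matched_true) / len(true_sites) if true_sites else None

    true_genes = {
        (genome_id, g)
        for t in tfs
        for genome_id, gids in truth.regulon_genes[t].items()
        for g in gids
    }
    if isinstance(predicted_genes, dict):
        pred_genes = {
            (genome_id, g)
            for genome_id, gids in predicted_genes.items()
            for g in gids
        }
    else:
        pred_genes = set(predicted_genes)
    tp = len(pred_genes & true_genes)
    gene_precision = tp / len(pred_genes) if pred_genes else None
    gene_recall = tp / len(true_genes) if true_genes else None
    return {
        "site_precision": site_precision,
        "site_recall": site_recall,
        "gene_precision": gene_precision,
        "gene_recall": gene_recall,
    }
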