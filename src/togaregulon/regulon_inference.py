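"""Cross-genome regulon assembly: propagation, conservation filter, refinement.

The comparative step is what separates regulon reconstruction from plain
motif scanning: a candidate site upstream of an operon counts as a regulatory
interaction only when orthologous operons in other genomes that also carry
the TF have passing sites.  Spurious single-genome hits are thereby
discarded, and genuinely conserved interactions survive even when one genome
has lost the TF (such genomes never vote).

Refinement follows the standard bootstrap: accepted sites join the training
set, the profile is rebuilt and the threshold reset, and scanning repeats
until the accepted site set is stable (a fixed point) or ``max_iter`` is hit.
Original training sites are never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from togaregulon.genome_model import GenomeAnnotation, Operon, OrthologGroup
from togaregulon.motif_discovery import MotifProfile, SiteInstance, build_pwm
from togaregulon.site_scan import ScanHit, scan_genome, set_threshold

logger = logging.getLogger(__name__)


@dataclass
class CandidateInteraction:
    """A TF -> target-ortholog-group interaction across genomes.

    ``support`` counts genomes with a passing hit among those that carry both
    the TF ortholog and the target ortholog; genomes lacking the TF may still
    contribute hits (recorded) but never support.
    """

    tf_group_id: str
    target_group_id: str
    best_hit_per_genome: dict[str, ScanHit] = field(default_factory=dict)
    operon_per_genome: dict[str, str] = field(default_factory=dict)
    support: int = 0


@dataclass
class RegulonModel:
    """A reconstructed regulon: profile plus per-genome members."""

    tf_group_id: str
    profile: MotifProfile
    members: dict[str, list[tuple[str, ScanHit]]] = field(default_factory=dict)
    # genome_id -> list of (operon_id, best site)
    genes: dict[str, list[str]] = field(default_factory=dict)
    operon_genes: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    effector: str | None = None
    iteration_count: int = 0
    converged: bool = True


def default_k_min(n_genomes_with_tf: int) -> int:
    """Conservation cutoff: 2 when at most 4 genomes carry the TF, else 3."""
    return 2 if n_genomes_with_tf <= 4 else 3


def propagate(
    profile: MotifProfile,
    genomes: dict[str, GenomeAnnotation],
    orthologs: dict[str, OrthologGroup],
    operons_by_genome: dict[str, list[Operon]],
    tf_group_id: str,
    window: tuple[int, int] = (300, 20),
) -> list[CandidateInteraction]:
    """Scan every genome and group passing hits by target ortholog group.

    The best (max-score) passing hit per operon represents that operon; hits
    are then aggregated across genomes through the ortholog table of the
    operons' first genes.  Support counts only genomes carrying the TF.
    """
    tf_group = orthologs[tf_group_id]
    tf_genomes = tf_group.genomes()

    # map gene_id -> ortholog group per genome
    gene_to_group: dict[tuple[str, str], str] = {}
    for grp in orthologs.values():
        for genome_id, gene_ids in grp.members.items():
            for gid in gene_ids:
                gene_to_group[(genome_id, gid)] = grp.group_id

    candidates: dict[str, CandidateInteraction] = {}
    for genome_id, genome in genomes.items():
        operons = operons_by_genome[genome_id]
        hits_by_operon = scan_genome(profile, genome, operons, window=window)
        op_by_id = {op.operon_id: op for op in operons}
        for operon_id, hits in hits_by_operon.items():
            passing = [h for h in hits if h.passed_threshold]
            if not passing:
                continue
            best = max(passing, key=lambda h: h.score)
            op = op_by_id[operon_id]
            # target group: ortholog group of the operon's first gene (lead
            # gene defines the orthologous transcription unit)
            groups = {
                gene_to_group.get((genome_id, gid)) for gid in op.gene_ids
            } - {None}
            for group_id in sorted(g for g in groups if g is not None):
                cand = candidates.setdefault(
                    group_id,
                    CandidateInteraction(tf_group_id=tf_group_id, target_group_id=group_id),
                )
                prev = cand.best_hit_per_genome.get(genome_id)
                if prev is None or best.score > prev.score:
                    cand.best_hit_per_genome[genome_id] = best
                    cand.operon_per_genome[genome_id] = operon_id
    for cand in candidates.values():
        cand.support = sum(
            1 for genome_id in cand.best_hit_per_genome if genome_id in tf_genomes
        )
    return sorted(candidates.values(), key=lambda c: c.target_group_id)


def consistency_filter(
    candidates: list[CandidateInteraction], k_min: int = 2
) -> list[CandidateInteraction]:
    """Keep interactions supported by at least ``k_min`` TF-carrying genomes."""
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    return [c for c in candidates if c.support >= k_min]


def _accepted_site_keys(accepted: list[CandidateInteraction]) -> set[tuple]:
    keys = set()
    for cand in accepted:
        for genome_id, hit in cand.best_hit_per_genome.items():
            keys.add((genome_id, hit.operon_id, hit.offset, hit.strand))
    return keys


def iterate_refinement(
    profile: MotifProfile,
    genomes: dict[str, GenomeAnnotation],
    orthologs: dict[str, OrthologGroup],
    operons_by_genome: dict[str, list[Operon]],
    tf_group_id: str,
    k_min: int | None = None,
    max_iter: int = 10,
    window: tuple[int, int] = (300, 20),
    effector: str | None = None,
) -> RegulonModel:
    """Iteratively rebuild the profile from accepted conserved sites.

    Each round scans, filters by conservation, adds accepted site sequences
    to the training set (original training sites are always retained),
    rebuilds the count matrix and resets the threshold.  Stops at a fixed
    point of the accepted site set; if ``max_iter`` rounds pass without one,
    the last model is returned with ``converged=False`` and a warning.
    """
    if np.isnan(profile.threshold):
        set_threshold(profile)
    tf_group = orthologs[tf_group_id]
    if k_min is None:
        k_min = default_k_min(len(tf_group.genomes()))

    original = list(profile.training_sites)
    original_sites = [s.sequence for s in original]
    current = profile
    # fixed point: the accepted site set stops changing; start from the
    # original training sites so a scan that adds nothing converges at once
    prev_keys: set[tuple] = {
        (s.genome_id, s.operon_id, s.offset, s.strand_relative) for s in original
    }
    accepted: list[CandidateInteraction] = []
    iteration = 0
    converged = False
    while iteration < max_iter:
        iteration += 1
        candidates = propagate(
            current, genomes, orthologs, operons_by_genome, tf_group_id, window=window
        )
        accepted = consistency_filter(candidates, k_min=k_min)
        keys = _accepted_site_keys(accepted)
        if keys == prev_keys:
            converged = True
            break
        prev_keys = keys
        accepted_hits = {
            (genome_id, hit.operon_id, hit.offset, hit.strand): hit
            for cand in accepted
            for genome_id, hit in cand.best_hit_per_genome.items()
        }
        new_sites = [
            SiteInstance(
                operon_id=hit.operon_id,
                genome_id=genome_id,
                offset=hit.offset,
                strand_relative=hit.strand,
                sequence=hit.sequence,
                score=hit.score,
            )
            for (genome_id, *_), hit in sorted(accepted_hits.items())
            if hit.sequence not in original_sites
        ]
        training = original_sites + [s.sequence for s in new_sites]
        rebuilt = build_pwm(
            training,
            background=current.background,
            pseudocount=current.pseudocount,
            palindromic=current.palindromic,
            profile_id=current.profile_id,
        )
        rebuilt.training_sites = original + new_sites
        set_threshold(rebuilt, training)
        current = rebuilt
    if not converged:
        logger.warning(
            "refinement of %s did not reach a fixed point in %d iterations",
            tf_group_id,
            max_iter,
        )

    model = RegulonModel(
        tf_group_id=tf_group_id,
        profile=current,
        effector=effector,
        iteration_count=iteration,
        converged=converged,
    )
    for cand in accepted:
        for genome_id, hit in cand.best_hit_per_genome.items():
            model.members.setdefault(genome_id, []).append((hit.operon_id, hit))
    op_index = {
        (genome_id, op.operon_id): op
        for genome_id, ops in operons_by_genome.items()
        for op in ops
    }
    for genome_id, pairs in model.members.items():
        genes: list[str] = []
        for operon_id, _ in pairs:
            op_genes = op_index[(genome_id, operon_id)].gene_ids
            model.operon_genes[(genome_id, operon_id)] = list(op_genes)
            genes.extend(op_genes)
        model.genes[genome_id] = sorted(set(genes))  # count each gene once
    return model


def summarize(
    regulons: list[RegulonModel],
    genomes: dict[str, GenomeAnnotation] | None = None,
) -> pd.DataFrame:
    """Per-TF summary: regulated operons, sites, genes, and role breakdown.

    Gene roles come from the genome annotations when given.  The final row
    holds totals; genes regulated by two TFs count once in the total gene
    column (deduplicated by (genome, gene_id)).
    """
    rows = []
    all_genes: set[tuple[str, str]] = set()
    role_of: dict[tuple[str, str], str] = {}
    if genomes:
        for genome_id, genome in genomes.items():
            for g in genome.genes:
                role_of[(genome_id, g.gene_id)] = g.role
    total_sites = 0
    for model in regulons:
        n_operons = sum(len(v) for v in model.members.values())
        genes = {
            (genome_id, gid)
            for genome_id, gids in model.genes.items()
            for gid in gids
        }
        all_genes |= genes
        roles = [role_of.get(key, "other") for key in genes]
        n_sites = n_operons  # one best site per member operon
        total_sites += n_sites
        rows.append(
            {
                "tf_group": model.tf_group_id,
                "n_genomes": len(model.members),
                "n_operons": n_operons,
                "n_sites": n_sites,
                "n_genes": len(genes),
                "n_enzymes": roles.count("enzyme"),
                "n_transporters": roles.count("transporter"),
                "n_TFs": roles.count("TF"),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "tf_group",
            "n_genomes",
            "n_operons",
            "n_sites",
            "n_genes",
            "n_enzymes",
            "n_transporters",
            "n_TFs",
        ],
    )
    totals = {
        "tf_group": "TOTAL",
        "n_genomes": 0,
        "n_operons": int(df["n_operons"].sum()) if len(df) else 0,
        "n_sites": total_sites,
        "n_genes": len(all_genes),
        "n_enzymes": sum(1 for k in all_genes if role_of.get(k) == "enzyme"),
        "n_transporters": sum(1 for k in all_genes if role_of.get(k) == "transporter"),
        "n_TFs": sum(1 for k in all_genes if role_of.get(k) == "TF"),
    }
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


def regulon_table(model: RegulonModel) -> pd.DataFrame:
    """Flat per-gene output table for one regulon."""
    rows = []
    for genome_id, pairs in sorted(model.members.items()):
        for operon_id, hit in pairs:
            for gid in model.operon_genes.get((genome_id, operon_id), []):
                rows.append(
                    {
                        "tf_group": model.tf_group_id,
                        "genome": genome_id,
                        "operon": operon_id,
                        "gene": gid,
                        "site_sequence": hit.sequence,
                        "score": round(hit.score, 4),
                    }
                )
    return pd.DataFrame(
        rows, columns=["tf_group", "genome", "operon", "gene", "site_sequence", "score"]
    )
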