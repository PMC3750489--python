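"""End-to-end reconstruction driver: neighborhoods -> motif -> regulon.

Glue over the stage modules, mainly for benchmarks and the CLI; each step is
available individually for custom workflows.
"""

from __future__ import annotations

from dataclasses import dataclass

from togaregulon.genome_model import (
    GenomeAnnotation,
    Operon,
    OrthologGroup,
    neighborhood_training_set,
    predict_operons,
)
from togaregulon.motif_discovery import MotifProfile, discover_profile
from togaregulon.regulon_inference import RegulonModel, iterate_refinement
from togaregulon.site_scan import set_threshold


@dataclass
class ReconstructionResult:
    tf_group_id: str
    model: RegulonModel
    n_training_regions: int


def reconstruct_regulon(
    tf_group_id: str,
    genomes: dict[str, GenomeAnnotation],
    orthologs: dict[str, OrthologGroup],
    motif_length: int = 17,
    radius_genes: int = 4,
    symmetry: str = "none",
    n_restarts: int = 10,
    seed: int = 0,
    k_min: int | None = None,
    max_iter: int = 10,
    window: tuple[int, int] = (300, 20),
    operons_by_genome: dict[str, list[Operon]] | None = None,
    zoops: bool = True,
    effector: str | None = None,
) -> ReconstructionResult:
    """Run the full reconstruction for one TF ortholog group.

    Training regions come from the TF's gene neighborhoods; discovery runs in
    zero-or-one-occurrence mode by default because not every neighborhood
    operon is regulated; the threshold is the minimum training-site score;
    propagation, conservation filtering and profile refinement then assemble
    the cross-genome regulon model.
    """
    if operons_by_genome is None:
        operons_by_genome = {g: predict_operons(gen) for g, gen in genomes.items()}
    regions = neighborhood_training_set(
        orthologs[tf_group_id],
        genomes,
        radius_genes=radius_genes,
        window=window,
        operons_by_genome=operons_by_genome,
    )
    profile, sites = discover_profile(
        regions,
        L=motif_length,
        symmetry=symmetry,
        n_restarts=n_restarts,
        seed=seed,
        zoops=zoops,
        profile_id=tf_group_id,
    )
    set_threshold(profile)
    model = iterate_refinement(
        profile,
        genomes,
        orthologs,
        operons_by_genome,
        tf_group_id,
        k_min=k_min,
        max_iter=max_iter,
        window=window,
        effector=effector,
    )
    return ReconstructionResult(
        tf_group_id=tf_group_id, model=model, n_training_regions=len(regions)
    )
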