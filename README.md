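# togaregulon

Comparative-genomics reconstruction of bacterial transcription-factor (TF)
regulons, modelled on the workflow used to map the carbohydrate-utilization
regulatory network of *Thermotoga maritima* and ten related Thermotogales
genomes.

Regulatory annotation of non-model bacteria cannot rely on experiments gene
by gene. The comparative approach leverages a group of related genomes: a TF
ortholog's gene neighborhood supplies an initial training set of candidate
regulated operons; a shared DNA motif discovered in their upstream regions
yields a positional weight matrix (PWM); genomes are scanned with the
additive score

    S(site) = Σᵢ w(bᵢ, i),   w(b, i) = log₂[(n(b,i) + p) / ((N + 4p)·q(b))]

using the **lowest training-set score** as the detection threshold; and a
candidate interaction enters the regulon only when passing sites occur
upstream of orthologous operons in multiple genomes that carry the TF.
Accepted sites are fed back into the training set and the profile rebuilt to
a fixed point. Reconstructed regulons are then checked against
condition-specific expression (fold change vs a reference sugar, induction
when FC > 2, hypergeometric enrichment with BH correction).

The package is aimed at microbial comparative genomicists and at method
developers who need a fully controllable benchmark: a synthetic-data module
generates multi-genome communities with motifs planted from known PWMs,
regulon memberships and induced expression, so every pipeline stage can be
scored against ground truth. A packaged catalog transcribes the published
*T. maritima* network inventory (pathways, regulons, sites, TF presence
across 11 genomes) and recomputes its headline numbers.

## Worked example

Reconstruct one planted regulon from a synthetic 5-genome community:

```python
from togaregulon.genome_model import predict_operons
from togaregulon.pipeline import reconstruct_regulon
from togaregulon.synthetic_data import generate_community, recovery_metrics

genomes, orthologs, truth = generate_community(seed=2)   # 5 genomes, 3 regulons
operons = {g: predict_operons(gen) for g, gen in genomes.items()}

tf_group = truth.params["tf_group_of"]["tfA"]
result = reconstruct_regulon(tf_group, genomes, orthologs,
                             seed=2, operons_by_genome=operons)
model = result.model
print("consensus :", model.profile.consensus())
print("threshold :", round(model.profile.threshold, 4))
print("iterations:", model.iteration_count, "converged:", model.converged)
hits = [h for pairs in model.members.values() for _, h in pairs]
print("members   :", {g: len(ops) for g, ops in model.members.items()})
print(recovery_metrics(hits, model.genes, truth, tf="tfA"))
```

Output:

```
consensus : CTCAGCTGGCTATTTGT
threshold : 14.162
iterations: 2 converged: True
members   : {'g1': 6, 'g2': 6, 'g3': 6, 'g4': 6}
{'site_precision': 1.0, 'site_recall': 1.0, 'gene_precision': 1.0, 'gene_recall': 1.0}
```

The regulon was planted in four of the five genomes; the pipeline discovered
the motif in the TF's gene neighborhoods, set the threshold at the weakest
training site (14.16 bits), and the conservation filter returned exactly the
24 planted operons — site- and gene-level precision and recall of 1.0
against the generator's truth table.

The packaged catalog is available from the command line:

```
togaregulon fixtures --check     # consistency report of the printed totals
togaregulon simulate --genomes 5 --regulons 3 --ic 1.2 --seed 42 --out sim/
togaregulon discover --regions regions.fasta -L 17 --restarts 20 --seed 7 --out motif.meme
```

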