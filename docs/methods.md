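# Methods

## The reconstruction procedure

`togaregulon` implements the comparative-genomics workflow for inferring
transcription-factor (TF) regulons in a group of closely related bacterial
genomes, of the kind used to map the sugar-catabolism regulatory network of
*Thermotoga maritima* and ten related Thermotogales genomes. The procedure
has five stages.

**1. Training-set assembly by gene-neighborhood analysis.** Bacterial
sugar-catabolism TFs are almost always encoded inside the gene loci they
control and are autoregulated, so the initial candidates for regulated
operons are the operons within a small gene-rank radius of each TF ortholog
(default radius 4 genes, including the TF's own operon). Operons are
predicted by the standard distance heuristic: adjacent same-strand genes with
intergenic gaps ≤ `max_gap` (default 100 nt) chain transitively. Upstream
regions span 300 nt upstream to 20 nt downstream of the first gene's start
(in transcription orientation), truncated so they never overlap the upstream
neighbor's coding span; regions shorter than 30 nt after truncation are
dropped with a warning. Divergently transcribed operon pairs whose windows
overlap a shared intergenic segment cross-reference each other, since one
operator there can control both. The window and gap defaults are
field-standard values for bacterial regulatory scans, not published
parameters of any specific study; both are configurable.

**2. Motif discovery.** A shared width-L motif is sought under the
one-occurrence-per-sequence model by Gibbs site sampling: each region's site
is resampled from the profile built from all other regions' sites, with a
deterministic hill-climbing second phase and `n_restarts` independent
restarts (default 20); the alignment with the highest total information
content wins. Both strands are always scored, because binding sites have no
preferred orientation relative to the downstream gene. A zero-or-one
occurrence mode handles the fact that not every neighborhood operon is
regulated: during the deterministic phase a region keeps no site when its
best window's log-odds score does not beat the uniform site-position prior,
`log2(2 · #windows)`; in that mode the restart objective is the alignment's
total log-likelihood ratio against background minus that prior per included
site, so alignments of different sizes compare fairly. Palindrome mode
(homodimeric repressor sites) symmetrises the count matrix with its
reverse-complement mirror, making weights satisfy
`w(b, i) = w(complement(b), L−1−i)`.

**3. Scoring and threshold.** Positional weights are log2 odds with a
per-base pseudocount p = 0.25:

    w(b, i) = log2[(n(b,i) + p) / ((N + 4p) · q(b))]

with N training sites and background mononucleotide probabilities q (uniform
for the synthetic benchmarks; genome-wide frequencies for real scans). A
candidate site's score is the sum of the weights of its bases. Any monotone
transform of the column frequencies preserves hit ranking; this particular
form is pinned down so thresholds are reproducible. The detection threshold
is deliberately non-statistical: **the lowest score observed among the
training sites**, so every training site passes by construction and no
p-value calibration is involved. Scanning enumerates every window of both
strands of every operon's upstream region; for palindromic profiles the
strand-mirror duplicate of each hit is collapsed.

**4. Cross-genome conservation filter and refinement.** Per-operon best hits
are grouped into candidate interactions through the ortholog table (the
operon's genes vote for their ortholog groups). An interaction's *support*
is the number of genomes with a passing hit **among genomes carrying the TF
ortholog** — a genome that lost the TF can contribute hits but never support
and never blocks acceptance. Interactions with support ≥ `k_min` are
accepted (default: 2 when at most 4 genomes carry the TF, else 3; the
conservation requirement in the source workflow is qualitative, so the
default is explicit and configurable). Refinement then loops: accepted sites
join the training set (original training sites are never dropped), the count
matrix is rebuilt, the threshold is reset to the new minimum training score,
and scanning repeats until the accepted site set reaches a fixed point or
`max_iter` (default 10) rounds pass; non-convergence returns the last model
with a warning flag. Because the threshold is a minimum over a growing set,
recall is non-decreasing over iterations in practice; this is exercised
directly in the tests.

**5. Expression concordance.** Validation mirrors carbon-source shift
experiments: log2 expression, replicates combined by the mean of log2 values
(median available), fold change of each test sugar against a reference sugar
and induction when the linear fold change strictly exceeds 2 (a gene at
exactly 2.0 is not induced). Genes missing from the matrix (absent probes)
are carried as `missing`, reported per regulon, and never imputed.
Regulon-level concordance — which the source experiments assessed
qualitatively — is formalised here as an upper-tail hypergeometric
enrichment of the induced set in each regulon, with Benjamini–Hochberg
correction across the regulons in one run (q < 0.05); reports flag this
statistic as a formalisation of the published ">2-fold correlates with the
regulon" argument, not a reproduction of it.

## The synthetic-data generator

The generator provides ground truth for every stage. A community of
`n_genomes` single-contig genomes shares `n_ortholog_groups` ortholog
groups, one gene per group per genome, separated by i.i.d. intergenic
spacers (default 250 nt, GC 46% — roughly the *T. maritima* genomic
average). Each regulon has a ground-truth PWM sampled from sparse Dirichlet
columns that are sharpened or flattened by bisection until the per-column
information content (measured with the same pseudocount convention the
pipeline uses) hits the target (default 1.2 bits/column — a realistic,
deliberately non-trivial motif strength); palindromic truth matrices are
built mirror-symmetric column by column. One site is sampled column-wise
from the PWM per regulated operon and planted at a uniform-random offset on
a random strand in the upstream spacer, in the designated subset of genomes.
The TF gene sits in the middle of its regulated locus, only in genomes that
carry it, and background buffer groups separate regulon blocks so the
gene-rank neighborhoods of different TFs stay disjoint. Expression matrices
draw per-gene baselines from Normal(8, 1) log2 units, induce each TF's
regulon genes on that TF's cognate condition by Normal(4, 0.3) (the
magnitude of strongly induced catabolic operons in sugar-shift experiments),
and add independent Normal(0, 0.3) replicate noise to every sample (two
replicates by default, matching the common biological-duplicate design). One
top-level seed drives named RNG streams per artifact (PWMs, sequences, site
placement, layout, expression) so stages regenerate independently and
outputs are byte-identical for a fixed seed.

What the generator deliberately omits — phylogenetic correlation between
genomes, indels inside sites, repeats, operon rearrangement, non-orthologous
regulator replacement, probe-level measurement artifacts — bounds what
passing benchmarks show: they demonstrate that the algorithms recover what
their own model class assumes, not that real Thermotogales regulons are this
clean.

## The packaged catalog

`togaregulon.fixtures` ships a machine-readable transcription of the
published *T. maritima* network inventory: the 21-row pathway table, 19
regulon models (18 *T. maritima* TFs plus the fructose regulator found only
in two other *Thermotoga* species), per-promoter site records with
dual-regulation flags (XylR/KdgR, CelR/GloR, TreR/GluR), and the TF-presence
matrix over the 11 genomes. Only discrete printed content was transcribed
(names, counts, presence marks); where the source enumerates a locus only
partially, gene lists are completed with locus-tag-style placeholders so
every headline count — 181 regulated genes, 163 targets, 40 binding sites,
19 regulon models, XylR 27 genes / 7 operons / 6 sites, CelR 22, GalR 15,
RhaR 14 — is *recomputed* from the lists rather than stored. Site records
follow the convention that a dual-regulated promoter counts one site per TF
and a divergent operon pair may share one site; this is the allocation
consistent with the printed 40-site total, which the source does not break
down exhaustively. Two printed column totals are not reproducible from the
printed rows (total genes: 240 recomputed vs 241 printed, excluding
fructose; enzymes: 126 vs 127); the consistency checker flags these as
EXPECTED-MISMATCH rather than failing, since no reconciliation is available.

## Numerical and design choices

- Coordinates: 1-based inclusive in files (GFF3 convention), 0-based
  half-open internally; converters are tested in both directions.
- Scores are exact floats internally and rounded to 4 decimals only in
  output tables. Ties between equal-objective restarts keep the earliest
  restart (deterministic under the per-restart seed stream).
- Overlapping scan hits are all reported; deduplication to one best site per
  operon happens at the regulon-assembly stage.
- One global threshold per profile across genomes; a per-call override
  exists for exploratory scans.
- Benchmarks sizes: the planted-motif benchmark uses 10 regions × 240 nt
  × 20 seeds with 20 restarts; the end-to-end benchmark uses 5 genomes ×
  40 ortholog groups × 3 regulons × 20 seeds with 8 restarts. These sizes
  give stable means while keeping the full suite fast on one CPU.
- Effector assignments are metadata (catalog or config), never inferred.

## Known limitations

- The Gibbs sampler assumes a fixed motif width; width selection is left to
  the caller (scan widths externally if needed).
- Mononucleotide background only; no dinucleotide or higher-order models.
- Operon prediction is the distance heuristic, with no terminator or
  expression evidence; readthrough transcription (as in the arabinose locus)
  is not modelled.
- The minimum-training-score threshold is sensitive to the weakest training
  site; a contaminated training set lowers the cutoff and costs precision —
  the zero-or-one discovery mode and the conservation filter are the
  designed mitigations.
- The catalog's unnamed member genes are count-preserving placeholders, not
  real locus tags; per-gene lookups beyond the named genes are meaningful
  only at the count level.
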