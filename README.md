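# devtx — stage-resolved transcriptome dynamics for early zebrafish development

`devtx` re-implements, as a tested Python library plus a numbered analysis
pipeline, the classic bulk RNA-seq analysis of an early developmental time
course: nine stage libraries spanning cleavage (64/128-cell) through
blastula, gastrula, segmentation, pharyngula and hatching to the early
larva (1 week). It is aimed at computational biologists who want the
complete chain — read-to-gene counting, background-calibrated expression
calling, count-based differential expression, stage-preferential gene
identification and expression-pattern clustering — as importable,
unit-tested functions rather than a one-off collection of scripts.

Because the original SOLiD libraries are not publicly deposited, the
package ships a first-class synthetic-data generator that emulates the
study's statistical structure (six trajectory archetypes, a never-expressed
background class, multi-mapping reads, intergenic noise), so every stage of
the analysis is exercised end to end against known ground truth.

## The methods at the core

**Fractional read counting.** A read with *n* reported alignment locations
(*n* ≤ 9; more are discarded) contributes weight 1/*n* per location. A
location overlapping an intron by more than 10 nt is intron-originated and
credits that intron; a location whose non-exonic overlap is at most 10 nt
credits the gene's exon count; locations covering several overlapping genes
split their weight equally. Intron *i* of gene *g* is *potentially
expressed* when its read density exceeds 80% of the exonic density,

    c_i / L_i  >  0.8 · C_g / L_g ,

and expressed-intron reads and lengths are folded into the gene's count and
effective length. Expression is reported as

    RPKM = c / ( L/10³ · N/10⁶ ),

with `L` the effective length and `N` the library's retained read weight.

**Expression threshold.** In log₂(RPKM + ε) space a Gaussian is fitted to
the per-region intergenic RPKM (regions further than 500 bp from any gene
end) and a two-component Gaussian mixture to the pooled late-stage gene
RPKM by EM, the lower component anchored to the intergenic fit. The
threshold is the maximum-likelihood class boundary — the point between the
component means where `w₁·φ(x;μ₁,σ₁) = w₂·φ(x;μ₂,σ₂)` — mapped back to
RPKM. Genes strictly above it are *expressed*; genes expressed at a stage
but not at the previous one are *activated* (and conversely *inactivated*),
with per-minute rates over the stage onset intervals (hpf).

**Differential and preferential expression.** For every gene and stage pair
a two-sided Fisher's exact test on `[[c_A, N_A − c_A], [c_B, N_B − c_B]]`
with Benjamini–Hochberg FDR control per pair; DE requires FDR < 0.001 and a
> 4-fold RPKM change. A gene is *stage-preferential* when it beats every
other stage at FDR < 0.001 with ≥ 2-fold higher RPKM.

**Trajectory clustering.** log₂ RPKM profiles are histogram-equalized
(quantile bins, piecewise-linear, invertible, scaled to [0,1]), a
self-organizing map is batch-trained on the equalized profiles (Gaussian
neighbourhood, linearly decaying radius, deterministic per seed), and the
unit codebooks are merged hierarchically (Ward by default) into six
expression-pattern classes; each cluster is summarized by the half of its
genes closest to the centroid.

**Stage structure.** Pearson correlation between stages, uncentered PCA of
the regulated genes (component 1 carries the shared expression scale),
per-gene z-scores, one-sided hypergeometric term enrichment, and TF-family
median profiles clustered three ways (complete linkage, cosine distance).

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on the
synthetic study design (2,000 genes, 9 stages, nominal 10⁶-read libraries;
intermediate data goes to `scratch/pipeline/`, summaries to `results/`):

```bash
cd analysis
python 01_simulate.py
python 02_count_reads.py
python 03_threshold.py
python 04_differential_expression.py
python 05_cluster_trajectories.py
python 06_stage_structure.py
```

Step 03 prints the fitted expression threshold and the per-stage expressed
counts:

```
threshold: 3.4057 RPKM (log2 boundary 1.768, background N(-7.89, 2.70))
```

(the threshold is in realized-depth units; at the fixture's sequencing
depth it corresponds to ≈ 0.09 RPKM at nominal depth, sitting between the
intergenic background and the weakest genuinely expressed genes). Expressed
gene counts rise from 614 at the 64/128-cell stage to 1,288 at 1 week,
reproducing the developmental broadening of the transcriptome. Step 04
reports

```
1449 genes DE in at least one of 36 stage pairs
```

and step 05 clusters those DE genes' trajectories:

```
grid 14x14, 1449 DE genes, ARI vs planted archetypes (regulated genes): 0.726
         n_genes  n_representative  dominant_archetype
1            178                89  maternal_sustained
2            298               149        maternal_off
3            359               180     early_sustained
4            241               121       gastrula_peak
5            217               109         larval_only
6            156                78      late_activated
```

Each recovered cluster is dominated by one planted archetype — the
maternal/zygotic split, the gastrula peak, and the late/larval activation
waves are all recovered from reads alone. Step 06 reports that the first
three principal components explain 87.0% of the variation among regulated
genes.

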