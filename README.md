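# ucekit

A toolkit for working with **ultraconserved elements (UCEs)** — genomic
regions showing perfect sequence identity between distantly related species
— as phylogenomic markers collected by target enrichment (sequence
capture).

It is written for phylogeneticists who have whole-genome pairwise
alignments of two divergent taxa and want to (a) identify conserved loci,
(b) design a filtered set of 120-nt enrichment baits against them, (c)
recover those loci from assembled contigs or other genomes, and (d) build
completeness-filtered concatenated matrices and capture-success summaries
from what comes back.

## What it does

| stage | module | operation |
| --- | --- | --- |
| conserved-region discovery | `ucekit.maf_scan` | maximal 100%-identical column runs longer than a cutoff (default 40 bp) in MAF blocks |
| paralog screen | `ucekit.seqmatch` | all-against-all local alignment; pairs more than 80% identical over 50% of their length are both removed |
| bait design | `ucekit.bait_design` | buffer loci to 180 bp, tile 120-nt baits at 2X density (60-bp overlap), drop baits with ambiguous bases, >25% soft-masked sequence, or >70% GC, then dedupe |
| locus harvesting | `ucekit.harvest` | match contigs/genome slices to baits at ≥80% identity over ≥80% of the bait; remove chimeric (multi-locus) contigs; mark loci with ambiguous (two-contig) orthology absent; keep a two-table relational match database |
| matrix assembly | `ucekit.matrix` | keep loci present in ≥ ⌈fraction·N⌉ taxa (70% of 14 → 10; 75% of 44 → 33), count parsimony-informative sites, concatenate to a PHYLIP supermatrix with charsets |
| enrichment QC | `ucekit.enrich_qc` | qPCR fold enrichment `efficiency^|ΔCp|` (default efficiency 1.78) and per-pool means |
| capture-success models | `ucekit.capture_stats` | Poisson/Gaussian GLMs ranked by AIC, Akaike weights `w_i = e^{-Δ_i/2}/Σ e^{-Δ_j/2}`, model-averaged coefficients over the valid set (w > 0.10) |
| synthetic truth | `ucekit.synth` | deterministic genome pairs with planted elements, duplicated elements, soft-masked repeats, diverged contigs, and Cp tables with known ΔCp |

Sequencing, read cleaning, assembly, multiple sequence alignment,
production trimming, and tree inference are external; ucekit consumes and
produces their standard formats (FASTA, MAF, BED, relaxed PHYLIP, minimal
NEXUS, RAxML partition files).

## Worked example

A fully synthetic run with planted truth (no external data needed):

```bash
ucekit --quiet synth genomes --seed 7 --out g
ucekit --quiet synth contigs --seed 7 --genome g/genomeA.fasta \
    --bed g/truth.bed --taxon taxon1 --out contigs
ucekit --quiet scan --maf g/truth.maf --min-len 40 \
    --out conserved.bed --fasta conserved.fasta
ucekit --quiet design --bed conserved.bed --genome g/genomeA.fasta \
    --out baits.fasta
ucekit --quiet harvest --contigs contigs --baits baits.fasta \
    --db matches.sqlite
```

which prints

```
50 conserved regions
107 baits across 50 loci
50 loci across 1 taxa
```

The scan recovered all 50 planted elements (exactly, at their truth-BED
coordinates); buffering each to ≥180 bp and tiling at 2X density gave 107
filtered baits (2 per 180-bp locus, more for longer loci); and matching the
5%-diverged contigs back against the bait set credited every locus for the
taxon. Bait headers carry design-genome coordinates:

```
>uce-1_p1 |chr1:528-648
CATCTCCTAATTTAACGTTCTCACAGTAAAAGGTCTTTACTTATTAACCAAACCCCGACG...
```

`ucekit counts --db matches.sqlite --taxa taxa.txt --fraction 0.75` then
lists the loci shared by at least ⌈0.75·n⌉ of the listed taxa, `ucekit
fastas` exports the monolithic per-locus FASTA, and `ucekit matrix`
concatenates externally aligned loci into a PHYLIP supermatrix with
charset and partition files.

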