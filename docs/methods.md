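# Methods

This note records the models, conventions, and numerical choices behind
ucekit, and what its synthetic test system does and does not establish
about real data.

## Conserved-region model

A conserved region is a maximal run of MAF alignment columns in which every
row carries the same nucleotide. The comparison is case-insensitive
(soft-mask case carries repeat annotation, not sequence difference), and a
column containing a gap, `N`, or any IUPAC ambiguity code terminates the
run: perfect conservation cannot be asserted through unknowns. Runs are
kept when **strictly longer** than `min_len`. The default cutoff is 40 bp,
exposed as a flag because reasonable pipelines differ on the exact minimum
(and because, in practice, post-screen locus sets are often characterized
by a larger effective minimum such as 60 bp); both behaviours are a
`--min-len` away. Coordinates are reported on the first row's source
sequence, converted to plus-strand, 0-based half-open. Regions are never
merged across blocks, and regions more than 25% lowercase are only
*flagged* here — the repeat filter proper belongs to bait design.

## Match criterion and alignment engine

Every similarity decision reduces to one criterion on the best local
alignment of a pair: identity (matching columns / aligned columns) and
coverage (aligned span on a basis sequence / its length) against two
thresholds. The three uses are:

* paralog screen of candidate regions: identity > 0.80 and coverage > 0.50
  (strict, per "more than"), basis = the **shorter** member — the
  conservative reading of "50% of their length"; configurable because the
  original basis is not documented. Both members of a qualifying pair are
  removed: a locus with an ambiguous paralog is unsafe as a probe target
  whichever copy is "original".
* bait deduplication: same thresholds, cross-locus pairs only. Neighbouring
  baits of one locus are exempt by design — 2X tiling makes them overlap by
  exactly half their length (60/120 = 0.50 is also not > 0.50).
* contig/genome matching: identity ≥ 0.80 over ≥ 0.80 of the **bait** —
  contigs legitimately extend far beyond the probe, so bait-basis coverage
  is the natural unit.

Alignment is exact Smith–Waterman (match +1, mismatch −1, linear gap −2)
through scikit-bio's pair aligner. At the input sizes this toolkit sees
(regions of 60–200 bp, 120-nt baits, kb-scale contigs) exact alignment is
fast enough that no seeding heuristic is needed for correctness-critical
decisions; an exact shared-12-mer prescreen is used only to skip hopeless
bait × contig pairs in bulk matching, where a true match at ≥80% identity
shares a seed with near-certainty. Reverse-complement matches count
everywhere — paralogy and capture are strand-agnostic. Matching is
case-insensitive.

## Bait design

Regions shorter than the 180-bp target are buffered with equal 5′/3′
flanking genome sequence; an odd remainder's extra base goes 3′
(deterministic tie-break), and at sequence ends the deficit shifts to the
other side, with loci that still fall short flagged rather than dropped.
Baits are 120 nt at a 60-bp stride. For locus lengths that are not exactly
tileable, one extra bait is placed flush with the 3′ end so the locus is
fully covered; exactly tileable lengths give `(L − 120)/60 + 1` baits.
Filters are strict inequalities: any ambiguous base; soft-masked
(lowercase) fraction > 0.25 — repeat content is read from the soft-masking
of the design genome, as no repeat masker is bundled; GC > 0.70. Exact
duplicate baits collapse to the copy with the lowest locus number, then
lowest index.

## Harvesting and orthology

Per taxon: a contig hit by baits of two or more loci is removed outright
(chimeric assembly or repeat); a locus backed by two or more surviving
contigs is marked absent (ambiguous orthology); survivors enter a
two-table relational database (locus × taxon status; contig name map)
stored as SQLite. Multiple baits of one locus hitting a contig count once,
best identity retained. Equal-evidence ties on a contig's locus assignment
are treated as multi-locus (conservative). When slicing loci from a
genome, bait hits are clustered into genomic sites (same sequence and
strand, within 100 bp); a locus matching more than one site is dropped by
default (`on_multiple_sites="best"` keeps the top-identity site), slices
take ±1000 bp of flank clamped at sequence ends, and minus-strand sites
are reverse-complemented into bait orientation.

## Matrix assembly

The completeness threshold is `ceil(fraction · N)` (guarded against binary
float artifacts), which reproduces the standard worked values: 70% of 14
taxa → 10, 75% of 44 → 33. Parsimony-informative sites require at least
two unambiguous states (A/C/G/T) each in at least two rows; gaps, `?`, and
ambiguity codes are missing data, never states — the standard convention.
Alignment-length summaries report a 95% CI half-width of `1.96·sd/√n`
(sample sd); "CI" is taken as a half-width about the mean, and a single
alignment reports 0 with a flag. Concatenation orders loci
lexicographically by id, fills absent taxa with `?` (distinct from the gap
`-`), and records 1-based inclusive charsets; charset extraction inverts
concatenation exactly. `edge_trim` is a deliberately simple sliding-window
fallback (20 columns, ≥0.5 mean pairwise identity, plus removal of
boundary columns with <2 data rows). It is **not** equivalent to dedicated
trimming tools, and the pipeline accepts pre-trimmed alignments; multiple
sequence alignment itself is likewise an external, pluggable step.

## Enrichment QC and capture-success models

Fold enrichment is `efficiency^|mean(enriched Cp) − mean(unenriched Cp)|`
with replicate Cp values averaged arithmetically and a default
amplification efficiency of 1.78 per cycle. Group summaries average fold
values (matching the "average fold enrichment" convention); averaging on
the |ΔCp| scale first is available as an option, and summaries are emitted
per blocker, per library, and per amplicon since the grouping convention
varies between labs.

Capture-success models are GLMs — Poisson/log for locus counts,
Gaussian/identity for mean locus lengths — fitted by maximum likelihood in
statsmodels. Genetic distance to the bait-design genome is consumed as a
covariate on [0, 1]; estimating it is out of scope. AIC uses `k` = number
of mean parameters including the intercept (the Gaussian scale is not
counted), so `AIC = 2k − 2lnL` matches the fitted likelihood exactly.
Akaike weights are `exp(−Δi/2)` normalized; model averaging keeps models
with `w > 0.10`, renormalizes, and by default substitutes 0 for terms a
model omits (zero-substitution averaging; conditional averaging is the
switchable alternative — the choice matters and is reported with the
method name). Non-converging models are excluded with a warning.

## The synthetic study system

`ucekit.synth` generates everything the pipeline consumes, as pure
functions of a seeded spec (identical specs give byte-identical files).
The default system: a 100-kb genome pair sharing 50 planted elements of
60–200 bp with ≥500 bp spacing, independently mutated at a 15% background
substitution rate outside elements, four 1.5-kb soft-masked repeat tracts,
a gapless truth MAF block per element (element ±100 bp of divergent
context), per-taxon contigs at 5% divergence with ≤400-bp flanks plus
decoys, and Cp tables whose planted ΔCp means (11.5 cycles for the chicken
blocker, 9.0 for the hymenopteran one) put mean folds in the
several-hundred range typical of successful enrichments.

Two generator guarantees make planted truth *exact* rather than
statistical: the column flanking each element is forced to mismatch
between the genomes, and accidental background identity runs are broken
every 25 matching bases. Without these, a 15%-divergent background would
produce both chance conserved runs longer than 40 bp and run-extension
past element boundaries. The background is therefore approximately, not
exactly, at the nominal rate. The degenerate zero-rate spec skips the
guards and yields identical genomes. Indel evolution is not modeled
(`indel_rate` must be 0): it would break the gapless truth-MAF coordinate
mapping, and element evolution here is substitution-only by scope.

What passing tests show — and don't. The planted system exercises the
decision logic (run detection, threshold arithmetic, orthology rules,
bookkeeping) under known truth. It does not model alignment error from a
real whole-genome aligner, assembly artifacts beyond simple chimeras and
duplicated contigs, base-composition or repeat-family structure, or indel
variation; recovery rates on real data depend on all of these. One
quantitative caveat found while validating: with optimal local alignment,
single 120-nt bait windows can clear the 0.8 identity cutoff by chance at
25% contig divergence (expected identity 0.75), so recovery there
collapses to a minority of loci rather than to zero; it reaches zero by
35%. The identity threshold brackets recovery, but not as a step function.

## Problem sizes

Tests and the acceptance script run desk-scale systems (50–55 planted loci
on 100-kb genomes, ~100 baits, 3 enriched taxa, 200-observation GLMs) —
sizes chosen so the whole suite re-runs from scratch in well under a
minute while still exercising every rule on non-trivial inputs.
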