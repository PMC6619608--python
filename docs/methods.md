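# Methods

This note documents the models and procedures implemented in `orgvar`, the
parameters that matter, the numerical and design choices made where the
design was genuinely open, and what the synthetic-data generator does and
does not emulate.

## Variant scanning

Input is a multiple alignment of near-identical organelle genomes over
{A,C,G,T,N,-}, one designated reference row. Coordinates are 1-based and
closed everywhere user-facing (GFF3/VCF convention); alignment columns map
to reference positions by prefix-counting non-gap reference characters.
Circularity is carried as a flag only: columns are linear and no event may
span the origin (a documented limitation, matched by the generator).

Every polymorphic column is assigned to exactly one event, with precedence
**Inversion > HomopolymerDiff > InDel > SNP**:

* A **SNP** is a single gap-free column with ≥ 2 distinct bases among
  non-missing entries. N, or a gap inside an otherwise substitution-type
  column, becomes `?` (missing) for that sample; a column with < 2 observed
  states is invariant. Multi-allelic columns count as one SNP site; the
  transition/transversion breakdown assigns one unordered base pair per
  minority allele, counted against the site's majority allele. At an exact
  50/50 frequency tie the lexicographically smaller base is called minor —
  an arbitrary but deterministic convention.
* An **InDel** is one maximal run of columns in which ≥ 1 row is gapped.
  Events, not columns, are counted; base variation inside the gapped run
  stays part of the same event.
* A **HomopolymerDiff** is an InDel whose varying bases are all one base X
  identical to the adjacent reference base, with the reference
  mononucleotide run of X at least `homopolymer_min_run` long (default 4;
  the threshold is a judgement call — published counts separate
  homopolymer-stretch differences from other InDels without defining a run
  length, and 4 is the shortest run for which polymerase slippage is a
  plausible mechanism).
* An **Inversion** is a maximal run of ≥ `inversion_min_span` (default 2)
  consecutive substitution columns whose two observed allele strings are
  reverse complements — the stem-loop flip. Classification is on the
  allele strings alone; flanking inverted-repeat arms are not required,
  since the alignment itself does not prove hairpin formation either way.
  A single A↔T column is never an inversion (span threshold), and blocks
  with more than two distinct strings fall back to per-column SNPs.

Pairwise differences count sites where both samples are observed and
unequal (SNP sites only; InDels, homopolymer and inversion events never
enter distances or networks). GC content is computed over the reference
row's non-gap bases.

VCF 4.2 output writes SNPs as single-base records, InDel-type events as
left-anchored indel records, and the short inversion as a multi-nucleotide
substitution. Genotypes are haploid (`0`, `1`, `.`): organelle genomes in
Pinaceae are haploid and uniparentally inherited, so diploid-style calls
would be misleading.

## Coding-effect annotation

Feature annotations carry 1-based closed intervals in transcription order;
minus-strand features list exons in descending genomic order. Context
assignment is deterministic under overlap with precedence intron > tRNA >
rRNA > pseudogene > gene (introns are annotated inside their genes and must
win). Pseudogenes are never translated.

For CDS hits the codon is assembled across exon boundaries in transcription
order, reverse-complemented for minus-strand genes, phase-trimmed, and
translated with codon table 11. The codon index is counted from the start
codon; start codons get no special treatment beyond position 1. An allele
that creates a premature stop is reported (alt residue `*`), not an error;
property fields stay unset for stops and for synonymous changes.

The default amino-acid property scheme is:

| class | residues |
|---|---|
| basic | R K H |
| acid/amide | D E N Q |
| hydrophilic | S T A P G |
| hydrophobic | V I L M F W Y |
| special | C |

This is the unique total mapping consistent with the published substitution
table this package reproduces (R and K basic; Q acid/amide; S, A, P
hydrophilic; V, I, L hydrophobic; C in its own class — the source table's
label for the cysteine class is read as the residue cysteine, and serine→
alanine is kept hydrophilic→hydrophilic even though hydropathy scales such
as Kyte–Doolittle would disagree). The scheme is a plain dict and can be
replaced wholesale.

## Mitochondrial robustness and paralog rules

A candidate site is kept iff

```
(n_observed >= 6  AND  minor_count >= 3)          # partial coverage
OR (n_observed == n_total  AND  minor_count >= 2) # full coverage
```

"Observed" means a non-missing, non-ambiguous call for that individual.
At multi-allelic sites the second-most-frequent allele's count is tested
and third alleles are ignored. Individuals, not contigs, are counted.
Verdicts record which rule applied (`full-coverage-rule`,
`partial-coverage-rule`) or why the site fell (`rejected-coverage`,
`rejected-minor`, `rejected-paralog`). The rule is monotone: adding an
observation of the minor allele can never flip a kept site to rejected.

A locus is flagged as paralog-contaminated when any single individual
contributes ≥ 2 aligned copies disagreeing at ≥ 1 site (strictest reading;
the threshold is configurable). Flagged loci are excluded before the
robustness rule and their sites marked `rejected-paralog`.

## Diagnostic screening and amplicon windows

A site is diagnostic for a two-group partition iff every observed group-A
allele is one base, every observed group-B allele a different base, and
each group has ≥ `min_obs_per_group` observations (default 2: with a
1-observation default any singleton would qualify, and the sparsest column
of the published matrix still observes 2 per group). Missing entries are
ignored, which is exactly why such calls are only *putative*. An optional
outgroup row is excluded from the test; its allele is recorded to polarize
the variants. The screen is invariant to sample order and to swapping the
group labels, and raising `min_obs_per_group` can only remove sites.

For assay design on degraded DNA, the shortest window of length
`min_len`..`max_len` (defaults 60 and 150 nt, the practical bounds for
sedimentary ancient DNA amplicons and High-Resolution-Melt screening)
containing the site is sought whose two terminal `flank_len` stretches
(default 20 nt, a typical primer footprint) are invariant across all
samples and gap-free; placements nearest to centered are preferred.
Windows are reported in reference coordinates and exported as BED
(0-based half-open).

## Statistical-parsimony networks

Individuals collapse into haplotypes over complete-case SNP sites (sites
observed in every individual — mirroring the use of fully covered
mitochondrial SNPs for network building; chloroplast alignments typically
have no missing entries, making the restriction moot there). Connection
proceeds distance by distance, d = 1..limit: every observed pair at profile
distance d not already joined by a network path of length ≤ d gets a
connecting path with d−1 inferred intermediates. A required intermediate
profile reuses any existing node with that profile — observed or inferred —
and this reuse is what creates loops (alternative genealogical pathways).
Pairs beyond the limit stay in separate components.

Determinism: candidate pairs at equal distance are processed in
lexicographic haplotype-id order, and intermediate profiles mutate the
differing sites in ascending site order. The reference TCS program's
internal orderings are unspecified, so topology equality with any
particular published figure is not a goal; the structural properties
(unit-step edges, intermediates on shortest paths, conservation of
multiplicities, loop retention, determinism) are.

**Connection limit.** The limit is the largest step count j whose estimated
probability of parsimony meets the confidence level (default 0.95). The
estimator is a uniform multiple-hit model: j mutations falling uniformly on
a molecule of m sites hit j distinct sites — so that observed differences
equal true steps — with probability

```
P(j, m) = prod_{i=1}^{j-1} (1 - i/m)
```

This is the package's own closed-form estimator of the probability of
parsimony underlying statistical-parsimony network building. It is
non-decreasing in m, non-increasing in the confidence level, and tends to
1 step as confidence → 1 (a single step is always parsimonious). The
sequence length fed to it is the molecule's alignment length, not the SNP
count — consistent with the estimator's definition — and is exposed as a
flag; passing an explicit `limit` bypasses the estimator entirely.

## Synthetic data generator

The generator emulates the study conditions at desk scale: 19 samples in
groups of 12/4/3 (Taymyr-, Omoloy-, Kolyma-like, with metadata placing
them on a west–east transect), a 20 kb circular genome at GC 0.3874, and
planted events defaulting to 84 SNPs / 5 InDels / 17 homopolymer
differences / 1 three-nucleotide inversion with a 44% transition
probability, 8 group-diagnostic sites among the SNPs, annotated genes
(one multi-exon, one reverse-strand, plus a tRNA and a pseudogene) whose
reference CDS translate without internal stops.

Planted loci are pairwise disjoint, ≥ 50 nt from the alignment ends and
≥ 12 nt apart, so no two events can merge into one and recovery is exact;
diagnostic SNPs additionally reserve a 40-nt invariant context either side
so they are amplicon-designable. InDel blocks are forced to contain two
distinct bases (so they can never be mistaken for homopolymer events);
homopolymer runs (5–7 nt) are guarded by flanking non-run bases and
contracted by 1–2 nt in carrier samples; the inversion block is chosen so
that it differs from its reverse complement at every position and is
framed by inverted-repeat arms. Sequence construction uses integer draws
only; a fixed seed reproduces bit-identical files.

The mitochondrial-style matrix defaults to 213 candidate sites with a 12%
per-cell missing rate, chosen so that roughly 8% of sites survive as
complete cases across 19 individuals — the proportion seen in the
motivating survey. Masking is repaired minimally so every site keeps two
observed states; an outgroup row carries a third state at diagnostic
sites. Paralog contamination gives one individual a second, 3-mismatch
divergent copy at each contaminated locus.

Deliberate simplifications — what passing tests on synthetic data does
*not* show about real data:

* All InDels and homopolymer contractions are deletions relative to the
  reference row; the reference stays ungapped, so alignment columns equal
  reference coordinates and VCF anchoring always succeeds. Real alignments
  contain insertions relative to any chosen reference.
* The background is i.i.d. sequence: no repeats, no alignment ambiguity,
  no aligner-induced gap placement artefacts — the hard parts of real
  whole-genome alignment are out of scope (alignments are an input).
* Events never overlap, never sit near one another and never span the
  circular origin; real variation clusters.
* No sequencing error model and no read-level simulation; missingness is
  i.i.d. per cell, whereas real contig coverage is block-structured.

## Pipeline

`orgvar run-all` executes, in order: read inputs → scan (chloroplast) or
ingest matrix, flag paralogs and filter (mitochondrial) → effect
annotation → summaries → diagnostic screen → complete-case reduction →
haplotype collapse → connection limit → network build → exports. A JSON
report (schema_version 1) aggregates every summary; counts are conserved
across stages (`sites_in == sites_kept + sites_rejected`), and identical
configs byte-reproduce all outputs. Stage failures abort with the failing
stage in the log, and the report is only written on success.

## Problem sizes used in the test suite

Unit tests run on 8–10 kb genomes with ~20–30 planted events; the
parameter-recovery check runs 100 study-scale simulations (20 kb, 107
events each); the transition-fraction check plants 2000 SNPs on a 60 kb
genome; oracle-equivalence checks use ≤ 6 observed haplotypes over ≤ 10
sites (exhaustive search) and 200 random matrices (exhaustive per-site
screen). The whole suite completes in well under a minute.
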