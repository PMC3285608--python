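# Methods

This note documents the models, conventions and design choices behind
`resevar`, in the spirit of a statistical-software methods appendix: what
is computed, under which assumptions, and what the synthetic validation
does and does not demonstrate.

## Setting and scope

The package re-implements the analysis layer of a genome-wide variation
comparison between closely related inbred lines resequenced against one
reference genome.  Alignment itself (read mapping, trimming/realignment
schedules) is out of scope; the pipeline starts from site-level evidence
("pileup-lite"), per-sample variant calls (VCF), coverage masks (BED),
the reference (FASTA) and gene models (GFF3).  All internal coordinates
are 0-based half-open; 1-based conventions exist only at the VCF/GFF3
boundary.  Standard formats are read through Biopython, cyvcf2 and
gffutils.

## Genotype model and quality values

At each site with read evidence, the caller evaluates all ten unordered
diploid genotypes over {A,C,G,T}.  Reads are independent; a base drawn
from allele *a* is observed correctly with probability 1 − ε and as each
of the other three bases with probability ε/3, where ε = 10^(−q/10) from
the base's phred quality.  A heterozygote emits each allele with
probability ½ before the same error channel.  Posteriors are computed in
log space and normalized; the genotype with the highest posterior is
called, with a deterministic tie-break (hom-ref, then hom-alt in allele
order, then heterozygotes in allele order).

The prior reflects an inbred line: hom-ref 0.998, each hom-alt 5 × 10⁻⁴,
each heterozygote 10⁻⁴ (normalized, configurable).

Two phred-scaled confidences are attached to each call:

* `genotype_qual` — the probability that the called *genotype* is wrong
  (posterior mass of the nine competitors);
* `qual` — the probability that the site is *homozygous reference*
  (for hom-ref calls, that it is not).

The acceptance filter (quality value strictly above 20, at least two
supporting reads) uses `qual`.  This is a deliberate modelling decision:
under any inbred prior the heterozygote competitor bounds the genotype
posterior of a hom-alt call at roughly 1 − 0.6·2^(−depth) *independently
of base quality*, so a genotype-posterior filter at Q > 20 would reject
every site with fewer than about six reads, which contradicts the intent
of a two-read support floor.  Reading the quality value as
variant-versus-reference confidence (the natural meaning for a filter
that accepts polymorphic loci) keeps both thresholds meaningful down to
the depths they name.

Filters, applied exactly as stated and tested at their boundaries:

| stage | rule |
|---|---|
| SNP | `qual` > 20 (strict) AND supporting reads ≥ 2 |
| InDel | gap length 1–5 bp AND gapped read pairs ≥ 3 |
| SV | same-signature sites within 1 kb clustered; summed abnormal pairs ≥ 3 |

The SV cluster join distance (1 kb) is a package default; the upstream
description gives none.

## Comparison rules

A locus enters between-sample comparison only if **every** compared
sample has at least one covered base at its position (the eligibility
rule); otherwise it is reported `ineligible`.  Locus identity: SNPs by
(chrom, position); InDels by position with the inserted/deleted sequence
as the allele identity, so "shared" means the same event; SVs by
same-type reciprocal overlap ≥ 50 % (configurable).  Classification over
the compared samples: `shared` (all carry the identical alternate),
`different` (all non-reference, not all identical — the allelic
pleomorphic case; for pairs, both non-reference with distinct alts),
`unique_to_X`, `partial` (a strict subset shares the allele — the
pair-shared case inside a three-way comparison).  A heterozygous call
participates through its non-reference allele, so het A/G versus hom G
counts as shared.

Union accounting uses inclusion–exclusion over per-sample totals,
pairwise shared and three-way shared counts, and is validated against
the direct cardinality of the merged event sets — both on random sets
(property test) and on every simulated dataset.

## Effect annotation

For a CDS SNP the affected codon is rebuilt strand-aware from the
spliced CDS (segments held in transcription order, phase from the
running length) and both codons are translated with the standard nuclear
code: same amino acid → synonymous; different → nonsynonymous; sense →
stop → premature stop; any change inside the initiation ATG → start
loss; terminal stop → sense → stop loss (stop → stop is synonymous).
Genes whose CDS length is not divisible by three are flagged and
excluded from codon-level calls.  Positions within 2 bp of an intron
boundary carry a `near_splice` flag rather than a dedicated effect
class.  InDels are placed CDS / non-CDS by footprint intersection;
frameshift status is metadata only.  The classifier is verified
exhaustively against an independent full-CDS re-translation oracle (all
nine substitutions at every CDS position of ≥ 20 genes, both strands)
and by a plus/minus-strand metamorphic test.

## Window scan

Windows of 100 kb advance in 50 kb steps; the final partial window is
kept if at least one step length remains, else dropped.  A variant
counts in every window containing it (≤ 2).  Frequency = count / covered
bases in the window; windows with under 10 % covered bases are masked
(small denominators make rates unstable; the floor is configurable).
ARG = arithmetic mean of unmasked window frequencies across all
chromosomes, pooled over samples, per variant class.  Labels use strict
inequalities — high: rate > 4 × ARG; low: rate < ARG/20 — so
boundary-equal windows stay unlabelled.  Regions shared between samples
are the windows where every in-scope sample carries the same label,
merged when adjacent; the deviation ratio DR = Σ_samples rate/ARG is
computed per window and reported as a diagnostic, not used as the
calling criterion (no operational mapping from DR to region calls is
defined upstream).

## Distances and the tree

The SNP distance between two taxa is the mismatch proportion over
eligible SNP loci (p-distance); the reference genome is included as a
taxon carrying the reference allele everywhere.  Heterozygote scoring:
identical genotypes 0, one shared allele ½, disjoint 1.  A Jukes–Cantor
correction is available behind a flag; the p-distance default keeps the
tree's branch lengths directly interpretable as mismatch fractions.
Neighbor joining is the standard Saitou–Nei agglomeration with the
Q-criterion, ties broken by taxon-name order, negative branch lengths
clamped to zero and flagged.  On additive matrices the source tree is
recovered exactly (verified over 100 random trees of 4–8 taxa, and
cross-checked against dendropy's NJ on topology).

## Synthetic data: what it emulates

The generator reproduces the *structure* of the target study at desk
scale: three inbred samples sharing most variants against a divergent
reference; configurable counts of shared-all, pair-shared, unique and
allelic-different loci; SNPs, InDels ≤ 5 bp and SVs (500–1500 bp spans);
~85 % coverage per sample with gaps placed away from planted loci (plus
deliberately uncovered loci to exercise ineligibility); a heterozygous
background drawn per sample as Binomial(covered bases, 2 × 10⁻⁴); and
two-exon genes with valid ORFs on both strands so every effect class is
reachable by one substitution.  Defaults: 2 chromosomes × 150 kb,
20 genes, 200/40/60/10 SNP class counts, mean depth 10 with a floor of
5 reads per emitted site, error-free base calls with qualities set to
the phred of the configured error rate (capped at Q40).

Two deliberate idealizations keep the truth table exactly recoverable
and are not properties of real data: heterozygous sites receive an exact
half split of their two alleles (up to a random odd read), and emitted
sites respect the depth floor.  Real pileups have binomial allele
sampling and depth dropout, under which heterozygote recovery at
marginal depth is necessarily probabilistic.  Passing the recovery tests
therefore demonstrates correctness of the *decision rules*, not
robustness to sampling noise; the error-rate and depth knobs allow the
noisy regime to be explored, where exact recovery is not expected.
Likewise the uniform base composition, uniform variant placement and
absence of repeats mean the scan and comparison results say nothing
about alignability artifacts in real genomes.

Determinism: one integer seed; each generator stage draws from its own
`numpy` stream keyed by (seed, stage), so stages can be regenerated
independently and byte-identical outputs follow from equal seeds.

## Published-count fixtures

The per-chromosome count tables of the three rice restorer lines (per
sample, pairwise, three-way, CDS effects, CDS InDels, large-effect SNPs)
are bundled as TSV fixtures.  `summaries.build_report` re-sums every
printed total, reproduces the non-redundant SNP union 568,787 by
inclusion–exclusion, and derives the genome-wide large-effect totals as
the shared-table column sums plus the small different-SNP supplement
(premature stop 233 + 5 = 238, ATG change 9 + 2 = 11, stop change
79 + 3 = 82) — the printed large-effect table covers shared SNPs only.
Two documented source inconsistencies are surfaced, not arbitrated: the
nonsynonymous total 2,962 (column sum) versus a narrative 2,902, and a
narrative/table swap of two pairwise shared-SNP totals (the tables are
followed; the union identity is insensitive to the order).

## Numerical and degenerate-input conventions

Posteriors are normalized via a max-shifted log-sum; error masses are
computed as sums of competitor posteriors rather than `1 − p`, which
stays accurate when the best posterior rounds to 1 (phred values cap at
10⁴).  Zero-depth sites are errors at the caller and omitted by the
generator.  Empty variant sets yield all-zero tables; a genome with no
eligible SNP loci is an error for distance estimation; all-masked window
sets are an error for the ARG.  Tie-breaks (genotypes, NJ joins, term
rankings) are deterministic and documented at each site.

## Known limitations

* The Bayesian caller is a standard independent-reads model, not a
  re-implementation of the original SOAP-era caller; only the published
  filter thresholds are reproduced exactly.
* SV handling is interval-level (signature clusters, reciprocal-overlap
  matching); no breakpoint refinement or sequence resolution.
* One isoform per gene; overlapping-gene SNPs yield one effect call per
  gene and are counted once per gene in summaries.
* The genome-scale headline counts of the original study derive from
  real sequencing data and are reproduced only at the level of their
  internal arithmetic, not re-estimated.
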