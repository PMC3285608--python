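"""Coding-effect annotation of variants against gene models.

SNPs inside a CDS are classified by strand-aware codon substitution with
the standard nuclear genetic code: synonymous, nonsynonymous, and the three
large-effect categories — premature stop (sense codon becomes a stop),
start loss (the initiation ATG is changed) and stop loss (the terminal stop
codon becomes a sense codon).  InDels are localized to CDS vs non-CDS by
footprint intersection; frameshift status is carried as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .core import GeneModel, GenomeSequence, ResevarError, VariantRecord

#: Effect labels for CDS SNPs; exactly one is assigned per (variant, gene).
EFFECTS = (
    "synonymous",
    "nonsynonymous",
    "premature_stop",
    "start_loss",
    "stop_loss",
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class EffectCall:
    """Effect of one variant on one gene (or intergenic)."""

    chrom: str
    pos: int
    gene_id: str | None
    region: str  # 'CDS' | 'non-CDS' | 'intergenic'
    effect: str  # one of EFFECTS or 'none'
    codon_index: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    near_splice: bool = False
    frameshift: bool = False


def cds_sequence(gene: GeneModel, genome: GenomeSequence) -> str:
    """Concatenated CDS in transcription order (mRNA sense strand)."""
    parts = []
    for s, e in gene.cds:
        seg = genome.slice(gene.chrom, s, e)
        if gene.strand == "-":
            seg = seg.translate(_COMPLEMENT)[::-1]
        parts.append(seg)
    return "".join(parts)


def cds_offset_of(gene: GeneModel, pos: int) -> int | None:
    """0-based offset of genomic position ``pos`` within the spliced CDS."""
    offset = 0
    for s, e in gene.cds:
        if s <= pos < e:
            return offset + (pos - s if gene.strand == "+" else e - 1 - pos)
        offset += e - s
    return None


def _near_splice(gene: GeneModel, pos: int, width: int = 2) -> bool:
    """True when ``pos`` lies within ``width`` bp of an intron boundary."""
    if len(gene.cds) < 2:
        return False
    bounds = sorted(gene.cds)
    for (s0, e0), (s1, _) in zip(bounds, bounds[1:]):
        # intron is [e0, s1)
        if e0 <= pos < min(e0 + width, s1) or max(s1 - width, e0) <= pos < s1:
            return True
    return False


def map_variant_to_gene(
    variant: VariantRecord,
    genes: Sequence[GeneModel],
    genome: GenomeSequence | None = None,
) -> list[tuple[str, str]]:
    """Localize a variant: ``[(gene_id, 'CDS'|'non-CDS'), ...]``; empty means
    intergenic.  Containment is strand-independent; overlapping genes each
    contribute one entry."""
    if genome is not None:
        L = genome.lengths.get(variant.chrom)
        if L is not None and variant.pos >= L:
            raise ResevarError(
                f"variant position {variant.pos} beyond end of {variant.chrom} ({L})"
            )
    hits: list[tuple[str, str]] = []
    for g in genes:
        if g.chrom != variant.chrom or not (g.span[0] <= variant.pos < g.span[1]):
            continue
        in_cds = any(s <= variant.pos < e for s, e in g.cds)
        hits.append((g.gene_id, "CDS" if in_cds else "non-CDS"))
    return hits


def classify_snp_effect(
    snp: VariantRecord, gene: GeneModel, genome: GenomeSequence
) -> EffectCall:
    """Classify a CDS SNP by its codon substitution.

    The affected codon is rebuilt strand-aware from the reference and the
    alternate base; reference and alternate codons are translated with the
    standard genetic code.  A change inside the initiation ATG is a start
    loss; a terminal stop codon changed to a sense codon is a stop loss; a
    sense codon changed to a stop is a premature stop; otherwise the call
    is synonymous or nonsynonymous by amino-acid identity.
    """
    if genome.base(snp.chrom, snp.pos) != snp.ref:
        raise ResevarError(
            f"reference mismatch at {snp.chrom}:{snp.pos + 1}: genome has "
            f"{genome.base(snp.chrom, snp.pos)!r}, record has {snp.ref!r}"
        )
    if not gene.annotatable:
        raise ResevarError(f"gene {gene.gene_id} is not annotatable (frame)")
    offset = cds_offset_of(gene, snp.pos)
    if offset is None:
        raise ResevarError(
            f"SNP {snp.chrom}:{snp.pos + 1} is not inside the CDS of {gene.gene_id}"
        )
    cds = cds_sequence(gene, genome)
    ci, within = divmod(offset, 3)
    ref_codon = cds[ci * 3 : ci * 3 + 3]
    alt_base = snp.alt if gene.strand == "+" else snp.alt.translate(_COMPLEMENT)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    n_codons = len(cds) // 3
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())

    if ci == 0 and ref_codon == "ATG":
        effect = "start_loss" if alt_codon != "ATG" else "synonymous"
    elif ci == n_codons - 1 and ref_aa == "*":
        effect = "synonymous" if alt_aa == "*" else "stop_loss"
    elif alt_aa == "*":
        effect = "premature_stop"
    elif alt_aa == ref_aa:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return EffectCall(
        chrom=snp.chrom,
        pos=snp.pos,
        gene_id=gene.gene_id,
        region="CDS",
        effect=effect,
        codon_index=ci,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        near_splice=_near_splice(gene, snp.pos),
    )


def annotate_snp(
    snp: VariantRecord, genes: Sequence[GeneModel], genome: GenomeSequence
) -> list[EffectCall]:
    """Full localization + effect call for one SNP (one call per gene hit)."""
    hits = map_variant_to_gene(snp, genes, genome)
    if not hits:
        return [
            EffectCall(snp.chrom, snp.pos, None, "intergenic", "none")
        ]
    by_id = {g.gene_id: g for g in genes}
    calls = []
    for gene_id, region in hits:
        gene = by_id[gene_id]
        if region == "CDS" and gene.annotatable:
            calls.append(classify_snp_effect(snp, gene, genome))
        else:
            calls.append(
                EffectCall(
                    snp.chrom,
                    snp.pos,
                    gene_id,
                    region,
                    "none",
                    near_splice=_near_splice(gene, snp.pos),
                )
            )
    return calls


def classify_indel_region(
    indel: VariantRecord, genes: Sequence[GeneModel]
) -> str:
    """'CDS' when the indel's reference footprint intersects any CDS segment
    of any gene, else 'non-CDS'."""
    f0, f1 = indel.footprint
    for g in genes:
        if g.chrom != indel.chrom:
            continue
        for s, e in g.cds:
            if f0 < e and s < f1:
                return "CDS"
    return "non-CDS"


def gene_survey(
    genes: Sequence[GeneModel],
    variant_sets: Mapping[str, Sequence[VariantRecord]],
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene variant counts per sample: whole gene span (DNA) vs
    mRNA-retained (exonic) sequence.

    Mirrors the cloned-gene survey layout: one row per gene, columns
    ``(sample, 'DNA')`` and ``(sample, 'mRNA')``.
    """
    by_id = {g.gene_id: g for g in genes}
    if gene_ids is None:
        gene_ids = list(by_id)
    unknown = [g for g in gene_ids if g not in by_id]
    if unknown:
        raise ResevarError(
            f"unknown gene id(s) {unknown}; known: {sorted(by_id)}"
        )
    samples = list(variant_sets)
    cols = pd.MultiIndex.from_product([samples, ["DNA", "mRNA"]])
    out = pd.DataFrame(0, index=list(gene_ids), columns=cols)
    for sample, recs in variant_sets.items():
        for r in recs:
            for gid in gene_ids:
                g = by_id[gid]
                if g.chrom != r.chrom or not (g.span[0] <= r.pos < g.span[1]):
                    continue
                out.loc[gid, (sample, "DNA")] += 1
                if any(s <= r.pos < e for s, e in g.cds):
                    out.loc[gid, (sample, "mRNA")] += 1
    return out
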