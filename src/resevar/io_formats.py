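"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are enforced here and nowhere else: VCF and GFF3 are
1-based inclusive on disk, BED is 0-based half-open, and everything inside
the package is 0-based half-open.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    SV_SYMBOL_TO_TYPE,
    SV_TYPE_TO_SYMBOL,
    CoverageMask,
    GeneModel,
    GenomeSequence,
    ResevarError,
    SiteEvidence,
    VariantRecord,
)

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Load a nucleotide FASTA into memory.

    Raises on duplicate chromosome names and on any character outside
    ``{A,C,G,T,N}`` (position reported 0-based).
    """
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ResevarError(f"duplicate chromosome name: {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = next((i for i, b in enumerate(seq) if b not in _VALID_BASES), None)
        if bad is not None:
            raise ResevarError(
                f"non-nucleotide character {seq[bad]!r} in {rec.id!r} at offset {bad}"
            )
        chroms[rec.id] = seq
    if not chroms:
        raise ResevarError(f"no records in FASTA {path}")
    return GenomeSequence(chroms)


def write_fasta(genome: GenomeSequence, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features into :class:`GeneModel` objects.

    One model per gene (first mRNA isoform).  CDS segments are converted to
    0-based half-open and ordered in transcription direction.  A gene whose
    CDS length is not a multiple of three is kept but flagged
    ``annotatable=False`` for codon-level effect calling.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.strand not in ("+", "-"):
            raise ResevarError(f"unknown strand {gene.strand!r} for gene {gene.id}")
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        cds = [
            (c.start - 1, c.end)
            for c in db.children(parent, featuretype="CDS", order_by="start")
        ]
        if not cds:
            continue
        gene_span = (gene.start - 1, gene.end)
        for s, e in cds:
            if s < gene_span[0] or e > gene_span[1]:
                raise ResevarError(
                    f"CDS [{s},{e}) outside span of gene {gene.id} {gene_span}"
                )
        if gene.strand == "-":
            cds = sorted(cds, key=lambda se: se[0], reverse=True)
        total = sum(e - s for s, e in cds)
        annotatable = total % 3 == 0
        if not annotatable:
            logger.warning(
                "gene %s CDS length %d not divisible by 3; "
                "excluded from codon-effect annotation",
                gene.id,
                total,
            )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                span=gene_span,
                cds=cds,
                annotatable=annotatable,
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Emit gene/mRNA/CDS rows (1-based inclusive) with correct phase."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chrom}\tresevar\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tresevar\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            cum = 0
            for cs, ce in g.cds:  # transcription order fixes the phase
                phase = (3 - cum % 3) % 3
                fh.write(
                    f"{g.chrom}\tresevar\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t{phase}\t"
                    f"ID=cds.{mrna_id};Parent={mrna_id}\n"
                )
                cum += ce - cs


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vtype_from_alleles(ref: str, alt: str) -> str:
    if alt.startswith("<"):
        return "SV"
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    return "INS" if len(alt) > len(ref) else "DEL"


def read_vcf_variants(path: str | os.PathLike, sample_id: str) -> list[VariantRecord]:
    """Read a single-sample VCF into :class:`VariantRecord` objects.

    Multi-allelic rows are split into one record per called ALT.  A missing
    genotype is treated as homozygous-alternate with a logged warning (the
    lines under study are inbred and predominantly homozygous).
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    for v in vcf:
        gt = v.genotypes[0] if v.genotypes else [-1, -1, False]
        allele_idx = [a for a in gt[:2] if a >= 0]
        missing = not allele_idx
        if missing:
            logger.warning(
                "missing genotype at %s:%d in %s; treated as hom-alt", v.CHROM, v.POS, path
            )
        qual = float(v.QUAL) if v.QUAL is not None else 99.0
        support = int(v.INFO.get("SUP", 0) or 0)
        for ai, alt in enumerate(v.ALT, start=1):
            if missing:
                zyg = "hom_alt"
            else:
                n = allele_idx.count(ai)
                if n == 0:
                    continue  # this ALT is not carried
                zyg = "hom_alt" if n == 2 else "het"
            vtype = _vtype_from_alleles(v.REF, alt)
            sv_type = None
            end = None
            if vtype == "SV":
                symbol = alt.strip("<>")
                sv_type = SV_SYMBOL_TO_TYPE.get(symbol) or (v.INFO.get("SVTYPE") or None)
                if sv_type in SV_SYMBOL_TO_TYPE:  # SVTYPE given as symbol
                    sv_type = SV_SYMBOL_TO_TYPE[sv_type]
                end = v.INFO.get("END")
                end = int(end) if end is not None else None
            records.append(
                VariantRecord(
                    sample=sample_id,
                    chrom=v.CHROM,
                    pos=v.POS - 1,
                    ref=v.REF,
                    alt=alt,
                    vtype=vtype,
                    zygosity=zyg,
                    qual=qual,
                    support=support,
                    sv_type=sv_type,
                    end=end,
                )
            )
    return records


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | os.PathLike,
    sample_id: str,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write single-sample VCF 4.2; records are sorted by (chrom, pos)."""
    recs = sorted(records, key=lambda r: (r.chrom, r.pos, r.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=resevar\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=SUP,Number=1,Type=Integer,Description="Supporting reads">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end (1-based)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id + "\n"
        )
        for r in recs:
            info = [f"SUP={r.support}"]
            alt = r.alt
            if r.vtype == "SV":
                symbol = SV_TYPE_TO_SYMBOL[r.sv_type]
                alt = f"<{symbol}>"
                info.append(f"SVTYPE={symbol}")
                if r.end is not None:
                    info.append(f"END={r.end}")
            gt = "0/1" if r.zygosity == "het" else "1/1"
            qual = f"{r.qual:.6g}"
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{alt}\t{qual}\tPASS\t"
                + ";".join(info)
                + f"\tGT\t{gt}\n"
            )


# ---------------------------------------------------------------------------
# BED coverage masks
# ---------------------------------------------------------------------------

def read_bed_coverage(path: str | os.PathLike) -> CoverageMask:
    """Load a BED file as a coverage mask; overlapping intervals are merged."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ResevarError(f"BED line {ln}: end {end} <= start {start}")
            raw.setdefault(chrom, []).append((start, end))
    intervals: dict[str, np.ndarray] = {}
    for chrom, ivs in raw.items():
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        intervals[chrom] = np.array(merged, dtype=np.int64)
    return CoverageMask(intervals)


def write_bed(mask: CoverageMask, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, iv in mask.intervals.items():
            for s, e in iv:
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Pileup-lite site evidence
# ---------------------------------------------------------------------------

_PILEUP_COLUMNS = (
    "chrom pos ref bases quals gap_type gap_seq n_gapped_pairs "
    "n_abnormal_pairs signature sv_end"
).split()


def write_pileup_lite(sites: Iterable[SiteEvidence], path: str | os.PathLike) -> None:
    """Write site evidence as TSV (positions 1-based on disk).

    Pileup-lite is this package's site-evidence exchange format: per site it
    records the base calls with phred qualities plus the gapped and abnormal
    read-pair counts consumed by the InDel and SV filters.
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_PILEUP_COLUMNS) + "\n")
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            quals = ",".join(str(q) for q in s.quals)
            fh.write(
                "\t".join(
                    [
                        s.chrom,
                        str(s.pos + 1),
                        s.ref,
                        s.bases or ".",
                        quals or ".",
                        s.gap_type or ".",
                        s.gap_seq or ".",
                        str(s.n_gapped_pairs),
                        str(s.n_abnormal_pairs),
                        s.abnormal_signature or ".",
                        str(s.sv_end + 1) if s.sv_end is not None else ".",
                    ]
                )
                + "\n"
            )


def read_pileup_lite(path: str | os.PathLike) -> list[SiteEvidence]:
    sites: list[SiteEvidence] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            bases = "" if f[3] == "." else f[3]
            quals = () if f[4] == "." else tuple(int(q) for q in f[4].split(","))
            sites.append(
                SiteEvidence(
                    chrom=f[0],
                    pos=int(f[1]) - 1,
                    ref=f[2],
                    bases=bases,
                    quals=quals,
                    gap_type=None if f[5] == "." else f[5],
                    gap_seq="" if f[6] == "." else f[6],
                    n_gapped_pairs=int(f[7]),
                    n_abnormal_pairs=int(f[8]),
                    abnormal_signature=None if f[9] == "." else f[9],
                    sv_end=None if f[10] == "." else int(f[10]) - 1,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# Misc: newick, gene -> GO/PFAM term map
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | os.PathLike) -> None:
    """Serialize a :class:`resevar.phylo.PhyloTree`; output ends with ';'."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_term_map(path: str | os.PathLike) -> pd.DataFrame:
    """Load a gene->term mapping TSV with columns gene_id, namespace, term."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "namespace", "term"}
    if not required.issubset(df.columns):
        raise ResevarError(
            f"term map must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return df
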