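"""Core domain types shared across the pipeline.

All internal coordinates are 0-based half-open.  Conversion to and from the
1-based conventions of VCF/GFF3 happens only at the I/O boundary
(:mod:`resevar.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NUCLEOTIDES = ("A", "C", "G", "T")

#: Structural-variation categories: deletion, duplication (replication),
#: inversion (reversion) and transposition of a segment.
SV_TYPES = ("deletion", "duplication", "inversion", "transposition")

#: Mapping between internal SV types and symbolic VCF ALT alleles.
SV_TYPE_TO_SYMBOL = {
    "deletion": "DEL",
    "duplication": "DUP",
    "inversion": "INV",
    "transposition": "TRA",
}
SV_SYMBOL_TO_TYPE = {v: k for k, v in SV_TYPE_TO_SYMBOL.items()}


class ResevarError(Exception):
    """Base class for pipeline errors."""


@dataclass
class GenomeSequence:
    """A reference genome held in memory.

    ``chroms`` maps chromosome name to an uppercase nucleotide string; the
    insertion order of the mapping is the canonical chromosome order.
    """

    chroms: dict[str, str]

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chroms)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    def base(self, chrom: str, pos: int) -> str:
        return self.chroms[chrom][pos]

    def slice(self, chrom: str, start: int, end: int) -> str:
        return self.chroms[chrom][start:end]


@dataclass
class CoverageMask:
    """Covered intervals of one sample, per chromosome.

    Intervals are sorted, disjoint, 0-based half-open ``(n, 2)`` integer
    arrays.  A position is *covered* when at least one effective read maps
    to it; only covered positions enter between-sample comparisons.
    """

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def covered_bases(self, chrom: str | None = None) -> int:
        if chrom is not None:
            iv = self.intervals.get(chrom)
            if iv is None or len(iv) == 0:
                return 0
            return int((iv[:, 1] - iv[:, 0]).sum())
        return sum(self.covered_bases(c) for c in self.intervals)

    def is_covered(self, chrom: str, pos: int) -> bool:
        iv = self.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            return False
        idx = int(np.searchsorted(iv[:, 0], pos, side="right")) - 1
        return idx >= 0 and pos < iv[idx, 1]

    def covered_in_window(self, chrom: str, start: int, end: int) -> int:
        """Number of covered bases intersecting ``[start, end)``."""
        iv = self.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            return 0
        lo = np.minimum(iv[:, 1], end)
        hi = np.maximum(iv[:, 0], start)
        return int(np.clip(lo - hi, 0, None).sum())


@dataclass
class GeneModel:
    """Strand-aware gene model used for coding-effect annotation.

    ``cds`` holds half-open CDS segments in *transcription* order (for a
    minus-strand gene that means descending genomic coordinates).  A gene
    whose concatenated CDS length is not divisible by three is flagged
    ``annotatable=False`` and excluded from codon-level effect calls.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    span: tuple[int, int]  # mRNA span, half-open
    cds: list[tuple[int, int]]
    annotatable: bool = True

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def genomic_cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in transcription order."""
        out: list[int] = []
        for s, e in self.cds:
            if self.strand == "+":
                out.extend(range(s, e))
            else:
                out.extend(range(e - 1, s - 1, -1))
        return out


@dataclass
class VariantRecord:
    """One called variant in one sample, relative to the reference.

    ``pos`` is 0-based.  For SNPs ``ref``/``alt`` are single bases.  For
    insertions/deletions they follow the VCF anchor-base convention
    (``ref='ACGT', alt='A'`` is a 3 bp deletion).  For SVs ``alt`` is the
    symbolic class and ``end`` marks the end of the affected span.
    """

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str  # 'SNP' | 'INS' | 'DEL' | 'SV'
    zygosity: str = "hom_alt"  # 'hom_alt' | 'het'
    qual: float = 99.0
    support: int = 0
    sv_type: str | None = None
    end: int | None = None

    @property
    def indel_seq(self) -> str:
        """Inserted or deleted sequence (without the anchor base)."""
        if self.vtype == "INS":
            return self.alt[1:]
        if self.vtype == "DEL":
            return self.ref[1:]
        return ""

    @property
    def footprint(self) -> tuple[int, int]:
        """Reference interval affected by the variant, half-open."""
        if self.vtype == "SV":
            return (self.pos, self.end if self.end is not None else self.pos + 1)
        if self.vtype == "DEL":
            return (self.pos + 1, self.pos + len(self.ref))
        if self.vtype == "INS":
            # insertion between pos and pos+1; use the anchor base
            return (self.pos, self.pos + 1)
        return (self.pos, self.pos + 1)


@dataclass
class SiteEvidence:
    """Read-level evidence at one reference site (pileup-lite row).

    Carries exactly the quantities the acceptance filters consume: base
    calls with phred qualities for the genotype model, gapped read-pair
    counts for short-InDel calling, and abnormal read-pair counts with an
    orientation/span signature for SV calling.
    """

    chrom: str
    pos: int  # 0-based
    ref: str
    bases: str = ""
    quals: tuple[int, ...] = ()
    gap_type: str | None = None  # 'INS' | 'DEL'
    gap_seq: str = ""
    n_gapped_pairs: int = 0
    n_abnormal_pairs: int = 0
    abnormal_signature: str | None = None  # one of SV_TYPES
    sv_end: int | None = None

    @property
    def depth(self) -> int:
        return len(self.bases)

    @property
    def gap_len(self) -> int:
        return len(self.gap_seq)


@dataclass
class GenotypeCall:
    """Maximum-posterior diploid genotype at one site.

    ``qual`` is the variant quality used by the acceptance filter: the
    phred-scaled posterior probability that the site is homozygous
    reference (for a hom-ref call, that it is not).  ``genotype_qual`` is
    the phred-scaled probability that the called genotype itself is wrong,
    ``-10*log10(1 - posterior)``.  ``supporting_reads`` counts reads
    carrying the called non-reference allele(s).
    """

    chrom: str
    pos: int
    ref: str
    alleles: tuple[str, str]  # sorted
    posterior: float
    qual: float
    genotype_qual: float
    depth: int
    supporting_reads: int

    @property
    def is_nonref(self) -> bool:
        return any(a != self.ref for a in self.alleles)

    @property
    def zygosity(self) -> str:
        if self.alleles[0] == self.alleles[1]:
            return "hom_alt" if self.alleles[0] != self.ref else "hom_ref"
        return "het"

    def nonref_alleles(self) -> list[str]:
        return sorted({a for a in self.alleles if a != self.ref})
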