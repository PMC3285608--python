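"""Synthetic genomes, gene models, variants, coverage and read evidence.

The generator emulates the study design the pipeline targets: three inbred
samples re-sequenced against a close reference, sharing most of their
variants, with small sets of pair-shared, sample-unique and allelic
pleomorphic ("different") loci; SNPs, short InDels (<=5 bp) and SVs; about
85% of the genome covered per sample; and a low heterozygous background of
about 2x10^-4 per covered base.  Genes are planted with valid ORFs so every
coding-effect class (synonymous, nonsynonymous, premature stop, start loss,
stop loss) is realizable by a single substitution.

Every generated locus is recorded in a truth table that downstream stages
must recover exactly, which makes the whole pipeline testable without any
external data.  All outputs are deterministic given the single integer
seed; each generator stage draws from its own stream derived from it.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io_formats
from .core import (
    NUCLEOTIDES,
    SV_TYPES,
    CoverageMask,
    GeneModel,
    GenomeSequence,
    ResevarError,
    SiteEvidence,
    VariantRecord,
)

_STOPS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# stream keys for per-stage random generators
_STREAMS = {"genome": 0, "genes": 1, "variants": 2, "coverage": 3, "pileup": 4,
            "terms": 5}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Counts are per comparison class; ``snp_shared_pair`` applies to each of
    the three sample pairs and ``snp_unique`` to each sample.  Defaults
    mirror the magnitudes of the target study scaled to a desk-size genome:
    most variants shared by all samples, few pair-shared or unique loci,
    and an order of magnitude fewer allelic-different loci.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 150_000
    n_genes: int = 20
    samples: tuple[str, ...] = ("R1", "R2", "R3")

    # SNP comparison classes
    snp_shared_all: int = 200
    snp_shared_pair: int = 40
    snp_unique: int = 60
    snp_different: int = 10
    n_uncovered: int = 0  # loci deliberately uncovered in one sample

    # coding-effect spikes (shared by all samples, inside CDS)
    n_synonymous: int = 8
    n_nonsynonymous: int = 8
    n_premature_stop: int = 4
    n_start_loss: int = 2
    n_stop_loss: int = 2

    # InDels and SVs
    indel_shared_all: int = 30
    indel_unique: int = 10
    indel_cds: int = 2  # of the shared InDels, placed inside CDS
    indel_max_len: int = 5
    sv_shared_all: int = 4
    sv_unique: int = 2

    # zygosity, coverage, read evidence
    het_fraction: float = 2e-4
    coverage_fraction: float = 0.85
    pileup_depth: float = 10.0
    min_depth: int = 5  # depth floor at emitted sites; 0 allows dropout
    base_error_rate: float = 0.0
    base_qual: int | None = None  # None: phred of base_error_rate, capped at 40
    gapped_pairs: int = 5
    abnormal_pairs: int = 4
    n_background_sites: int = 50  # homozygous-reference evidence sites

    def validate(self) -> None:
        counts = [
            self.n_chroms, self.n_genes, self.snp_shared_all, self.snp_shared_pair,
            self.snp_unique, self.snp_different, self.n_uncovered,
            self.n_synonymous, self.n_nonsynonymous, self.n_premature_stop,
            self.n_start_loss, self.n_stop_loss, self.indel_shared_all,
            self.indel_unique, self.indel_cds, self.sv_shared_all, self.sv_unique,
        ]
        if any(c < 0 for c in counts):
            raise ResevarError("all simulation counts must be >= 0")
        if not (0.0 < self.coverage_fraction <= 1.0):
            raise ResevarError("coverage_fraction must be in (0, 1]")
        if not (1 <= self.indel_max_len <= 5):
            raise ResevarError("indel_max_len must be in [1, 5]")
        if self.chrom_length <= 0:
            raise ResevarError("chrom_length must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class SimulatedDataset:
    """All in-memory products of one simulation run."""

    config: SimulationConfig
    genome: GenomeSequence
    genes: list[GeneModel]
    truth: pd.DataFrame
    variant_sets: dict[str, list[VariantRecord]]
    masks: dict[str, CoverageMask]
    pileups: dict[str, list[SiteEvidence]]
    term_map: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------

_MIN_GENE_FOOTPRINT = 3 * 20 + 60  # shortest CDS plus intron


def generate_genome(config: SimulationConfig) -> GenomeSequence:
    """Uniform-composition random genome, deterministic under the seed."""
    config.validate()
    if config.chrom_length < 3 * _MIN_GENE_FOOTPRINT:
        raise ResevarError(
            f"chrom_length {config.chrom_length} too short; need at least "
            f"{3 * _MIN_GENE_FOOTPRINT}"
        )
    rng = config.rng("genome")
    chroms = {}
    for i in range(config.n_chroms):
        name = f"chr{i + 1:02d}"
        seq = rng.choice(list(NUCLEOTIDES), size=config.chrom_length)
        chroms[name] = "".join(seq)
    return GenomeSequence(chroms)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(NUCLEOTIDES), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def generate_gene_models(
    genome: GenomeSequence, config: SimulationConfig
) -> list[GeneModel]:
    """Plant non-overlapping two-exon genes with valid ORFs on both strands.

    The genome sequence is modified in place so that every CDS, extracted
    strand-aware and translated, starts with Met and ends with a stop with
    no internal stop codon.
    """
    rng = config.rng("genes")
    genes: list[GeneModel] = []
    names = genome.chrom_names
    per_chrom = [config.n_genes // len(names)] * len(names)
    for i in range(config.n_genes % len(names)):
        per_chrom[i] += 1
    intron_len = 60
    for chrom, n_here in zip(names, per_chrom):
        if n_here == 0:
            continue
        L = len(genome.chroms[chrom])
        slot = L // n_here
        if slot < _MIN_GENE_FOOTPRINT + 200:
            raise ResevarError(
                f"cannot place {n_here} genes on {chrom} without overlap; "
                "request fewer genes or a longer chromosome"
            )
        seq = list(genome.chroms[chrom])
        for k in range(n_here):
            n_codons = int(rng.integers(20, 51))
            cds_len = 3 * n_codons
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            gene_len = cds_len + intron_len
            start = k * slot + int(rng.integers(50, slot - gene_len - 50))
            cds_seq = _random_cds(rng, n_codons)
            split = int(rng.integers(1, cds_len))  # bases in first exon
            if strand == "+":
                seg1 = (start, start + split)
                seg2 = (start + split + intron_len, start + gene_len)
                seq[seg1[0] : seg1[1]] = cds_seq[:split]
                seq[seg2[0] : seg2[1]] = cds_seq[split:]
                cds = [seg1, seg2]
            else:
                # first transcribed exon occupies the rightmost segment
                rc = cds_seq.translate(_COMPLEMENT)[::-1]
                seg_left = (start, start + cds_len - split)
                seg_right = (start + cds_len - split + intron_len, start + gene_len)
                seq[seg_left[0] : seg_left[1]] = rc[: cds_len - split]
                seq[seg_right[0] : seg_right[1]] = rc[cds_len - split :]
                cds = [seg_right, seg_left]
            gid = f"gene_{chrom}_{k + 1:03d}"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    span=(start, start + gene_len),
                    cds=cds,
                )
            )
        genome.chroms[chrom] = "".join(seq)
    return genes


# ---------------------------------------------------------------------------
# Variant spiking
# ---------------------------------------------------------------------------

def _classify_substitution(cds: str, offset: int, alt_cds_base: str) -> str:
    """Effect of substituting the CDS base at ``offset`` (re-translation)."""
    ci, within = divmod(offset, 3)
    ref_codon = cds[ci * 3 : ci * 3 + 3]
    alt_codon = ref_codon[:within] + alt_cds_base + ref_codon[within + 1 :]
    n_codons = len(cds) // 3
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ci == 0:
        return "start_loss" if alt_codon != "ATG" else "synonymous"
    if ci == n_codons - 1:
        return "synonymous" if alt_aa == "*" else "stop_loss"
    if alt_aa == "*":
        return "premature_stop"
    return "synonymous" if alt_aa == ref_aa else "nonsynonymous"


def _effect_candidates(
    genome: GenomeSequence, genes: list[GeneModel]
) -> dict[str, list[tuple[str, int, str]]]:
    """All (chrom, pos, alt) single substitutions per effect class."""
    from .effect_annotation import cds_sequence

    out: dict[str, list[tuple[str, int, str]]] = {
        "synonymous": [], "nonsynonymous": [], "premature_stop": [],
        "start_loss": [], "stop_loss": [],
    }
    for g in genes:
        cds = cds_sequence(g, genome)
        positions = g.genomic_cds_positions()
        for offset, pos in enumerate(positions):
            ref_cds_base = cds[offset]
            for alt_cds in NUCLEOTIDES:
                if alt_cds == ref_cds_base:
                    continue
                eff = _classify_substitution(cds, offset, alt_cds)
                alt = alt_cds if g.strand == "+" else alt_cds.translate(_COMPLEMENT)
                out[eff].append((g.chrom, pos, alt))
    return out


class _PositionPool:
    """Tracks occupied reference positions with a safety margin."""

    def __init__(self, margin: int = 6) -> None:
        self.margin = margin
        self.taken: dict[str, set[int]] = {}

    def reserve(self, chrom: str, start: int, end: int) -> bool:
        taken = self.taken.setdefault(chrom, set())
        span = range(start - self.margin, end + self.margin)
        if any(p in taken for p in span):
            return False
        taken.update(range(start, end))
        return True


def _draw_positions(
    rng: np.random.Generator,
    genome: GenomeSequence,
    pool: _PositionPool,
    n: int,
    exclude_cds: set[tuple[str, int]] | None,
    footprint: int = 1,
) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    names = genome.chrom_names
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 500 * max(n, 1) + 5000:
            raise ResevarError("could not place requested variant loci")
        chrom = names[int(rng.integers(0, len(names)))]
        L = len(genome.chroms[chrom])
        pos = int(rng.integers(10, L - footprint - 10))
        if exclude_cds is not None and any(
            (chrom, p) in exclude_cds for p in range(pos, pos + footprint)
        ):
            continue
        if pool.reserve(chrom, pos, pos + footprint):
            out.append((chrom, pos))
    return out


def _alt_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in NUCLEOTIDES if b != ref]
    return choices[int(rng.integers(0, 3))]


def spike_variants(
    genome: GenomeSequence, genes: list[GeneModel], config: SimulationConfig
) -> tuple[dict[str, list[VariantRecord]], pd.DataFrame]:
    """Plant variants of every comparison and effect class.

    Returns per-sample variant records and the truth table.  Every truth
    row appears exactly once; comparison classes are mutually exclusive per
    locus.  At a "different" locus every sample receives a distinct
    alternate base; "uncovered" loci are carried by all but one sample and
    that sample is later left without coverage there, making the locus
    ineligible for between-sample comparison.
    """
    rng = config.rng("variants")
    samples = list(config.samples)
    pool = _PositionPool()
    cds_positions = {
        (g.chrom, p) for g in genes for s, e in g.cds for p in range(s, e)
    }
    rows: list[dict] = []

    def add_row(chrom, pos, vtype, ref, carriers, alts, comp_class, effect=".",
                zygosity="hom_alt", sv_type=".", end=-1, uncovered_sample="."):
        rows.append(
            dict(
                chrom=chrom, pos=pos, vtype=vtype, ref=ref,
                carriers=",".join(carriers), alts=",".join(alts),
                comp_class=comp_class, effect=effect, zygosity=zygosity,
                sv_type=sv_type, end=end, uncovered_sample=uncovered_sample,
            )
        )

    # --- structural variations (placed first: their long footprints need
    # --- room before point variants crowd the position pool) --------------
    def spike_sv(carriers, comp_class):
        span = int(rng.integers(500, 1501))
        ((chrom, pos),) = _draw_positions(
            rng, genome, pool, 1, cds_positions, footprint=span
        )
        sv_type = SV_TYPES[int(rng.integers(0, len(SV_TYPES)))]
        add_row(chrom, pos, "SV", genome.base(chrom, pos), carriers,
                [sv_type] * len(carriers), comp_class, sv_type=sv_type,
                end=pos + span)

    for _ in range(config.sv_shared_all):
        spike_sv(samples, "shared_all")
    for s in samples:
        for _ in range(config.sv_unique):
            spike_sv([s], f"unique_{s}")

    # --- coding-effect SNP spikes (shared by every sample) ----------------
    candidates = _effect_candidates(genome, genes)
    effect_requests = {
        "synonymous": config.n_synonymous,
        "nonsynonymous": config.n_nonsynonymous,
        "premature_stop": config.n_premature_stop,
        "start_loss": config.n_start_loss,
        "stop_loss": config.n_stop_loss,
    }
    for effect, n in effect_requests.items():
        cand = candidates[effect]
        order = rng.permutation(len(cand))
        placed = 0
        for idx in order:
            if placed == n:
                break
            chrom, pos, alt = cand[idx]
            if pool.reserve(chrom, pos, pos + 1):
                add_row(chrom, pos, "SNP", genome.base(chrom, pos), samples,
                        [alt] * len(samples), "shared_all", effect=effect)
                placed += 1
        if placed < n:
            raise ResevarError(
                f"requested {n} {effect} spikes but only {placed} codon sites "
                "are available; increase n_genes"
            )

    # --- plain SNP comparison classes (outside CDS) -----------------------
    for chrom, pos in _draw_positions(
        rng, genome, pool, config.snp_shared_all, cds_positions
    ):
        ref = genome.base(chrom, pos)
        alt = _alt_base(rng, ref)
        add_row(chrom, pos, "SNP", ref, samples, [alt] * len(samples), "shared_all")

    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            pair = [samples[i], samples[j]]
            for chrom, pos in _draw_positions(
                rng, genome, pool, config.snp_shared_pair, cds_positions
            ):
                ref = genome.base(chrom, pos)
                alt = _alt_base(rng, ref)
                add_row(chrom, pos, "SNP", ref, pair, [alt, alt],
                        f"shared_pair_{pair[0]}_{pair[1]}")

    for s in samples:
        for chrom, pos in _draw_positions(
            rng, genome, pool, config.snp_unique, cds_positions
        ):
            ref = genome.base(chrom, pos)
            add_row(chrom, pos, "SNP", ref, [s], [_alt_base(rng, ref)],
                    f"unique_{s}")

    for chrom, pos in _draw_positions(
        rng, genome, pool, config.snp_different, cds_positions
    ):
        ref = genome.base(chrom, pos)
        alts = [b for b in NUCLEOTIDES if b != ref]
        alts = [alts[k] for k in rng.permutation(3)][: len(samples)]
        add_row(chrom, pos, "SNP", ref, samples, alts, "different")

    # --- deliberately uncovered (ineligible) loci -------------------------
    for k, (chrom, pos) in enumerate(
        _draw_positions(rng, genome, pool, config.n_uncovered, cds_positions)
    ):
        uncov = samples[k % len(samples)]
        carriers = [s for s in samples if s != uncov]
        ref = genome.base(chrom, pos)
        alt = _alt_base(rng, ref)
        add_row(chrom, pos, "SNP", ref, carriers, [alt] * len(carriers),
                "ineligible", uncovered_sample=uncov)

    # --- heterozygous background (per sample, at the target rate) ---------
    approx_covered = int(
        config.coverage_fraction * config.n_chroms * config.chrom_length
    )
    for s in samples:
        n_het = int(rng.binomial(approx_covered, config.het_fraction))
        for chrom, pos in _draw_positions(rng, genome, pool, n_het, cds_positions):
            ref = genome.base(chrom, pos)
            add_row(chrom, pos, "SNP", ref, [s], [_alt_base(rng, ref)],
                    f"unique_{s}", zygosity="het")

    # --- short InDels ------------------------------------------------------
    def spike_indel(chrom, pos, carriers, comp_class):
        ref_anchor = genome.base(chrom, pos)
        length = int(rng.integers(1, config.indel_max_len + 1))
        if rng.integers(0, 2) == 0:  # deletion
            ref = genome.slice(chrom, pos, pos + 1 + length)
            alt = ref_anchor
            vtype = "DEL"
        else:
            ins = "".join(rng.choice(list(NUCLEOTIDES), size=length))
            ref = ref_anchor
            alt = ref_anchor + ins
            vtype = "INS"
        add_row(chrom, pos, vtype, ref, carriers, [alt] * len(carriers), comp_class)

    n_noncds = config.indel_shared_all - config.indel_cds
    if n_noncds < 0:
        raise ResevarError("indel_cds exceeds indel_shared_all")
    for chrom, pos in _draw_positions(
        rng, genome, pool, n_noncds, cds_positions, footprint=config.indel_max_len + 1
    ):
        spike_indel(chrom, pos, samples, "shared_all")
    # CDS-footprint InDels: drawn from CDS interiors
    cds_inner = [
        (g.chrom, p)
        for g in genes
        for s, e in g.cds
        for p in range(s + 3, e - config.indel_max_len - 3)
    ]
    order = rng.permutation(len(cds_inner))
    placed = 0
    for idx in order:
        if placed == config.indel_cds:
            break
        chrom, pos = cds_inner[idx]
        if pool.reserve(chrom, pos, pos + config.indel_max_len + 1):
            spike_indel(chrom, pos, samples, "shared_all")
            placed += 1
    if placed < config.indel_cds:
        raise ResevarError("could not place requested CDS InDels")
    for s in samples:
        for chrom, pos in _draw_positions(
            rng, genome, pool, config.indel_unique, cds_positions,
            footprint=config.indel_max_len + 1,
        ):
            spike_indel(chrom, pos, [s], f"unique_{s}")

    truth = pd.DataFrame(rows).sort_values(
        ["chrom", "pos", "vtype"], ignore_index=True
    )
    variant_sets = truth_to_variant_sets(truth, config)
    return variant_sets, truth


def truth_to_variant_sets(
    truth: pd.DataFrame, config: SimulationConfig
) -> dict[str, list[VariantRecord]]:
    """Expand truth rows into per-sample variant records."""
    sets: dict[str, list[VariantRecord]] = {s: [] for s in config.samples}
    for row in truth.itertuples():
        carriers = row.carriers.split(",")
        alts = row.alts.split(",")
        for sample, alt in zip(carriers, alts):
            if row.vtype == "SV":
                rec = VariantRecord(
                    sample=sample, chrom=row.chrom, pos=int(row.pos), ref=row.ref,
                    alt=f"<{alt}>", vtype="SV", zygosity=row.zygosity,
                    support=config.abnormal_pairs, sv_type=row.sv_type,
                    end=int(row.end),
                )
            else:
                support = (
                    int(round(config.pileup_depth))
                    if row.vtype == "SNP"
                    else config.gapped_pairs
                )
                rec = VariantRecord(
                    sample=sample, chrom=row.chrom, pos=int(row.pos), ref=row.ref,
                    alt=alt, vtype=row.vtype, zygosity=row.zygosity,
                    support=support,
                )
            sets[sample].append(rec)
    for s in sets:
        sets[s].sort(key=lambda r: (r.chrom, r.pos, r.vtype, r.alt))
    return sets


# ---------------------------------------------------------------------------
# Coverage masks
# ---------------------------------------------------------------------------

def generate_coverage(
    genome: GenomeSequence, config: SimulationConfig, truth: pd.DataFrame
) -> dict[str, CoverageMask]:
    """Per-sample coverage masks at the configured covered fraction.

    Gaps avoid every truth locus except the designated sample of each
    "uncovered" locus, where a small gap is punched on purpose.  The
    realized covered fraction stays within one percentage point of the
    target.
    """
    rng = config.rng("coverage")
    masks: dict[str, CoverageMask] = {}
    for sample in config.samples:
        intervals: dict[str, np.ndarray] = {}
        for chrom in genome.chrom_names:
            L = len(genome.chroms[chrom])
            gap = np.zeros(L, dtype=bool)
            protected = np.zeros(L, dtype=bool)
            sub = truth[truth.chrom == chrom]
            for row in sub.itertuples():
                end = int(row.end) if row.vtype == "SV" and row.end >= 0 else (
                    int(row.pos) + len(row.ref)
                )
                lo = max(0, int(row.pos) - 2)
                hi = min(L, end + 2)
                if row.uncovered_sample == sample:
                    # punch exactly the locus footprint; spiked loci keep a
                    # spacing margin so neighbours stay covered
                    gap[int(row.pos) : min(L, end)] = True
                else:
                    protected[lo:hi] = True
            target_gap = int(round((1.0 - config.coverage_fraction) * L))
            attempts = 0
            while int(gap.sum()) < target_gap:
                attempts += 1
                if attempts > 10000:
                    raise ResevarError(
                        "coverage_fraction too low to keep all spiked loci covered"
                    )
                remaining = target_gap - int(gap.sum())
                glen = int(min(remaining, rng.integers(200, 801)))
                start = int(rng.integers(0, L - glen))
                seg = slice(start, start + glen)
                if protected[seg].any() or gap[seg].any():
                    continue
                gap[seg] = True
            covered = ~gap
            frac = covered.mean()
            if abs(frac - config.coverage_fraction) > 0.01:
                raise ResevarError(
                    f"covered fraction {frac:.3f} misses target "
                    f"{config.coverage_fraction:.3f} on {chrom}"
                )
            # boolean mask -> half-open intervals
            edges = np.flatnonzero(np.diff(covered.astype(np.int8)))
            starts = [0] if covered[0] else []
            starts += [int(e) + 1 for e in edges if covered[e + 1]]
            ends = [int(e) + 1 for e in edges if covered[e]]
            if covered[-1]:
                ends.append(L)
            intervals[chrom] = np.array(
                list(zip(starts, ends)), dtype=np.int64
            ).reshape(-1, 2)
        masks[sample] = CoverageMask(intervals)
    return masks


# ---------------------------------------------------------------------------
# Pileup-lite evidence
# ---------------------------------------------------------------------------

def generate_pileups(
    genome: GenomeSequence, truth: pd.DataFrame, config: SimulationConfig
) -> dict[str, list[SiteEvidence]]:
    """Read-level evidence per sample at every truth locus.

    SNP sites draw a Poisson depth around the configured mean; base calls
    follow the sample's genotype through a uniform error channel.  Carrier
    samples at InDel loci get the configured gapped-pair support; carriers
    at SV loci get the configured abnormal-pair support with the matching
    signature.  Non-carrier samples receive homozygous-reference base
    evidence at SNP loci.  Sites that draw depth zero are omitted.
    """
    rng = config.rng("pileup")
    out: dict[str, list[SiteEvidence]] = {s: [] for s in config.samples}
    if config.base_qual is not None:
        base_qual = config.base_qual
    else:
        # qualities consistent with the simulated error channel
        err = max(config.base_error_rate, 1e-4)
        base_qual = min(40, int(round(-10.0 * np.log10(err))))

    def draw_bases(genotype: tuple[str, str], depth: int) -> str:
        # Heterozygous sites get an exact half split of the two alleles (up
        # to parity), keeping them callable whenever the depth floor holds;
        # the error channel below still perturbs individual base calls.
        a, b = genotype
        if a == b:
            alleles = [a] * depth
        else:
            n_a = depth // 2 + (depth % 2 and int(rng.integers(0, 2)))
            alleles = [a] * n_a + [b] * (depth - n_a)
            rng.shuffle(alleles)
        bases = []
        for allele in alleles:
            if config.base_error_rate > 0 and rng.random() < config.base_error_rate:
                allele = [x for x in NUCLEOTIDES if x != allele][
                    int(rng.integers(0, 3))
                ]
            bases.append(allele)
        return "".join(bases)

    def draw_depth() -> int:
        depth = int(rng.poisson(config.pileup_depth))
        return max(depth, config.min_depth)

    for row in truth.itertuples():
        carriers = dict(zip(row.carriers.split(","), row.alts.split(",")))
        for sample in config.samples:
            if row.uncovered_sample == sample:
                continue  # no reads map here by design
            alt = carriers.get(sample)
            if row.vtype == "SNP":
                ref = row.ref
                if alt is None:
                    genotype = (ref, ref)
                elif row.zygosity == "het":
                    genotype = (ref, alt)
                else:
                    genotype = (alt, alt)
                depth = draw_depth()
                if depth == 0:
                    continue
                out[sample].append(
                    SiteEvidence(
                        chrom=row.chrom, pos=int(row.pos), ref=ref,
                        bases=draw_bases(genotype, depth),
                        quals=(base_qual,) * depth,
                    )
                )
            elif row.vtype in ("INS", "DEL") and alt is not None:
                if row.vtype == "DEL":
                    gap_seq = row.ref[1:]
                else:
                    gap_seq = alt[1:]
                out[sample].append(
                    SiteEvidence(
                        chrom=row.chrom, pos=int(row.pos), ref=row.ref[0],
                        gap_type=row.vtype, gap_seq=gap_seq,
                        n_gapped_pairs=config.gapped_pairs,
                    )
                )
            elif row.vtype == "SV" and alt is not None:
                out[sample].append(
                    SiteEvidence(
                        chrom=row.chrom, pos=int(row.pos), ref=row.ref,
                        n_abnormal_pairs=config.abnormal_pairs,
                        abnormal_signature=row.sv_type,
                        sv_end=int(row.end),
                    )
                )

    # homozygous-reference background sites (false-positive control)
    taken = {(r.chrom, int(r.pos)) for r in truth.itertuples()}
    names = genome.chrom_names
    for sample in config.samples:
        placed = 0
        while placed < config.n_background_sites:
            chrom = names[int(rng.integers(0, len(names)))]
            pos = int(rng.integers(0, len(genome.chroms[chrom])))
            if (chrom, pos) in taken:
                continue
            depth = draw_depth()
            if depth == 0:
                placed += 1
                continue
            ref = genome.base(chrom, pos)
            out[sample].append(
                SiteEvidence(
                    chrom=chrom, pos=pos, ref=ref,
                    bases=draw_bases((ref, ref), depth),
                    quals=(base_qual,) * depth,
                )
            )
            placed += 1
    for s in out:
        out[s].sort(key=lambda e: (e.chrom, e.pos))
    return out


# ---------------------------------------------------------------------------
# Gene -> GO/PFAM style term map
# ---------------------------------------------------------------------------

_TOY_TERMS = (
    "protein kinase activity", "nucleic acid binding", "protein binding",
    "DNA binding", "catalytic activity", "transporter activity",
)
_TOY_DOMAINS = ("LRR", "NB-ARC", "Pkinase", "Myb_DNA-binding")


def generate_term_map(
    genes: list[GeneModel], config: SimulationConfig
) -> pd.DataFrame:
    """Toy gene -> GO/PFAM mapping so functional tallies are exercisable."""
    rng = config.rng("terms")
    rows = []
    for g in genes:
        rows.append(
            {"gene_id": g.gene_id, "namespace": "GO",
             "term": _TOY_TERMS[int(rng.integers(0, len(_TOY_TERMS)))]}
        )
        if rng.random() < 0.6:
            rows.append(
                {"gene_id": g.gene_id, "namespace": "PFAM",
                 "term": _TOY_DOMAINS[int(rng.integers(0, len(_TOY_DOMAINS)))]}
            )
    return pd.DataFrame(rows, columns=["gene_id", "namespace", "term"])


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate(
    config: SimulationConfig, outdir: str | os.PathLike | None = None
) -> SimulatedDataset:
    """Run all generator stages; optionally write every artifact to disk."""
    genome = generate_genome(config)
    genes = generate_gene_models(genome, config)
    variant_sets, truth = spike_variants(genome, genes, config)
    masks = generate_coverage(genome, config, truth)
    pileups = generate_pileups(genome, truth, config)
    term_map = generate_term_map(genes, config)
    ds = SimulatedDataset(
        config=config, genome=genome, genes=genes, truth=truth,
        variant_sets=variant_sets, masks=masks, pileups=pileups,
        term_map=term_map,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"genome": outdir / "genome.fa", "genes": outdir / "genes.gff3",
                 "truth": outdir / "truth.tsv", "terms": outdir / "terms.tsv"}
        io_formats.write_fasta(genome, paths["genome"])
        io_formats.write_gff3(genes, paths["genes"])
        truth.to_csv(paths["truth"], sep="\t", index=False)
        term_map.to_csv(paths["terms"], sep="\t", index=False)
        for s in config.samples:
            paths[f"vcf_{s}"] = outdir / f"{s}.vcf"
            io_formats.write_vcf(
                variant_sets[s], paths[f"vcf_{s}"], s, contigs=genome.lengths
            )
            paths[f"bed_{s}"] = outdir / f"{s}.bed"
            io_formats.write_bed(masks[s], paths[f"bed_{s}"])
            paths[f"pileup_{s}"] = outdir / f"{s}.pileup.tsv"
            io_formats.write_pileup_lite(pileups[s], paths[f"pileup_{s}"])
        ds.paths = paths
    return ds


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a plain mapping (CLI/YAML entry point)."""
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ResevarError(f"unknown simulation parameter(s): {sorted(unknown)}")
    if "samples" in d:
        d = {**d, "samples": tuple(d["samples"])}
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg
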