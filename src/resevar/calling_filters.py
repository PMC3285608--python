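"""Simplified Bayesian genotype caller and variant acceptance filters.

The caller assigns each site one of the ten diploid genotypes over
``{A,C,G,T}`` by maximum posterior under an independent-reads error model:
a base observed from a homozygote matches its allele with probability
``1 - eps`` (``eps = 10^(-q/10)``, spread equally over the other three
bases), and a heterozygote emits each of its alleles with probability 1/2
before the same error channel.  The quality value attached to a call is
the phred-scaled posterior probability that the site is homozygous
reference; the phred-scaled genotype posterior is carried alongside.  With
an inbred-line prior the heterozygote competitor bounds the genotype
posterior of a homozygous-alternate call near ``1 - 0.6 * 2**-depth``
whatever the base qualities, so filtering on the genotype posterior would
reject every site below about six reads; the against-reference reading
keeps the documented quality/support thresholds meaningful at the depths
the filters name.

The downstream acceptance filters encode the conservative thresholds used
throughout the pipeline: SNPs need a quality value strictly above 20 and
at least two supporting reads; short InDels are 1-5 bp gaps supported by at
least three gapped read pairs; SVs need at least three abnormal read pairs
with a consistent signature.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Sequence

from .core import (
    NUCLEOTIDES,
    SV_TYPES,
    GenotypeCall,
    ResevarError,
    SiteEvidence,
    VariantRecord,
)

logger = logging.getLogger(__name__)

#: The ten unordered diploid genotypes, alphabetical.
DIPLOID_GENOTYPES: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations_with_replacement(NUCLEOTIDES, 2)
)


def default_prior(ref: str) -> dict[tuple[str, str], float]:
    """Genotype prior for a predominantly homozygous inbred line.

    Hom-ref mass 0.998; 5e-4 for each hom-alt; 1e-4 for each heterozygote.
    Normalized to sum to one.  Any proper prior preserves the caller's
    acceptance properties; this default merely reflects the inbred-line
    expectation that non-reference and heterozygous sites are rare.
    """
    prior: dict[tuple[str, str], float] = {}
    for g in DIPLOID_GENOTYPES:
        if g == (ref, ref):
            prior[g] = 0.998
        elif g[0] == g[1]:
            prior[g] = 5e-4
        else:
            prior[g] = 1e-4
    total = sum(prior.values())
    return {g: p / total for g, p in prior.items()}


def _log_base_likelihood(base: str, genotype: tuple[str, str], eps: float) -> float:
    def p_from_allele(allele: str) -> float:
        return 1.0 - eps if base == allele else eps / 3.0

    a, b = genotype
    if a == b:
        return math.log(p_from_allele(a))
    return math.log(0.5 * p_from_allele(a) + 0.5 * p_from_allele(b))


def genotype_posteriors(
    evidence: SiteEvidence, prior: dict[tuple[str, str], float] | None = None
) -> dict[tuple[str, str], float]:
    """Posterior probability of each of the ten genotypes at a site."""
    if evidence.depth == 0:
        raise ResevarError(f"no evidence at {evidence.chrom}:{evidence.pos + 1}")
    if prior is None:
        prior = default_prior(evidence.ref)
    log_post = {}
    for g in DIPLOID_GENOTYPES:
        lp = math.log(prior[g])
        for base, q in zip(evidence.bases, evidence.quals):
            eps = 10.0 ** (-q / 10.0)
            lp += _log_base_likelihood(base, g, eps)
        log_post[g] = lp
    mx = max(log_post.values())
    unnorm = {g: math.exp(lp - mx) for g, lp in log_post.items()}
    z = sum(unnorm.values())
    return {g: u / z for g, u in unnorm.items()}


def genotype_site(
    evidence: SiteEvidence, prior: dict[tuple[str, str], float] | None = None
) -> GenotypeCall:
    """Call the maximum-posterior genotype at one site.

    Ties are broken deterministically: hom-ref first, then hom-alt in
    allele-alphabetical order, then heterozygotes in allele-alphabetical
    order.
    """
    post = genotype_posteriors(evidence, prior)
    ref = evidence.ref

    def rank(g: tuple[str, str]) -> tuple:
        if g == (ref, ref):
            tier = 0
        elif g[0] == g[1]:
            tier = 1
        else:
            tier = 2
        return (tier, g)

    best = min(post, key=lambda g: (-post[g], rank(g)))
    p_best = post[best]

    def phred(p: float) -> float:
        return 10000.0 if p <= 1e-300 else -10.0 * math.log10(p)

    # Error masses are computed as posterior sums of the competing
    # genotypes, which stays accurate when p_best is within rounding of 1.
    p_wrong_genotype = sum(p for g, p in post.items() if g != best)
    p_hom_ref = post[(ref, ref)]
    # Variant quality: confidence that the site differs from the reference
    # (for a hom-ref call, that it does not).
    qual = phred(p_hom_ref if best != (ref, ref) else 1.0 - p_hom_ref)
    nonref = {a for a in best if a != ref}
    support = sum(1 for b in evidence.bases if b in nonref)
    return GenotypeCall(
        chrom=evidence.chrom,
        pos=evidence.pos,
        ref=ref,
        alleles=best,
        posterior=p_best,
        qual=qual,
        genotype_qual=phred(p_wrong_genotype),
        depth=evidence.depth,
        supporting_reads=support,
    )


def filter_snp_calls(
    calls: Iterable[GenotypeCall],
    sample: str,
    min_qual: float = 20.0,
    min_reads: int = 2,
) -> list[VariantRecord]:
    """Keep non-reference calls with quality strictly above ``min_qual`` and
    at least ``min_reads`` supporting reads; emit one SNP record per
    non-reference allele."""
    out: list[VariantRecord] = []
    for c in calls:
        if not c.is_nonref:
            continue
        if not (c.qual > min_qual and c.supporting_reads >= min_reads):
            continue
        for alt in c.nonref_alleles():
            out.append(
                VariantRecord(
                    sample=sample,
                    chrom=c.chrom,
                    pos=c.pos,
                    ref=c.ref,
                    alt=alt,
                    vtype="SNP",
                    zygosity="het" if c.zygosity == "het" else "hom_alt",
                    qual=c.qual,
                    support=c.supporting_reads,
                )
            )
    return out


def call_indels(
    evidence: Iterable[SiteEvidence],
    sample: str,
    max_len: int = 5,
    min_gapped_pairs: int = 3,
) -> list[VariantRecord]:
    """Accept 1-5 bp gaps supported by at least three gapped read pairs."""
    out: list[VariantRecord] = []
    for site in evidence:
        if site.gap_type is None:
            continue
        glen = site.gap_len
        if glen == 0:
            logger.warning(
                "gap of length 0 at %s:%d skipped", site.chrom, site.pos + 1
            )
            continue
        if glen > max_len or site.n_gapped_pairs < min_gapped_pairs:
            continue
        if site.gap_type == "DEL":
            ref = site.ref + site.gap_seq
            alt = site.ref
        elif site.gap_type == "INS":
            ref = site.ref
            alt = site.ref + site.gap_seq
        else:
            raise ResevarError(f"unknown gap type {site.gap_type!r}")
        out.append(
            VariantRecord(
                sample=sample,
                chrom=site.chrom,
                pos=site.pos,
                ref=ref,
                alt=alt,
                vtype=site.gap_type,
                qual=99.0,
                support=site.n_gapped_pairs,
            )
        )
    return out


def call_svs(
    evidence: Iterable[SiteEvidence],
    sample: str,
    min_abnormal_pairs: int = 3,
    join_distance: int = 1000,
) -> list[VariantRecord]:
    """Cluster abnormal-pair sites and emit one SV per supported cluster.

    Adjacent sites carrying the same abnormal signature on the same
    chromosome are merged when separated by at most ``join_distance``; a
    cluster becomes an SV when its summed abnormal-pair support reaches
    ``min_abnormal_pairs``.
    """
    sv_sites = [s for s in evidence if s.abnormal_signature is not None]
    for s in sv_sites:
        if s.abnormal_signature not in SV_TYPES:
            raise ResevarError(f"unknown SV signature {s.abnormal_signature!r}")
    sv_sites.sort(key=lambda s: (s.chrom, s.abnormal_signature, s.pos))
    out: list[VariantRecord] = []
    cluster: list[SiteEvidence] = []

    def flush() -> None:
        if not cluster:
            return
        total = sum(s.n_abnormal_pairs for s in cluster)
        if total >= min_abnormal_pairs:
            first, last = cluster[0], cluster[-1]
            end = max(
                [s.sv_end for s in cluster if s.sv_end is not None] or [last.pos + 1]
            )
            out.append(
                VariantRecord(
                    sample=sample,
                    chrom=first.chrom,
                    pos=first.pos,
                    ref=first.ref,
                    alt=f"<{first.abnormal_signature}>",
                    vtype="SV",
                    qual=99.0,
                    support=total,
                    sv_type=first.abnormal_signature,
                    end=end,
                )
            )
        cluster.clear()

    for s in sv_sites:
        if cluster and (
            s.chrom != cluster[-1].chrom
            or s.abnormal_signature != cluster[-1].abnormal_signature
            or s.pos - cluster[-1].pos > join_distance
        ):
            flush()
        cluster.append(s)
    flush()
    out.sort(key=lambda r: (r.chrom, r.pos))
    return out


def call_sample(
    evidence: Sequence[SiteEvidence],
    sample: str,
    min_snp_qual: float = 20.0,
    min_snp_reads: int = 2,
    max_indel_len: int = 5,
    min_gapped_pairs: int = 3,
    min_abnormal_pairs: int = 3,
    sv_join_distance: int = 1000,
    prior: dict[tuple[str, str], float] | None = None,
) -> list[VariantRecord]:
    """Run the full calling stage for one sample's evidence stream."""
    snp_sites = [s for s in evidence if s.depth > 0 and s.gap_type is None
                 and s.abnormal_signature is None]
    calls = [genotype_site(s, prior) for s in snp_sites]
    records = filter_snp_calls(calls, sample, min_snp_qual, min_snp_reads)
    records += call_indels(evidence, sample, max_indel_len, min_gapped_pairs)
    records += call_svs(evidence, sample, min_abnormal_pairs, sv_join_distance)
    records.sort(key=lambda r: (r.chrom, r.pos, r.vtype, r.alt))
    return records
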