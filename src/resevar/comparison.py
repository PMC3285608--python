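"""Multi-sample locus classification: shared, different, unique, ineligible.

A *locus* groups the per-sample variant records that describe the same
site-level event class: SNPs by exact position, short InDels by position
(with the inserted/deleted sequence as the allele identity, so "shared"
means the same event), and SVs by same-type reciprocal-overlap clustering.

Classification over the compared samples follows the consensus rules:

* ``shared``     — every compared sample carries the identical alternate
  allele.
* ``different``  — every compared sample is non-reference but the alternate
  alleles are not all identical (allelic pleomorphic locus).
* ``unique_to_X``— exactly one compared sample is non-reference.
* ``partial``    — a strict subset (>=2) of samples carries the variant
  (shared within a pair when three samples are compared).
* ``ineligible`` — some compared sample has no read coverage at the locus,
  so the locus is excluded from between-sample comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import CoverageMask, ResevarError, VariantRecord

#: Variant-class labels used in the summary tables.
CATEGORIES = ("SNP", "InDel", "SV")


def _category(vtype: str) -> str:
    if vtype == "SNP":
        return "SNP"
    if vtype in ("INS", "DEL"):
        return "InDel"
    if vtype == "SV":
        return "SV"
    raise ResevarError(f"unknown variant type {vtype!r}")


def _allele_id(rec: VariantRecord) -> str:
    """Identity of the alternate event used for shared/different calls."""
    cat = _category(rec.vtype)
    if cat == "SNP":
        return rec.alt
    if cat == "InDel":
        return f"{rec.vtype}:{rec.indel_seq}"
    return rec.sv_type or "SV"


@dataclass
class Locus:
    """All per-sample records describing one comparable variant locus."""

    chrom: str
    pos: int
    category: str
    ref: str
    alleles: dict[str, str] = field(default_factory=dict)  # sample -> allele id
    records: dict[str, VariantRecord] = field(default_factory=dict)


def _cluster_svs(
    variant_sets: Mapping[str, Sequence[VariantRecord]], min_reciprocal_overlap: float
) -> list[Locus]:
    """Group SVs across samples by same type and reciprocal overlap."""
    svs: list[VariantRecord] = [
        r for recs in variant_sets.values() for r in recs if r.vtype == "SV"
    ]
    svs.sort(key=lambda r: (r.chrom, r.sv_type or "", r.pos))
    loci: list[Locus] = []
    current: list[VariantRecord] = []

    def overlaps(a: VariantRecord, b: VariantRecord) -> bool:
        a0, a1 = a.footprint
        b0, b1 = b.footprint
        ov = min(a1, b1) - max(a0, b0)
        if ov <= 0:
            return False
        return (
            ov >= min_reciprocal_overlap * (a1 - a0)
            and ov >= min_reciprocal_overlap * (b1 - b0)
        )

    def flush() -> None:
        if not current:
            return
        loc = Locus(
            chrom=current[0].chrom,
            pos=min(r.pos for r in current),
            category="SV",
            ref=current[0].ref,
        )
        for r in current:
            loc.alleles[r.sample] = _allele_id(r)
            loc.records[r.sample] = r
        loci.append(loc)
        current.clear()

    for r in svs:
        if current and not (
            r.chrom == current[0].chrom
            and r.sv_type == current[0].sv_type
            and any(overlaps(r, c) for c in current)
        ):
            flush()
        current.append(r)
    flush()
    return loci


def build_loci(
    variant_sets: Mapping[str, Sequence[VariantRecord]],
    sv_min_reciprocal_overlap: float = 0.5,
) -> list[Locus]:
    """Collate per-sample variant records into comparable loci."""
    site_loci: dict[tuple, Locus] = {}
    for sample, recs in variant_sets.items():
        for r in recs:
            cat = _category(r.vtype)
            if cat == "SV":
                continue
            key = (r.chrom, r.pos, cat)
            loc = site_loci.get(key)
            if loc is None:
                loc = Locus(chrom=r.chrom, pos=r.pos, category=cat, ref=r.ref[0])
                site_loci[key] = loc
            loc.alleles[sample] = _allele_id(r)
            loc.records[sample] = r
    loci = list(site_loci.values())
    loci += _cluster_svs(variant_sets, sv_min_reciprocal_overlap)
    loci.sort(key=lambda l: (l.chrom, l.pos, l.category))
    return loci


def eligible_loci(
    loci: Iterable[Locus],
    masks: Mapping[str, CoverageMask],
    samples: Sequence[str],
) -> tuple[list[Locus], list[Locus]]:
    """Split loci into (eligible, ineligible) under the coverage rule.

    A locus is eligible only when every compared sample has at least one
    effective read mapped at its position.
    """
    for s in samples:
        if s not in masks:
            raise ResevarError(f"no coverage mask for sample {s!r}")
    ok: list[Locus] = []
    bad: list[Locus] = []
    for loc in loci:
        if all(masks[s].is_covered(loc.chrom, loc.pos) for s in samples):
            ok.append(loc)
        else:
            bad.append(loc)
    return ok, bad


def classify_locus(locus: Locus, samples: Sequence[str]) -> str:
    """Classify one eligible locus over the compared samples."""
    carriers = [s for s in samples if s in locus.alleles]
    if not carriers:
        raise ResevarError(
            f"{locus.chrom}:{locus.pos + 1} is not a variant locus in the "
            "compared samples"
        )
    alleles = {locus.alleles[s] for s in carriers}
    if len(carriers) == len(samples):
        return "shared" if len(alleles) == 1 else "different"
    if len(carriers) == 1:
        return f"unique_to_{carriers[0]}"
    return "partial"


def classify_all(
    variant_sets: Mapping[str, Sequence[VariantRecord]],
    masks: Mapping[str, CoverageMask] | None = None,
    samples: Sequence[str] | None = None,
    sv_min_reciprocal_overlap: float = 0.5,
) -> pd.DataFrame:
    """Classify every variant locus across the compared samples.

    Returns a tidy frame with one row per locus: chrom, pos, category,
    class, carriers (comma-joined) and the number of distinct alternate
    alleles.  When ``masks`` is given, loci failing the every-sample
    coverage rule are labelled ``ineligible``.
    """
    if samples is None:
        samples = list(variant_sets)
    loci = build_loci(variant_sets, sv_min_reciprocal_overlap)
    if masks is not None:
        ok, bad = eligible_loci(loci, masks, samples)
    else:
        ok, bad = loci, []
    rows = []
    for loc in ok:
        rows.append(
            {
                "chrom": loc.chrom,
                "pos": loc.pos,
                "category": loc.category,
                "class": classify_locus(loc, samples),
                "carriers": ",".join(s for s in samples if s in loc.alleles),
                "n_alleles": len({locus_allele for locus_allele in loc.alleles.values()}),
            }
        )
    for loc in bad:
        rows.append(
            {
                "chrom": loc.chrom,
                "pos": loc.pos,
                "category": loc.category,
                "class": "ineligible",
                "carriers": ",".join(s for s in samples if s in loc.alleles),
                "n_alleles": len(set(loc.alleles.values())),
            }
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "category", "class", "carriers", "n_alleles"]
    )
    return df.sort_values(["chrom", "pos", "category"], ignore_index=True)


def _count_table(
    df: pd.DataFrame, chrom_order: Sequence[str]
) -> pd.DataFrame:
    """Per-chromosome shared/different counts by category, plus totals."""
    out = pd.DataFrame(
        0,
        index=list(chrom_order),
        columns=pd.MultiIndex.from_product([CATEGORIES, ["shared", "different"]]),
    )
    sub = df[df["class"].isin(["shared", "different"])]
    for (chrom, cat, cls), n in sub.groupby(["chrom", "category", "class"]).size().items():
        if chrom in out.index:
            out.loc[chrom, (cat, cls)] = n
    out.loc["Total"] = out.sum(axis=0)
    return out


def pairwise_summary(
    variant_sets: Mapping[str, Sequence[VariantRecord]],
    masks: Mapping[str, CoverageMask] | None,
    sample_i: str,
    sample_j: str,
    chrom_order: Sequence[str],
) -> pd.DataFrame:
    """Shared/different counts between two samples, per chromosome."""
    pair_sets = {sample_i: variant_sets[sample_i], sample_j: variant_sets[sample_j]}
    df = classify_all(pair_sets, masks, samples=sorted([sample_i, sample_j]))
    return _count_table(df, chrom_order)


def threeway_summary(
    variant_sets: Mapping[str, Sequence[VariantRecord]],
    masks: Mapping[str, CoverageMask] | None,
    chrom_order: Sequence[str],
) -> pd.DataFrame:
    """Shared/different counts over all compared samples, per chromosome."""
    df = classify_all(variant_sets, masks)
    return _count_table(df, chrom_order)


def event_sets(
    variant_sets: Mapping[str, Sequence[VariantRecord]],
    sv_min_reciprocal_overlap: float = 0.5,
) -> dict[str, set]:
    """Per-sample sets of variant-event keys for set-theoretic accounting.

    Two records map to the same key exactly when the comparison logic
    considers them the same variant (SV cluster membership included).
    """
    loci = build_loci(variant_sets, sv_min_reciprocal_overlap)
    sets: dict[str, set] = {s: set() for s in variant_sets}
    for idx, loc in enumerate(loci):
        for sample, allele in loc.alleles.items():
            anchor = idx if loc.category == "SV" else loc.pos
            sets[sample].add((loc.chrom, anchor, loc.category, allele))
    return sets


def union_accounting(
    per_sample_totals: Sequence[int],
    pairwise_shared: Sequence[int],
    threeway_shared: int,
) -> int:
    """Non-redundant union of three variant collections by
    inclusion-exclusion: ``|A∪B∪C| = Σ|X| − Σ|pair∩| + |A∩B∩C|``."""
    if len(per_sample_totals) != 3 or len(pairwise_shared) != 3:
        raise ResevarError("union accounting expects three samples and three pairs")
    if any(p < threeway_shared for p in pairwise_shared):
        raise ResevarError(
            "inconsistent counts: pairwise shared below three-way shared"
        )
    union = sum(per_sample_totals) - sum(pairwise_shared) + threeway_shared
    if union < max(per_sample_totals):
        raise ResevarError(
            f"inconsistent counts: union {union} below largest sample total"
        )
    return union
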