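"""Report tables, heterozygosity, functional tallies and cross-checks.

Besides summarizing a pipeline run, this module bundles the published
per-chromosome count tables for the three elite restorer lines IR24, MH63
and SH527 against the 9311 reference (shipped under ``resevar/data``) and
verifies their internal arithmetic: every printed total must equal the sum
of its per-chromosome rows, and the per-sample totals, pairwise shared and
three-way shared counts must reproduce the non-redundant SNP union by
inclusion-exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .comparison import _category, union_accounting
from .core import CoverageMask, GenomeSequence, ResevarError, VariantRecord

PUBLISHED_SAMPLES = ("IR24", "MH63", "SH527")
PUBLISHED_PAIRS = ("IR24_vs_MH63", "MH63_vs_SH527", "IR24_vs_SH527")


# ---------------------------------------------------------------------------
# Tables from a pipeline run
# ---------------------------------------------------------------------------

def per_chromosome_table(
    variant_sets: Mapping[str, Sequence[VariantRecord]],
    genome: GenomeSequence,
) -> pd.DataFrame:
    """Per-sample variant counts by chromosome and class, with totals."""
    chroms = genome.chrom_names
    cols = pd.MultiIndex.from_product([list(variant_sets), ("SNP", "InDel", "SV")])
    out = pd.DataFrame(0, index=chroms, columns=cols)
    for sample, recs in variant_sets.items():
        for r in recs:
            if r.chrom not in genome.chroms:
                raise ResevarError(f"chromosome {r.chrom!r} absent from genome")
            out.loc[r.chrom, (sample, _category(r.vtype))] += 1
    out.loc["Total"] = out.sum(axis=0)
    return out


def heterozygosity_rate(
    variant_sets: Mapping[str, Sequence[VariantRecord]],
    masks: Mapping[str, CoverageMask],
) -> dict[str, float]:
    """Heterozygous calls per covered base, per sample."""
    out = {}
    for sample, recs in variant_sets.items():
        covered = masks[sample].covered_bases()
        if covered == 0:
            raise ResevarError(f"sample {sample} has zero covered bases")
        n_het = sum(1 for r in recs if r.zygosity == "het")
        out[sample] = n_het / covered
    return out


def go_top_tally(
    genes_by_class: Mapping[str, Iterable[str]],
    term_map: pd.DataFrame,
    n: int = 10,
    namespace: str = "GO",
) -> dict[str, list[tuple[str, int]]]:
    """Top-``n`` term tallies per comparison class.

    Counts distinct genes per term among the genes of each class; genes
    absent from the mapping are pooled under ``unannotated``.  Ranked by
    descending count with ties broken by term name.
    """
    sub = term_map[term_map["namespace"] == namespace]
    gene_terms: dict[str, set[str]] = {}
    for row in sub.itertuples():
        gene_terms.setdefault(row.gene_id, set()).add(row.term)
    out: dict[str, list[tuple[str, int]]] = {}
    for cls, genes in genes_by_class.items():
        counts: dict[str, set[str]] = {}
        for g in set(genes):
            terms = gene_terms.get(g)
            if not terms:
                counts.setdefault("unannotated", set()).add(g)
                continue
            for t in terms:
                counts.setdefault(t, set()).add(g)
        ranked = sorted(counts.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        out[cls] = [(t, len(gs)) for t, gs in ranked[:n]]
    return out


def domain_ratio_table(
    effect_by_gene: Mapping[str, Mapping[str, int]],
    term_map: pd.DataFrame,
    namespace: str = "PFAM",
    test: bool = False,
) -> pd.DataFrame:
    """Nonsynonymous/synonymous SNP ratio per protein domain.

    ``effect_by_gene`` maps gene id to its synonymous / nonsynonymous SNP
    counts.  The ratio elevation is reported descriptively; with
    ``test=True`` a per-domain binomial test against the genome-wide
    nonsynonymous proportion is added with Benjamini-Hochberg adjustment.
    """
    sub = term_map[term_map["namespace"] == namespace]
    rows = []
    tot_syn = sum(v.get("synonymous", 0) for v in effect_by_gene.values())
    tot_non = sum(v.get("nonsynonymous", 0) for v in effect_by_gene.values())
    for term, grp in sub.groupby("term"):
        syn = non = 0
        for g in grp["gene_id"]:
            counts = effect_by_gene.get(g, {})
            syn += counts.get("synonymous", 0)
            non += counts.get("nonsynonymous", 0)
        rows.append(
            {"domain": term, "synonymous": syn, "nonsynonymous": non,
             "ratio": non / syn if syn else float("inf") if non else float("nan")}
        )
    df = pd.DataFrame(rows).sort_values("domain", ignore_index=True)
    if test and tot_syn + tot_non > 0:
        from scipy.stats import binomtest, false_discovery_control

        p0 = tot_non / (tot_non + tot_syn)
        pvals = [
            binomtest(int(r.nonsynonymous), int(r.nonsynonymous + r.synonymous), p0).pvalue
            if r.nonsynonymous + r.synonymous > 0
            else 1.0
            for r in df.itertuples()
        ]
        df["pvalue"] = pvals
        df["qvalue"] = false_discovery_control(pvals, method="bh")
    return df


# ---------------------------------------------------------------------------
# Published-count fixtures and the cross-checking report
# ---------------------------------------------------------------------------

def load_published_counts() -> dict[str, pd.DataFrame]:
    """Published per-chromosome count tables bundled with the package."""
    names = {
        "per_sample": "sample_variant_counts.tsv",
        "pairwise": "pairwise_variant_counts.tsv",
        "threeway": "threeway_variant_counts.tsv",
        "cds_effects": "cds_snp_effect_counts.tsv",
        "indel_cds": "indel_cds_counts.tsv",
        "large_effect": "large_effect_counts.tsv",
        "large_effect_different": "large_effect_different.tsv",
    }
    out = {}
    for key, fname in names.items():
        with resources.files("resevar.data").joinpath(fname).open() as fh:
            out[key] = pd.read_csv(fh, sep="\t")
    return out


@dataclass
class SummaryReport:
    """Cross-checked summary of count tables.

    ``checks`` holds (name, passed, detail) triples; ``passed`` is True only
    when every check holds.
    """

    tables: dict[str, pd.DataFrame]
    checks: list[tuple[str, bool, str]] = field(default_factory=list)
    snp_union: int | None = None
    large_effect_totals: dict[str, int] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list[str]:
        return [f"{name}: {detail}" for name, ok, detail in self.checks if not ok]

    def to_text(self) -> str:
        lines = ["resevar summary report", "=" * 30]
        for name, ok, detail in self.checks:
            lines.append(f"[{'ok' if ok else 'FAIL'}] {name}: {detail}")
        if self.snp_union is not None:
            lines.append(f"non-redundant SNP union: {self.snp_union}")
        for k, v in self.large_effect_totals.items():
            lines.append(f"large-effect {k}: {v}")
        return "\n".join(lines)


def _check_total_rows(
    report: SummaryReport,
    name: str,
    df: pd.DataFrame,
    group_cols: list[str],
    value_cols: list[str],
) -> None:
    """Verify each printed Total row against the sum of its chromosome rows."""
    for key, grp in df.groupby(group_cols) if group_cols else [((), df)]:
        body = grp[grp["chromosome"] != "Total"]
        total = grp[grp["chromosome"] == "Total"]
        if total.empty:
            continue
        for col in value_cols:
            want = int(total.iloc[0][col])
            got = int(body[col].sum())
            label = "/".join(map(str, key if isinstance(key, tuple) else (key,)))
            report.checks.append(
                (
                    f"{name}[{label}].{col}",
                    got == want,
                    f"sum {got} vs printed total {want}",
                )
            )


def build_report(tables: dict[str, pd.DataFrame] | None = None) -> SummaryReport:
    """Assemble the cross-checked report over count tables.

    Defaults to the bundled published tables.  Executes every total-row
    identity, the inclusion-exclusion SNP union identity, and derives the
    genome-wide large-effect totals (shared tables plus the different-SNP
    supplement).
    """
    if tables is None:
        tables = load_published_counts()
    report = SummaryReport(tables=tables)

    _check_total_rows(report, "per_sample", tables["per_sample"], ["sample"],
                      ["snps", "indels", "svs"])
    _check_total_rows(report, "pairwise", tables["pairwise"], ["pair", "category"],
                      ["shared", "different"])
    _check_total_rows(report, "threeway", tables["threeway"], ["category"],
                      ["shared", "different"])
    _check_total_rows(report, "cds_effects", tables["cds_effects"],
                      ["comparison", "group"], ["syn_cds", "nonsyn_cds"])
    _check_total_rows(report, "indel_cds", tables["indel_cds"],
                      ["comparison", "group"], ["non_cds", "cds"])
    _check_total_rows(report, "large_effect", tables["large_effect"],
                      ["comparison"], ["atg_change", "premature_stop", "stop_change"])

    # inclusion-exclusion union of the three SNP collections
    per_sample = tables["per_sample"]
    totals = [
        int(per_sample[(per_sample["sample"] == s)
                       & (per_sample["chromosome"] == "Total")]["snps"].iloc[0])
        for s in PUBLISHED_SAMPLES
    ]
    pairwise = tables["pairwise"]
    pair_shared = [
        int(pairwise[(pairwise["pair"] == p) & (pairwise["category"] == "SNP")
                     & (pairwise["chromosome"] == "Total")]["shared"].iloc[0])
        for p in PUBLISHED_PAIRS
    ]
    threeway = tables["threeway"]
    three_shared = int(
        threeway[(threeway["category"] == "SNP")
                 & (threeway["chromosome"] == "Total")]["shared"].iloc[0]
    )
    report.snp_union = union_accounting(totals, pair_shared, three_shared)

    # genome-wide large-effect totals: the per-comparison shared tables plus
    # the small complement observed among the different SNPs
    le = tables["large_effect"]
    le_tot = le[le["chromosome"] == "Total"]
    diff = tables["large_effect_different"].iloc[0]
    for col in ("atg_change", "premature_stop", "stop_change"):
        report.large_effect_totals[col] = int(le_tot[col].sum()) + int(diff[col])

    return report
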