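import pytest
from Bio.Seq import Seq

from resevar import effect_annotation as ea
from resevar.core import GeneModel, GenomeSequence, ResevarError, VariantRecord

COMP = str.maketrans("ACGT", "TGCA")


def retranslation_oracle(gene, genome, pos, alt):
    """Classify a CDS substitution by re-translating the whole CDS."""
    cds = ea.cds_sequence(gene, genome)
    off = ea.cds_offset_of(gene, pos)
    base = alt if gene.strand == "+" else alt.translate(COMP)
    alt_cds = cds[:off] + base + cds[off + 1 :]
    p_ref = str(Seq(cds).translate())
    p_alt = str(Seq(alt_cds).translate())
    ci = off // 3
    if ci == 0 and cds[:3] == "ATG" and alt_cds[:3] != "ATG":
        return "start_loss"
    if ci == len(p_ref) - 1 and p_ref[-1] == "*":
        return "synonymous" if p_alt[-1] == "*" else "stop_loss"
    if p_alt[ci] == "*":
        return "premature_stop"
    return "synonymous" if p_alt == p_ref else "nonsynonymous"


def make_gene(seq_cds, strand="+", chrom="c", pad=30):
    """Single-exon gene embedded in a padded chromosome."""
    genomic = seq_cds if strand == "+" else seq_cds.translate(COMP)[::-1]
    chrom_seq = "A" * pad + genomic + "A" * pad
    genome = GenomeSequence({chrom: chrom_seq})
    gene = GeneModel("g1", chrom, strand, (pad, pad + len(seq_cds)),
                     [(pad, pad + len(seq_cds))])
    return gene, genome


def snp(pos, ref, alt, chrom="c"):
    return VariantRecord("s", chrom, pos, ref, alt, "SNP")


@pytest.mark.parametrize(
    "codon_idx,within,alt_cds,expected",
    [
        (1, 2, "G", "synonymous"),      # GGA -> GGG (Gly -> Gly)
        (2, 0, "T", "premature_stop"),  # CAG -> TAG mid-CDS
        (0, 1, "C", "start_loss"),      # ATG -> ACG at the initiation codon
        (3, 0, "C", "stop_loss"),       # TAA -> CAA at the terminal codon
        (1, 0, "C", "nonsynonymous"),   # GGA -> CGA (Gly -> Arg)
    ],
)
def test_codon_level_effect_examples(codon_idx, within, alt_cds, expected):
    gene, genome = make_gene("ATG" + "GGA" + "CAG" + "TAA")
    off = codon_idx * 3 + within
    pos = gene.cds[0][0] + off
    ref = genome.base("c", pos)
    call = ea.classify_snp_effect(snp(pos, ref, alt_cds), gene, genome)
    assert call.effect == expected


def test_minus_strand_matches_plus_strand_construction():
    """Classifying a minus-strand gene equals classifying the same CDS
    planted on the plus strand (metamorphic strand consistency)."""
    cds = "ATG" + "GGACAGTTCAAG" + "TGA"
    gplus, gen_plus = make_gene(cds, "+")
    gminus, gen_minus = make_gene(cds, "-")
    for off in range(len(cds)):
        pos_p = gplus.cds[0][0] + off
        pos_m = gminus.cds[0][1] - 1 - off
        ref_p = gen_plus.base("c", pos_p)
        ref_m = gen_minus.base("c", pos_m)
        for alt_cds_base in "ACGT":
            if alt_cds_base == cds[off]:
                continue
            eff_p = ea.classify_snp_effect(
                snp(pos_p, ref_p, alt_cds_base), gplus, gen_plus
            ).effect
            eff_m = ea.classify_snp_effect(
                snp(pos_m, ref_m, alt_cds_base.translate(COMP)), gminus, gen_minus
            ).effect
            assert eff_p == eff_m


def test_agrees_with_retranslation_oracle_on_spliced_genes(sim):
    """Spot-check codon classification against full re-translation on a few
    two-exon genes from the simulated annotation (both strands)."""
    plus = next(g for g in sim.genes if g.strand == "+")
    minus = next(g for g in sim.genes if g.strand == "-")
    for gene in (plus, minus):
        for pos in gene.genomic_cds_positions():
            ref = sim.genome.base(gene.chrom, pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = ea.classify_snp_effect(snp(pos, ref, alt, gene.chrom),
                                             gene, sim.genome).effect
                assert got == retranslation_oracle(gene, sim.genome, pos, alt)


def test_reference_mismatch_is_an_error():
    gene, genome = make_gene("ATGGGATAA")
    pos = gene.cds[0][0]
    wrong_ref = "C" if genome.base("c", pos) != "C" else "G"
    with pytest.raises(ResevarError, match="reference mismatch"):
        ea.classify_snp_effect(snp(pos, wrong_ref, "T"), gene, genome)


def test_variant_localization_regions(sim):
    gene = next(g for g in sim.genes if len(g.cds) == 2)
    cds_pos = gene.cds[0][0]
    bounds = sorted(gene.cds)
    intron_pos = bounds[0][1] + 5
    hits = ea.map_variant_to_gene(snp(cds_pos, "A", "G", gene.chrom), sim.genes)
    assert hits == [(gene.gene_id, "CDS")]
    hits = ea.map_variant_to_gene(snp(intron_pos, "A", "G", gene.chrom), sim.genes)
    assert hits == [(gene.gene_id, "non-CDS")]
    # far from every gene
    assert ea.map_variant_to_gene(snp(0, "A", "G", gene.chrom), sim.genes) == []
    with pytest.raises(ResevarError, match="beyond"):
        ea.map_variant_to_gene(
            snp(10**9, "A", "G", gene.chrom), sim.genes, sim.genome
        )


def test_indel_region_by_footprint_intersection():
    gene, _ = make_gene("ATG" + "GGA" * 10 + "TAA", pad=50)
    genes = [gene]
    inside = VariantRecord("s", "c", 60, "AACG", "A", "DEL")
    assert ea.classify_indel_region(inside, genes) == "CDS"
    intergenic_ins = VariantRecord("s", "c", 5, "A", "ATT", "INS")
    assert ea.classify_indel_region(intergenic_ins, genes) == "non-CDS"
    # deletion straddling the CDS start: footprint intersects -> CDS
    straddle = VariantRecord("s", "c", 47, "AAAAT", "A", "DEL")
    assert ea.classify_indel_region(straddle, genes) == "CDS"


def test_gene_survey_counts_dna_vs_mrna():
    gene = GeneModel("g1", "c", "+", (100, 400), [(100, 200), (300, 400)])
    intronic = [snp(p, "A", "G") for p in (210, 220, 230, 240, 250)]
    exonic = [snp(p, "A", "G") for p in (150, 350)]
    out = ea.gene_survey([gene], {"s": intronic + exonic})
    assert int(out.loc["g1", ("s", "DNA")]) == 7
    assert int(out.loc["g1", ("s", "mRNA")]) == 2
    empty = ea.gene_survey([gene], {"s": []})
    assert int(empty.loc["g1", ("s", "DNA")]) == 0
    with pytest.raises(ResevarError, match="unknown gene"):
        ea.gene_survey([gene], {"s": []}, gene_ids=["nope"])


def test_gene_survey_recovers_truth_spikes(sim):
    out = ea.gene_survey(sim.genes, sim.variant_sets)
    for gene in sim.genes[:5]:
        for sample in sim.config.samples:
            want_dna = sum(
                1 for r in sim.variant_sets[sample]
                if r.chrom == gene.chrom and gene.span[0] <= r.pos < gene.span[1]
            )
            assert int(out.loc[gene.gene_id, (sample, "DNA")]) == want_dna


def test_effect_spikes_annotate_as_intended(sim):
    """Spiked coding-effect SNPs are recovered with their intended labels."""
    spikes = sim.truth[sim.truth.effect != "."]
    assert len(spikes) == (
        sim.config.n_synonymous + sim.config.n_nonsynonymous
        + sim.config.n_premature_stop + sim.config.n_start_loss
        + sim.config.n_stop_loss
    )
    for row in spikes.itertuples():
        alt = row.alts.split(",")[0]
        rec = snp(int(row.pos), row.ref, alt, row.chrom)
        calls = ea.annotate_snp(rec, sim.genes, sim.genome)
        assert [c.effect for c in calls] == [row.effect]
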