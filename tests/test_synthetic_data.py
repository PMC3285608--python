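import dataclasses

import pandas as pd
import pytest
from Bio.Seq import Seq

from resevar import synthetic_data as sd
from resevar.core import ResevarError
from resevar.effect_annotation import cds_sequence


def test_genome_is_deterministic_and_sized(small_config, tmp_path):
    a = sd.simulate(small_config, tmp_path / "a")
    b = sd.simulate(small_config, tmp_path / "b")
    assert (a.paths["genome"].read_bytes() == b.paths["genome"].read_bytes())
    for s in small_config.samples:
        assert (a.paths[f"vcf_{s}"].read_bytes()
                == b.paths[f"vcf_{s}"].read_bytes())
        assert (a.paths[f"pileup_{s}"].read_bytes()
                == b.paths[f"pileup_{s}"].read_bytes())
    assert a.genome.lengths == {"chr01": small_config.chrom_length}


def test_genome_rejects_bad_lengths():
    with pytest.raises(ResevarError):
        sd.generate_genome(sd.SimulationConfig(chrom_length=0))
    with pytest.raises(ResevarError):
        sd.generate_genome(sd.SimulationConfig(chrom_length=300))


def test_gene_models_are_valid_orfs(sim):
    strands = set()
    for g in sim.genes:
        strands.add(g.strand)
        assert g.cds_length % 3 == 0
        prot = str(Seq(cds_sequence(g, sim.genome)).translate())
        assert prot.startswith("M")
        assert prot.endswith("*")
        assert "*" not in prot[:-1]
    assert strands == {"+", "-"}
    # genes do not overlap
    spans = sorted((g.chrom, *g.span) for g in sim.genes)
    for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
        assert c1 != c2 or e1 <= s2


def test_zero_genes_gives_empty_valid_gff(tmp_path, small_config):
    cfg = dataclasses.replace(
        small_config,
        n_genes=0, n_synonymous=0, n_nonsynonymous=0, n_premature_stop=0,
        n_start_loss=0, n_stop_loss=0, indel_cds=0,
    )
    ds = sd.simulate(cfg, tmp_path)
    assert ds.genes == []
    assert ds.paths["genes"].read_text().startswith("##gff-version 3")


def test_shared_only_request_gives_identical_variant_sets(small_config):
    cfg = dataclasses.replace(
        small_config,
        snp_shared_all=10, snp_shared_pair=0, snp_unique=0, snp_different=0,
        n_synonymous=0, n_nonsynonymous=0, n_premature_stop=0, n_start_loss=0,
        n_stop_loss=0, indel_shared_all=0, indel_unique=0, indel_cds=0,
        sv_shared_all=0, sv_unique=0, het_fraction=0.0,
    )
    genome = sd.generate_genome(cfg)
    genes = sd.generate_gene_models(genome, cfg)
    sets, truth = sd.spike_variants(genome, genes, cfg)
    assert len(truth) == 10

    def key(recs):
        return [(r.chrom, r.pos, r.ref, r.alt, r.zygosity) for r in recs]

    assert key(sets["R1"]) == key(sets["R2"]) == key(sets["R3"])
    assert len(sets["R1"]) == 10


def test_different_loci_have_distinct_alternate_bases(sim):
    diff = sim.truth[sim.truth.comp_class == "different"]
    assert len(diff) == sim.config.snp_different
    for row in diff.itertuples():
        alts = row.alts.split(",")
        assert len(set(alts)) == 3
        assert row.ref not in alts


def test_class_count_conservation(sim):
    """Per-sample record counts match what the truth table implies."""
    for sample in sim.config.samples:
        want = sum(
            1 for row in sim.truth.itertuples()
            if sample in row.carriers.split(",")
        )
        assert len(sim.variant_sets[sample]) == want


def test_full_coverage_is_single_interval(small_config):
    cfg = dataclasses.replace(small_config, coverage_fraction=1.0)
    ds = sd.simulate(cfg)
    for mask in ds.masks.values():
        for chrom, iv in mask.intervals.items():
            assert iv.tolist() == [[0, cfg.chrom_length]]


def test_coverage_fraction_and_truth_loci_covered(sim):
    total = sum(sim.genome.lengths.values())
    for sample, mask in sim.masks.items():
        frac = mask.covered_bases() / total
        assert abs(frac - sim.config.coverage_fraction) <= 0.01
        for row in sim.truth.itertuples():
            covered = mask.is_covered(row.chrom, int(row.pos))
            if row.uncovered_sample == sample:
                assert not covered
            else:
                assert covered


def test_coverage_too_low_for_spiked_loci_errors(small_config):
    cfg = dataclasses.replace(small_config, coverage_fraction=0.02)
    genome = sd.generate_genome(cfg)
    genes = sd.generate_gene_models(genome, cfg)
    _, truth = sd.spike_variants(genome, genes, cfg)
    with pytest.raises(ResevarError):
        sd.generate_coverage(genome, cfg, truth)


def test_pileups_match_genotypes_without_error(sim):
    """With an error-free channel, carrier evidence is pure alt."""
    by_site = {
        s: {(e.chrom, e.pos): e for e in ev} for s, ev in sim.pileups.items()
    }
    checked_hom = checked_sv = 0
    for row in sim.truth.itertuples():
        carriers = dict(zip(row.carriers.split(","), row.alts.split(",")))
        for sample, alt in carriers.items():
            ev = by_site[sample].get((row.chrom, int(row.pos)))
            assert ev is not None
            if row.vtype == "SNP" and row.zygosity == "hom_alt":
                assert set(ev.bases) == {alt}
                assert ev.depth >= sim.config.min_depth
                checked_hom += 1
            elif row.vtype == "SV":
                assert ev.abnormal_signature == row.sv_type
                assert ev.n_abnormal_pairs == sim.config.abnormal_pairs
                checked_sv += 1
    assert checked_hom > 100 and checked_sv > 0


def test_het_pileup_allele_balance():
    cfg = sd.SimulationConfig(seed=9, pileup_depth=10_000)
    truth = pd.DataFrame(
        [dict(chrom="c", pos=100, vtype="SNP", ref="A", carriers="R1",
              alts="G", comp_class="unique_R1", effect=".", zygosity="het",
              sv_type=".", end=-1, uncovered_sample=".")]
    )
    genome = sd.GenomeSequence({"c": "A" * 1000})
    piles = sd.generate_pileups(genome, truth, cfg)
    (site,) = [e for e in piles["R1"] if e.pos == 100]
    frac = site.bases.count("G") / site.depth
    # three binomial standard deviations around one half
    assert abs(frac - 0.5) <= 3 * 0.5 / site.depth ** 0.5


def test_low_abnormal_support_is_recorded_for_filter_tests():
    cfg = sd.SimulationConfig(seed=9, abnormal_pairs=2)
    truth = pd.DataFrame(
        [dict(chrom="c", pos=50, vtype="SV", ref="A", carriers="R1",
              alts="deletion", comp_class="unique_R1", effect=".",
              zygosity="hom_alt", sv_type="deletion", end=600,
              uncovered_sample=".")]
    )
    genome = sd.GenomeSequence({"c": "A" * 1000})
    piles = sd.generate_pileups(genome, truth, cfg)
    (site,) = [e for e in piles["R1"] if e.abnormal_signature]
    assert site.n_abnormal_pairs == 2


def test_config_from_dict_rejects_unknown_keys():
    with pytest.raises(ResevarError, match="unknown"):
        sd.config_from_dict({"seed": 1, "bogus": 2})
    cfg = sd.config_from_dict({"seed": 4, "samples": ["a", "b", "c"]})
    assert cfg.samples == ("a", "b", "c")
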