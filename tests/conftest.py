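import collections

import pytest

from resevar.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """One full synthetic dataset shared across the suite.

    Includes seven deliberately uncovered loci so eligibility handling is
    exercised everywhere.
    """
    cfg = SimulationConfig(seed=7, n_uncovered=7)
    return simulate(cfg, tmp_path_factory.mktemp("sim"))


@pytest.fixture()
def small_config():
    """A fast single-chromosome configuration for generator-level tests."""
    return SimulationConfig(
        seed=3,
        n_chroms=1,
        chrom_length=40_000,
        n_genes=6,
        snp_shared_all=30,
        snp_shared_pair=5,
        snp_unique=8,
        snp_different=3,
        n_synonymous=2,
        n_nonsynonymous=2,
        n_premature_stop=1,
        n_start_loss=1,
        n_stop_loss=1,
        indel_shared_all=6,
        indel_unique=2,
        indel_cds=1,
        sv_shared_all=1,
        sv_unique=1,
        n_background_sites=10,
    )


def expected_comparison_counts(truth) -> dict[str, int]:
    """Three-way classification counts implied by a truth table."""
    exp: collections.Counter = collections.Counter()
    for row in truth.itertuples():
        cls = row.comp_class
        if cls == "shared_all":
            exp["shared"] += 1
        elif cls.startswith("shared_pair"):
            exp["partial"] += 1
        elif cls.startswith("unique_"):
            exp["unique_to_" + cls.split("_", 1)[1]] += 1
        elif cls == "different":
            exp["different"] += 1
        elif cls == "ineligible":
            exp["ineligible"] += 1
    return dict(exp)
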