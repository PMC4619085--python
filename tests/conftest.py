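import pytest

from decko.allele_sim import make_synthetic_locus
from decko.genome_io import GenomeRegion
from decko.genotyping import pick_primers, predict_amplicons
from decko.pair_designer import DesignConfig, design_pairs

FIXTURE_TARGET = GenomeRegion("synthetic_locus", 2200, 2800, ".")


@pytest.fixture(scope="session")
def fixture_target():
    return FIXTURE_TARGET


@pytest.fixture(scope="session")
def fixture_locus():
    """5-kb seeded locus with engineered guide sites flanking a 600-bp target."""
    return make_synthetic_locus(seed=42, length=5000, gc=0.5,
                                target=FIXTURE_TARGET)


@pytest.fixture(scope="session")
def designed_pairs(fixture_locus, fixture_target):
    return design_pairs(fixture_locus, fixture_target, DesignConfig())


@pytest.fixture(scope="session")
def designed_pair(designed_pairs):
    return designed_pairs[0]


@pytest.fixture(scope="session")
def fixture_primers(fixture_locus, designed_pair):
    return pick_primers(fixture_locus, designed_pair)


@pytest.fixture(scope="session")
def fixture_plan(fixture_locus, designed_pair, fixture_primers):
    return predict_amplicons(fixture_locus, designed_pair, fixture_primers,
                             name="fixture")
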