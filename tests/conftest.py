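import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vquad import (
    G4CassetteSpec,
    GermlineSimConfig,
    IghvAllele,
    ReferenceG4Scorer,
    simulate_germline_alleles,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_dna(rng: np.random.Generator, length: int, p_g: float = 0.25) -> str:
    probs = [(1 - p_g) / 3] * 3 + [p_g]
    return "".join(rng.choice(list("ACTG"), size=length, p=probs))


@pytest.fixture(scope="session")
def ref_scorer() -> ReferenceG4Scorer:
    return ReferenceG4Scorer()


@pytest.fixture(scope="session")
def germline_set():
    """40 simulated V alleles, half carrying a top-strand cassette, with truth."""
    return simulate_germline_alleles(GermlineSimConfig(seed=11))


@pytest.fixture(scope="session")
def ccc_design():
    """One allele with a bottom-strand cassette plus standalone top CCC coldspots.

    The cassette's top-strand face is CCC runs whose mutation disrupts the
    bottom-strand quadruplex; the standalone CCCs leave it untouched.
    """
    cfg = GermlineSimConfig(
        n_alleles=1,
        g4_cassette=G4CassetteSpec(strand="bottom", count=2),
        cassette_fraction=1.0,
        planted_motifs=(("CCC", "top", 6),),
        seed=23,
    )
    alleles, truth = simulate_germline_alleles(cfg)
    return alleles[0], truth


@pytest.fixture
def toy_allele() -> IghvAllele:
    return IghvAllele(
        allele_id="IGHV3-7*01",
        gapped_seq="ACGT.ACGGGTAGGGTTGGGAGGGT.AC",
        region_map=[("FW1", 1, 10), ("CDR1", 11, 20), ("FW2", 21, 28)],
    )
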