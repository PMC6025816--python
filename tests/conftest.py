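import pytest

from barcodegap.records import SampleRecord, RegionAlignment
from barcodegap.simulate import SimConfig, simulate_dataset


def rec(sid, sp, seq, region="R1"):
    return SampleRecord(sample_id=sid, species=sp, region=region, sequence=seq)


@pytest.fixture
def tiny_alignment():
    """Two species, hand-checkable distances (8 columns)."""
    return RegionAlignment(
        region="R1",
        records=[
            rec("a1", "Alpha", "ACGTACGT"),
            rec("a2", "Alpha", "ACGTACGA"),
            rec("b1", "Beta", "ACGTTTTT"),
            rec("b2", "Beta", "ACGTTTTA"),
        ],
    )


@pytest.fixture(scope="session")
def sim_recovery():
    """The recovery-scale simulation: 13 species x 5, 400 bp, fixed seed."""
    config = SimConfig(
        n_species=13, individuals=5, length=400,
        inter_depth=0.08, intra_depth=0.01, seed=2024,
    )
    records, truth = simulate_dataset(config)
    return config, records, truth


@pytest.fixture(scope="session")
def sim_default():
    """Default uneven study-like design (69 samples, 6 singletons)."""
    config = SimConfig(seed=7)
    records, truth = simulate_dataset(config)
    return config, records, truth
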