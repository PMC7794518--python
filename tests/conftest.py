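import numpy as np
import pytest

from ctdnaflow.records import VariantObservation
from ctdnaflow.synthetic_cohort import SimulationConfig, simulate_patient


def make_obs(
    chrom="chr17",
    pos=7_577_120,
    ref="C",
    alt="T",
    gene="TP53",
    effect="protein_altering",
    depth=1000,
    alt_reads=100,
    mapq=60.0,
    end_distance=40.0,
    region_flag="autosome",
):
    return VariantObservation(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        effect=effect,
        depth=depth,
        alt_reads=alt_reads,
        mean_mapq_alt=mapq,
        mean_end_distance_alt=end_distance,
        region_flag=region_flag,
    )


@pytest.fixture
def obs_factory():
    return make_obs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully featured patient configuration for unit tests."""
    return SimulationConfig(
        n_patients=3,
        panel_footprint=20_000,
        serial_timepoints=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def simulated_patient(small_config):
    return simulate_patient(small_config, patient_seed=2024)
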