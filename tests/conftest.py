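import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from invseek import sv_caller
from invseek.architecture import RoseCombArchitecture
from invseek.annotation import toy_gene_models
from invseek.genotyping import build_assay
from invseek.synthetic_data import InsertSizeModel, forge_reference, simulate_matepairs

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_arch() -> RoseCombArchitecture:
    return RoseCombArchitecture.toy()


@pytest.fixture(scope="session")
def full_arch() -> RoseCombArchitecture:
    return RoseCombArchitecture.galgal3()


@pytest.fixture(scope="session")
def ref(toy_arch):
    return forge_reference(toy_arch.ref_length, gc=0.41, seed=7, name="chr7T")


@pytest.fixture(scope="session")
def alleles(toy_arch):
    return toy_arch.alleles()


@pytest.fixture(scope="session")
def insert_model():
    return InsertSizeModel(mean=3900.0, sd=300.0, read_len=50)


@pytest.fixture(scope="session")
def gene_models(toy_arch):
    return toy_gene_models(toy_arch)


@pytest.fixture(scope="session")
def assay(toy_arch, alleles):
    return build_assay(toy_arch, alleles)


@pytest.fixture(scope="session")
def hom_r1_records(toy_arch, alleles, insert_model):
    """Homozygous-R1 pool mate pairs at 10x coverage (shared across tests)."""
    return simulate_matepairs(
        {"R1": 2}, alleles, toy_arch.ref_length, insert_model, 10.0, seed=101
    )


@pytest.fixture(scope="session")
def hom_r1_calls(hom_r1_records, insert_model):
    est = sv_caller.estimate_insert_model(hom_r1_records)
    calls, stats = sv_caller.call_sv_windows(hom_r1_records, est)
    return est, calls, stats
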