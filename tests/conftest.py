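import logging

import pytest

from mirreg.io import RunConfig
from mirreg.pipeline import run_pipeline
from mirreg.simulate import generate_bundle

logging.getLogger("mirreg").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic input bundle (seed 1)."""
    return generate_bundle(seed=1)


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    """One full pipeline run on the default bundle, shared across tests."""
    return run_pipeline(bundle, RunConfig(seed=1), stability_genes=0)


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced bundle for fast smoke tests."""
    from mirreg.simulate import ModuleSpec
    return generate_bundle(
        seed=3, samples_per_condition=30, normals_per_cancer=15,
        n_genes=60, n_mirnas=12, n_tfs=5, n_conditions=4,
        regulated_genes_per_condition=15,
        module_spec=ModuleSpec(k=3, n_conditions=2, n_pathways=2,
                               n_target_genes=8))
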