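import numpy as np
import pytest

from chloridesim.model_core import build_cell, GeometryConfig


@pytest.fixture(scope="session")
def default_cell():
    return build_cell()


@pytest.fixture(scope="session")
def soma_only_cell():
    """A single isolated somatic compartment (closed-books tests)."""
    return build_cell(GeometryConfig(n_primary_dendrites=0,
                                     include_axon=False))


@pytest.fixture(scope="session")
def small_cell():
    """Soma plus one short dendrite; cheap full-physics runs."""
    return build_cell(GeometryConfig(n_primary_dendrites=1,
                                     comps_per_dendrite=5,
                                     include_axon=False))
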