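import dataclasses

import numpy as np
import pytest

from mitoscore import simcell
from mitoscore.imaging_io import normalize_percentile


@pytest.fixture(scope="session")
def default_spec():
    return simcell.MorphologySpec(phi=0.5, seed=11)


@pytest.fixture(scope="session")
def noiseless_field(default_spec):
    """One noiseless default field (phi=0.5), rendered once per session."""
    spec = dataclasses.replace(default_spec, noise_level=0.0)
    return simcell.simulate_field(spec)


@pytest.fixture(scope="session")
def normalized_field(noiseless_field):
    return normalize_percentile(noiseless_field.image)
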