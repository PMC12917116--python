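import numpy as np
import pytest

from spineplan.evaluation import STUDY_VARIATION
from spineplan.phantom import PhantomSpec, cohort_specs, generate_phantom

# smaller grid for unit tests that only need a valid rasterized phantom
SMALL_GRID = dict(grid_shape=(64, 72, 128), spacing=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom (1.5 mm grid) shared across tests."""
    spec = PhantomSpec()
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom():
    spec = PhantomSpec(**SMALL_GRID)
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def hern_phantom():
    spec = PhantomSpec(herniation={"L3/4": {"extent": 8.0, "zone": "A"}})
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def recovery_cohort():
    """The 50-phantom evaluation cohort under the standard study
    conditions, generated once per session (images dropped)."""
    out = []
    for sp in cohort_specs(50, variation=STUDY_VARIATION, seed=20):
        label_vol, _, truth = generate_phantom(sp)
        out.append((label_vol, None, truth))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
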