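import numpy as np
import pytest

import microenc as me


@pytest.fixture(scope="session")
def study():
    """Bundled 13-run study: design table + response table (as printed)."""
    return me.quebracho_study(correct_run7_ey=False)


@pytest.fixture(scope="session")
def study_corrected():
    """Bundled study with the run-7 encapsulation-yield text value (29.75)."""
    return me.quebracho_study(correct_run7_ey=True)


@pytest.fixture(scope="session")
def design_spec():
    return me.quebracho_design_spec()


@pytest.fixture(scope="session")
def lc_fit(study):
    design, responses = study
    return me.fit_quadratic(design, responses["lc"].to_numpy(float), "lc")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
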