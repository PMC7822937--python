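import numpy as np
import pytest

from ribchron.synthetic import PopulationSpec, RenderOptions, build_parameter_table


@pytest.fixture(scope="session")
def cohort_table():
    """Default-structure synthetic cohort at the study size (n=113)."""
    return build_parameter_table(seed=11)


@pytest.fixture(scope="session")
def fast_render_options():
    """Render options scaled for test speed (fewer indents per site)."""
    return RenderOptions(indents_per_site=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_population():
    return PopulationSpec(n_specimens=12, seed=5)
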