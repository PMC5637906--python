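import pytest

from paleodiet.synthetic_data import FoodWebSpec, make_fixture_files


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Deterministic synthetic CSV fixture set shared across the suite."""
    outdir = tmp_path_factory.mktemp("fixtures")
    return make_fixture_files(outdir, FoodWebSpec(seed=0, n_per_group=5))
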