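import pytest

from chemotype_map.synth import SynthConfig, simulate_study


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study (in memory), shared across tests."""
    return simulate_study(SynthConfig(), seed=1)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """The same default study written to disk as the CLI-facing bundle."""
    out = tmp_path_factory.mktemp("study")
    simulate_study(SynthConfig(), out_dir=out, seed=1)
    return out
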