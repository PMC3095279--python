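import json
from pathlib import Path

import pytest

from famevol.simulate import SimulationConfig, simulate_genome, write_bundle


@pytest.fixture(scope="session")
def default_bundle():
    return simulate_genome(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def bundle_dir(default_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    write_bundle(default_bundle, d)
    return d


@pytest.fixture(scope="session")
def bundle_truth(bundle_dir):
    return json.loads((bundle_dir / "ground_truth.json").read_text())
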