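import json

import pytest

from circaxis.pipeline import ReferenceBundle, RunConfig, build_network, screen_events
from circaxis.reference import read_circ_junctions
from circaxis.simulate import make_acceptance_fixture

FIXTURE_SEED = 1
FLANK_N = 3_000


@pytest.fixture(scope="session")
def fixture_obj():
    """The full planted-truth study fixture (20 circRNAs, all feature types)."""
    return make_acceptance_fixture(FIXTURE_SEED)


@pytest.fixture(scope="session")
def bundle_dir(fixture_obj, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    fixture_obj.write_bundle(out)
    return out


@pytest.fixture(scope="session")
def truth(bundle_dir):
    with open(bundle_dir / "truth.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def bundle(bundle_dir):
    return ReferenceBundle.from_dir(bundle_dir)


@pytest.fixture(scope="session")
def circs(bundle_dir):
    return read_circ_junctions(bundle_dir / "circ.tsv")


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(dist=FLANK_N)


@pytest.fixture(scope="session")
def screens(bundle, circs, run_config):
    """Per-event screening results for the whole fixture (computed once)."""
    return screen_events(bundle, circs, run_config)


@pytest.fixture(scope="session")
def net(bundle, screens, run_config):
    return build_network(bundle, screens, run_config)
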