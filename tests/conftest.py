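import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from cnvscore.database import load_database
from cnvscore.evidence import load_metric_config
from cnvscore.fixtures import generate_cnv_suite, generate_fixture_db


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Synthetic annotation database + CNV suite, seed 1."""
    directory = tmp_path_factory.mktemp("fixdb")
    generate_fixture_db(directory, seed=1)
    generate_cnv_suite(directory, seed=1)
    return directory


@pytest.fixture(scope="session")
def db(fixture_dir):
    return load_database(fixture_dir)


@pytest.fixture(scope="session")
def cfg():
    return load_metric_config()
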