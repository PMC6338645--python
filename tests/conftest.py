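import numpy as np
import pytest

from nrfloop.model import ParameterSet, default_parameters


@pytest.fixture(scope="session")
def human_params() -> ParameterSet:
    return default_parameters("human_cell")


@pytest.fixture(scope="session")
def worm_params() -> ParameterSet:
    return default_parameters("worm")


@pytest.fixture
def write_fasta(tmp_path):
    def _write(text: str, name: str = "seqs.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture(scope="session")
def grid_4h() -> np.ndarray:
    return np.linspace(0.0, 4.0, 201)
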