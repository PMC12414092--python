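import pytest

from pepfunnel import MotifSpec, io


@pytest.fixture(scope="session")
def motif():
    return MotifSpec("GEPDTYWQ")


@pytest.fixture(scope="session")
def table1():
    return io.load_table1_hits()


@pytest.fixture(scope="session")
def table4_records():
    from pepfunnel.energetics import read_energy_csv
    from pepfunnel.io import _data_path
    from importlib import resources

    with resources.as_file(_data_path("table4_mmgbsa.csv")) as p:
        return read_energy_csv(p)
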