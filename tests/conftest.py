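import numpy as np
import pytest

from cachesense import seqscan, synthsite


@pytest.fixture(scope="session")
def library():
    return seqscan.load_default_library()


@pytest.fixture(scope="session")
def melt_grid():
    """0.5 °C plate read from 25 to 95 °C."""
    return np.arange(25.0, 95.0 + 0.25, 0.5)


@pytest.fixture(scope="session")
def site_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("structures") / "a4_site_synthetic.pdb"
    synthsite.write_synthetic_a4_site(path)
    return path


@pytest.fixture(scope="session")
def site_cif(tmp_path_factory):
    path = tmp_path_factory.mktemp("structures") / "a4_site_synthetic.cif"
    synthsite.write_synthetic_a4_site(path)
    return path
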