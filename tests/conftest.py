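"""Shared fixtures: all test inputs are generated programmatically."""
import warnings

import pytest

from mabstitch.fixtures import make_ideal_peptide, make_paired_hinge


@pytest.fixture(scope="session")
def paired_hinge():
    """Two-chain CPPC hinge with both inter-chain disulfides formed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # SG distance warning is expected
        return make_paired_hinge()


@pytest.fixture(scope="session")
def flanked_hinge():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_paired_hinge(flank_n="GS", flank_c="AG")


@pytest.fixture()
def small_peptide():
    return make_ideal_peptide("GAVLG")
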