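import pytest

from asbscaffolds.chem_core import load_default_rules, make_compound


@pytest.fixture(scope="session")
def rules():
    return load_default_rules()


@pytest.fixture(scope="session")
def benzamide_triple():
    """N-methyl / N-ethyl / N-propyl benzamide: the canonical 3-clique series."""
    return [
        make_compound("C1", "CNC(=O)c1ccccc1"),
        make_compound("C2", "CCNC(=O)c1ccccc1"),
        make_compound("C3", "CCCNC(=O)c1ccccc1"),
    ]


@pytest.fixture(scope="session")
def two_site_triple():
    """Methoxy/amide analogs varied at two sites: A is the only SK compound."""
    return [
        make_compound("A", "COc1ccccc1C(=O)NC"),
        make_compound("B", "COc1ccccc1C(=O)NCC"),
        make_compound("C", "CCOc1ccccc1C(=O)NC"),
    ]
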