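import pytest

from pkscan import load_parameters


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture()
def hairpin():
    """Single hairpin: one 3-nt hairpin-loop section."""
    from pkscan import parse_dotbracket

    return parse_dotbracket("GGGAAACCC\n(((...)))")
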