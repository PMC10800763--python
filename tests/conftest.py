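import pytest

from abekit import builtin_profiles, enumerate_guides, pah_locus
from abekit.amplicon_quant import QuantWindow


@pytest.fixture(scope="session")
def pah():
    """Patient PAH c.1222C>T locus (synthetic slice, codons 400-414)."""
    return pah_locus()


@pytest.fixture(scope="session")
def profiles():
    pams, deaminases = builtin_profiles()
    return {p.cas_name: p for p in pams}, {d.name: d for d in deaminases}


@pytest.fixture(scope="session")
def pah4_guide(pah, profiles):
    """SpRY/ABE8.8 placement with the AAA PAM and the target at position 5."""
    pams, deams = profiles
    candidates = enumerate_guides(pah, pams["SpRY"], deams["ABE8.8"])
    (guide,) = [c for c in candidates if c.target_position == 5]
    return guide


@pytest.fixture(scope="session")
def pah_window(pah, pah4_guide):
    return QuantWindow.from_guide(pah4_guide, len(pah.context))
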