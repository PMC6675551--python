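import pytest

from neopept.synthetic import SimConfig
from neopept.variantdb import ProteinRecord, SomaticVariant


@pytest.fixture
def sim_config():
    return SimConfig(seed=1234)


@pytest.fixture
def toy_protein():
    # 40-aa canonical protein with a known residue layout
    return ProteinRecord(
        id="P_TOY",
        sequence="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRV",
    )


@pytest.fixture
def toy_variant(toy_protein):
    # A->W at position 20 (0-based 19 is 'S'? use a verified residue)
    pos = 20
    ref = toy_protein.sequence[pos - 1]
    alt = "W" if ref != "W" else "Y"
    return SomaticVariant(
        protein_id=toy_protein.id,
        position=pos,
        ref_aa=ref,
        alt_aa=alt,
        coverage=50,
        tpm=12.5,
    )
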