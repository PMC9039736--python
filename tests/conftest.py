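import pytest

from slimscreen import ProbeLibrary, ProteinRecord, load_probe_library


@pytest.fixture
def two_probe_library() -> ProbeLibrary:
    return load_probe_library("P17\tNFW\nP3\tLFF\n")


@pytest.fixture
def tiny_proteome() -> list[ProteinRecord]:
    # A: one NFW + one LFF; B: no matches; C: two NFW (one at the end)
    return [
        ProteinRecord(accession="A", entry_name="A_T", sequence="MNFWLFFAAA"),
        ProteinRecord(accession="B", entry_name="B_T", sequence="AAAAAAAAAA"),
        ProteinRecord(accession="C", entry_name="C_T", sequence="NFWAAAANFW"),
    ]
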