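import pytest

from circbsj.io import CircRNARecord, ProteomeRecord


@pytest.fixture
def make_circ():
    def _make(seq: str, circ_id: str = "c1") -> CircRNARecord:
        return CircRNARecord(circ_id, seq.upper().replace("U", "T"))

    return _make


@pytest.fixture
def small_proteome():
    return [
        ProteomeRecord("sp|P00001|ONE", "test protein PE=1 SV=2",
                       "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
        ProteomeRecord("sp|P00002|TWO", "another protein",
                       "MSEQNNTEMTFQIQRIYTKDISFEAPNAPHVFQKDW"),
    ]
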