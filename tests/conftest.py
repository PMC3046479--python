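import pytest

from tagqc.barcodes import design_barcodes


@pytest.fixture(scope="session")
def designed_set():
    """Default 96 x 9 bp barcode set, designed once per session."""
    return design_barcodes(seed=0)
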