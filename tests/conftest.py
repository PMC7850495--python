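import pytest

from msilico import MarkerPanel, load_panel23
from msilico.markers import Marker


@pytest.fixture(scope="session")
def panel23():
    return load_panel23()


@pytest.fixture
def tiny_panel():
    """Four well-separated mononucleotide markers on two toy chromosomes."""
    return MarkerPanel(
        name="tiny",
        markers=[
            Marker("M1", "chr1", 200, 220, "A", 20),
            Marker("M2", "chr1", 600, 626, "T", 26),
            Marker("M3", "chr2", 200, 215, "A", 15),
            Marker("M4", "chr2", 600, 624, "AC", 24),
        ],
    )
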