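import numpy as np
import pytest

from snpkin.panel_io import Panel, PanelSite


@pytest.fixture
def small_panel() -> Panel:
    """Ten deterministic biallelic sites, incl. C/T and G/A damage-prone ones."""
    sites = [
        PanelSite("s01", "1", 100, "C", "T"),
        PanelSite("s02", "1", 200, "G", "A"),
        PanelSite("s03", "1", 300, "A", "G"),
        PanelSite("s04", "1", 400, "T", "C"),
        PanelSite("s05", "1", 500, "A", "C"),
        PanelSite("s06", "2", 100, "G", "T"),
        PanelSite("s07", "2", 200, "C", "A"),
        PanelSite("s08", "2", 300, "T", "G"),
        PanelSite("s09", "2", 400, "A", "T"),
        PanelSite("s10", "2", 500, "C", "G"),
    ]
    return Panel(sites)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
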