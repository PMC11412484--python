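import numpy as np
import pytest

from recordevo import (
    AnnualBestSeries,
    EventSpec,
    PanelSpec,
    default_panel_spec,
    load_default_catalog,
    simulate_panel,
)


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture(scope="session")
def default_panel():
    """One draw of the packaged 24-event synthetic spec."""
    return simulate_panel(default_panel_spec(seed=7))


@pytest.fixture
def sprint_series():
    """A small minimize-type series with hand-picked marks."""
    return AnnualBestSeries(
        "100m", "minimize", "seconds",
        {1992: 9.93, 1993: 9.87, 1994: 9.85, 1995: 9.91, 1996: 9.84},
        year_range=(1992, 2018),
    )


@pytest.fixture
def jump_series():
    return AnnualBestSeries(
        "long_jump", "maximize", "meters",
        {1992: 8.60, 1993: 8.70, 1994: 8.55, 1995: 8.74},
        year_range=(1992, 2018),
    )


def make_two_block_spec(seed, block_size=12, within=0.9, between=0.0):
    """Two planted blocks of identical events with block-constant
    fluctuation correlation; all stationary minimize events."""
    k = 2 * block_size
    events = [
        EventSpec(f"e{i:02d}", "minimize", "seconds", level=100.0, sigma=1.0)
        for i in range(k)
    ]
    C = np.full((k, k), between)
    for blk in (range(block_size), range(block_size, k)):
        for a in blk:
            for b in blk:
                C[a, b] = within
    np.fill_diagonal(C, 1.0)
    return PanelSpec(events=events, correlation=C, years=(1992, 2018), seed=seed)
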