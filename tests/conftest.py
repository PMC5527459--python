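import numpy as np
import pandas as pd
import pytest

from ithkit.io import PANEL_COLUMNS, CountsPanel, Site, SiteCounts


@pytest.fixture
def small_config():
    from ithkit.simulate import SimConfig

    return SimConfig(n_sectors=5, n_clones=6, n_mutations=60, seed=11)


def make_panel(rows):
    """rows: (sample_id, role, tier, pos, var, q30, total) on a shared SNV locus."""
    data = [
        (sid, role, tier, "chr7", pos, "G", "A", var, q30, total)
        for (sid, role, tier, pos, var, q30, total) in rows
    ]
    return CountsPanel(pd.DataFrame(data, columns=PANEL_COLUMNS))


@pytest.fixture
def site7():
    return Site("chr7", 100, "G", "A")


def tier2_site_rows(pos, sector_vars, normal_var=0, control_vars=(0, 0, 0), depth=16000):
    rows = []
    for i, v in enumerate(sector_vars):
        rows.append((chr(ord("A") + i), "sector", "tier2", pos, v, depth, depth))
    rows.append(("N", "normal", "tier2", pos, normal_var, depth, depth))
    for j, v in enumerate(control_vars):
        rows.append((f"CTRL{j+1}", "control", "tier2", pos, v, depth, depth))
    return rows


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def sc(var, q30=None, total=None):
    q30 = var if q30 is None else q30
    total = q30 if total is None else total
    return SiteCounts(var, q30, total)
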