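"""Session fixtures: reduced-scale phantom scans shared across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from scansaxs import (
    ScanGrid,
    default_geometry,
    default_phantom,
    make_phantom,
    simulate_scan,
)
from scansaxs.reduce import write_scan


@pytest.fixture(scope="session")
def default_scan():
    """Standard study conditions: 20 cells, 120x120 scan, 128x128 detector."""
    phantom = default_phantom(seed=0)
    geom = default_geometry()
    stack = simulate_scan(phantom, geom, seed=1)
    return phantom, geom, stack


@pytest.fixture(scope="session")
def default_scan_file(default_scan, tmp_path_factory):
    phantom, geom, stack = default_scan
    path = tmp_path_factory.mktemp("scans") / "default_scan.h5"
    write_scan(path, stack, truth=phantom, seed=0)
    return path, phantom


@pytest.fixture(scope="session")
def small_scan():
    """Cheap scan for orchestration tests: 6 cells, 60x60 grid, 64x64 detector."""
    grid = ScanGrid(n_rows=60, n_cols=60)
    phantom = make_phantom(6, grid, seed=3)
    geom = default_geometry((64, 64))
    stack = simulate_scan(phantom, geom, seed=4)
    return phantom, geom, stack


@pytest.fixture(scope="session")
def small_scan_file(small_scan, tmp_path_factory):
    phantom, geom, stack = small_scan
    path = tmp_path_factory.mktemp("scans") / "small_scan.h5"
    write_scan(path, stack, truth=phantom, seed=3)
    return path, phantom


def match_cells_to_truth(found_id_map: np.ndarray, true_id_map: np.ndarray) -> dict:
    """Map each true cell id to the found id with maximal pixel overlap (0 = none)."""
    mapping = {}
    for tid in range(1, int(true_id_map.max()) + 1):
        sel = found_id_map[true_id_map == tid]
        sel = sel[sel > 0]
        mapping[tid] = int(np.bincount(sel).argmax()) if sel.size else 0
    return mapping
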