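"""Shared label conventions for scan-grid maps and detector frames."""

from __future__ import annotations

import enum

import numpy as np


class RegionClass(enum.IntEnum):
    """Per-scan-point class of the segmented dark-field image."""

    BACKGROUND = 0
    CYTOPLASM = 1
    NUCLEUS = 2
    DISREGARDED = 3


#: Sentinel stored at masked detector pixels in count stacks.
#: Counts are unsigned 32-bit; the sentinel is -1 cast to uint32
#: (Eiger-style gap semantics).
MASKED_SENTINEL = np.uint32(0xFFFFFFFF)


def is_masked_count(counts: np.ndarray) -> np.ndarray:
    """Boolean map of sentinel-valued (masked) pixels in a count array."""
    return counts == MASKED_SENTINEL
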