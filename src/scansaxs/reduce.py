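"""Data reduction: count stacks -> dark-field images and radial profiles.

The dark-field contrast image is, per scan point, the *sum* of counts over
unmasked detector pixels with q below a cutoff (2.99 nm^-1 by default) —
the total scattered intensity in a fixed detector ROI.  Radial profiles
are obtained by azimuthal integration: pixels are assigned to linear q bins
by their center q, and each bin reports the *mean* counts per contributing
pixel, so profiles are comparable across differently masked regions.
Bins with no contributing pixel are flagged invalid (NaN intensity), never
reported as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
import tifffile

from .geometry import DetectorGeometry, ScanGrid, build_qmap
from .labels import MASKED_SENTINEL

#: Dark-field / integration q cutoff (nm^-1): the detector ROI used
#: throughout, matching real-space features down to ~2.1 nm.
DEFAULT_QMAX = 2.99

#: Default number of linear q bins over (0, DEFAULT_QMAX].
DEFAULT_NBINS = 300


class EmptyROIError(ValueError):
    """No unmasked detector pixel satisfies the requested q selection."""


@dataclass
class PatternStack:
    """Scan-grid-indexed stack of detector count frames.

    ``counts`` has shape (n_rows, n_cols, det_rows, det_cols), dtype uint32;
    masked pixels hold :data:`~scansaxs.labels.MASKED_SENTINEL`.
    """

    counts: np.ndarray
    grid: ScanGrid
    geom: DetectorGeometry
    exposure: float

    def __post_init__(self):
        expected = (*self.grid.shape, *self.geom.shape)
        if self.counts.shape != expected:
            raise ValueError(
                f"counts shape {self.counts.shape} != scan+detector shape {expected}"
            )
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")

    def frame(self, row: int, col: int) -> np.ndarray:
        """One detector frame as float with NaN at masked pixels."""
        f = self.counts[row, col].astype(float)
        f[self.counts[row, col] == MASKED_SENTINEL] = np.nan
        return f


@dataclass
class DarkFieldImage:
    """Scan-grid-shaped map of total scattered counts within q <= q_max."""

    values: np.ndarray
    q_max: float


@dataclass
class RadialProfile:
    """Azimuthally integrated 1D intensity.

    ``intensity`` is mean counts per unmasked pixel per bin (per ms once
    exposure-normalized); ``n_pixels`` counts contributing pixels; bins with
    ``n_pixels == 0`` carry NaN intensity.
    """

    q_centers: np.ndarray
    intensity: np.ndarray
    n_pixels: np.ndarray

    def __post_init__(self):
        if not np.all(np.diff(self.q_centers) > 0):
            raise ValueError("q_centers must be strictly increasing")

    @property
    def valid(self) -> np.ndarray:
        return (self.n_pixels > 0) & np.isfinite(self.intensity)


# ---------------------------------------------------------------------------
# Reduction operations
# ---------------------------------------------------------------------------

def darkfield(stack: PatternStack, q_max: float = DEFAULT_QMAX) -> DarkFieldImage:
    """Sum counts over unmasked pixels with q <= q_max, per scan point."""
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    qmap = build_qmap(stack.geom)
    roi = (~stack.geom.mask) & (qmap.q <= q_max)
    if not roi.any():
        raise EmptyROIError(f"no unmasked pixel with q <= {q_max} nm^-1")
    flat_idx = np.flatnonzero(roi.ravel())
    n_rows, n_cols = stack.grid.shape
    values = np.empty((n_rows, n_cols), dtype=np.float64)
    for i in range(n_rows):  # row-wise to bound the working set
        frames = stack.counts[i].reshape(n_cols, -1)[:, flat_idx]
        values[i] = frames.sum(axis=1, dtype=np.float64)
    return DarkFieldImage(values=values, q_max=float(q_max))


def average_pattern(stack: PatternStack, indices) -> np.ndarray:
    """Pixel-wise mean frame over a set of scan points.

    ``indices`` is a sequence of (row, col) pairs or a pair of index arrays.
    Masked pixels stay NaN in the result.
    """
    rows, cols = _as_index_arrays(indices)
    if rows.size == 0:
        raise ValueError("index set must be non-empty")
    det_shape = stack.geom.shape
    acc = np.zeros(det_shape, dtype=np.float64)
    for start in range(0, rows.size, 512):  # chunked accumulation
        sel = stack.counts[rows[start:start + 512], cols[start:start + 512]]
        acc += sel.sum(axis=0, dtype=np.float64)
    mean = acc / rows.size
    mean[stack.geom.mask] = np.nan
    return mean


def _as_index_arrays(indices):
    if isinstance(indices, tuple) and len(indices) == 2 and np.ndim(indices[0]) > 0:
        return np.asarray(indices[0], dtype=int), np.asarray(indices[1], dtype=int)
    pairs = np.atleast_2d(np.asarray(list(indices), dtype=int))
    if pairs.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    return pairs[:, 0], pairs[:, 1]


def azimuthal_integrate(
    frame: np.ndarray,
    geom: DetectorGeometry,
    n_bins: int = DEFAULT_NBINS,
    q_range: tuple[float, float] = (0.0, DEFAULT_QMAX),
) -> RadialProfile:
    """Azimuthally integrate one frame into a linear-q radial profile.

    Bin membership is by pixel-center q (no pixel splitting); per-bin
    intensity is the mean over contributing unmasked, finite pixels.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    q_min, q_max = q_range
    if q_min >= q_max:
        raise ValueError(f"degenerate q_range {q_range}")
    frame = np.asarray(frame, dtype=float)
    sentinel = frame == float(MASKED_SENTINEL)
    q = build_qmap(geom).q
    valid = (~geom.mask) & np.isfinite(frame) & ~sentinel & (q > q_min) & (q <= q_max)
    width = (q_max - q_min) / n_bins
    bins = np.clip(((q[valid] - q_min) / width).astype(int), 0, n_bins - 1)
    sums = np.bincount(bins, weights=frame[valid], minlength=n_bins)
    n_pix = np.bincount(bins, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        intensity = np.where(n_pix > 0, sums / np.maximum(n_pix, 1), np.nan)
    q_centers = q_min + (np.arange(n_bins) + 0.5) * width
    return RadialProfile(q_centers=q_centers, intensity=intensity, n_pixels=n_pix)


# ---------------------------------------------------------------------------
# HDF5 scan files, TIFF maps, CSV profiles
# ---------------------------------------------------------------------------

def write_scan(path, stack: PatternStack, truth=None, seed: int | None = None) -> None:
    """Write a scan to HDF5: counts (chunked by scan row), geometry attrs,
    mask dataset, and optionally a ``truth`` group with the phantom maps."""
    geom, grid = stack.geom, stack.grid
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "counts",
            data=stack.counts,
            dtype=np.uint32,
            chunks=(1, grid.n_cols, *geom.shape),
        )
        f.create_dataset("mask", data=geom.mask.astype(np.uint8))
        f.attrs["energy_keV"] = geom.energy
        f.attrs["distance_m"] = geom.distance
        f.attrs["pixel_size_m"] = geom.pixel_size
        f.attrs["beam_center_row"] = geom.beam_center[0]
        f.attrs["beam_center_col"] = geom.beam_center[1]
        f.attrs["det_shape"] = geom.shape
        f.attrs["exposure_ms"] = stack.exposure
        f.attrs["step_y_um"] = grid.step_y
        f.attrs["step_z_um"] = grid.step_z
        if truth is not None:
            g = f.create_group("truth")
            g.create_dataset("class_map", data=truth.class_map)
            g.create_dataset("cell_id_map", data=truth.cell_id_map)
            g.create_dataset("K_map", data=truth.K_map)
            g.create_dataset("alpha_map", data=truth.alpha_map)
            g.create_dataset("B_map", data=truth.B_map)
            if seed is not None:
                g.attrs["seed"] = int(seed)


def read_scan(path) -> PatternStack:
    """Load a scan written by :func:`write_scan` (ground truth ignored)."""
    with h5py.File(path, "r") as f:
        counts = f["counts"][()]
        mask = f["mask"][()].astype(bool)
        geom = DetectorGeometry(
            energy=float(f.attrs["energy_keV"]),
            distance=float(f.attrs["distance_m"]),
            pixel_size=float(f.attrs["pixel_size_m"]),
            beam_center=(float(f.attrs["beam_center_row"]), float(f.attrs["beam_center_col"])),
            shape=tuple(int(s) for s in f.attrs["det_shape"]),
            mask=mask,
        )
        exposure = float(f.attrs["exposure_ms"])
        grid = ScanGrid(
            n_rows=counts.shape[0],
            n_cols=counts.shape[1],
            step_y=float(f.attrs["step_y_um"]),
            step_z=float(f.attrs["step_z_um"]),
            exposure=exposure,
        )
    return PatternStack(counts=counts, grid=grid, geom=geom, exposure=exposure)


def read_truth(path):
    """Load the ground-truth maps from a simulated scan file, or None."""
    with h5py.File(path, "r") as f:
        if "truth" not in f:
            return None
        g = f["truth"]
        return {
            "class_map": g["class_map"][()],
            "cell_id_map": g["cell_id_map"][()],
            "K_map": g["K_map"][()],
            "alpha_map": g["alpha_map"][()],
            "B_map": g["B_map"][()],
            "seed": int(g.attrs["seed"]) if "seed" in g.attrs else None,
        }


def write_darkfield_tiff(path, image: DarkFieldImage) -> None:
    tifffile.imwrite(path, image.values.astype(np.float32))


def write_profile_csv(path, profile: RadialProfile) -> None:
    pd.DataFrame(
        {
            "q_nm_inv": profile.q_centers,
            "intensity_per_ms": profile.intensity,
            "n_pixels": profile.n_pixels,
        }
    ).to_csv(path, index=False)


def read_profile_csv(path) -> RadialProfile:
    df = pd.read_csv(path)
    return RadialProfile(
        q_centers=df["q_nm_inv"].to_numpy(),
        intensity=df["intensity_per_ms"].to_numpy(),
        n_pixels=df["n_pixels"].to_numpy(),
    )
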