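"""Dark-field image segmentation into background / cytoplasm / nucleus ROIs.

Cells are separated from the background by Bradley-Roth adaptive
thresholding (local mean via an integral image, windows clipped at the
borders), labeled as 8-connected components, and each cell gets its own
Otsu threshold — computed on a 256-bin histogram of the cell's min-max
rescaled intensities — to find the nucleus, taken as the largest connected
component above threshold.  The nucleus is the *bright* class because it is
thicker and denser than the cytoplasm, hence brighter in dark-field.

Cell fragments are removed by configurable pixel-count criteria
(:class:`FilterCriteria`); rejected cells are relabeled "disregarded".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import measure, morphology

from .labels import RegionClass


@dataclass
class SegmentationLabels:
    """Per-scan-point class map, cell ids, and background surroundings."""

    class_map: np.ndarray        # uint8 of RegionClass
    cell_id_map: np.ndarray      # int32, 0 = no cell
    surroundings_map: np.ndarray  # int32: cell id owning this background pixel

    @property
    def n_cells(self) -> int:
        return int(self.cell_id_map.max())

    def cell_indices(self, cell_id: int, region: RegionClass | None = None):
        """(rows, cols) of one cell's pixels, optionally restricted to a class."""
        sel = self.cell_id_map == cell_id
        if region is not None:
            sel &= self.class_map == int(region)
        return np.nonzero(sel)

    def surroundings_indices(self, cell_id: int):
        return np.nonzero(self.surroundings_map == cell_id)


@dataclass(frozen=True)
class FilterCriteria:
    """Pixel-count conditions retained cells must satisfy.

    Defaults (min 30 nucleus pixels, 5000-10000 background pixels) are
    reconstructions of empirical whole-cell conditions for full-size
    (~3000 x 3000 position) scans; reduced-scale runs must override the
    background bounds.
    """

    min_nucleus_pixels: int = 30
    background_pixel_bounds: tuple[float, float] = (5000, 10000)
    cyt_nuc_ratio_bounds: tuple[float, float] | None = None

    def __post_init__(self):
        lo, hi = self.background_pixel_bounds
        if lo > hi or self.min_nucleus_pixels < 0:
            raise ValueError("filter bounds must be ordered and non-negative")
        if self.cyt_nuc_ratio_bounds is not None:
            rlo, rhi = self.cyt_nuc_ratio_bounds
            if rlo > rhi:
                raise ValueError("ratio bounds must be ordered")


# ---------------------------------------------------------------------------
# Adaptive (Bradley-Roth) cell/background separation
# ---------------------------------------------------------------------------

def _clipped_window_mean(image: np.ndarray, half: int) -> np.ndarray:
    """Mean over a (2*half+1)^2 window clipped at the image borders,
    computed with an integral image."""
    img = np.asarray(image, dtype=np.float64)
    n, m = img.shape
    S = np.zeros((n + 1, m + 1))
    S[1:, 1:] = img.cumsum(0).cumsum(1)
    r = np.arange(n)[:, None]
    c = np.arange(m)[None, :]
    r0 = np.clip(r - half, 0, n)
    r1 = np.clip(r + half + 1, 0, n)
    c0 = np.clip(c - half, 0, m)
    c1 = np.clip(c + half + 1, 0, m)
    total = S[r1, c1] - S[r0, c1] - S[r1, c0] + S[r0, c0]
    area = (r1 - r0) * (c1 - c0)
    return total / area


def bradley_mask(
    image: np.ndarray,
    window_fraction: float = 0.125,
    sensitivity: float = 0.5,
    min_object_pixels: int = 20,
    fill_holes: bool = True,
) -> np.ndarray:
    """Adaptive local thresholding of a dark-field image.

    A pixel is foreground iff its value exceeds the mean of the surrounding
    square window (side = ``window_fraction`` x the larger image dimension,
    rounded odd, clipped at borders) by the relative offset ``sensitivity``:
    ``v > (1 + sensitivity) * local_mean``.  This is the bright-foreground
    form of the Bradley-Roth criterion: cells scatter more than the support,
    so a constant image yields an empty mask and a flat positive background
    is never foreground.  The window must be a few cell diameters wide for
    the local mean to represent the background.  Holes in foreground objects
    are filled and objects below ``min_object_pixels`` are dropped.
    Invariant under positive rescaling of the image.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    image = np.asarray(image, dtype=float)
    side = int(round(window_fraction * max(image.shape)))
    side = max(side | 1, 3)  # odd, at least 3
    local_mean = _clipped_window_mean(image, side // 2)
    mask = image > (1.0 + sensitivity) * local_mean
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if min_object_pixels > 1:
        comps = measure.label(mask, connectivity=2)
        sizes = np.bincount(comps.ravel())
        mask = mask & (sizes[comps] >= min_object_pixels)
    return mask


def label_cells(mask: np.ndarray) -> np.ndarray:
    """8-connected component labeling; ids follow raster order of first pixels."""
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    return labels.astype(np.int32)


# ---------------------------------------------------------------------------
# Per-cell Otsu nucleus detection
# ---------------------------------------------------------------------------

def otsu_threshold_256(values: np.ndarray) -> float:
    """Otsu threshold on a 256-bin histogram of min-max rescaled values.

    Returns the threshold mapped back to the original intensity scale (the
    upper edge of the argmax bin); pixels strictly above it are "nucleus".
    Raises ValueError for constant input.
    """
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        raise ValueError("constant intensity: Otsu threshold undefined")
    scaled = (values - vmin) / (vmax - vmin)
    hist, _ = np.histogram(scaled, bins=256, range=(0.0, 1.0))
    p = hist / hist.sum()
    omega0 = np.cumsum(p)                 # class-0 weight up to and incl. bin t
    mu_t = np.cumsum(p * np.arange(256))  # cumulative first moment
    mu_total = mu_t[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_total * omega0 - mu_t) ** 2 / (omega0 * omega1)
    between = np.nan_to_num(between[:-1], nan=-1.0)  # t = 255 leaves class 1 empty
    t = int(np.argmax(between))
    return vmin + (t + 1) / 256.0 * (vmax - vmin)


def nucleus_by_otsu(image: np.ndarray, cell_mask: np.ndarray):
    """Nucleus pixels of one cell: above its own Otsu threshold, largest
    connected component only.

    Returns ``(nucleus_mask, threshold)``; for a constant-intensity cell the
    mask is empty and the threshold is NaN (flagged no-nucleus result).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    vals = np.asarray(image, dtype=float)[cell_mask]
    if vals.size == 0:
        return np.zeros_like(cell_mask), float("nan")
    try:
        thresh = otsu_threshold_256(vals)
    except ValueError:
        return np.zeros_like(cell_mask), float("nan")
    above = np.zeros_like(cell_mask)
    above[cell_mask] = np.asarray(image, dtype=float)[cell_mask] > thresh
    if not above.any():
        return above, thresh
    comps = measure.label(above, connectivity=2)
    sizes = np.bincount(comps.ravel())
    sizes[0] = 0
    return comps == int(np.argmax(sizes)), thresh


# ---------------------------------------------------------------------------
# Surroundings and fragment filtering
# ---------------------------------------------------------------------------

def build_surroundings_map(
    class_map: np.ndarray, cell_id_map: np.ndarray, margin: int = 20
) -> np.ndarray:
    """Assign background pixels to the surroundings of at most one cell.

    A background-class pixel belongs to cell ``c`` iff it lies inside c's
    bounding box dilated by ``margin`` pixels and c is its nearest cell
    (by distance to the nearest cell-body pixel), so overlapping boxes give
    disjoint surroundings.
    """
    out = np.zeros_like(cell_id_map, dtype=np.int32)
    if cell_id_map.max() == 0:
        return out
    # nearest cell body pixel for every grid point
    _, (ir, ic) = ndimage.distance_transform_edt(cell_id_map == 0, return_indices=True)
    nearest = cell_id_map[ir, ic]
    background = class_map == int(RegionClass.BACKGROUND)
    objects = ndimage.find_objects(cell_id_map)
    for cid, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        r0 = max(sl[0].start - margin, 0)
        r1 = min(sl[0].stop + margin, cell_id_map.shape[0])
        c0 = max(sl[1].start - margin, 0)
        c1 = min(sl[1].stop + margin, cell_id_map.shape[1])
        box = np.zeros_like(background)
        box[r0:r1, c0:c1] = True
        out[box & background & (nearest == cid)] = cid
    return out


def cell_surroundings(labels: SegmentationLabels, cell_id: int, margin: int = 20):
    """(rows, cols) of the background pixels surrounding one cell."""
    if not (labels.cell_id_map == cell_id).any():
        raise ValueError(f"cell {cell_id} does not exist")
    surr = build_surroundings_map(labels.class_map, labels.cell_id_map, margin=margin)
    rows, cols = np.nonzero(surr == cell_id)
    if rows.size == 0:
        raise ValueError(
            f"cell {cell_id} has empty surroundings at margin={margin}; "
            "increase the margin"
        )
    return rows, cols


def filter_cells(records, criteria: FilterCriteria = FilterCriteria()):
    """Keep records meeting all pixel-count criteria.

    ``records`` need attributes ``n_nuc``, ``n_cyt``, ``n_bg``.  Returns
    ``(retained, rejections)`` where rejections counts failures per
    criterion (a record can fail several).
    """
    retained = []
    rejections = {"min_nucleus_pixels": 0, "background_pixel_bounds": 0,
                  "cyt_nuc_ratio_bounds": 0}
    lo, hi = criteria.background_pixel_bounds
    for rec in records:
        ok = True
        if rec.n_nuc < criteria.min_nucleus_pixels:
            rejections["min_nucleus_pixels"] += 1
            ok = False
        if not (lo <= rec.n_bg <= hi):
            rejections["background_pixel_bounds"] += 1
            ok = False
        if criteria.cyt_nuc_ratio_bounds is not None and rec.n_nuc > 0:
            rlo, rhi = criteria.cyt_nuc_ratio_bounds
            ratio = rec.n_cyt / rec.n_nuc
            if not (rlo <= ratio <= rhi):
                rejections["cyt_nuc_ratio_bounds"] += 1
                ok = False
        if ok:
            retained.append(rec)
    return retained, rejections


# ---------------------------------------------------------------------------
# Full segmentation of a dark-field image
# ---------------------------------------------------------------------------

def segment_darkfield(
    image: np.ndarray,
    window_fraction: float = 0.125,
    sensitivity: float = 0.5,
    min_object_pixels: int = 20,
    surroundings_margin: int = 20,
) -> SegmentationLabels:
    """Segment a dark-field image into the four classes plus cell ids.

    Pipeline: Bradley mask -> 8-connected labeling -> per-cell Otsu nucleus
    -> surroundings assignment.  Cells whose Otsu threshold is undefined
    keep an empty nucleus (they can be filtered later).
    """
    image = np.asarray(image, dtype=float)
    mask = bradley_mask(
        image,
        window_fraction=window_fraction,
        sensitivity=sensitivity,
        min_object_pixels=min_object_pixels,
    )
    cell_id_map = label_cells(mask)
    class_map = np.full(image.shape, int(RegionClass.BACKGROUND), dtype=np.uint8)
    class_map[mask] = int(RegionClass.CYTOPLASM)
    for cid in range(1, cell_id_map.max() + 1):
        nuc, _ = nucleus_by_otsu(image, cell_id_map == cid)
        class_map[nuc] = int(RegionClass.NUCLEUS)
    surroundings = build_surroundings_map(class_map, cell_id_map, margin=surroundings_margin)
    return SegmentationLabels(
        class_map=class_map, cell_id_map=cell_id_map, surroundings_map=surroundings
    )


def relabel_disregarded(labels: SegmentationLabels, rejected_ids) -> SegmentationLabels:
    """Mark rejected cells' pixels disregarded (mirrors the black pixels of
    a final ROI map) and drop their surroundings claims."""
    rejected_ids = set(int(i) for i in rejected_ids)
    class_map = labels.class_map.copy()
    surroundings = labels.surroundings_map.copy()
    for cid in rejected_ids:
        class_map[labels.cell_id_map == cid] = int(RegionClass.DISREGARDED)
        surroundings[surroundings == cid] = 0
    return SegmentationLabels(
        class_map=class_map, cell_id_map=labels.cell_id_map.copy(),
        surroundings_map=surroundings,
    )


def cell_geometry_table(labels: SegmentationLabels) -> pd.DataFrame:
    """Per-cell pixel counts, bounding box and centroid as a DataFrame."""
    rows = []
    objects = ndimage.find_objects(labels.cell_id_map)
    for cid, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        body = labels.cell_id_map == cid
        nuc = body & (labels.class_map == int(RegionClass.NUCLEUS))
        cyt = body & (labels.class_map == int(RegionClass.CYTOPLASM))
        rr, cc = np.nonzero(body)
        rows.append(
            {
                "cell_id": cid,
                "N_nuc": int(nuc.sum()),
                "N_cyt": int(cyt.sum()),
                "N_bg": int((labels.surroundings_map == cid).sum()),
                "bbox_row0": sl[0].start, "bbox_row1": sl[0].stop,
                "bbox_col0": sl[1].start, "bbox_col1": sl[1].stop,
                "centroid_row": float(rr.mean()), "centroid_col": float(cc.mean()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "N_nuc", "N_cyt", "N_bg", "bbox_row0", "bbox_row1",
                 "bbox_col0", "bbox_col1", "centroid_row", "centroid_col"],
    )


def write_label_tiffs(class_path, cellid_path, labels: SegmentationLabels) -> None:
    tifffile.imwrite(class_path, labels.class_map.astype(np.uint16))
    tifffile.imwrite(cellid_path, labels.cell_id_map.astype(np.uint16))
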