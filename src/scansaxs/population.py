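"""Population-level orchestration and statistics.

Three analysis levels operate on a segmented scan:

* **window** — one average scattering pattern per ROI class over the whole
  scan, mirroring a population-wide characterization;
* **cell** — per-cell average patterns for nucleus and cytoplasm, each
  corrected with the cell's own surroundings background;
* **pattern** — per-scan-point fits inside cell bodies with row-matched
  background subtraction, yielding K and alpha maps.

Subpopulation statistics split retained cells by area quartiles ("small" =
first, "large" = fourth) and compare the K and alpha distributions per
region with two-sample Kolmogorov-Smirnov tests (raw p-values, no
multiple-testing correction).  Orientation/anisotropy of a scattering
pattern is summarized by the second circular moment of its azimuthal
intensity distribution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import special

from . import fitmodel, reduce, segment
from .geometry import DetectorGeometry, build_qmap
from .labels import MASKED_SENTINEL, RegionClass


@dataclass
class CellRecord:
    """Per-cell bookkeeping: pixel counts, geometry, fits, filter flags."""

    cell_id: int
    n_nuc: int
    n_cyt: int
    n_bg: int
    centroid: tuple[float, float] = (np.nan, np.nan)
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)
    fit_nucleus: fitmodel.PowerLawFit | None = None
    fit_cytoplasm: fitmodel.PowerLawFit | None = None
    retained: bool = True
    reject_reasons: list[str] = field(default_factory=list)

    @property
    def area(self) -> int:
        """Cell-body pixel count (nucleus + cytoplasm)."""
        return self.n_nuc + self.n_cyt


@dataclass
class PopulationSummary:
    """Small-vs-large comparison of fitted (K, alpha) per region."""

    quartile_boundaries: tuple[float, float, float]
    group_sizes: dict
    group_stats: dict      # {group: {region: {param: {mean, median, sd}}}}
    ks_tests: dict         # {"K_nucleus": {"D": ..., "p": ...}, ...}
    underpowered: bool


@dataclass
class Config:
    """Pipeline configuration; flat YAML keys use dots (e.g. bradley.sensitivity)."""

    qmax_darkfield: float = 2.99
    fit_qmin: float = 0.185
    fit_qmax: float = 1.723
    n_qbins: int = 300
    bradley_window_fraction: float = 0.125
    bradley_sensitivity: float = 0.5
    bradley_min_object_pixels: int = 20
    filter_min_nucleus_pixels: int = 30
    filter_bg_bounds: tuple[float, float] = (5000, 10000)
    surroundings_margin: int = 20
    dose_mu_over_rho: float = fitmodel.MU_OVER_RHO_PROTEIN
    dose_flux: float = 1.7e12
    seed: int = 0

    _ALIASES = {
        "bradley.window_fraction": "bradley_window_fraction",
        "bradley.sensitivity": "bradley_sensitivity",
        "bradley.min_object_pixels": "bradley_min_object_pixels",
        "filter.min_nucleus_pixels": "filter_min_nucleus_pixels",
        "filter.bg_bounds": "filter_bg_bounds",
        "surroundings.margin": "surroundings_margin",
        "dose.mu_over_rho": "dose_mu_over_rho",
        "dose.flux": "dose_flux",
    }

    @classmethod
    def from_yaml(cls, path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        kwargs = {}
        for key, value in raw.items():
            name = cls._ALIASES.get(key, key.replace(".", "_"))
            if name not in known:
                raise KeyError(f"unknown config key {key!r}")
            if name == "filter_bg_bounds":
                value = tuple(value)
            kwargs[name] = value
        return cls(**kwargs)

    @property
    def fit_qrange(self) -> tuple[float, float]:
        return (self.fit_qmin, self.fit_qmax)

    @property
    def filter_criteria(self) -> segment.FilterCriteria:
        return segment.FilterCriteria(
            min_nucleus_pixels=self.filter_min_nucleus_pixels,
            background_pixel_bounds=tuple(self.filter_bg_bounds),
        )


def reduced_scale_config(**overrides) -> Config:
    """Config tuned to the reduced-scale study conditions (120x120 scan,
    128x128 detector, ~20 cells of ~10 px semi-axis).

    The Bradley window is widened to a few cell diameters and the
    fragment-filter pixel bounds are rescaled from their full-size
    (~3000x3000 scan) values to this grid.
    """
    defaults = dict(
        bradley_window_fraction=0.35,
        bradley_sensitivity=0.5,
        filter_min_nucleus_pixels=5,
        filter_bg_bounds=(50, 10000),
    )
    defaults.update(overrides)
    return Config(**defaults)


# ---------------------------------------------------------------------------
# Statistics primitives
# ---------------------------------------------------------------------------

def area_quartiles(areas) -> tuple[float, float, float]:
    """25/50/75 empirical percentiles with linear interpolation."""
    areas = np.asarray(list(areas), dtype=float)
    if areas.size < 4:
        raise ValueError("need at least 4 areas for quartiles")
    q25, q50, q75 = np.percentile(areas, [25, 50, 75])
    return float(q25), float(q50), float(q75)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact supremum distance between the two empirical CDFs; the
    p-value comes from the asymptotic Kolmogorov distribution evaluated at
    sqrt(n_eff) * D with n_eff = n_x n_y / (n_x + n_y).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    D = float(np.max(np.abs(cdf_x - cdf_y)))
    n_eff = x.size * y.size / (x.size + y.size)
    p = float(special.kolmogorov(np.sqrt(n_eff) * D))
    return D, min(max(p, 0.0), 1.0)


def orientation_anisotropy(
    frame: np.ndarray,
    geom: DetectorGeometry,
    q_range: tuple[float, float],
    n_sectors: int = 36,
) -> tuple[float, float]:
    """Predominant orientation (deg, in [0, 180)) and anisotropy (|m2|).

    The frame's intensity within ``q_range`` is binned into azimuthal
    sectors; the second circular moment
    m2 = sum w(phi) exp(2i phi) / sum w(phi) gives anisotropy |m2| and
    orientation arg(m2)/2.  For a cos-2phi modulated pattern of amplitude
    ``a`` this yields |m2| = a/2 at the modulation's phase angle.
    """
    frame = np.asarray(frame, dtype=float)
    qmap = build_qmap(geom)
    sel = (
        (~geom.mask)
        & np.isfinite(frame)
        & (frame != float(MASKED_SENTINEL))
        & (qmap.q >= q_range[0])
        & (qmap.q <= q_range[1])
    )
    width = 2.0 * np.pi / n_sectors
    sector = np.clip((qmap.azimuth[sel] / width).astype(int), 0, n_sectors - 1)
    sums = np.bincount(sector, weights=frame[sel], minlength=n_sectors)
    n_pix = np.bincount(sector, minlength=n_sectors)
    valid = n_pix > 0
    if valid.sum() < 2:
        raise ValueError("fewer than 2 valid azimuthal sectors")
    w = sums[valid] / n_pix[valid]
    phi = (np.arange(n_sectors)[valid] + 0.5) * width
    total = w.sum()
    if total <= 0:
        return 0.0, 0.0
    m2 = np.sum(w * np.exp(2j * phi)) / total
    angle = np.degrees(0.5 * np.angle(m2)) % 180.0
    return float(angle), float(np.abs(m2))


def compare_small_vs_large(records: list[CellRecord]) -> PopulationSummary:
    """KS comparison of (K, alpha) distributions for first- vs
    fourth-area-quartile cells, per region.

    Only retained cells with converged fits enter.  With a degenerate group
    the summary is flagged underpowered and KS entries are NaN.
    """
    usable = [
        r for r in records
        if r.retained and r.fit_nucleus is not None and r.fit_cytoplasm is not None
        and r.fit_nucleus.converged and r.fit_cytoplasm.converged
    ]
    if len(usable) < 4:
        raise ValueError("need at least 4 retained, converged cells")
    areas = np.array([r.area for r in usable], dtype=float)
    q25, q50, q75 = area_quartiles(areas)
    small = [r for r in usable if r.area <= q25]
    large = [r for r in usable if r.area >= q75]
    groups = {"small": small, "large": large}

    def values(group, region, param):
        fits = [getattr(r, f"fit_{region}") for r in group]
        return np.array([getattr(f, param) for f in fits], dtype=float)

    group_stats = {}
    for gname, group in groups.items():
        group_stats[gname] = {}
        for region in ("nucleus", "cytoplasm"):
            group_stats[gname][region] = {}
            for param in ("K", "alpha"):
                v = values(group, region, param)
                group_stats[gname][region][param] = {
                    "mean": float(v.mean()) if v.size else np.nan,
                    "median": float(np.median(v)) if v.size else np.nan,
                    "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
                }

    underpowered = min(len(small), len(large)) < 2
    ks_tests = {}
    for region in ("nucleus", "cytoplasm"):
        for param in ("K", "alpha"):
            key = f"{param}_{region}"
            if underpowered:
                ks_tests[key] = {"D": np.nan, "p": np.nan}
            else:
                D, p = ks_two_sample(
                    values(small, region, param), values(large, region, param)
                )
                ks_tests[key] = {"D": D, "p": p}

    return PopulationSummary(
        quartile_boundaries=(q25, q50, q75),
        group_sizes={k: len(v) for k, v in groups.items()},
        group_stats=group_stats,
        ks_tests=ks_tests,
        underpowered=underpowered,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    darkfield: reduce.DarkFieldImage
    labels: segment.SegmentationLabels
    records: list[CellRecord]
    window_fits: dict               # {"nucleus": PowerLawFit, "cytoplasm": ...}
    pattern_maps: dict              # {"K": 2D array, "alpha": 2D array} or {}
    summary: PopulationSummary | None
    manifest: dict


def run_pipeline(
    scan_path,
    config: Config | None = None,
    output_dir=None,
    levels: tuple[str, ...] = ("window", "cell"),
) -> PipelineResult:
    """Execute reduce -> segment -> fit at the requested analysis levels.

    Fully determined by the input file and config (no randomness); rerunning
    with the same inputs reproduces every output byte-for-byte.  Artifacts
    (TIFF maps, CSV tables, JSON summary, manifest) are written when
    ``output_dir`` is given; on a stage failure the partial outputs written
    so far remain on disk alongside the manifest.
    """
    config = config or Config()
    for level in levels:
        if level not in ("window", "cell", "pattern"):
            raise ValueError(f"unknown analysis level {level!r}")
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"scan": str(scan_path), "levels": list(levels), "outputs": []}

    def _save(name, writer, *args):
        if out is not None:
            writer(out / name, *args)
            manifest["outputs"].append(name)

    stack = _stage("reduce", reduce.read_scan, scan_path)
    df = _stage("reduce", reduce.darkfield, stack, config.qmax_darkfield)
    _save("darkfield.tiff", reduce.write_darkfield_tiff, df)

    labels = _stage(
        "segment",
        segment.segment_darkfield,
        df.values,
        config.bradley_window_fraction,
        config.bradley_sensitivity,
        config.bradley_min_object_pixels,
        config.surroundings_margin,
    )
    geo = segment.cell_geometry_table(labels)
    records = [
        CellRecord(
            cell_id=int(row.cell_id), n_nuc=int(row.N_nuc), n_cyt=int(row.N_cyt),
            n_bg=int(row.N_bg),
            centroid=(float(row.centroid_row), float(row.centroid_col)),
            bbox=(int(row.bbox_row0), int(row.bbox_row1), int(row.bbox_col0), int(row.bbox_col1)),
        )
        for row in geo.itertuples()
    ]
    retained, rejections = segment.filter_cells(records, config.filter_criteria)
    retained_ids = {r.cell_id for r in retained}
    for rec in records:
        rec.retained = rec.cell_id in retained_ids
        if not rec.retained:
            rec.reject_reasons = _reject_reasons(rec, config.filter_criteria)
    labels = segment.relabel_disregarded(
        labels, [r.cell_id for r in records if not r.retained]
    )
    manifest["n_cells"] = len(records)
    manifest["n_retained"] = len(retained)
    manifest["rejections"] = rejections
    _save("class_map.tiff", lambda p: segment.write_label_tiffs(
        p, (out / "cell_id_map.tiff"), labels))
    if out is not None and "cell_id_map.tiff" not in manifest["outputs"]:
        manifest["outputs"].append("cell_id_map.tiff")
    _save("cells.csv", lambda p: geo.assign(
        retained=[r.retained for r in records]).to_csv(p, index=False))

    window_fits: dict = {}
    if "window" in levels:
        window_fits = _stage("fit", _window_level, stack, labels, config)
        _save("fits_window.csv", _write_fits_csv,
              [("window", region, fit) for region, fit in window_fits.items()])

    if "cell" in levels and retained:
        _stage("fit", _cell_level, stack, labels, retained, config)
        _save("fits_cell.csv", _write_fits_csv,
              [(r.cell_id, region, getattr(r, f"fit_{region}"))
               for r in retained for region in ("nucleus", "cytoplasm")
               if getattr(r, f"fit_{region}") is not None])

    pattern_maps: dict = {}
    if "pattern" in levels and retained:
        pattern_maps = _stage("fit", _pattern_level, stack, labels, retained, config)
        if out is not None:
            tifffile.imwrite(out / "K_map.tiff", pattern_maps["K"].astype(np.float32))
            tifffile.imwrite(out / "alpha_map.tiff", pattern_maps["alpha"].astype(np.float32))
            manifest["outputs"] += ["K_map.tiff", "alpha_map.tiff"]

    summary = None
    if "cell" in levels:
        try:
            summary = compare_small_vs_large(records)
        except ValueError:
            summary = None
    if out is not None:
        if summary is not None:
            (out / "summary.json").write_text(json.dumps(asdict(summary), indent=2))
            manifest["outputs"].append("summary.json")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        darkfield=df, labels=labels, records=records, window_fits=window_fits,
        pattern_maps=pattern_maps, summary=summary, manifest=manifest,
    )


def _stage(name, fn, *args):
    try:
        return fn(*args)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def _reject_reasons(rec: CellRecord, crit: segment.FilterCriteria) -> list[str]:
    reasons = []
    if rec.n_nuc < crit.min_nucleus_pixels:
        reasons.append("min_nucleus_pixels")
    lo, hi = crit.background_pixel_bounds
    if not (lo <= rec.n_bg <= hi):
        reasons.append("background_pixel_bounds")
    return reasons


def _region_indices(labels, region: RegionClass):
    return np.nonzero(labels.class_map == int(region))


def _window_level(stack, labels, config: Config) -> dict:
    """Whole-scan ROI-average fits for nucleus and cytoplasm."""
    bg_idx = _region_indices(labels, RegionClass.BACKGROUND)
    fits = {}
    for region, cls in (("nucleus", RegionClass.NUCLEUS), ("cytoplasm", RegionClass.CYTOPLASM)):
        idx = _region_indices(labels, cls)
        if idx[0].size == 0:
            continue
        fit, _ = fitmodel.fit_region_profile(
            stack, idx, bg_idx, n_bins=config.n_qbins,
            integrate_qrange=(0.0, config.qmax_darkfield),
            fit_qrange=config.fit_qrange,
        )
        fits[region] = fit
    return fits


def _cell_level(stack, labels, retained: list[CellRecord], config: Config) -> None:
    """Per-cell fits against each cell's own surroundings background."""
    for rec in retained:
        bg_idx = labels.surroundings_indices(rec.cell_id)
        if bg_idx[0].size == 0:
            continue
        for region, cls in (("nucleus", RegionClass.NUCLEUS), ("cytoplasm", RegionClass.CYTOPLASM)):
            idx = labels.cell_indices(rec.cell_id, cls)
            if idx[0].size == 0:
                continue
            try:
                fit, _ = fitmodel.fit_region_profile(
                    stack, idx, bg_idx, n_bins=config.n_qbins,
                    integrate_qrange=(0.0, config.qmax_darkfield),
                    fit_qrange=config.fit_qrange,
                )
            except ValueError:
                continue
            setattr(rec, f"fit_{region}", fit)


def _pattern_level(stack, labels, retained: list[CellRecord], config: Config) -> dict:
    """Single-pattern fits with row-matched background; K/alpha maps."""
    shape = labels.class_map.shape
    K_map = np.full(shape, np.nan)
    alpha_map = np.full(shape, np.nan)
    for rec in retained:
        rows, cols = labels.cell_indices(rec.cell_id)
        cell_bg_idx = labels.surroundings_indices(rec.cell_id)
        for row, col in zip(rows, cols):
            try:
                bg = fitmodel.row_matched_background(
                    stack, labels, rec.cell_id, (row, col),
                    n_bins=config.n_qbins, q_range=(0.0, config.qmax_darkfield),
                )
            except ValueError:
                if cell_bg_idx[0].size == 0:
                    continue
                bg = reduce.azimuthal_integrate(
                    reduce.average_pattern(stack, cell_bg_idx), stack.geom,
                    n_bins=config.n_qbins, q_range=(0.0, config.qmax_darkfield),
                )
            sig = reduce.azimuthal_integrate(
                stack.frame(row, col), stack.geom,
                n_bins=config.n_qbins, q_range=(0.0, config.qmax_darkfield),
            )
            sig = fitmodel.normalize_exposure(sig, stack.exposure)
            bg = fitmodel.normalize_exposure(bg, stack.exposure)
            corrected = fitmodel.subtract_background(sig, bg)
            try:
                fit = fitmodel.fit_power_law(corrected, q_range=config.fit_qrange)
            except ValueError:
                continue
            if fit.converged:
                K_map[row, col] = fit.K
                alpha_map[row, col] = fit.alpha
    return {"K": K_map, "alpha": alpha_map}


def _write_fits_csv(path, rows) -> None:
    records = []
    for cell_id, region, fit in rows:
        records.append(
            {
                "cell_id": cell_id, "region": region,
                "K": fit.K, "alpha": fit.alpha, "B": fit.B,
                "K_err": fit.K_err, "alpha_err": fit.alpha_err, "B_err": fit.B_err,
                "converged": fit.converged, "n_bins": fit.n_bins,
            }
        )
    pd.DataFrame(
        records,
        columns=["cell_id", "region", "K", "alpha", "B", "K_err", "alpha_err",
                 "B_err", "converged", "n_bins"],
    ).to_csv(path, index=False)
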