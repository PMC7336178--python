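"""Forward model of a scanning-SAXS acquisition on freeze-dried cells.

A :class:`Phantom` is a field of non-overlapping elliptical cells on a scan
grid, each with a concentric elliptical nucleus.  Every scan point scatters
as a power law

    I(q) = K * q**alpha + B        (counts per ms per pixel, q in nm^-1)

with per-region ground-truth parameters (nucleus brighter than cytoplasm),
on top of a weakly anisotropic instrument background

    b(q) * (1 + a * cos 2(phi - phi0)),    b(q) = K_bg * q**alpha_bg + B_bg,

which is the only anisotropic term.  Detector frames are independent
Poisson draws of expectation * exposure.  Analytic sphere / rod / disc form
factors are provided for validating the power-law fitter in its asymptotic
(Porod) regimes: slopes -4, -1 and -2 respectively.

Intensity units are arbitrary (no absolute calibration is modeled); K is
quoted in counts * nm^alpha / ms at q = 1 nm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

from .geometry import DetectorGeometry, ScanGrid, build_qmap
from .labels import MASKED_SENTINEL, RegionClass


class PlacementError(RuntimeError):
    """Raised when the requested number of cells cannot be placed."""


# ---------------------------------------------------------------------------
# Phantom description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundParams:
    """Instrument background: weak power law with optional cos-2phi anisotropy."""

    K: float = 0.02
    alpha: float = -3.0
    B: float = 0.002
    aniso: float = 0.0          # amplitude a in [0, 1)
    aniso_angle: float = 0.0    # phi0, rad

    def __post_init__(self):
        if not (0.0 <= self.aniso < 1.0):
            raise ValueError("anisotropy amplitude must be in [0, 1)")


@dataclass(frozen=True)
class CellShapeParams:
    """One phantom cell: body/nucleus ellipses and scattering parameters."""

    center: tuple[float, float]          # (row, col), scan pixels
    axes: tuple[float, float]            # semi-axes (a, b), scan pixels
    orientation: float                   # rad
    nucleus_scale: float                 # nucleus semi-axes = scale * body axes
    K_cyt: float
    K_nuc: float
    alpha_cyt: float
    alpha_nuc: float
    B: float
    delta_rho: float = 1.0               # electron-density contrast (arb.)
    surface: float = 1.0                 # scatterer interface area (arb.)


@dataclass(frozen=True)
class PhantomParams:
    """Distributions used by :func:`make_phantom`.

    Defaults emulate a confluent field of freeze-dried fibroblasts at
    reduced scale: power-law exponents near -4.1 (slightly below Porod),
    nuclei 1.5-3x brighter than cytoplasm, a small additive constant, and
    an instrument background at roughly 10-30% of the cytoplasmic signal
    inside the fit band.
    """

    major_axis_mean: float = 9.0         # scan pixels
    major_axis_sd: float = 2.0
    min_axis: float = 3.0
    axis_ratio_range: tuple[float, float] = (0.55, 0.9)
    nucleus_scale_range: tuple[float, float] = (0.35, 0.55)
    alpha_mean: float = -4.1
    alpha_sd: float = 0.1
    alpha_bounds: tuple[float, float] = (-6.0, -2.0)
    log_K_mean: float = float(np.log(0.05))
    log_K_sd: float = 0.4
    nucleus_K_factor_range: tuple[float, float] = (1.5, 3.0)
    B_range: tuple[float, float] = (0.001, 0.005)
    k_mode: str = "lognormal"            # "lognormal" | "porod" | "inverse_area"
    porod_coeff: float = 0.002           # K = c * delta_rho**2 * surface
    delta_rho_range: tuple[float, float] = (0.8, 1.2)
    inverse_area_scale: float = 10.0     # K = scale / area(px)
    min_separation: float = 2.0          # px kept clear between cell bodies
    background: BackgroundParams = field(default_factory=BackgroundParams)


@dataclass
class Phantom:
    """Ground-truth cell field on a scan grid."""

    grid: ScanGrid
    class_map: np.ndarray       # uint8, RegionClass values
    cell_id_map: np.ndarray     # int32, 0 = no cell
    K_map: np.ndarray
    alpha_map: np.ndarray
    B_map: np.ndarray
    background: BackgroundParams
    cells: list[CellShapeParams] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _ellipse_mask(shape, center, axes, orientation):
    """Boolean scan-grid mask of pixels inside the ellipse."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dr = rr - center[0]
    dc = cc - center[1]
    co, si = np.cos(orientation), np.sin(orientation)
    u = dc * co + dr * si
    v = -dc * si + dr * co
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def phantom_from_cells(
    cells: list[CellShapeParams],
    grid: ScanGrid,
    background: BackgroundParams | None = None,
) -> Phantom:
    """Rasterize an explicit cell list into ground-truth maps.

    Cells are painted in order; callers are responsible for non-overlap.
    A cell whose nucleus ellipse covers no pixel gets its most central body
    pixel promoted to nucleus so every cell has at least one nucleus pixel.
    """
    shape = grid.shape
    class_map = np.full(shape, int(RegionClass.BACKGROUND), dtype=np.uint8)
    cell_id_map = np.zeros(shape, dtype=np.int32)
    K_map = np.zeros(shape, dtype=float)
    alpha_map = np.zeros(shape, dtype=float)
    B_map = np.zeros(shape, dtype=float)

    for idx, cell in enumerate(cells, start=1):
        body = _ellipse_mask(shape, cell.center, cell.axes, cell.orientation)
        nuc_axes = (cell.axes[0] * cell.nucleus_scale, cell.axes[1] * cell.nucleus_scale)
        nuc = _ellipse_mask(shape, cell.center, nuc_axes, cell.orientation) & body
        if not nuc.any() and body.any():
            rr, cc = np.nonzero(body)
            d2 = (rr - cell.center[0]) ** 2 + (cc - cell.center[1]) ** 2
            k = int(np.argmin(d2))
            nuc = np.zeros(shape, dtype=bool)
            nuc[rr[k], cc[k]] = True
        cyt = body & ~nuc
        class_map[cyt] = int(RegionClass.CYTOPLASM)
        class_map[nuc] = int(RegionClass.NUCLEUS)
        cell_id_map[body] = idx
        K_map[cyt] = cell.K_cyt
        K_map[nuc] = cell.K_nuc
        alpha_map[cyt] = cell.alpha_cyt
        alpha_map[nuc] = cell.alpha_nuc
        B_map[body] = cell.B

    return Phantom(
        grid=grid,
        class_map=class_map,
        cell_id_map=cell_id_map,
        K_map=K_map,
        alpha_map=alpha_map,
        B_map=B_map,
        background=background if background is not None else BackgroundParams(),
        cells=list(cells),
    )


def make_phantom(
    n_cells: int,
    grid: ScanGrid,
    seed: int,
    params: PhantomParams | None = None,
    max_attempts_per_cell: int = 200,
) -> Phantom:
    """Draw a reproducible phantom with non-overlapping elliptical cells.

    Placement is by rejection sampling against an occupancy mask dilated by
    ``params.min_separation`` so cell bodies never touch (they stay separate
    under 8-connected labeling).  Raises :class:`PlacementError` naming the
    number of cells achieved when the grid is too crowded.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    shape = grid.shape
    occupied = np.zeros(shape, dtype=bool)
    cells: list[CellShapeParams] = []
    attempts_left = max_attempts_per_cell * max(n_cells, 1)

    while len(cells) < n_cells:
        if attempts_left <= 0:
            raise PlacementError(
                f"placed only {len(cells)} of {n_cells} cells without overlap"
            )
        attempts_left -= 1
        a = max(params.min_axis, rng.normal(params.major_axis_mean, params.major_axis_sd))
        b = a * rng.uniform(*params.axis_ratio_range)
        margin = a + params.min_separation
        if 2 * margin >= min(shape):
            raise PlacementError(
                f"grid {shape} too small for cells of semi-axis ~{a:.1f} px"
            )
        center = (
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
        )
        orientation = rng.uniform(0, np.pi)
        pad = params.min_separation
        body_pad = _ellipse_mask(shape, center, (a + pad, b + pad), orientation)
        if (body_pad & occupied).any():
            continue
        occupied |= body_pad

        alpha_cyt = _trunc_normal(rng, params.alpha_mean, params.alpha_sd, params.alpha_bounds)
        alpha_nuc = _trunc_normal(rng, params.alpha_mean, params.alpha_sd, params.alpha_bounds)
        delta_rho = rng.uniform(*params.delta_rho_range)
        # perimeter-like proxy for the scatterer interface area
        surface = float(np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b))))
        if params.k_mode == "lognormal":
            K_cyt = float(rng.lognormal(params.log_K_mean, params.log_K_sd))
        elif params.k_mode == "porod":
            K_cyt = params.porod_coeff * delta_rho**2 * surface
        elif params.k_mode == "inverse_area":
            K_cyt = params.inverse_area_scale / (np.pi * a * b)
        else:
            raise ValueError(f"unknown k_mode {params.k_mode!r}")
        cells.append(
            CellShapeParams(
                center=center,
                axes=(a, b),
                orientation=orientation,
                nucleus_scale=rng.uniform(*params.nucleus_scale_range),
                K_cyt=K_cyt,
                K_nuc=K_cyt * rng.uniform(*params.nucleus_K_factor_range),
                alpha_cyt=alpha_cyt,
                alpha_nuc=alpha_nuc,
                B=rng.uniform(*params.B_range),
                delta_rho=delta_rho,
                surface=surface,
            )
        )

    return phantom_from_cells(cells, grid, params.background)


def _trunc_normal(rng, mean, sd, bounds):
    while True:
        x = rng.normal(mean, sd)
        if bounds[0] < x < bounds[1]:
            return float(x)


# ---------------------------------------------------------------------------
# Expectation and Poisson rendering
# ---------------------------------------------------------------------------

class ExpectationEngine:
    """Caches per-alpha q-power maps so rendering a scan stays cheap."""

    def __init__(self, phantom: Phantom, geom: DetectorGeometry):
        self.phantom = phantom
        self.geom = geom
        qmap = build_qmap(geom)
        q = qmap.q.copy()
        positive = q[q > 0]
        if positive.size == 0:
            raise ValueError("q map has no positive values")
        # the q = 0 (beam center) pixel borrows the nearest positive q
        q[q == 0] = positive.min()
        self._q = q
        bg = phantom.background
        base = bg.K * q**bg.alpha + bg.B
        if bg.aniso > 0:
            base = base * (1.0 + bg.aniso * np.cos(2.0 * (qmap.azimuth - bg.aniso_angle)))
        self.background = base
        self._pow_cache: dict[float, np.ndarray] = {}

    def _qpow(self, alpha: float) -> np.ndarray:
        key = float(alpha)
        arr = self._pow_cache.get(key)
        if arr is None:
            arr = self._q**key
            self._pow_cache[key] = arr
        return arr

    def pattern(self, row: int, col: int) -> np.ndarray:
        """Expected counts per ms per pixel at one scan point."""
        K = self.phantom.K_map[row, col]
        out = self.background.copy()
        if K > 0:
            alpha = self.phantom.alpha_map[row, col]
            out += K * self._qpow(alpha) + self.phantom.B_map[row, col]
        return out


def expected_pattern(phantom: Phantom, point: tuple[int, int], geom: DetectorGeometry) -> np.ndarray:
    """Expected counts per ms for the scan point ``(row, col)``."""
    row, col = point
    if not (0 <= row < phantom.grid.n_rows and 0 <= col < phantom.grid.n_cols):
        raise IndexError(f"scan point {point} outside grid {phantom.grid.shape}")
    return ExpectationEngine(phantom, geom).pattern(row, col)


def simulate_scan(
    phantom: Phantom,
    geom: DetectorGeometry,
    exposure: float | None = None,
    flux_scale: float = 1.0,
    seed: int = 0,
    row_flux: np.ndarray | None = None,
):
    """Render the full scan as Poisson count frames.

    Parameters
    ----------
    exposure : ms per scan position; defaults to the phantom grid's exposure.
    flux_scale : global multiplier on the expectation.
    row_flux : optional per-scan-row multiplicative drift (models incoming
        beam intensity fluctuating in time along the slow axis).

    Returns
    -------
    PatternStack with uint32 counts; masked pixels carry the sentinel value.
    """
    from .reduce import PatternStack  # deferred: reduce owns the container

    exposure = phantom.grid.exposure if exposure is None else float(exposure)
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    if row_flux is not None:
        row_flux = np.asarray(row_flux, dtype=float)
        if row_flux.shape != (phantom.grid.n_rows,):
            raise ValueError("row_flux must have one entry per scan row")

    engine = ExpectationEngine(phantom, geom)
    rng = np.random.default_rng(seed)
    n_rows, n_cols = phantom.grid.shape
    det_shape = geom.shape
    counts = np.empty((n_rows, n_cols, *det_shape), dtype=np.uint32)
    mask = geom.mask
    for i in range(n_rows):
        scale = exposure * flux_scale * (row_flux[i] if row_flux is not None else 1.0)
        lam = np.stack([engine.pattern(i, j) for j in range(n_cols)]) * scale
        row_counts = rng.poisson(lam).astype(np.uint32)
        row_counts[:, mask] = MASKED_SENTINEL
        counts[i] = row_counts

    grid = replace(phantom.grid, exposure=exposure)
    return PatternStack(counts=counts, grid=grid, geom=geom, exposure=exposure)


# ---------------------------------------------------------------------------
# Analytic form factors (orientation-averaged, normalized to P(0) = 1)
# ---------------------------------------------------------------------------

def sphere_profile(q, R: float, polydispersity: float = 0.0) -> np.ndarray:
    """Sphere form factor, optionally smeared over a normal size distribution.

    P(q; R) = [3 (sin u - u cos u) / u^3]^2 with u = qR.  For
    ``polydispersity`` sigma_R/R > 0 the profile is averaged over
    N(R, (polydispersity*R)^2) by 61-point Gauss-Hermite quadrature,
    truncated to R > 0 (deterministic - no sampling noise).
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if polydispersity < 0:
        raise ValueError("polydispersity must be non-negative")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if polydispersity == 0:
        return _sphere_P(q * R)
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    radii = R + polydispersity * R * nodes
    keep = radii > 0
    radii, weights = radii[keep], weights[keep]
    weights = weights / weights.sum()
    out = np.zeros_like(q)
    for r_i, w_i in zip(radii, weights):
        out += w_i * _sphere_P(q * r_i)
    return out


def _sphere_P(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    out = np.ones_like(u)
    nz = u != 0
    un = u[nz]
    amp = 3.0 * (np.sin(un) - un * np.cos(un)) / un**3
    out[nz] = amp**2
    return out


def rod_profile(q, L: float) -> np.ndarray:
    """Infinitely-thin-rod form factor: P = 2 Si(x)/x - 4 sin^2(x/2)/x^2, x = qL."""
    if L <= 0:
        raise ValueError("L must be positive")
    x = np.atleast_1d(np.asarray(q, dtype=float)) * L
    out = np.ones_like(x)
    nz = x != 0
    xn = x[nz]
    si, _ = special.sici(xn)
    out[nz] = 2.0 * si / xn - 4.0 * np.sin(xn / 2.0) ** 2 / xn**2
    return out


def disc_profile(q, R: float) -> np.ndarray:
    """Infinitely-thin-disc form factor: P = (2/x^2)(1 - J1(2x)/x), x = qR."""
    if R <= 0:
        raise ValueError("R must be positive")
    x = np.atleast_1d(np.asarray(q, dtype=float)) * R
    out = np.ones_like(x)
    nz = x != 0
    xn = x[nz]
    out[nz] = (2.0 / xn**2) * (1.0 - special.j1(2.0 * xn) / xn)
    return out


def porod_prefactor(delta_rho: float, surface: float, coeff: float = 1.0) -> float:
    """Porod link K = c * delta_rho^2 * S (arbitrary units)."""
    if delta_rho <= 0 or surface <= 0:
        raise ValueError("delta_rho and surface must be positive")
    return coeff * delta_rho**2 * surface


# ---------------------------------------------------------------------------
# Reduced-scale defaults used across tests and examples
# ---------------------------------------------------------------------------

def default_geometry(
    det_shape: tuple[int, int] = (128, 128),
    distance: float = 0.15,
    energy: float = 13.0,
    pixel_size: float = 75e-6,
    beamstop_radius: float = 3.5,
) -> DetectorGeometry:
    """Centered-beam reduced-scale detector that still spans q up to ~3 nm^-1.

    The sample-detector distance is shortened (vs the 0.9 m of a full-size
    ~2070x2167 detector) so a small frame covers both the dark-field ROI
    (q <= 2.99 nm^-1) and the fit band [0.185, 1.723] nm^-1.  The mask is a
    circular beamstop of ``beamstop_radius`` pixels.
    """
    beam_center = (det_shape[0] / 2.0, det_shape[1] / 2.0)
    rr, cc = np.meshgrid(
        np.arange(det_shape[0]) + 0.5 - beam_center[0],
        np.arange(det_shape[1]) + 0.5 - beam_center[1],
        indexing="ij",
    )
    mask = np.hypot(rr, cc) <= beamstop_radius
    return DetectorGeometry(
        energy=energy,
        distance=distance,
        pixel_size=pixel_size,
        beam_center=beam_center,
        shape=det_shape,
        mask=mask,
    )


def default_phantom(seed: int = 0, n_cells: int = 20, grid: ScanGrid | None = None,
                    params: PhantomParams | None = None) -> Phantom:
    """The standard reduced-scale study phantom: 20 cells on a 120x120 grid."""
    if grid is None:
        grid = ScanGrid(n_rows=120, n_cols=120)
    return make_phantom(n_cells, grid, seed=seed, params=params)
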