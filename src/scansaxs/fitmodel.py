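"""Power-law modeling of radial profiles and radiation-dose estimation.

Background-corrected radial profiles are fitted by unweighted non-linear
least squares to

    I(q) = K * q**alpha + B

over a configurable q band ([0.185, 1.723] nm^-1 by default, i.e. real-space
features between 3.6 and 34.0 nm).  K is the power-law prefactor (the Porod
constant when alpha = -4), alpha encodes scatterer morphology (-1 rods,
-2 platelets, -4 sharp-interfaced 3D scatterers), and the additive constant
B absorbs small density fluctuations plus inelastic/incoherent scattering.

The absorbed dose for a raster scan is the Howells-type estimate

    D = (mu/rho) * Phi * E * T / (dy * dz)        [Gy]

with mu/rho the mass attenuation coefficient over mass density of an
"average protein" (H50 C30 N9 O10 S), Phi the photon flux, E the photon
energy, T the exposure per scan point and dy, dz the scan step sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .labels import RegionClass
from .reduce import RadialProfile, average_pattern, azimuthal_integrate

#: Default fit band (nm^-1): 3.6-34.0 nm in real space.
DEFAULT_FIT_QRANGE = (0.185, 1.723)

#: mu/rho for the "average protein" H50 C30 N9 O10 S at 13 keV, cm^2 g^-1.
MU_OVER_RHO_PROTEIN = 2.55

#: keV -> J.
KEV_TO_JOULE = 1.602176634e-16


@dataclass
class PowerLawFit:
    """Result of fitting I(q) = K q^alpha + B."""

    K: float
    alpha: float
    B: float
    covariance: np.ndarray          # over the free parameters, fit order
    q_range: tuple[float, float]
    converged: bool
    residual_norm: float
    n_bins: int
    b_fixed: bool = False

    @property
    def K_err(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def alpha_err(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    @property
    def B_err(self) -> float:
        if self.b_fixed:
            return 0.0
        return float(np.sqrt(self.covariance[2, 2]))


@dataclass(frozen=True)
class DoseParams:
    """Beam and scan parameters entering the dose estimate.

    Defaults are a 13.0 keV microfocus beam of 1.7e12 photons/s rastered in
    0.5 um steps; ``exposure`` is in seconds.
    """

    mu_over_rho: float = MU_OVER_RHO_PROTEIN   # cm^2 g^-1
    flux: float = 1.7e12                       # photons s^-1
    energy: float = 13.0                       # keV
    exposure: float = 1.34e-3                  # s
    step_y: float = 0.5e-6                     # m
    step_z: float = 0.5e-6                     # m

    def __post_init__(self):
        for name in ("mu_over_rho", "flux", "energy", "exposure", "step_y", "step_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


# ---------------------------------------------------------------------------
# Profile arithmetic
# ---------------------------------------------------------------------------

def normalize_exposure(profile: RadialProfile, exposure: float) -> RadialProfile:
    """Divide intensities by the exposure time (ms) -> counts/pixel/ms."""
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    return RadialProfile(
        q_centers=profile.q_centers.copy(),
        intensity=profile.intensity / exposure,
        n_pixels=profile.n_pixels.copy(),
    )


def subtract_background(signal: RadialProfile, background: RadialProfile) -> RadialProfile:
    """Bin-wise difference; invalid bins in either input stay invalid.

    Negative differences are retained — clamping would bias the additive
    constant of a subsequent fit.
    """
    if signal.q_centers.shape != background.q_centers.shape or not np.allclose(
        signal.q_centers, background.q_centers
    ):
        raise ValueError("signal and background must share the same q binning")
    both = signal.valid & background.valid
    diff = np.where(both, signal.intensity - background.intensity, np.nan)
    n_pix = np.where(both, signal.n_pixels, 0)
    return RadialProfile(
        q_centers=signal.q_centers.copy(), intensity=diff, n_pixels=n_pix
    )


def row_matched_background(stack, labels, cell_id: int, scan_point, n_bins: int = 300,
                           q_range=(0.0, 2.99)) -> RadialProfile:
    """Background profile from the cell's surroundings restricted to the
    scan row of ``scan_point``.

    Patterns on the same row are acquired close in time, so this matches
    the incoming-beam intensity of the pattern under analysis even when the
    flux drifts over the scan.
    """
    row, col = scan_point
    if labels.cell_id_map[row, col] != cell_id:
        raise ValueError(f"scan point {scan_point} does not belong to cell {cell_id}")
    rows, cols = labels.surroundings_indices(cell_id)
    if rows.size == 0:
        raise ValueError(f"cell {cell_id} has no surroundings assigned")
    in_row = rows == row
    if not in_row.any():
        raise ValueError(
            f"surroundings of cell {cell_id} do not intersect scan row {row}; "
            "fall back to the per-cell (whole-surroundings) background"
        )
    mean = average_pattern(stack, (rows[in_row], cols[in_row]))
    return azimuthal_integrate(mean, stack.geom, n_bins=n_bins, q_range=q_range)


# ---------------------------------------------------------------------------
# Power-law fitting
# ---------------------------------------------------------------------------

def fit_power_law(
    profile: RadialProfile,
    q_range: tuple[float, float] = DEFAULT_FIT_QRANGE,
    fix_b: float | None = None,
    alpha_bounds: tuple[float, float] = (-8.0, 0.0),
    min_bins: int = 8,
    sigma: np.ndarray | None = None,
) -> PowerLawFit:
    """Least-squares fit of K q^alpha + B over valid bins in ``q_range``.

    The default is unweighted minimization of the linear-intensity
    residuals.  ``sigma`` optionally supplies per-bin standard deviations
    (same length as the profile) for weighted (e.g. Poisson) fitting, in
    which case the parameter covariance follows the usual generalized
    least-squares form instead of assuming i.i.d. residuals.

    Initialization: B0 = min(I)/2 and a log-log linear regression of
    I - min(I) for (K0, alpha0).  ``fix_b`` pins the additive constant
    (e.g. to 0 for analytic form-factor profiles).  Non-convergence is
    reported through the ``converged`` flag, not an exception.
    """
    sel = profile.valid & (profile.q_centers >= q_range[0]) & (profile.q_centers <= q_range[1])
    q = profile.q_centers[sel]
    I = profile.intensity[sel]
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)[sel]
        if np.any(sigma <= 0):
            raise ValueError("sigma must be strictly positive on fitted bins")
    if q.size < min_bins:
        raise ValueError(
            f"only {q.size} valid bins in q_range {q_range}; need >= {min_bins}"
        )

    w = 1.0 / sigma if sigma is not None else np.ones_like(q)
    K0, alpha0 = _loglog_init(q, I, alpha_bounds)
    if fix_b is None:
        B0 = float(I.min()) * 0.5

        def resid(p):
            return w * (p[0] * q ** p[1] + p[2] - I)

        p0 = [K0, alpha0, B0]
        lower = [0.0, alpha_bounds[0], -np.inf]
        upper = [np.inf, alpha_bounds[1], np.inf]
    else:

        def resid(p):
            return w * (p[0] * q ** p[1] + fix_b - I)

        p0 = [K0, alpha0]
        lower = [0.0, alpha_bounds[0]]
        upper = [np.inf, alpha_bounds[1]]

    res = optimize.least_squares(resid, p0, bounds=(lower, upper), method="trf",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    n_free = len(p0)
    dof = max(q.size - n_free, 1)
    JTJ = res.jac.T @ res.jac
    try:
        if sigma is not None:
            cov = np.linalg.inv(JTJ)  # residuals already whitened by 1/sigma
        else:
            cov = np.linalg.inv(JTJ) * 2.0 * res.cost / dof
    except np.linalg.LinAlgError:
        cov = np.full((n_free, n_free), np.nan)
    if fix_b is None:
        K, alpha, B = res.x
    else:
        (K, alpha), B = res.x, fix_b
    return PowerLawFit(
        K=float(K), alpha=float(alpha), B=float(B),
        covariance=cov, q_range=tuple(q_range),
        converged=bool(res.success), residual_norm=float(np.sqrt(2.0 * res.cost)),
        n_bins=int(q.size), b_fixed=fix_b is not None,
    )


def _loglog_init(q, I, alpha_bounds):
    """Starting (K, alpha) from a log-log regression of I - min(I)."""
    shifted = I - I.min()
    pos = shifted > 0
    if pos.sum() >= 2:
        slope, intercept, *_ = stats.linregress(np.log(q[pos]), np.log(shifted[pos]))
        alpha0 = float(np.clip(slope, alpha_bounds[0] + 1e-6, alpha_bounds[1] - 1e-6))
        K0 = float(np.exp(intercept))
        if not np.isfinite(K0) or K0 <= 0:
            K0 = max(float(abs(I).max()), 1e-12)
    else:
        alpha0 = float(np.clip(-4.0, *alpha_bounds))
        K0 = max(float(abs(I).max()), 1e-12)
    return K0, alpha0


# ---------------------------------------------------------------------------
# Dose
# ---------------------------------------------------------------------------

def dose(params: DoseParams = DoseParams()) -> float:
    """Absorbed dose in Gy: D = (mu/rho) * Phi * E * T / (dy * dz).

    Unit handling: mu/rho in cm^2 g^-1 is converted to m^2 kg^-1 (x 0.1),
    E from keV to J; the result is J/kg = Gy.  Exactly linear in flux,
    energy and exposure, and inversely proportional to the step area.
    """
    mu_rho_si = params.mu_over_rho * 0.1           # cm^2/g -> m^2/kg
    energy_j = params.energy * KEV_TO_JOULE
    return mu_rho_si * params.flux * energy_j * params.exposure / (
        params.step_y * params.step_z
    )


# ---------------------------------------------------------------------------
# Region-averaged fitting helpers
# ---------------------------------------------------------------------------

def fit_region_profile(
    stack,
    indices,
    background_indices,
    n_bins: int = 300,
    integrate_qrange=(0.0, 2.99),
    fit_qrange=DEFAULT_FIT_QRANGE,
) -> tuple[PowerLawFit, RadialProfile]:
    """Average patterns over a region, integrate, exposure-normalize,
    subtract the equally processed background, and fit.

    Returns the fit together with the background-corrected profile.
    """
    sig = azimuthal_integrate(
        average_pattern(stack, indices), stack.geom, n_bins=n_bins, q_range=integrate_qrange
    )
    bg = azimuthal_integrate(
        average_pattern(stack, background_indices), stack.geom,
        n_bins=n_bins, q_range=integrate_qrange,
    )
    sig = normalize_exposure(sig, stack.exposure)
    bg = normalize_exposure(bg, stack.exposure)
    corrected = subtract_background(sig, bg)
    return fit_power_law(corrected, q_range=fit_qrange), corrected
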