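"""Detector and scan geometry.

Maps every detector pixel to the magnitude of the scattering vector

    q = (4 pi / lambda) * sin(theta),    theta = arctan(r / L) / 2,

with ``lambda`` the X-ray wavelength, ``r`` the in-plane radial distance of
the pixel center from the beam center and ``L`` the sample-detector
distance.  Real-space feature sizes follow from ``d = 2 pi / q``.

Conventions
-----------
* Detector pixel (0, 0) is the top-left corner; pixel centers sit at
  integer + 0.5 offsets.  The beam center is given in the same fractional
  pixel frame and may lie outside the frame.
* Azimuth is measured counter-clockwise from the detector +column axis
  (i.e. from +col toward -row when the image is displayed with row 0 on
  top), wrapped to [0, 2 pi).
* The detector is assumed flat and normal to the beam; no solid-angle or
  polarization correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: hc in keV * nm (CODATA).
HC_KEV_NM = 1.2398419


def wavelength_from_energy(energy_kev: float) -> float:
    """X-ray wavelength in nm for a photon energy in keV (lambda = hc/E)."""
    if not energy_kev > 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_NM / energy_kev


def d_spacing(q):
    """Real-space length d = 2 pi / q (nm for q in nm^-1). Involutive."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be strictly positive")
    out = 2.0 * np.pi / q
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ScanGrid:
    """Raster-scan layout: grid shape, step sizes (um) and exposure (ms)."""

    n_rows: int
    n_cols: int
    step_y: float = 0.5
    step_z: float = 0.5
    exposure: float = 1.34

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("scan grid dimensions must be positive")
        if self.step_y <= 0 or self.step_z <= 0 or self.exposure <= 0:
            raise ValueError("step sizes and exposure must be positive")

    @property
    def n_positions(self) -> int:
        """Total number of scan positions (= number of patterns)."""
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


@dataclass(frozen=True)
class DetectorGeometry:
    """Detector placement and masking.

    Parameters
    ----------
    energy : photon energy in keV.
    distance : sample-detector distance in m.
    pixel_size : square pixel edge in m.
    beam_center : (row, col) beam position in fractional pixels.
    shape : (det_rows, det_cols).
    mask : boolean array, True = pixel excluded; defaults to all-False.
    """

    energy: float
    distance: float
    pixel_size: float
    beam_center: tuple[float, float]
    shape: tuple[int, int]
    mask: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.energy <= 0 or self.distance <= 0 or self.pixel_size <= 0:
            raise ValueError("energy, distance and pixel_size must be positive")
        if len(self.shape) != 2 or min(self.shape) < 1:
            raise ValueError(f"invalid detector shape {self.shape}")
        mask = self.mask
        if mask is None:
            mask = np.zeros(self.shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != tuple(self.shape):
                raise ValueError(
                    f"mask shape {mask.shape} != detector shape {self.shape}"
                )
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(
            self, "beam_center", (float(self.beam_center[0]), float(self.beam_center[1]))
        )

    @property
    def wavelength(self) -> float:
        """Wavelength in nm."""
        return wavelength_from_energy(self.energy)


@dataclass(frozen=True)
class QMap:
    """Per-pixel scattering-vector magnitude (nm^-1) and azimuth (rad)."""

    q: np.ndarray
    azimuth: np.ndarray


def pixel_radii(geom: DetectorGeometry) -> np.ndarray:
    """Radial distance (m) of each pixel center from the beam center."""
    rows = np.arange(geom.shape[0]) + 0.5 - geom.beam_center[0]
    cols = np.arange(geom.shape[1]) + 0.5 - geom.beam_center[1]
    dr, dc = np.meshgrid(rows, cols, indexing="ij")
    return geom.pixel_size * np.hypot(dr, dc)


def build_qmap(geom: DetectorGeometry) -> QMap:
    """Per-pixel q (nm^-1, full trigonometric form) and azimuth map.

    The mask is intentionally ignored: the map is pure geometry, exclusion
    happens downstream.
    """
    rows = np.arange(geom.shape[0]) + 0.5 - geom.beam_center[0]
    cols = np.arange(geom.shape[1]) + 0.5 - geom.beam_center[1]
    dr, dc = np.meshgrid(rows, cols, indexing="ij")
    r = geom.pixel_size * np.hypot(dr, dc)
    theta = 0.5 * np.arctan2(r, geom.distance)
    q = (4.0 * np.pi / geom.wavelength) * np.sin(theta)
    azimuth = np.mod(np.arctan2(-dr, dc), 2.0 * np.pi)
    return QMap(q=q, azimuth=azimuth)


def radius_to_q(r, geom: DetectorGeometry):
    """q (nm^-1) at radial detector-plane distance r (m) from the beam center."""
    r = np.asarray(r, dtype=float)
    theta = 0.5 * np.arctan2(r, geom.distance)
    out = (4.0 * np.pi / geom.wavelength) * np.sin(theta)
    return float(out) if out.ndim == 0 else out


def q_to_radius(q, geom: DetectorGeometry):
    """Inverse of :func:`radius_to_q`: detector-plane radius (m) for a given q."""
    q = np.asarray(q, dtype=float)
    s = q * geom.wavelength / (4.0 * np.pi)
    if np.any(s < 0) or np.any(s >= 1):
        raise ValueError("q outside the range reachable by this geometry")
    out = geom.distance * np.tan(2.0 * np.arcsin(s))
    return float(out) if out.ndim == 0 else out
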