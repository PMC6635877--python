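"""Optical model and cell geometry for image simulation.

The imaging model is a 3D Gaussian approximation to the microscope point
spread function (PSF) applied to point-like emitters inside a rod-shaped
(spherocylindrical) cyanobacterial cell.  The cell body contributes a
diffuse fluorescence background from two compartments: an inner cytosol
and a surrounding thylakoid-membrane shell, whose chlorophyll emission
bleeds into the YFP detection channel at a configurable level.

Units: lengths at the camera are in nm, cell-scale lengths in µm,
photon fluxes in photons per frame, camera output in counts.
Image axes follow the numpy convention ``image[row, col]`` with physical
``x`` along columns (the cell long axis) and ``y`` along rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .errors import ConfigurationError

__all__ = ["OpticalModel", "CellGeometry", "OrganelleSpec", "pixel_grid"]


@dataclass(frozen=True)
class OpticalModel:
    """Camera and PSF parameters.

    Parameters
    ----------
    psf_sigma_lateral : float
        In-focus lateral Gaussian PSF sigma, nm.  The default of 160 nm
        (2 px at 80 nm/px) yields fitted focus widths of ~250 nm FWHM-scale
        for diffraction-limited organelles, matching measured focus widths.
    psf_sigma_axial : float
        Axial sigma of the 3D PSF, nm; controls defocus broadening.
    pixel_size : float
        Camera pixel size in sample space, nm/pixel (80 for the
        single-molecule EMCCD path, 41.5 for the confocal path).
    counts_per_photon : float
        Linear camera gain, counts per detected photon.
    baseline : float
        Camera offset added to every pixel, counts.
    exposure : float
        Exposure time per frame, ms (metadata; emission rates are
        specified per frame).
    read_noise_sd : float
        Optional additive Gaussian read noise, counts (default off).
    """

    psf_sigma_lateral: float = 160.0
    psf_sigma_axial: float = 400.0
    pixel_size: float = 80.0
    counts_per_photon: float = 1.0
    baseline: float = 100.0
    exposure: float = 5.0
    read_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("psf_sigma_lateral", "psf_sigma_axial", "pixel_size", "counts_per_photon"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.baseline < 0 or self.read_noise_sd < 0 or self.exposure <= 0:
            raise ConfigurationError("baseline/read_noise_sd must be >= 0 and exposure > 0")

    def sigma_lateral_um(self, z_um: float = 0.0) -> float:
        """Defocus-broadened lateral sigma (µm) for an emitter at axial offset z."""
        s0 = self.psf_sigma_lateral * 1e-3
        sz = self.psf_sigma_axial * 1e-3
        return s0 * float(np.sqrt(1.0 + (z_um / sz) ** 2))

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size * 1e-3


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylindrical cell: a cylinder of total length ``length`` capped by
    hemispheres of ``radius``, its long axis along x and centered at the origin.

    ``thylakoid_thickness`` is the depth of the membrane shell measured inward
    from the cell surface; the remainder is cytosol.  The two photon densities
    set the diffuse background each compartment emits into the imaged channel
    (photons/µm³/frame); for a YFP channel the thylakoid density represents
    chlorophyll bleed-through.
    """

    length: float = 3.0
    radius: float = 0.5
    thylakoid_thickness: float = 0.15
    thylakoid_photon_density: float = 0.0
    cytosol_photon_density: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length < 2 * self.radius:
            raise ConfigurationError("need length >= 2*radius > 0")
        if not 0 <= self.thylakoid_thickness <= self.radius:
            raise ConfigurationError("thylakoid_thickness must lie in [0, radius]")
        if self.thylakoid_photon_density < 0 or self.cytosol_photon_density < 0:
            raise ConfigurationError("photon densities must be >= 0")

    @property
    def half_axis(self) -> float:
        """Half-length of the cylindrical segment of the axis."""
        return self.length / 2.0 - self.radius

    def _axis_distance(self, x: np.ndarray, y: np.ndarray, z: np.ndarray | float = 0.0):
        cx = np.clip(x, -self.half_axis, self.half_axis)
        return np.sqrt((x - cx) ** 2 + np.asarray(y) ** 2 + np.asarray(z) ** 2), cx

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask for 3D points (…, 3) in µm lying inside the cell."""
        p = np.asarray(points, dtype=float)
        d, _ = self._axis_distance(p[..., 0], p[..., 1], p[..., 2])
        return d <= self.radius

    def column_depths(self, x: np.ndarray, y: np.ndarray):
        """z-extent (µm) of the cytosol and the thylakoid shell along the optical
        axis at in-plane position (x, y).  Returns (cytosol_depth, thylakoid_depth)."""
        d, _ = self._axis_distance(np.asarray(x, float), np.asarray(y, float), 0.0)
        r_in = self.radius - self.thylakoid_thickness
        full = 2.0 * np.sqrt(np.clip(self.radius**2 - d**2, 0.0, None))
        inner = 2.0 * np.sqrt(np.clip(r_in**2 - d**2, 0.0, None))
        return inner, full - inner

    def reflect(self, point: np.ndarray, max_bounce: int = 8) -> np.ndarray:
        """Specular reflection of a 3D point back inside the cell surface."""
        p = np.asarray(point, dtype=float).copy()
        for _ in range(max_bounce):
            d, cx = self._axis_distance(p[0], p[1], p[2])
            if d <= self.radius:
                return p
            foot = np.array([cx, 0.0, 0.0])
            u = (p - foot) / d
            p = foot + u * (2.0 * self.radius - d)
        # Pathologically long step: clamp just inside the surface.
        d, cx = self._axis_distance(p[0], p[1], p[2])
        foot = np.array([cx, 0.0, 0.0])
        return foot + (p - foot) / d * (self.radius * 0.999)

    def sample_interior(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Uniform 3D points inside the cell (rejection sampling)."""
        out = np.empty((n, 3))
        filled = 0
        while filled < n:
            m = 2 * (n - filled) + 8
            cand = rng.uniform(
                [-self.length / 2, -self.radius, -self.radius],
                [self.length / 2, self.radius, self.radius],
                size=(m, 3),
            )
            good = cand[self.contains(cand)]
            take = min(len(good), n - filled)
            out[filled : filled + take] = good[:take]
            filled += take
        return out


@dataclass(frozen=True)
class OrganelleSpec:
    """One organelle: position, size, labelling and kinetics.

    ``copy_number`` is the number of fluorescent protein copies attached to
    the organelle; each surviving fluorophore emits
    ``photons_per_fluorophore`` photons per frame until it bleaches
    (per-frame hazard ``bleach_rate``).  ``diffusion_coefficient`` (µm²/s)
    drives Brownian motion in the time-lapse simulator.
    """

    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    diameter: float = 200.0
    copy_number: int = 1
    photons_per_fluorophore: float = 200.0
    bleach_rate: float = 0.0
    diffusion_coefficient: float = 0.0
    render_as: str = "point"

    def __post_init__(self) -> None:
        if self.copy_number < 0 or self.diameter < 0:
            raise ConfigurationError("copy_number and diameter must be >= 0")
        if self.bleach_rate < 0 or self.diffusion_coefficient < 0:
            raise ConfigurationError("bleach_rate and diffusion_coefficient must be >= 0")
        if self.render_as not in ("point", "sphere"):
            raise ConfigurationError("render_as must be 'point' or 'sphere'")


def pixel_grid(shape: tuple[int, int], pixel_size_um: float):
    """Physical (x, y) centers (µm) of each pixel, origin at the image center.

    Returns 1D arrays ``x`` (per column) and ``y`` (per row).
    """
    nrows, ncols = shape
    x = (np.arange(ncols) - (ncols - 1) / 2.0) * pixel_size_um
    y = (np.arange(nrows) - (nrows - 1) / 2.0) * pixel_size_um
    return x, y


def gaussian_pixel_masses(
    shape: tuple[int, int],
    pixel_size_um: float,
    x0: float,
    y0: float,
    sigma_um: float,
) -> np.ndarray:
    """Fraction of a unit 2D Gaussian centered at (x0, y0) falling in each pixel.

    Uses the pixel-integrated (erf) form, exact for a Gaussian PSF.
    """
    x, y = pixel_grid(shape, pixel_size_um)
    h = pixel_size_um / 2.0
    fx = ndtr((x + h - x0) / sigma_um) - ndtr((x - h - x0) / sigma_um)
    fy = ndtr((y + h - y0) / sigma_um) - ndtr((y - h - y0) / sigma_um)
    return np.outer(fy, fx)
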