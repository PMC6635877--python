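"""Synthetic microscopy stacks with full ground truth.

Two acquisition modes are emulated:

* **photobleach stacks** — millisecond-exposure single-molecule acquisitions
  in which every fluorophore bleaches at an exponentially distributed time
  and organelles stay put;
* **time-lapse stacks** — slow confocal-style acquisitions (60 s default
  interval) in which organelles undergo Brownian motion inside the cell.

Both return an :class:`~organelle_stoich.io.ImageStack` plus a
:class:`GroundTruth` record of everything the analysis is later asked to
recover: per-frame centroids, per-frame surviving fluorophore counts, the
bleach time of every fluorophore and the seed used.

Pixel expectations follow the physical model

``E[counts] = baseline + gain * (focus photons * PSF mass in pixel
+ background density integrated over the pixel column)``

with Poisson noise applied on the photon scale and then scaled by the gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .io import ImageStack
from .optics import CellGeometry, OpticalModel, OrganelleSpec, gaussian_pixel_masses, pixel_grid

__all__ = [
    "GroundTruth",
    "default_shape",
    "render_frame",
    "simulate_photobleach_stack",
    "simulate_diffusion_stack",
    "simulate_bleach_traces",
]


@dataclass
class GroundTruth:
    """Everything the simulator knows that an analysis must recover.

    ``centroids`` has shape (n_frames, n_organelles, 3) in µm; ``surviving``
    has shape (n_frames, n_organelles); ``bleach_frames`` holds, per
    organelle, the first frame index at which each fluorophore no longer
    emits (``inf`` if it never bleaches).
    """

    centroids: np.ndarray
    surviving: np.ndarray
    bleach_frames: list[np.ndarray]
    seed: int | None
    true_diffusion: list[float] = field(default_factory=list)
    pixel_size: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "centroids_um": self.centroids.tolist(),
            "surviving": self.surviving.tolist(),
            "bleach_frames": [np.where(np.isfinite(b), b, -1).astype(int).tolist() for b in self.bleach_frames],
            "seed": self.seed,
            "true_diffusion_um2_s": self.true_diffusion,
            "pixel_size_nm": self.pixel_size,
        }

    def centroid_pixels(self, frame: int, shape: tuple[int, int]) -> np.ndarray:
        """Ground-truth (x, y) centroids in pixel coordinates for one frame."""
        px = self.pixel_size * 1e-3
        x, y = pixel_grid(shape, px)
        c = self.centroids[frame]
        col = c[:, 0] / px + (shape[1] - 1) / 2.0
        row = c[:, 1] / px + (shape[0] - 1) / 2.0
        return np.column_stack([col, row])


def default_shape(geometry: CellGeometry, optics: OpticalModel, margin_um: float = 0.8) -> tuple[int, int]:
    """Image size (rows, cols) covering the cell plus a margin on every side."""
    px = optics.pixel_size_um
    nrows = int(np.ceil((2 * geometry.radius + 2 * margin_um) / px))
    ncols = int(np.ceil((geometry.length + 2 * margin_um) / px))
    return nrows, ncols


def _effective_sigma(org: OrganelleSpec, optics: OpticalModel, z_um: float) -> float:
    sigma = optics.sigma_lateral_um(z_um)
    if org.render_as == "sphere":
        # Gaussian surrogate for a uniform solid sphere: per-axis variance r^2/5.
        r_um = org.diameter * 1e-3 / 2.0
        sigma = float(np.sqrt(sigma**2 + r_um**2 / 5.0))
    return sigma


def render_frame(
    geometry: CellGeometry,
    organelles: list[OrganelleSpec],
    optics: OpticalModel,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] | None = None,
    surviving: np.ndarray | None = None,
    positions: np.ndarray | None = None,
    noise: bool = True,
) -> np.ndarray:
    """Render one camera frame (float counts).

    ``surviving`` overrides each organelle's emitting fluorophore count
    (defaults to ``copy_number``); ``positions`` overrides organelle 3D
    positions (µm).  With ``noise=False`` the expectation image is returned.
    """
    if shape is None:
        shape = default_shape(geometry, optics)
    px = optics.pixel_size_um
    if surviving is None:
        surviving = np.array([o.copy_number for o in organelles], dtype=float)
    if positions is None:
        positions = np.array([o.position for o in organelles], dtype=float).reshape(-1, 3)
    surviving = np.asarray(surviving, dtype=float)
    if np.any(surviving > np.array([o.copy_number for o in organelles])):
        raise ConfigurationError("surviving fluorophore counts cannot exceed copy_number")

    photons = np.zeros(shape, dtype=float)
    for org, n_surv, pos in zip(organelles, surviving, positions):
        if n_surv <= 0 or org.photons_per_fluorophore <= 0:
            continue
        sigma = _effective_sigma(org, optics, pos[2])
        photons += (
            n_surv
            * org.photons_per_fluorophore
            * gaussian_pixel_masses(shape, px, pos[0], pos[1], sigma)
        )

    if geometry.cytosol_photon_density > 0 or geometry.thylakoid_photon_density > 0:
        x, y = pixel_grid(shape, px)
        xx, yy = np.meshgrid(x, y)
        cyt, thy = geometry.column_depths(xx, yy)
        photons += (
            geometry.cytosol_photon_density * cyt + geometry.thylakoid_photon_density * thy
        ) * px**2

    if noise:
        if rng is None:
            rng = np.random.default_rng()
        photons = rng.poisson(photons).astype(float)
    counts = optics.baseline + optics.counts_per_photon * photons
    if noise and optics.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, optics.read_noise_sd, size=shape)
    return counts


def _sample_bleach_frames(
    organelles: list[OrganelleSpec], rng: np.random.Generator
) -> list[np.ndarray]:
    """Frame index at which each fluorophore stops emitting.

    Per-frame bleaching hazard ``1 - exp(-rate)`` (geometric approximation of
    the exponential law on whole frames); a fluorophore with bleach frame b
    emits during frames 0..b-1.  Rate 0 means the fluorophore never bleaches.
    """
    out = []
    for org in organelles:
        if org.bleach_rate <= 0:
            out.append(np.full(org.copy_number, np.inf))
        else:
            p = 1.0 - np.exp(-org.bleach_rate)
            out.append(rng.geometric(p, size=org.copy_number).astype(float))
    return out


def _surviving_counts(bleach_frames: list[np.ndarray], n_frames: int) -> np.ndarray:
    surv = np.empty((n_frames, len(bleach_frames)))
    t = np.arange(n_frames)[:, None]
    for j, b in enumerate(bleach_frames):
        surv[:, j] = (b[None, :] > t).sum(axis=1)
    return surv


def simulate_photobleach_stack(
    geometry: CellGeometry,
    organelles: list[OrganelleSpec],
    optics: OpticalModel,
    n_frames: int,
    rng_seed: int | None = None,
    shape: tuple[int, int] | None = None,
    noise: bool = True,
) -> tuple[ImageStack, GroundTruth]:
    """Static organelles, exponential per-fluorophore bleaching."""
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if shape is None:
        shape = default_shape(geometry, optics)
    bleach = _sample_bleach_frames(organelles, rng)
    surv = _surviving_counts(bleach, n_frames)
    positions = np.array([o.position for o in organelles], dtype=float).reshape(-1, 3)
    centroids = np.broadcast_to(positions, (n_frames, len(organelles), 3)).copy()
    frames = np.empty((n_frames, *shape))
    for t in range(n_frames):
        frames[t] = render_frame(
            geometry, organelles, optics, rng=rng, shape=shape, surviving=surv[t], noise=noise
        )
    stack = ImageStack(
        frames, pixel_size=optics.pixel_size, exposure=optics.exposure, channel="yfp",
        metadata={"mode": "photobleach"},
    )
    gt = GroundTruth(centroids, surv, bleach, rng_seed, pixel_size=optics.pixel_size)
    return stack, gt


def simulate_diffusion_stack(
    geometry: CellGeometry,
    organelles: list[OrganelleSpec],
    optics: OpticalModel,
    n_frames: int,
    frame_interval: float,
    rng_seed: int | None = None,
    shape: tuple[int, int] | None = None,
    noise: bool = True,
    bounded: bool = True,
) -> tuple[ImageStack, GroundTruth]:
    """Brownian organelles in the cell, slow time-lapse acquisition.

    Per-frame displacements per axis are Gaussian with variance
    ``2 * D * frame_interval``; positions are specularly reflected at the
    spherocylinder surface (``bounded=False`` disables reflection, for
    moment checks against free diffusion).
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    if frame_interval <= 0:
        raise ConfigurationError("frame_interval must be > 0")
    rng = np.random.default_rng(rng_seed)
    if shape is None:
        shape = default_shape(geometry, optics)
    positions = np.array([o.position for o in organelles], dtype=float).reshape(-1, 3)
    if bounded and not np.all(geometry.contains(positions)):
        raise ConfigurationError("organelle initial position outside cell")

    bleach = _sample_bleach_frames(organelles, rng)
    surv = _surviving_counts(bleach, n_frames)
    centroids = np.empty((n_frames, len(organelles), 3))
    frames = np.empty((n_frames, *shape))
    pos = positions.copy()
    for t in range(n_frames):
        centroids[t] = pos
        frames[t] = render_frame(
            geometry, organelles, optics, rng=rng, shape=shape,
            surviving=surv[t], positions=pos, noise=noise,
        )
        for j, org in enumerate(organelles):
            step_sd = np.sqrt(2.0 * org.diffusion_coefficient * frame_interval)
            nxt = pos[j] + rng.normal(0.0, step_sd, size=3)
            pos[j] = geometry.reflect(nxt) if bounded else nxt
    stack = ImageStack(
        frames, pixel_size=optics.pixel_size, frame_interval=frame_interval,
        exposure=optics.exposure, channel="yfp", metadata={"mode": "timelapse"},
    )
    gt = GroundTruth(
        centroids, surv, bleach, rng_seed,
        true_diffusion=[o.diffusion_coefficient for o in organelles],
        pixel_size=optics.pixel_size,
    )
    return stack, gt


def simulate_bleach_traces(
    copy_numbers,
    counts_per_fluorophore: float,
    bleach_rate: float,
    n_frames: int,
    background_noise_sd: float = 0.0,
    rng_seed: int | None = None,
    shot_noise: bool = True,
):
    """Background-corrected intensity traces without image rendering.

    A fast counterpart of :func:`simulate_photobleach_stack` for
    population-scale studies: each organelle's trace is
    ``gain-scaled Poisson(surviving * photons) + N(0, background_noise_sd)``
    expressed directly in counts (``counts_per_fluorophore`` already folds in
    camera gain).  Returns ``(traces, surviving, bleach_frames)`` with
    ``traces`` of shape (n_organelles, n_frames).
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    rng = np.random.default_rng(rng_seed)
    copy_numbers = np.atleast_1d(np.asarray(copy_numbers, dtype=int))
    organelles = [
        OrganelleSpec(copy_number=int(n), photons_per_fluorophore=counts_per_fluorophore,
                      bleach_rate=bleach_rate)
        for n in copy_numbers
    ]
    bleach = _sample_bleach_frames(organelles, rng)
    surv = _surviving_counts(bleach, n_frames).T  # (n_org, n_frames)
    mean_counts = surv * counts_per_fluorophore
    if shot_noise:
        # Shot noise on the photon scale; counts_per_fluorophore is used as
        # the photon scale directly (gain folded in).
        traces = rng.poisson(mean_counts).astype(float)
    else:
        traces = mean_counts.astype(float)
    if background_noise_sd > 0:
        traces = traces + rng.normal(0.0, background_noise_sd, size=traces.shape)
    return traces, surv, bleach
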