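"""Focus detection, sub-pixel localization, photometry and tracking.

The measurement chain mirrors single-molecule narrow-field ("Slimfield")
analysis practice:

1. candidate spots from a morphological top-hat transform plus thresholding;
2. sub-pixel centroids by iterative Gaussian masking;
3. intensity as the background-corrected sum inside a circular ROI of
   5 px radius, background statistics from the surrounding 17 × 17 px window;
4. acceptance gate on signal-to-noise ratio (inner mean / outer sd) > 0.4;
5. greedy nearest-neighbor frame-to-frame linking, with optional
   "overtracking" — continuing photometry at the last known position after
   the focus has bleached below detection, to sample single-fluorophore and
   background intensity levels.

Coordinates are 0-based pixel indices; sub-pixel positions ``(x, y)`` =
(column, row) with the origin at the center of pixel (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max
from skimage.morphology import disk, white_tophat

from .errors import ConvergenceError, ParameterError

__all__ = [
    "FocusMeasurement",
    "TrackedFocus",
    "find_candidates",
    "iterative_gaussian_mask",
    "measure_intensity",
    "accept_focus",
    "link_foci",
    "overtrack",
    "analyze_stack",
]

ROI_RADIUS = 5.0          # px, inner circular photometry region
BG_HALFWIDTH = 8          # px, half-width of the 17 x 17 background window
SNR_THRESHOLD = 0.4


@dataclass
class FocusMeasurement:
    """One focus in one frame: centroid, photometry and quality flags."""

    frame: int
    x: float
    y: float
    summed_intensity: float
    bg_mean: float
    bg_sd: float
    snr: float
    n_inner: int = 0
    flags: tuple[str, ...] = ()

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class TrackedFocus:
    """A focus linked through time, plus overtracked tail measurements."""

    track_id: int
    measurements: list[FocusMeasurement] = field(default_factory=list)
    overtracked_tail: list[FocusMeasurement] = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([m.frame for m in self.measurements])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([m.summed_intensity for m in self.measurements])

    @property
    def tail_intensities(self) -> np.ndarray:
        return np.array([m.summed_intensity for m in self.overtracked_tail])

    @property
    def positions(self) -> np.ndarray:
        return np.array([[m.x, m.y] for m in self.measurements])

    @property
    def last_position(self) -> tuple[float, float]:
        return self.measurements[-1].position

    def __len__(self) -> int:
        return len(self.measurements)


def find_candidates(
    image: np.ndarray,
    tophat_radius: int = 4,
    threshold: float | None = None,
    threshold_sigma: float = 5.0,
    min_separation: int = 3,
    smooth_sigma: float = 1.0,
) -> list[tuple[int, int]]:
    """Pixel-level candidate focus positions ``(x, y)``.

    The image is lightly smoothed (suppressing single-pixel shot noise), a
    white top-hat transform (disk footprint) removes the smooth cell
    background, and candidates are local maxima of the transform exceeding
    ``threshold`` (default: robust ``median + threshold_sigma * 1.4826*MAD``),
    separated by at least ``min_separation`` pixels.  A featureless image
    yields an empty list, not an error.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or not np.all(np.isfinite(image)):
        raise ParameterError("image must be a finite 2D array")
    if image.size == 0 or image.max() == image.min():
        return []
    if smooth_sigma > 0:
        image = gaussian_filter(image, smooth_sigma)
    th = white_tophat(image, footprint=disk(tophat_radius))
    if threshold is None:
        med = np.median(th)
        mad = np.median(np.abs(th - med))
        threshold = med + threshold_sigma * 1.4826 * max(mad, 1e-12)
    peaks = peak_local_max(th, min_distance=min_separation, threshold_abs=threshold)
    return [(int(c), int(r)) for r, c in peaks]


def iterative_gaussian_mask(
    image: np.ndarray,
    initial_position: tuple[float, float],
    mask_sigma: float = 2.0,
    tol: float = 1e-3,
    max_iter: int = 100,
    window_halfwidth: int = BG_HALFWIDTH,
) -> tuple[float, float]:
    """Sub-pixel centroid by iterative Gaussian masking.

    The centroid of ``(image - local background) x Gaussian mask`` is
    recomputed with the mask recentered on the previous estimate until the
    displacement falls below ``tol`` (px).  Raises
    :class:`~organelle_stoich.errors.ConvergenceError` when the iteration
    does not settle within ``max_iter`` or the masked mass vanishes.
    """
    image = np.asarray(image, dtype=float)
    if mask_sigma <= 0:
        raise ParameterError("mask_sigma must be > 0")
    x, y = float(initial_position[0]), float(initial_position[1])
    nrows, ncols = image.shape
    if not (0 <= x < ncols and 0 <= y < nrows):
        raise ParameterError("initial position outside image")

    for _ in range(max_iter):
        c0 = int(round(x))
        r0 = int(round(y))
        c_lo, c_hi = max(0, c0 - window_halfwidth), min(ncols, c0 + window_halfwidth + 1)
        r_lo, r_hi = max(0, r0 - window_halfwidth), min(nrows, r0 + window_halfwidth + 1)
        win = image[r_lo:r_hi, c_lo:c_hi]
        cols = np.arange(c_lo, c_hi)
        rows = np.arange(r_lo, r_hi)
        # Local background subtraction so diffuse signal does not drag the centroid.
        signal = win - np.median(win)
        mask = np.exp(
            -((cols[None, :] - x) ** 2 + (rows[:, None] - y) ** 2) / (2.0 * mask_sigma**2)
        )
        w = np.clip(signal, 0.0, None) * mask
        total = w.sum()
        if total <= 0:
            raise ConvergenceError("Gaussian-masked mass vanished; no focus at this position")
        x_new = float((w * cols[None, :]).sum() / total)
        y_new = float((w * rows[:, None]).sum() / total)
        shift = np.hypot(x_new - x, y_new - y)
        x, y = x_new, y_new
        if shift < tol:
            return x, y
    raise ConvergenceError(f"iterative Gaussian masking did not converge in {max_iter} iterations")


def _roi_masks(shape, centroid, roi_radius, bg_halfwidth):
    """Inner-disk and background masks of the (2h+1)^2 window, plus window slices.

    Returns None when the window does not fit in the image (edge policy).
    """
    nrows, ncols = shape
    c0 = int(round(centroid[0]))
    r0 = int(round(centroid[1]))
    r_lo, r_hi = r0 - bg_halfwidth, r0 + bg_halfwidth + 1
    c_lo, c_hi = c0 - bg_halfwidth, c0 + bg_halfwidth + 1
    truncated = r_lo < 0 or c_lo < 0 or r_hi > nrows or c_hi > ncols
    r_lo, c_lo = max(0, r_lo), max(0, c_lo)
    r_hi, c_hi = min(nrows, r_hi), min(ncols, c_hi)
    rows = np.arange(r_lo, r_hi)
    cols = np.arange(c_lo, c_hi)
    dist2 = (cols[None, :] - centroid[0]) ** 2 + (rows[:, None] - centroid[1]) ** 2
    inner = dist2 <= roi_radius**2   # pixel-center-in-circle membership
    return (slice(r_lo, r_hi), slice(c_lo, c_hi)), inner, truncated


def measure_intensity(
    image: np.ndarray,
    centroid: tuple[float, float],
    frame: int = 0,
    roi_radius: float = ROI_RADIUS,
    bg_halfwidth: int = BG_HALFWIDTH,
) -> FocusMeasurement:
    """Background-corrected ROI photometry at a (sub-pixel) centroid.

    ``summed_intensity = sum(inner disk) - n_inner * bg_mean`` with the
    background mean/sd computed over the surrounding window excluding the
    inner disk.  SNR is the background-corrected mean inner intensity divided
    by the background sd (+inf when the background sd is zero and the inner
    mean positive).  A window extending past the image edge flags the
    measurement ``edge-truncated``.
    """
    image = np.asarray(image, dtype=float)
    window, inner, truncated = _roi_masks(image.shape, centroid, roi_radius, bg_halfwidth)
    win = image[window]
    inner_vals = win[inner]
    bg_vals = win[~inner]
    flags: tuple[str, ...] = ("edge-truncated",) if truncated else ()
    if bg_vals.size == 0:
        bg_mean, bg_sd = 0.0, 0.0
        flags = flags + ("no-background",)
    else:
        bg_mean = float(bg_vals.mean())
        bg_sd = float(bg_vals.std(ddof=1)) if bg_vals.size > 1 else 0.0
    n_inner = int(inner_vals.size)
    summed = float(inner_vals.sum() - n_inner * bg_mean)
    inner_mean = summed / n_inner if n_inner else 0.0
    if bg_sd > 0:
        snr = inner_mean / bg_sd
    else:
        snr = float("inf") if inner_mean > 0 else 0.0
    return FocusMeasurement(
        frame=frame, x=float(centroid[0]), y=float(centroid[1]),
        summed_intensity=summed, bg_mean=bg_mean, bg_sd=bg_sd, snr=snr,
        n_inner=n_inner, flags=flags,
    )


def accept_focus(measurement: FocusMeasurement, snr_threshold: float = SNR_THRESHOLD) -> bool:
    """Gate on signal-to-noise ratio: accepted iff snr is strictly above threshold."""
    if snr_threshold <= 0:
        raise ParameterError("snr_threshold must be > 0")
    return measurement.snr > snr_threshold


def link_foci(
    measurements: list[FocusMeasurement],
    max_displacement: float,
    max_gap: int = 0,
) -> list[TrackedFocus]:
    """Greedy nearest-neighbor linking of per-frame measurements into tracks.

    Frame pairs are processed in order; candidate links are taken in order of
    increasing distance (ties broken by lowest track id), each focus and each
    track used at most once per frame, links beyond ``max_displacement``
    forbidden.  Tracks missing more than ``max_gap`` consecutive frames are
    closed and unmatched measurements seed new tracks.
    """
    by_frame: dict[int, list[FocusMeasurement]] = {}
    for m in measurements:
        by_frame.setdefault(m.frame, []).append(m)

    tracks: list[TrackedFocus] = []
    active: list[TrackedFocus] = []
    for frame in sorted(by_frame):
        dets = by_frame[frame]
        active = [t for t in active if frame - t.measurements[-1].frame <= max_gap + 1]
        pairs = []
        for t in active:
            tx, ty = t.last_position
            for j, d in enumerate(dets):
                dist = np.hypot(d.x - tx, d.y - ty)
                if dist <= max_displacement:
                    pairs.append((dist, t.track_id, t, j))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, tid, t, j in sorted(pairs, key=lambda p: (p[0], p[1], p[3])):
            if tid in used_tracks or j in used_dets:
                continue
            t.measurements.append(dets[j])
            used_tracks.add(tid)
            used_dets.add(j)
        for j, d in enumerate(dets):
            if j not in used_dets:
                t = TrackedFocus(track_id=len(tracks), measurements=[d])
                tracks.append(t)
                active.append(t)
    return tracks


def overtrack(
    stack_frames: np.ndarray,
    tracks: list[TrackedFocus],
    n_tail: int,
    roi_radius: float = ROI_RADIUS,
    bg_halfwidth: int = BG_HALFWIDTH,
) -> list[TrackedFocus]:
    """Append up to ``n_tail`` photometry measurements at each track's last
    position after the track ends ("overtracked" foci), in place."""
    n_frames = stack_frames.shape[0]
    for t in tracks:
        last = t.measurements[-1]
        for f in range(last.frame + 1, min(last.frame + 1 + n_tail, n_frames)):
            m = measure_intensity(
                stack_frames[f], last.position, frame=f,
                roi_radius=roi_radius, bg_halfwidth=bg_halfwidth,
            )
            t.overtracked_tail.append(m)
    return tracks


def analyze_stack(
    frames: np.ndarray,
    snr_threshold: float = SNR_THRESHOLD,
    max_displacement: float = 3.0,
    max_gap: int = 0,
    n_tail: int = 0,
    mask_sigma: float = 2.0,
    detection_kwargs: dict | None = None,
    exclude_edge: bool = True,
    merge_radius: float = 3.0,
) -> list[TrackedFocus]:
    """Full per-frame detection → localization → photometry → linking chain.

    Candidates that converge onto the same focus after sub-pixel
    localization are merged (within ``merge_radius`` px, first kept: the
    candidate list is ordered brightest-first).  Edge-truncated measurements
    are excluded from tracks when ``exclude_edge`` is set (they cannot
    support quantitative photometry).
    """
    detection_kwargs = detection_kwargs or {}
    accepted: list[FocusMeasurement] = []
    for f, image in enumerate(frames):
        localized: list[FocusMeasurement] = []
        for cand in find_candidates(image, **detection_kwargs):
            try:
                pos = iterative_gaussian_mask(image, cand, mask_sigma=mask_sigma)
            except ConvergenceError:
                continue
            if localized and min(
                np.hypot(m.x - pos[0], m.y - pos[1]) for m in localized
            ) <= merge_radius:
                continue
            m = measure_intensity(image, pos, frame=f)
            if exclude_edge and "edge-truncated" in m.flags:
                continue
            if accept_focus(m, snr_threshold):
                localized.append(m)
        accepted.extend(localized)
    tracks = link_foci(accepted, max_displacement=max_displacement, max_gap=max_gap)
    if n_tail > 0:
        overtrack(frames, tracks, n_tail)
    return tracks
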