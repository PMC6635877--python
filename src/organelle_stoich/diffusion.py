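"""Organelle mobility from time-lapse stacks: drift registration, tracking,
time-averaged mean squared displacement (MSD), apparent diffusion
coefficients and anomalous exponents.

The apparent diffusion coefficient is slope/4 of an ordinary least squares
fit (with free intercept, absorbing the localization-noise offset) to the
first six points of the 2D time-averaged MSD versus lag time; the anomalous
exponent α is the log-log slope of MSD versus lag over the full usable
range (α ≈ 1 Brownian, α < 1 subdiffusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .detection import analyze_stack
from .errors import EstimationError, ParameterError

__all__ = [
    "TimeLapseTrack",
    "MSDProfile",
    "register_drift",
    "msd",
    "fit_apparent_D",
    "anomalous_exponent",
    "tracks_from_stack",
]


@dataclass
class TimeLapseTrack:
    """Positions (µm) of one organelle at strictly increasing, evenly
    spaced frame times (s)."""

    times: np.ndarray
    positions: np.ndarray  # (n, 2) in µm
    track_id: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ParameterError("times must be strictly increasing with a constant interval")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class MSDProfile:
    tau: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    apparent_D: float | None = None
    intercept: float | None = None
    alpha: float | None = None
    flags: tuple[str, ...] = ()


def register_drift(
    stack_frames: np.ndarray,
    upsample: int = 20,
    focus_clip_percentile: float = 80.0,
):
    """Translation registration of every frame against the first.

    Shifts are estimated by cross-correlation at 1/``upsample`` px precision
    and applied to the original frames by linear interpolation.  Bright
    (moving) foci are suppressed before correlation by clipping each frame at
    ``focus_clip_percentile`` of its intensities, so the stationary cell body
    — not the diffusing organelles — anchors the registration.  Featureless
    frames get a zero shift with a warning flag.  Returns (registered stack,
    shifts (row, col) per frame, flags).
    """
    frames = np.asarray(stack_frames, dtype=float)
    if frames.shape[0] < 2:
        raise ParameterError("need >= 2 frames to register")
    ref = frames[0]
    ref_clip = np.minimum(ref, np.percentile(ref, focus_clip_percentile))
    out = frames.copy()
    shifts = np.zeros((frames.shape[0], 2))
    flags = []
    for t in range(1, frames.shape[0]):
        if frames[t].std() == 0 or ref.std() == 0:
            flags.append(f"frame-{t}-featureless")
            continue
        mov_clip = np.minimum(frames[t], np.percentile(frames[t], focus_clip_percentile))
        shift, _, _ = phase_cross_correlation(
            ref_clip, mov_clip, upsample_factor=upsample, normalization=None
        )
        shifts[t] = shift
        out[t] = ndimage.shift(frames[t], shift, order=1, mode="nearest")
    return out, shifts, tuple(flags)


def msd(track: TimeLapseTrack, max_lag_fraction: float = 0.5) -> MSDProfile:
    """Time-averaged MSD over all start frames, for lags up to half the track.

    ``MSD(k Δt) = mean_i |r_{i+k} - r_i|²`` — the standard single-track
    estimator, which is symmetric under time reversal.
    """
    n = len(track)
    if n < 8:
        raise EstimationError(f"track of length {n} too short for MSD (need >= 8)")
    dt = track.times[1] - track.times[0]
    max_lag = max(int(n * max_lag_fraction), 1)
    taus = np.arange(1, max_lag + 1) * dt
    msds = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=int)
    r = track.positions
    for k in range(1, max_lag + 1):
        d = r[k:] - r[:-k]
        msds[k - 1] = float((d**2).sum(axis=1).mean())
        n_pairs[k - 1] = len(d)
    return MSDProfile(tau=taus, msd=msds, n_pairs=n_pairs)


def fit_apparent_D(profile: MSDProfile, n_points: int = 6) -> float:
    """Apparent diffusion coefficient from the first ``n_points`` MSD lags.

    OLS of MSD on τ with a free intercept; D = slope / 4 (2D convention).
    A negative fitted slope reports D = 0 with a flag.
    """
    if profile.tau.size < n_points:
        raise EstimationError(f"profile has {profile.tau.size} lags; need >= {n_points}")
    t = profile.tau[:n_points]
    m = profile.msd[:n_points]
    slope, intercept = np.polyfit(t, m, 1)
    if slope < 0:
        profile.flags = profile.flags + ("negative-slope",)
        slope = 0.0
    profile.apparent_D = float(slope / 4.0)
    profile.intercept = float(intercept)
    return profile.apparent_D


def anomalous_exponent(profile: MSDProfile, min_lags: int = 10) -> float:
    """Power-law exponent α of MSD ∝ τ^α over all positive-MSD lags."""
    good = profile.msd > 0
    if good.sum() < min_lags:
        raise EstimationError(f"need >= {min_lags} positive MSD lags, got {int(good.sum())}")
    alpha, _ = np.polyfit(np.log(profile.tau[good]), np.log(profile.msd[good]), 1)
    profile.alpha = float(alpha)
    return profile.alpha


def tracks_from_stack(
    stack_frames: np.ndarray,
    pixel_size_um: float,
    frame_interval: float,
    expected_D: float = 1.3e-5,
    min_length: int = 12,
    snr_threshold: float = 0.4,
    detection_kwargs: dict | None = None,
) -> list[TimeLapseTrack]:
    """Detect and link foci in a time-lapse stack, returning physical tracks.

    The linking search radius follows the expected Brownian step,
    ``sqrt(4 D Δt)`` converted to pixels, plus a 3 px guard band.
    """
    max_disp = np.sqrt(4.0 * expected_D * frame_interval) / pixel_size_um + 3.0
    tracks = analyze_stack(
        stack_frames, snr_threshold=snr_threshold, max_displacement=max_disp,
        detection_kwargs=detection_kwargs,
    )
    out = []
    for t in tracks:
        if len(t) < min_length:
            continue
        frames = t.frames
        # require a contiguous run for a well-defined constant interval
        if np.any(np.diff(frames) != 1):
            runs = np.split(np.arange(len(frames)), np.nonzero(np.diff(frames) != 1)[0] + 1)
            longest = max(runs, key=len)
            if len(longest) < min_length:
                continue
            sel = longest
        else:
            sel = np.arange(len(frames))
        pos = t.positions[sel] * pixel_size_um
        out.append(
            TimeLapseTrack(
                times=frames[sel] * frame_interval, positions=pos, track_id=t.track_id
            )
        )
    return out
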