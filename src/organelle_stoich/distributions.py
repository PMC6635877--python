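"""Population-level statistics of per-organelle copy numbers.

Covers the summary statistics used throughout single-organelle
quantification: kernel-density peak ± half width at half maximum (HWHM),
subtraction of an autofluorescence (chlorophyll) background distribution,
triple-Gaussian population decomposition, a nearest-neighbor model for
random overlap of diffraction-limited foci, conversion of subunit copies to
functional oligomeric units, calibration of confocal intensities to
absolute copies, Mann-Whitney condition comparison, and randomized-grouping
sampling errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit
from scipy.ndimage import label as ndi_label
from shapely.geometry import LineString, Point
from skimage.morphology import h_maxima, local_maxima

from .errors import EstimationError, ParameterError
from .optics import CellGeometry

__all__ = [
    "CopyNumberDistribution",
    "MixtureFit",
    "OverlapModel",
    "CalibrationFactor",
    "ConditionComparison",
    "kde_estimate",
    "subtract_background_distribution",
    "functional_units",
    "proportion_percent",
    "fit_triple_gaussian",
    "overlap_fraction",
    "confocal_foci_intensities",
    "cytosolic_background_correct",
    "calibrate",
    "compare_conditions",
    "grouped_sampling_error",
    "significance_stars",
]


# --------------------------------------------------------------------------
# Kernel density estimation, peak ± HWHM
# --------------------------------------------------------------------------

@dataclass
class CopyNumberDistribution:
    """Per-organelle copy estimates with their kernel-density summary."""

    values: np.ndarray
    kernel_width: float
    grid: np.ndarray
    density: np.ndarray
    peak: float
    hwhm: float
    n: int
    corrected: bool = False

    def local_maxima(self, min_height_fraction: float = 0.05) -> np.ndarray:
        """Grid positions of local density maxima above a height fraction of the mode."""
        d = self.density
        m = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])
        idx = np.nonzero(m)[0] + 1
        idx = idx[d[idx] > min_height_fraction * d.max()]
        return self.grid[idx]


def silverman_bandwidth(values: np.ndarray) -> float:
    """Rule-of-thumb Gaussian-kernel bandwidth (the "standard kernel width")."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = 0.9 * spread * values.size ** (-0.2)
    return max(bw, 1e-3 * (abs(float(np.mean(values))) + 1.0))


def _density_on_grid(values: np.ndarray, grid: np.ndarray, w: float) -> np.ndarray:
    dens = np.zeros(grid.size)
    for chunk in np.array_split(values, max(1, values.size // 2000)):
        dens += np.exp(-0.5 * ((grid[:, None] - chunk[None, :]) / w) ** 2).sum(axis=1)
    return dens / (values.size * w * np.sqrt(2 * np.pi))


def _peak_hwhm(grid: np.ndarray, density: np.ndarray) -> tuple[float, float]:
    """Mode and HWHM from a density curve; half-max crossings are linearly
    interpolated and the two half-widths averaged (one-sided if truncated)."""
    i = int(np.argmax(density))
    peak = float(grid[i])
    half = density[i] / 2.0

    def crossing(idx_range, direction):
        prev = i
        for j in idx_range:
            if density[j] <= half:
                # linear interpolation between j and prev
                d0, d1 = density[prev], density[j]
                g0, g1 = grid[prev], grid[j]
                if d0 == d1:
                    return g1
                return g0 + (half - d0) * (g1 - g0) / (d1 - d0)
            prev = j
        return None

    right = crossing(range(i + 1, grid.size), +1)
    left = crossing(range(i - 1, -1, -1), -1)
    widths = [abs(peak - c) for c in (left, right) if c is not None]
    hwhm = float(np.mean(widths)) if widths else float(grid[-1] - grid[0])
    return peak, hwhm


def kde_estimate(values, kernel_width="standard", n_grid: int = 2048) -> CopyNumberDistribution:
    """Gaussian-kernel density of copy numbers with peak ± HWHM.

    ``kernel_width`` is the kernel sd in molecules; ``"standard"`` applies
    Silverman's rule.  An explicit width of 0.5 molecules (the uncertainty
    of the characteristic single-fluorophore intensity) resolves periodic
    features such as pentamer multiples.  Requires n >= 10 values.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise EstimationError(f"need >= 10 values for a density estimate, got {values.size}")
    if kernel_width == "standard":
        w = silverman_bandwidth(values)
    else:
        w = float(kernel_width)
        if w <= 0:
            raise ParameterError("kernel_width must be > 0 or 'standard'")
    grid = np.linspace(values.min() - 3 * w, values.max() + 3 * w, n_grid)
    density = _density_on_grid(values, grid, w)
    peak, hwhm = _peak_hwhm(grid, density)
    return CopyNumberDistribution(
        values=values, kernel_width=w, grid=grid, density=density,
        peak=peak, hwhm=hwhm, n=values.size,
    )


def subtract_background_distribution(
    sample: CopyNumberDistribution,
    background: CopyNumberDistribution,
    background_rate: float | None = None,
    sample_foci_per_cell: float | None = None,
    background_foci_per_cell: float | None = None,
) -> CopyNumberDistribution:
    """Remove an autofluorescence background component from a copy-number density.

    ``background_rate`` is the expected fraction of sample foci that are
    actually background (chlorophyll) foci; when omitted it is estimated as
    ``background_foci_per_cell / sample_foci_per_cell``.  The corrected
    density is ``max(sample - rate * background, 0)``, renormalized, with
    peak and HWHM recomputed.
    """
    if background_rate is None:
        if not sample_foci_per_cell or background_foci_per_cell is None:
            raise ParameterError("provide background_rate or foci-per-cell counts")
        background_rate = background_foci_per_cell / sample_foci_per_cell
    if not 0 <= background_rate <= 1:
        raise ParameterError(f"background_rate must lie in [0, 1], got {background_rate}")
    bg = np.interp(sample.grid, background.grid, background.density, left=0.0, right=0.0)
    corrected = np.clip(sample.density - background_rate * bg, 0.0, None)
    area = np.trapezoid(corrected, sample.grid)
    if area <= 0:
        # total self-subtraction: return the (flat-zero) density unnormalized
        return CopyNumberDistribution(
            values=sample.values, kernel_width=sample.kernel_width, grid=sample.grid,
            density=corrected, peak=float("nan"), hwhm=float("nan"), n=sample.n, corrected=True,
        )
    corrected = corrected / area
    peak, hwhm = _peak_hwhm(sample.grid, corrected)
    return CopyNumberDistribution(
        values=sample.values, kernel_width=sample.kernel_width, grid=sample.grid,
        density=corrected, peak=peak, hwhm=hwhm, n=sample.n, corrected=True,
    )


# --------------------------------------------------------------------------
# Functional units and simple proportions
# --------------------------------------------------------------------------

def functional_units(copies, oligomer_size: float):
    """Subunit copies → oligomeric functional units (pentamers, hexamers,
    L8S8 holoenzymes...): ``copies / oligomer_size``, unrounded."""
    if oligomer_size < 1:
        raise ParameterError("oligomer_size must be >= 1")
    return np.asarray(copies, dtype=float) / oligomer_size if np.ndim(copies) else copies / oligomer_size


def proportion_percent(count: int, total: int) -> int:
    """Proportion as a percentage rounded to the nearest percent."""
    if total <= 0 or count < 0 or count > total:
        raise ParameterError("need 0 <= count <= total with total > 0")
    return int(round(100.0 * count / total))


# --------------------------------------------------------------------------
# Triple-Gaussian population decomposition
# --------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Three-Gaussian decomposition of a copy-number density curve."""

    means: np.ndarray
    sds: np.ndarray
    fractions: np.ndarray  # component area fractions, sum to 1
    r_squared: float
    flags: tuple[str, ...] = ()


def _triple_gauss(x, a1, m1, s1, a2, m2, s2, a3, m3, s3):
    return (
        a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2)
        + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2)
        + a3 * np.exp(-0.5 * ((x - m3) / s3) ** 2)
    )


def fit_triple_gaussian(
    distribution: CopyNumberDistribution,
    initial_means=None,
    merge_sd_factor: float = 1.5,
) -> MixtureFit:
    """Least-squares fit of a sum of three Gaussians to the KDE curve.

    Seeds default to the three tallest local density maxima (padded with
    quantiles of the values when fewer exist).  A three-component fit of a
    unimodal density is degenerate — several overlapping components can tile
    one bump — so components whose means lie within ``merge_sd_factor`` times
    the wider sd of each other are merged afterwards (area-weighted moments);
    the vacated components keep their means with zero area and are flagged
    degenerate, as is any component carrying < 1% of the area.  Components
    are reported in ascending order of mean.
    """
    x, y = distribution.grid, distribution.density
    if initial_means is None:
        maxima = distribution.local_maxima()
        seeds = list(maxima[np.argsort(
            -np.interp(maxima, x, y))][:3])
        qs = np.percentile(distribution.values, [25, 50, 75])
        for q in qs:
            if len(seeds) >= 3:
                break
            seeds.append(q)
        initial_means = sorted(seeds)
    if len(initial_means) != 3:
        raise ParameterError("initial_means must contain exactly 3 values")
    span = x[-1] - x[0]
    s0 = max(distribution.hwhm / 1.177, span / 50)
    p0 = []
    for m in initial_means:
        p0 += [float(np.interp(m, x, y)), float(m), s0]
    lb = [0.0, x[0], span * 1e-3] * 3
    ub = [np.inf, x[-1], span] * 3
    try:
        popt, _ = curve_fit(_triple_gauss, x, y, p0=p0, bounds=(lb, ub), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise EstimationError(f"triple-Gaussian fit did not converge: {exc}") from exc
    amps = popt[0::3]
    means = popt[1::3]
    sds = popt[2::3]
    areas = amps * sds * np.sqrt(2 * np.pi)
    order = np.argsort(means)
    means, sds, areas = list(means[order]), list(sds[order]), list(areas[order])

    # merge overlapping components (iterate until stable)
    merged = True
    while merged:
        merged = False
        pairs = [(i, j) for i in range(len(means)) for j in range(i + 1, len(means))]
        for i, j in pairs:
            if areas[i] <= 0 or areas[j] <= 0:
                continue
            if abs(means[i] - means[j]) < merge_sd_factor * max(sds[i], sds[j]):
                a = areas[i] + areas[j]
                mu = (areas[i] * means[i] + areas[j] * means[j]) / a
                second = (
                    areas[i] * (sds[i] ** 2 + means[i] ** 2)
                    + areas[j] * (sds[j] ** 2 + means[j] ** 2)
                ) / a
                means[i], sds[i], areas[i] = mu, float(np.sqrt(max(second - mu**2, 0.0))), a
                areas[j] = 0.0
                merged = True
                break

    means = np.asarray(means)
    sds = np.asarray(sds)
    areas = np.asarray(areas)
    fractions = areas / areas.sum()
    resid = y - _triple_gauss(x, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    flags = tuple(
        f"component-{i}-degenerate" for i, f in enumerate(fractions) if f < 0.01
    )
    return MixtureFit(means=means, sds=sds, fractions=fractions, r_squared=r2, flags=flags)


# --------------------------------------------------------------------------
# Nearest-neighbor overlap model
# --------------------------------------------------------------------------

@dataclass
class OverlapModel:
    """Probability that diffraction-limited foci of distinct organelles overlap.

    Organelle centers are modelled as uniform points in the 2D projection of
    the rod-shaped cell (a stadium: rectangle plus semicircular caps); two
    foci closer than ``resolution_radius`` merge into one apparent focus.
    ``pair_distribution`` (grid, density) is the predicted copy-number
    density of merged two-organelle foci: the self-convolution of the
    singles distribution.
    """

    n_foci_per_cell: int
    cell_area: float            # µm²
    resolution_radius: float    # nm
    overlap_fraction: float
    mode: str
    mc_sd: float | None = None
    pair_distribution: tuple[np.ndarray, np.ndarray] | None = None


def _cell_projection(geometry: CellGeometry):
    h = geometry.half_axis
    return LineString([(-h, 0.0), (h, 0.0)]).buffer(geometry.radius, quad_segs=90)


def _uniform_in_polygon(poly, rng: np.random.Generator, n: int) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    pts = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = 2 * (n - filled) + 8
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(m, 2))
        keep = np.fromiter((poly.contains(Point(p)) for p in cand), bool, count=m)
        good = cand[keep]
        take = min(len(good), n - filled)
        pts[filled : filled + take] = good[:take]
        filled += take
    return pts


def overlap_fraction(
    n_foci: int,
    cell_geometry: CellGeometry,
    resolution_radius: float = 250.0,
    mode: str = "analytic",
    singles: CopyNumberDistribution | None = None,
    n_placements: int = 100_000,
    rng_seed: int | None = None,
) -> OverlapModel:
    """Fraction of foci with at least one neighbor within the resolution radius.

    ``analytic`` integrates, over focus positions p uniform in the projected
    cell, ``1 - (1 - a(p)/A)^(n-1)`` where ``a(p)`` is the area of the
    resolution disk around p clipped to the cell — an edge-corrected
    nearest-neighbor probability for n uniform points in a finite region.
    ``montecarlo`` places n points repeatedly (>= ``n_placements`` total) and
    counts neighbors directly.
    """
    if n_foci < 1:
        raise ParameterError("n_foci must be >= 1")
    if resolution_radius <= 0:
        raise ParameterError("resolution_radius must be > 0")
    r_um = resolution_radius * 1e-3
    poly = _cell_projection(cell_geometry)
    area = poly.area
    if r_um >= 2 * cell_geometry.radius:
        warnings.warn("resolution radius exceeds the cell width; overlap fraction ~ 1")

    if n_foci == 1:
        frac, mc_sd = 0.0, 0.0
    elif mode == "analytic":
        rng = np.random.default_rng(0)  # quasi-deterministic integration nodes
        # stratified grid of integration nodes inside the polygon
        minx, miny, maxx, maxy = poly.bounds
        nx = 160
        ny = max(int(nx * (maxy - miny) / (maxx - minx)), 40)
        gx = np.linspace(minx, maxx, nx)
        gy = np.linspace(miny, maxy, ny)
        fracs = []
        for yv in gy:
            for xv in gx:
                p = Point(xv, yv)
                if not poly.contains(p):
                    continue
                a = p.buffer(r_um, quad_segs=32).intersection(poly).area
                fracs.append(1.0 - (1.0 - a / area) ** (n_foci - 1))
        frac = float(np.mean(fracs))
        mc_sd = None
    elif mode == "montecarlo":
        rng = np.random.default_rng(rng_seed)
        n_cells = max(int(np.ceil(n_placements / n_foci)), 1)
        overlaps = 0
        total = 0
        per_cell = []
        for _ in range(n_cells):
            pts = _uniform_in_polygon(poly, rng, n_foci)
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            has_nb = (d.min(axis=1) <= r_um)
            overlaps += int(has_nb.sum())
            total += n_foci
            per_cell.append(has_nb.mean())
        frac = overlaps / total
        mc_sd = float(np.std(per_cell, ddof=1) / np.sqrt(len(per_cell)))
    else:
        raise ParameterError("mode must be 'analytic' or 'montecarlo'")

    pair = None
    if singles is not None:
        dx = singles.grid[1] - singles.grid[0]
        conv = np.convolve(singles.density, singles.density) * dx
        grid2 = singles.grid[0] * 2 + dx * np.arange(conv.size)
        pair = (grid2, conv)
    return OverlapModel(
        n_foci_per_cell=n_foci, cell_area=area, resolution_radius=resolution_radius,
        overlap_fraction=frac, mode=mode, mc_sd=mc_sd, pair_distribution=pair,
    )


# --------------------------------------------------------------------------
# Confocal foci photometry
# --------------------------------------------------------------------------

def confocal_foci_intensities(
    image: np.ndarray,
    noise_tolerance: float,
    saturation_level: float | None = None,
    return_positions: bool = False,
):
    """Peak pixel intensities of confocal foci by prominence-gated local maxima.

    A regional maximum counts as a focus only if it stands more than
    ``noise_tolerance`` above its surroundings (h-maxima transform), which
    also merges twin peaks separated by a dip shallower than the tolerance.
    Foci containing saturated pixels are excluded.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("image must be 2D")
    if noise_tolerance < 0:
        raise ParameterError("noise_tolerance must be >= 0")
    if image.max() == image.min():
        out = np.empty(0)
        return (out, np.empty((0, 2))) if return_positions else out
    if noise_tolerance > 0:
        mask = h_maxima(image, noise_tolerance)
    else:
        mask = local_maxima(image)
    labels, n = ndi_label(mask)
    peaks, positions = [], []
    for k in range(1, n + 1):
        rows, cols = np.nonzero(labels == k)
        region_vals = image[rows, cols]
        if saturation_level is not None and np.any(region_vals >= saturation_level):
            continue
        j = int(np.argmax(region_vals))
        peaks.append(float(region_vals[j]))
        positions.append((float(cols[j]), float(rows[j])))
    peaks = np.asarray(peaks)
    if return_positions:
        return peaks, np.asarray(positions).reshape(-1, 2)
    return peaks


def cytosolic_background_correct(
    peak_intensities,
    axis_profile,
    focus_mask=None,
    mad_sigma: float = 3.0,
):
    """Subtract the cytosolic background from confocal focus peak intensities.

    The background level is the mean of the cell's central-line intensity
    profile over non-focus positions (``focus_mask`` True marks focus pixels;
    when omitted, profile values more than ``mad_sigma`` robust sd above the
    median are treated as foci).  Corrected values below zero are clipped and
    flagged.  Returns ``(corrected, background, flags)``.
    """
    peaks = np.asarray(peak_intensities, dtype=float)
    profile = np.asarray(axis_profile, dtype=float)
    if focus_mask is None:
        med = np.median(profile)
        mad = np.median(np.abs(profile - med))
        focus_mask = profile > med + mad_sigma * 1.4826 * max(mad, 1e-12)
    focus_mask = np.asarray(focus_mask, dtype=bool)
    bg_vals = profile[~focus_mask]
    if bg_vals.size == 0:
        warnings.warn("no non-focus region on the central line; correction skipped")
        return peaks.copy(), 0.0, ("no-background-region",)
    bg = float(bg_vals.mean())
    corrected = peaks - bg
    flags = tuple(f"clipped-{i}" for i in np.nonzero(corrected < 0)[0])
    return np.clip(corrected, 0.0, None), bg, flags


# --------------------------------------------------------------------------
# Calibration, condition comparison, sampling error
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationFactor:
    """Molecules per confocal intensity unit, anchored on a single-molecule
    (Slimfield) absolute count under the reference condition."""

    slimfield_peak: float   # molecules
    confocal_peak: float    # intensity units
    strain: str | None = None

    @property
    def factor(self) -> float:
        return self.slimfield_peak / self.confocal_peak

    def apply(self, confocal_intensity):
        return np.asarray(confocal_intensity, dtype=float) * self.factor


def calibrate(
    confocal_peak: float,
    slimfield_peak: float,
    strain_confocal: str | None = None,
    strain_slimfield: str | None = None,
) -> CalibrationFactor:
    """Conversion factor from confocal intensity to absolute molecule copies.

    Both peaks must come from the same strain under the reference growth
    condition; mismatched strain labels are refused.
    """
    if confocal_peak <= 0 or slimfield_peak <= 0:
        raise ParameterError("both peaks must be > 0")
    if strain_confocal is not None and strain_slimfield is not None and strain_confocal != strain_slimfield:
        raise ParameterError(
            f"strain mismatch: confocal={strain_confocal!r} vs slimfield={strain_slimfield!r}"
        )
    return CalibrationFactor(
        slimfield_peak=slimfield_peak, confocal_peak=confocal_peak, strain=strain_confocal
    )


def significance_stars(p: float) -> str:
    """Significance label: *** for P < 0.005, * for P < 0.05, ns otherwise."""
    if p < 0.005:
        return "***"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ConditionComparison:
    u_statistic: float
    p_value: float
    fold_change: float
    n_a: int
    n_b: int
    stars: str


def compare_conditions(sample_a, sample_b, oligomer_size: float = 1.0) -> ConditionComparison:
    """Two-sided Mann-Whitney U comparison of two copy-number samples.

    The fold change is the ratio of functional-unit medians, A over B.
    Samples whose pooled values are all identical give p = 1 with a warning.
    """
    a = functional_units(np.asarray(sample_a, dtype=float), oligomer_size)
    b = functional_units(np.asarray(sample_b, dtype=float), oligomer_size)
    if a.size < 8 or b.size < 8:
        raise ParameterError("need n >= 8 in both samples")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("degenerate all-tie samples; p set to 1")
        u = a.size * b.size / 2.0
        p = 1.0
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        u, p = float(res.statistic), float(res.pvalue)
    fold = float(np.median(a) / np.median(b))
    return ConditionComparison(
        u_statistic=u, p_value=p, fold_change=fold, n_a=a.size, n_b=b.size,
        stars=significance_stars(p),
    )


@dataclass
class GroupedSamplingError:
    relative_error: float
    group_peaks: np.ndarray
    group_size: int
    exceeds_5_percent: bool


def grouped_sampling_error(
    values,
    group_size: int = 85,
    n_resamples: int = 10,
    kernel_width="standard",
    rng_seed: int | None = None,
) -> GroupedSamplingError:
    """Sampling error of the KDE peak by randomized grouping.

    Values are repeatedly shuffled and split into disjoint groups of
    ``group_size`` (70–100 entries by convention); each group's KDE peak is
    recorded and the relative error reported as sd/mean of the group peaks.
    Errors above 5% raise the quality flag used to gate distribution
    estimates.
    """
    values = np.asarray(values, dtype=float)
    if not 2 <= group_size <= values.size // 2:
        raise EstimationError(
            f"need n >= 2 * group_size = {2 * group_size} values, got {values.size}"
        )
    rng = np.random.default_rng(rng_seed)
    n_groups = values.size // group_size
    peaks = []
    for _ in range(n_resamples):
        perm = rng.permutation(values)
        for g in range(n_groups):
            grp = perm[g * group_size : (g + 1) * group_size]
            peaks.append(kde_estimate(grp, kernel_width=kernel_width).peak)
    peaks = np.asarray(peaks)
    mean = float(peaks.mean())
    rel = float(peaks.std(ddof=1) / abs(mean)) if mean != 0 else 0.0
    if np.allclose(peaks, peaks[0]):
        rel = 0.0
    return GroupedSamplingError(
        relative_error=rel, group_peaks=peaks, group_size=group_size,
        exceeds_5_percent=rel > 0.05,
    )
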