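"""Spheroid radius tracking and SHG/TPF stack quantification.

Two families of measurements:

* **Time-lapse frames** — the spheroid centre is located by exhaustive
  coarse-to-fine minimization of a two-phase piecewise-constant
  (Mumford-Shah-type) disk energy; the radius is then read from the radial
  "graininess" profile (radially binned mean of the squared first-difference
  image gradient) as the furthest radius beyond the profile maximum where
  the graininess first falls and stays below 75% of its maximum.

* **Multiphoton stacks** — SHG images are binarized with a global threshold
  defined as the largest over experimental groups of (mean + 2 x sample SD)
  of per-image background maxima; areal porosity (= volumetric porosity for
  randomly oriented fibers) is 1 minus the fiber area fraction; SHG masks
  gate the paired TPF channel; radial and axial intensity profiles quantify
  densified collagen layers; gel thickness is read from the axial profile
  onset, averaged over three lateral sub-regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, peak_widths

from collagenmech.errors import (
    DegenerateInputError,
    InvalidArgumentError,
    UnreliableDetectionError,
)

__all__ = [
    "ImageStack",
    "IntensityProfile",
    "ThresholdReport",
    "DensifiedLayer",
    "find_center",
    "radial_graininess",
    "spheroid_radius",
    "global_threshold",
    "binarize_and_porosity",
    "masked_tpf_intensity",
    "radial_shg_profile",
    "axial_shg_profile",
    "gel_thickness",
    "densified_layer_metrics",
    "read_stack",
    "write_stack",
]


@dataclass(frozen=True)
class ImageStack:
    """Calibrated volumetric image (z, y, x), non-negative intensities.

    ``pixel_size_xy`` is the lateral calibration in um/pixel and ``step_z``
    the axial slice spacing in um. Depth is measured from slice 0, the
    compressed / objective-side surface.
    """

    data: np.ndarray
    pixel_size_xy: float
    step_z: float
    channel: str = "SHG"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise InvalidArgumentError("stack must be 3-D (z, y, x) with all dims >= 1")
        if self.pixel_size_xy <= 0 or self.step_z <= 0:
            raise InvalidArgumentError("calibrations must be positive")
        object.__setattr__(self, "data", data)

    @property
    def depths(self) -> np.ndarray:
        """Depth coordinate zeta of each slice in um."""
        return np.arange(self.data.shape[0]) * self.step_z


@dataclass(frozen=True)
class IntensityProfile:
    """Binned mean-intensity profile vs radius or depth (um)."""

    coords: np.ndarray
    mean_intensity: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if np.any(np.diff(c) <= 0):
            raise InvalidArgumentError("profile coordinates must be strictly increasing")
        object.__setattr__(self, "coords", c)

    def total_mean(self) -> float:
        """Count-weighted overall mean intensity (conserved under re-binning)."""
        n = self.counts.sum()
        if n == 0:
            return 0.0
        return float(np.sum(self.mean_intensity * self.counts) / n)


@dataclass(frozen=True)
class ThresholdReport:
    """Per-group and global SHG intensity thresholds."""

    group_means: dict
    group_thresholds: dict
    global_threshold: float


@dataclass(frozen=True)
class DensifiedLayer:
    """Detected densified-collagen layer in an intensity profile."""

    position: float  # peak depth or radius, um
    prominence: float
    width: float  # full width at half prominence, um


# ---------------------------------------------------------------------------
# Spheroid time-lapse analysis
# ---------------------------------------------------------------------------


def _disk_energy_map(frame: np.ndarray, centers: np.ndarray, r_max: int) -> np.ndarray:
    """Two-phase piecewise-constant energy, minimized over radius, per center.

    For a candidate disk the energy is the within-class sum of squares of
    intensities inside vs outside; minimizing it is equivalent to maximizing
    S_in^2/n_in + S_out^2/n_out, evaluated for every integer radius via
    cumulative ring sums.
    """
    h, w = frame.shape
    total_s = float(frame.sum())
    total_ss = float((frame.astype(float) ** 2).sum())
    n_pix = frame.size
    yy, xx = np.mgrid[0:h, 0:w]
    energies = np.empty(len(centers))
    for idx, (cy, cx) in enumerate(centers):
        r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2).astype(int).ravel()
        nbins = r.max() + 1
        ring_n = np.bincount(r, minlength=nbins)
        ring_s = np.bincount(r, weights=frame.ravel(), minlength=nbins)
        n_in = np.cumsum(ring_n)[: r_max + 1]
        s_in = np.cumsum(ring_s)[: r_max + 1]
        n_out = n_pix - n_in
        s_out = total_s - s_in
        with np.errstate(divide="ignore", invalid="ignore"):
            between = np.where(n_in > 0, s_in**2 / n_in, 0.0) + np.where(
                n_out > 0, s_out**2 / n_out, 0.0
            )
        # exclude degenerate radii (all-in or all-out disks)
        valid = (n_in > 0) & (n_out > 0)
        between[~valid] = -np.inf
        energies[idx] = total_ss - between.max()
    return energies


def find_center(frame: np.ndarray, coarse_step: int = 8) -> tuple[float, float]:
    """Locate the spheroid centre (cx, cy) in pixel coordinates.

    Exhaustive coarse-to-fine search of the two-phase piecewise-constant disk
    energy, marginalized over the disk radius. Deterministic given the frame.
    Raises :class:`DegenerateInputError` on a constant frame.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise InvalidArgumentError("frame must be 2-D")
    if np.ptp(frame) == 0:
        raise DegenerateInputError("constant frame has no detectable centre")
    h, w = frame.shape
    r_max = int(np.hypot(h, w) / 2)

    ys = np.arange(coarse_step // 2, h, coarse_step)
    xs = np.arange(coarse_step // 2, w, coarse_step)
    centers = np.array([(y, x) for y in ys for x in xs])
    e = _disk_energy_map(frame, centers, r_max)
    cy, cx = centers[int(np.argmin(e))]

    span = coarse_step
    for step in (2, 1):
        ys = np.arange(max(0, cy - span), min(h, cy + span + 1), step)
        xs = np.arange(max(0, cx - span), min(w, cx + span + 1), step)
        centers = np.array([(y, x) for y in ys for x in xs])
        e = _disk_energy_map(frame, centers, r_max)
        cy, cx = centers[int(np.argmin(e))]
        span = step * 2
    return float(cx), float(cy)


def _graininess_image(frame: np.ndarray) -> np.ndarray:
    """Squared first-difference gradient magnitude (first-order approximation)."""
    frame = np.asarray(frame, dtype=float)
    gx = np.diff(frame, axis=1, append=frame[:, -1:])
    gy = np.diff(frame, axis=0, append=frame[-1:, :])
    return gx * gx + gy * gy


def radial_graininess(
    frame: np.ndarray,
    center: tuple[float, float],
    bin_width: float = 2.0,
) -> IntensityProfile:
    """Radially binned mean of the squared image gradient around ``center``.

    ``center`` is (cx, cy) in pixels and must lie inside the frame;
    coordinates of the returned profile are bin centres in pixels.
    """
    frame = np.asarray(frame, dtype=float)
    cx, cy = center
    h, w = frame.shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise InvalidArgumentError("center lies outside the frame")
    grain = _graininess_image(frame)
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - cx, yy - cy).ravel()
    bins = (r / bin_width).astype(int)
    nbins = bins.max() + 1
    counts = np.bincount(bins, minlength=nbins)
    sums = np.bincount(bins, weights=grain.ravel(), minlength=nbins)
    with np.errstate(divide="ignore", invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    coords = (np.arange(nbins) + 0.5) * bin_width
    return IntensityProfile(coords=coords, mean_intensity=means, counts=counts)


def spheroid_radius(
    frame: np.ndarray,
    pixel_size_um: float = 1.0,
    center: Optional[tuple[float, float]] = None,
    drop_fraction: float = 0.75,
    min_consecutive: int = 2,
    bin_width: float = 1.0,
    min_texture_fraction: float = 0.01,
    reliability_ratio: float = 3.0,
    min_bin_pixels: int = 200,
) -> float:
    """Spheroid radius in micrometres from one (projected) frame.

    The radius is the furthest radial bin boundary beyond which the
    graininess profile stays below ``drop_fraction`` of its maximum (for at
    least ``min_consecutive`` bins of support). The reference maximum is
    taken over bins pooling at least ``min_bin_pixels`` pixels — the
    innermost rings carry too few pixels for a max-based rule. Two
    reliability guards raise :class:`UnreliableDetectionError`: the peak
    graininess must exceed the detectability floor set by
    ``min_texture_fraction`` of the mean frame intensity (zero-contrast
    frames fail this), and the mean graininess inside the detected radius
    must exceed ``reliability_ratio`` times the mean outside (flat or
    white-noise profiles fail this).
    """
    if center is None:
        center = find_center(frame)
    prof = radial_graininess(frame, center, bin_width=bin_width)
    sel = prof.counts > 0
    # count-weighted pooling over neighbouring bins
    sums = gaussian_filter1d(prof.mean_intensity[sel] * prof.counts[sel], sigma=1.0)
    cnts = gaussian_filter1d(prof.counts[sel].astype(float), sigma=1.0)
    g = sums / np.maximum(cnts, 1e-300)
    support = cnts >= min_bin_pixels
    g_max = float(g[support].max()) if support.any() else float(g.max())
    floor = (min_texture_fraction * float(np.asarray(frame, dtype=float).mean())) ** 2
    if g_max <= floor:
        raise UnreliableDetectionError("graininess below the detectability floor")
    thr = drop_fraction * g_max
    above = np.nonzero(g >= thr)[0]
    j = int(above[-1])
    if j + min_consecutive > g.size - 1:
        raise UnreliableDetectionError("graininess never settles below the detection threshold")
    inside = float(g[: j + 1].mean())
    outside = float(g[j + 1 :].mean())
    if inside < reliability_ratio * outside:
        raise UnreliableDetectionError("graininess profile is flat; radius unreliable")
    coords = prof.coords[sel]
    # sub-bin interpolation of the threshold crossing between bins j and j+1
    drop = g[j] - g[j + 1]
    frac = (g[j] - thr) / drop if drop > 0 else 0.5
    r_px = coords[j] + frac * bin_width
    return float(r_px * pixel_size_um)


# ---------------------------------------------------------------------------
# SHG/TPF stack quantification
# ---------------------------------------------------------------------------


def global_threshold(background_rois: Mapping[str, Sequence[np.ndarray]]) -> ThresholdReport:
    """Global SHG threshold from fiber-free background regions.

    For each group, the threshold is mean + 2 x sample SD (ddof=1; zero for
    a single ROI) of the per-image ROI maxima; the global threshold is the
    largest group threshold.
    """
    if not background_rois:
        raise InvalidArgumentError("at least one group of background ROIs is required")
    means, thresholds = {}, {}
    for group, rois in background_rois.items():
        if len(rois) == 0:
            raise InvalidArgumentError(f"group {group!r} has no background ROIs")
        maxima = []
        for roi in rois:
            roi = np.asarray(roi)
            if roi.size == 0:
                raise InvalidArgumentError(f"empty ROI in group {group!r}")
            maxima.append(float(roi.max()))
        maxima = np.asarray(maxima)
        mean = float(maxima.mean())
        sd = float(maxima.std(ddof=1)) if maxima.size > 1 else 0.0
        means[group] = mean
        thresholds[group] = mean + 2.0 * sd
    return ThresholdReport(
        group_means=means,
        group_thresholds=thresholds,
        global_threshold=max(thresholds.values()),
    )


def binarize_and_porosity(
    stack: ImageStack, threshold: float
) -> tuple[np.ndarray, float, float]:
    """Binarize a stack and measure fiber area fraction and areal porosity.

    The mask is ``intensity >= threshold``; the fiber area fraction is the
    mask coverage averaged over slices and porosity its complement (areal =
    volumetric porosity for randomly oriented fibers).
    """
    if threshold < 0:
        raise InvalidArgumentError("threshold must be non-negative")
    mask = stack.data >= threshold
    area_fraction = float(mask.mean(axis=(1, 2)).mean())
    return mask, area_fraction, 1.0 - area_fraction


def masked_tpf_intensity(tpf: ImageStack, mask: np.ndarray) -> float:
    """Mean TPF intensity over the SHG-mask-positive voxels only."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tpf.data.shape:
        raise InvalidArgumentError("mask and TPF stack shapes must match")
    if not mask.any():
        raise DegenerateInputError("empty mask: masked mean intensity is undefined")
    return float(tpf.data[mask].mean())


def radial_shg_profile(
    stack: ImageStack,
    center: tuple[float, float],
    bin_width_um: float = 5.0,
) -> IntensityProfile:
    """Mean intensity vs radius (um) from ``center``, pooled over slices."""
    cx, cy = center
    nz, h, w = stack.data.shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise InvalidArgumentError("center lies outside the frame")
    yy, xx = np.mgrid[0:h, 0:w]
    r_um = np.hypot(xx - cx, yy - cy).ravel() * stack.pixel_size_xy
    bins = (r_um / bin_width_um).astype(int)
    nbins = bins.max() + 1
    counts = np.bincount(bins, minlength=nbins) * nz
    sums = np.zeros(nbins)
    for z in range(nz):
        sums += np.bincount(bins, weights=stack.data[z].ravel().astype(float), minlength=nbins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    coords = (np.arange(nbins) + 0.5) * bin_width_um
    return IntensityProfile(coords=coords, mean_intensity=means, counts=counts)


def axial_shg_profile(stack: ImageStack) -> IntensityProfile:
    """Mean intensity per slice vs depth zeta (um)."""
    if stack.data.shape[0] < 2:
        raise InvalidArgumentError("axial profile requires at least 2 slices")
    means = stack.data.mean(axis=(1, 2)).astype(float)
    counts = np.full(stack.data.shape[0], stack.data.shape[1] * stack.data.shape[2])
    return IntensityProfile(coords=stack.depths, mean_intensity=means, counts=counts)


def _onset_terminal(profile: np.ndarray, fraction: float) -> tuple[int, int]:
    """First sustained (2-slice) and last crossing of fraction*max."""
    if profile.max() <= 0:
        raise UnreliableDetectionError("no signal in axial profile")
    thr = fraction * profile.max()
    above = profile >= thr
    onset = None
    for i in range(above.size - 1):
        if above[i] and above[i + 1]:
            onset = i
            break
    if onset is None:
        raise UnreliableDetectionError("no sustained onset in axial profile")
    terminal = int(np.nonzero(above)[0][-1])
    return onset, terminal


def gel_thickness(
    stack: ImageStack,
    onset_fraction: float = 0.5,
    n_lateral: int = 3,
) -> float:
    """Gel thickness (um): surface onset to coverslip landmark.

    The axial mean-intensity profile is computed in ``n_lateral`` lateral
    sub-regions (vertical strips); in each, the gel surface is the first
    sustained crossing of ``onset_fraction`` of the profile maximum and the
    coverslip landmark the last slice above it. The reported thickness is
    the mean of the sub-region measurements.
    """
    nz, h, w = stack.data.shape
    edges = np.linspace(0, w, n_lateral + 1).astype(int)
    measurements = []
    for a, b in zip(edges[:-1], edges[1:]):
        prof = stack.data[:, :, a:b].mean(axis=(1, 2)).astype(float)
        onset, terminal = _onset_terminal(prof, onset_fraction)
        measurements.append((terminal - onset) * stack.step_z)
    return float(np.mean(measurements))


def densified_layer_metrics(
    profile: IntensityProfile,
    prominence_floor_frac: float = 0.05,
    noise_sigmas: float = 4.0,
    guard_bins: int = 3,
) -> Optional[DensifiedLayer]:
    """Detect a densified-collagen layer as a peak over the attenuation baseline.

    A single-exponential baseline is fitted to the profile excluding a guard
    band around candidate peaks; peaks are then sought in the residual
    relative to the baseline (attenuation makes the noise multiplicative)
    and the most prominent one above the floor is returned with its full
    width at half prominence. The floor is the larger of
    ``prominence_floor_frac`` (relative units) and ``noise_sigmas`` times
    the robust (MAD) relative residual noise, so bin-count fluctuations in
    sparse stacks do not masquerade as layers. Ties break
    toward the smaller coordinate. Returns ``None`` (the "no layer"
    sentinel) when no peak clears the floor.
    """
    y = np.asarray(profile.mean_intensity, dtype=float)
    x = np.asarray(profile.coords, dtype=float)
    if y.size < 5:
        raise InvalidArgumentError("layer detection requires at least 5 bins")
    floor = prominence_floor_frac * max(y.max(), 1e-300)

    # candidate peaks on the raw (lightly smoothed) profile
    y_s = gaussian_filter1d(y, sigma=1.0)
    cand, _ = find_peaks(y_s, prominence=0.5 * floor)
    exclude = np.zeros(y.size, dtype=bool)
    for c in cand:
        exclude[max(0, c - guard_bins) : c + guard_bins + 1] = True
    base_sel = (~exclude) & (y > 0)
    if base_sel.sum() >= 3:
        # log-linear fit of A * exp(-x / L)
        coeffs = np.polyfit(x[base_sel], np.log(y[base_sel]), 1)
        baseline = np.exp(np.polyval(coeffs, x))
    else:
        baseline = np.full_like(y, float(np.median(y)))
    # relative residual: attenuation makes the noise scale with the baseline,
    # and a densified layer is a multiplicative enhancement
    resid = (y - baseline) / np.maximum(baseline, 1e-300)
    # MAD over all bins: robust to a genuine (localized) layer peak while
    # capturing the full bin-to-bin fluctuation level
    noise = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    floor_rel = max(prominence_floor_frac, noise_sigmas * noise)

    peaks, props = find_peaks(resid, prominence=floor_rel)
    if peaks.size == 0:
        return None
    proms = props["prominences"]
    best_order = np.lexsort((peaks, -proms))  # prominence desc, then smaller coord
    j = best_order[0]
    widths = peak_widths(resid, [peaks[j]], rel_height=0.5)[0]
    dx = float(np.mean(np.diff(x)))
    return DensifiedLayer(
        position=float(x[peaks[j]]),
        prominence=float(proms[j] * baseline[peaks[j]]),
        width=float(widths[0] * dx),
    )


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------


def read_stack(path, pixel_size_xy: float, step_z: float, channel: str = "SHG") -> ImageStack:
    """Read a multi-page grayscale TIFF as a calibrated stack."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data=data, pixel_size_xy=pixel_size_xy, step_z=step_z, channel=channel)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF (float32)."""
    tifffile.imwrite(path, stack.data.astype(np.float32))
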