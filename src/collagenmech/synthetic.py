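"""Synthetic inputs with the statistical structure the analyses assume.

Every downstream stage of the package is testable without laboratory data:

* :func:`gen_relaxation_trace` — multi-exponential (generalized Maxwell)
  stress decays with additive Gaussian noise, the forward model of the
  relaxation-spectrum inversion.
* :func:`gen_biphasic_trace` — full rheometer-style gap/force records from
  the biphasic forward solver (force is the inverse of the stress/force
  conversion), with additive and/or multiplicative force noise.
* :func:`gen_shg_stack` — fiber-rendered SHG-like stacks: random 3-D line
  segments, Gaussian blur as a PSF stand-in, exponential depth attenuation
  and an optional high-density surface slab. Not a physical SHG model; it
  exercises thresholding and profile analyses.
* :func:`gen_spheroid_timelapse` — textured growing-disk frames with known
  ground-truth radii for radius-recovery tests.
* :func:`manifest_count` — enumerates an imaging design (channels x slices
  x stacks x gels x groups x concentrations) into a manifest.

All generators are reproducible: identical seed and parameters give
identical output. Noise is additive i.i.d. Gaussian on force/intensity.
Ground-truth sidecar JSON files accompany every dataset written to disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from collagenmech.biphasic import BiphasicParams, solve_confined_compression
from collagenmech.compression import CompressionTrace, GelGeometry, StepProtocol
from collagenmech.errors import InvalidArgumentError
from collagenmech.imaging import ImageStack
from collagenmech.kinematics import SpheroidTrack

__all__ = [
    "MaxwellModeSet",
    "ImagingDesign",
    "gen_relaxation_trace",
    "gen_biphasic_trace",
    "gen_shg_stack",
    "gen_spheroid_timelapse",
    "manifest_count",
    "build_manifest",
    "write_ground_truth",
]

# Study-condition defaults for synthetic confined-compression experiments:
# a soft collagen-gel-like Yeoh solid (aggregate modulus 1 kPa at small
# strain, mild softening then stiffening) and a permeability giving a
# consolidation time constant of ~90 s for a 3 mm gel.
DEFAULT_BIPHASIC = BiphasicParams(c1=250.0, c2=-50.0, c3=1000.0, k=1e-10)


@dataclass(frozen=True)
class MaxwellModeSet:
    """Equilibrium stress plus discrete Maxwell modes (amplitude, tau).

    Taus must be positive and strictly increasing; amplitudes positive;
    ``noise_sd`` is the additive Gaussian noise SD in Pa.
    """

    equilibrium_stress: float
    modes: tuple
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        modes = tuple((float(a), float(t)) for a, t in self.modes)
        taus = [t for _, t in modes]
        if any(a <= 0 for a, _ in modes):
            raise InvalidArgumentError("mode amplitudes must be positive")
        if any(t <= 0 for t in taus) or any(b <= a for a, b in zip(taus, taus[1:])):
            raise InvalidArgumentError("taus must be positive and strictly increasing")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be non-negative")
        object.__setattr__(self, "modes", modes)

    def evaluate(self, t) -> np.ndarray:
        """Noiseless closed form sigma(t) = sigma_e + sum A_i exp(-t/tau_i)."""
        t = np.asarray(t, dtype=float)
        s = np.full_like(t, self.equilibrium_stress, dtype=float)
        for a, tau in self.modes:
            s += a * np.exp(-t / tau)
        return s

    @property
    def total_amplitude(self) -> float:
        return float(sum(a for a, _ in self.modes))


@dataclass(frozen=True)
class ImagingDesign:
    """Factorial multiphoton imaging design (all counts >= 1)."""

    n_channels: int = 2
    images_per_stack: int = 11
    stacks_per_gel: int = 3
    gels_per_group: int = 4
    n_groups: int = 2
    n_concentrations: int = 4

    def __post_init__(self) -> None:
        if min(
            self.n_channels,
            self.images_per_stack,
            self.stacks_per_gel,
            self.gels_per_group,
            self.n_groups,
            self.n_concentrations,
        ) < 1:
            raise InvalidArgumentError("all design counts must be >= 1")


def gen_relaxation_trace(
    modes: MaxwellModeSet,
    duration: float,
    rate: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled multi-exponential stress decay with additive Gaussian noise.

    Returns ``(times, stresses)`` sampled at ``rate`` Hz over ``duration``
    seconds starting at t = 0.
    """
    if duration <= 0 or rate <= 0:
        raise InvalidArgumentError("duration and rate must be positive")
    t = np.arange(0.0, duration, 1.0 / rate)
    s = modes.evaluate(t)
    if modes.noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, modes.noise_sd, size=t.size)
    return t, s


def gen_biphasic_trace(
    params: BiphasicParams = DEFAULT_BIPHASIC,
    protocol: Optional[StepProtocol] = None,
    geometry: Optional[GelGeometry] = None,
    noise_sd: float = 0.0,
    noise_rel: float = 0.0,
    rate: float = 100.0,
    seed: int = 0,
    n_spatial_nodes: int = 60,
    return_solution: bool = False,
):
    """Rheometer-style gap/force record from the biphasic forward solver.

    The noiseless force is the solver's boundary stress times the indenter
    area plus the force offset; the gap is the prescribed thickness plus the
    coverslip. ``noise_sd`` adds Gaussian force noise in newtons;
    ``noise_rel`` adds multiplicative Gaussian noise (fractional SD).
    """
    protocol = protocol or StepProtocol()
    geometry = geometry or GelGeometry()
    if rate <= 0:
        raise InvalidArgumentError("sampling rate must be positive")
    total = protocol.n_steps * (protocol.ramp_duration + protocol.hold_duration)
    t = np.arange(0.0, total, 1.0 / rate)
    # solve on a refined internal grid (ramps linear, holds log-spaced) and
    # interpolate the boundary stress to the sampling grid
    grid: list[np.ndarray] = [np.array([0.0])]
    t0 = 0.0
    for _ in range(protocol.n_steps):
        ramp = protocol.ramp_duration
        # refine toward the ramp end, where the stress peak is sharpest
        grid.append(t0 + ramp * np.linspace(0.0, 0.8, 30)[1:])
        grid.append(t0 + ramp * (1.0 - np.geomspace(0.2, 1e-4, 40)))
        grid.append(np.array([t0 + ramp]))
        t0 += ramp
        grid.append(t0 + np.geomspace(protocol.hold_duration * 1e-5, protocol.hold_duration, 350))
        t0 += protocol.hold_duration
    t_grid = np.concatenate(grid)
    t_grid = t_grid[t_grid <= total]
    sol = solve_confined_compression(
        params, protocol, geometry, n_spatial_nodes=n_spatial_nodes, t_eval=t_grid
    )
    sigma_zz0 = np.interp(t, sol.times, sol.sigma_zz0)
    force = geometry.force_offset + (-sigma_zz0) * geometry.indenter_area
    if noise_sd > 0 or noise_rel > 0:
        rng = np.random.default_rng(seed)
        if noise_rel > 0:
            force = force * (1.0 + rng.normal(0.0, noise_rel, size=force.size))
        if noise_sd > 0:
            force = force + rng.normal(0.0, noise_sd, size=force.size)
    breaks, values = protocol.thickness_history(geometry.unloaded_thickness)
    gap = np.interp(t, breaks, values) + geometry.coverslip_thickness
    trace = CompressionTrace(time=t, gap=gap, force=force)
    if return_solution:
        return trace, sol
    return trace


def _render_fibers(
    rng: np.random.Generator,
    vol: np.ndarray,
    n_fibers: int,
    fiber_length_um: float,
    pixel_size_xy: float,
    step_z: float,
    z_range_um: Optional[tuple[float, float]] = None,
) -> None:
    """Rasterize straight 3-D segments into ``vol`` (z, y, x), in place.

    Fiber centres are seeded in a half-fiber-length margin beyond the target
    region so the rendered line density is uniform up to the volume edges.
    """
    nz, ny, nx = vol.shape
    depth_um = nz * step_z
    z_lo, z_hi = z_range_um if z_range_um is not None else (0.0, depth_um)
    margin = fiber_length_um / 2.0
    step = pixel_size_xy / 2.0
    n_pts = max(2, int(fiber_length_um / step))
    for _ in range(n_fibers):
        cz = rng.uniform(z_lo - margin, z_hi + margin)
        cy = rng.uniform(-margin, ny * pixel_size_xy + margin)
        cx = rng.uniform(-margin, nx * pixel_size_xy + margin)
        # uniform direction on the sphere
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        s = np.linspace(-fiber_length_um / 2, fiber_length_um / 2, n_pts)
        pz = cz + v[0] * s
        py = cy + v[1] * s
        px = cx + v[2] * s
        iz = np.round(pz / step_z).astype(int)
        iy = np.round(py / pixel_size_xy).astype(int)
        ix = np.round(px / pixel_size_xy).astype(int)
        ok = (iz >= 0) & (iz < nz) & (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
        np.add.at(vol, (iz[ok], iy[ok], ix[ok]), 1.0)


def gen_shg_stack(
    fiber_density: float = 0.005,
    densified_layer: Optional[tuple[float, float, float]] = None,
    attenuation_length: float = 100.0,
    psf_sigma: float = 0.5,
    shape: tuple[int, int, int] = (11, 128, 128),
    pixel_size_xy: float = 0.5,
    step_z: float = 1.0,
    fiber_length_um: float = 8.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> ImageStack:
    """Fiber-rendered SHG-like stack with depth attenuation.

    Parameters
    ----------
    fiber_density
        Fibers per cubic micrometre (density proxy).
    densified_layer
        Optional ``(z_lo_um, z_hi_um, amplification)``: within that depth
        slab the fiber density is multiplied by ``amplification``.
    attenuation_length
        Exponential decay length of the signal with depth, um.
    psf_sigma
        In-plane Gaussian blur SD (um), a point-spread-function stand-in.
    """
    if attenuation_length <= 0:
        raise InvalidArgumentError("attenuation_length must be positive")
    if fiber_density <= 0:
        raise InvalidArgumentError("fiber_density must be positive")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    # seeding volume is margin-extended by a fiber length per dimension
    L = fiber_length_um
    lat_y = ny * pixel_size_xy + L
    lat_x = nx * pixel_size_xy + L
    vol_um3 = (nz * step_z + L) * lat_y * lat_x
    vol = np.zeros(shape, dtype=float)
    _render_fibers(
        rng, vol, int(round(fiber_density * vol_um3)), fiber_length_um, pixel_size_xy, step_z
    )
    if densified_layer is not None:
        z_lo, z_hi, amp = densified_layer
        if amp <= 1 or z_hi <= z_lo:
            raise InvalidArgumentError("densified layer needs z_hi > z_lo and amplification > 1")
        slab_vol = (z_hi - z_lo + L) * lat_y * lat_x
        extra = int(round((amp - 1.0) * fiber_density * slab_vol))
        _render_fibers(
            rng, vol, extra, fiber_length_um, pixel_size_xy, step_z, z_range_um=(z_lo, z_hi)
        )
    sigma_px = psf_sigma / pixel_size_xy
    for z in range(nz):
        vol[z] = gaussian_filter(vol[z], sigma_px)
    vol *= 100.0  # arbitrary intensity scale
    depths = (np.arange(nz) * step_z)[:, None, None]
    vol *= np.exp(-depths / attenuation_length)
    if noise_sd > 0:
        vol += rng.normal(0.0, noise_sd, size=shape)
    vol = np.clip(vol, 0.0, None)
    return ImageStack(data=vol, pixel_size_xy=pixel_size_xy, step_z=step_z, channel="SHG")


def gen_spheroid_timelapse(
    radius_curve: SpheroidTrack,
    frame_size: int = 128,
    texture_contrast: float = 0.3,
    pixel_size_um: float = 1.126,
    base_intensity: float = 100.0,
    background_noise: float = 0.01,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Textured growing-disk frames emulating DIC time-lapse imaging.

    The disk radius follows ``radius_curve`` (radii in um, converted to
    pixels); inside the disk, pixel-scale Gaussian texture of fractional
    contrast ``texture_contrast`` is added and the mean intensity is
    attenuated in proportion to the contrast (spheroids appear darker than
    the surrounding gel); the background carries only a smooth low-amplitude
    field. At zero contrast the disk is invisible, emulating a failed
    acquisition. Returns ``(frames, true_radii_px)``.
    """
    radii_px = np.asarray(radius_curve.radii, dtype=float) / pixel_size_um
    if np.any(radii_px >= frame_size / 2):
        raise InvalidArgumentError("radius exceeds the frame half-width")
    rng = np.random.default_rng(seed)
    c = (frame_size - 1) / 2.0
    yy, xx = np.mgrid[0:frame_size, 0:frame_size]
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    frames = np.empty((radii_px.size, frame_size, frame_size), dtype=float)
    for i, r in enumerate(radii_px):
        bg = gaussian_filter(rng.normal(0, 1, (frame_size, frame_size)), 8.0)
        frame = base_intensity * (1.0 + background_noise * bg)
        inside = r2 < r * r
        texture = rng.normal(0, 1, (frame_size, frame_size))
        frame = frame - inside * 0.5 * texture_contrast * base_intensity
        frame = frame + inside * (texture_contrast * base_intensity) * texture
        frames[i] = frame
    return frames, radii_px


def manifest_count(design: ImagingDesign) -> int:
    """Total number of images in an imaging design (product of all counts)."""
    return (
        design.n_channels
        * design.images_per_stack
        * design.stacks_per_gel
        * design.gels_per_group
        * design.n_groups
        * design.n_concentrations
    )


def build_manifest(design: ImagingDesign) -> pd.DataFrame:
    """Enumerated image manifest (group, concentration, gel, stack, slice, channel)."""
    rows = pd.MultiIndex.from_product(
        [
            range(design.n_groups),
            range(design.n_concentrations),
            range(design.gels_per_group),
            range(design.stacks_per_gel),
            range(design.images_per_stack),
            range(design.n_channels),
        ],
        names=["group", "concentration", "gel", "stack", "slice", "channel"],
    )
    return rows.to_frame(index=False)


def write_ground_truth(data_path, truth: dict) -> Path:
    """Write the ground-truth sidecar JSON next to a synthetic dataset."""
    path = Path(str(data_path) + ".truth.json")
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=float)
    return path
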