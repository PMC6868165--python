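"""Matrix kinematics around a growing spheroid (expanding spherical inclusion).

A spheroid growing from initial radius ``a0`` to radius ``a`` inside an
infinite, isotropic, incompressible matrix displaces material points radially.
A point at material (undeformed) radius ``R >= a0`` moves to

    r^3 = R^3 + a^3 - a0^3,

which conserves matrix volume exactly. The principal stretch ratios are

    lambda_theta = lambda_phi = r / R        (tangential, tensile for growth)
    lambda_r     = (R / r)^2                 (radial, compressive for growth)

so that ``lambda_r * lambda_theta * lambda_phi = 1`` everywhere. At the
spheroid boundary (``R = a0``) these reduce to ``lambda_theta = a/a0`` and
``lambda_r = (a0/a)^2``. Growth therefore loads the peri-spheroidal matrix
radially in compression and tangentially in tension, the kinematic signature
of a densifying, tangentially aligned collagen capsule (TACS-2).

Only kinematics is computed here; no constitutive model is attached. A
compressible-inclusion variant is a deliberate extension hook
(:func:`stretch_field` takes the incompressible solution as its default and
single implementation).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from collagenmech.errors import InvalidArgumentError

__all__ = [
    "SpheroidTrack",
    "StretchTriplet",
    "boundary_stretches",
    "stretch_field",
    "track_to_stretches",
    "read_track",
    "write_track",
]


@dataclass(frozen=True)
class SpheroidTrack:
    """Spheroid radius time course.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing.
    radii
        Spheroid radii in micrometres, all positive.
    """

    times: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        if times.ndim != 1 or radii.ndim != 1 or times.size != radii.size:
            raise InvalidArgumentError("times and radii must be 1-D and equal length")
        if times.size == 0:
            raise InvalidArgumentError("track must contain at least one sample")
        if np.any(np.diff(times) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if np.any(radii <= 0):
            raise InvalidArgumentError("radii must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "radii", radii)

    @property
    def a0(self) -> float:
        """Initial (reference) radius in micrometres."""
        return float(self.radii[0])


@dataclass(frozen=True)
class StretchTriplet:
    """Principal stretch ratios (radial, polar, azimuthal) at one point."""

    lambda_r: float
    lambda_theta: float
    lambda_phi: float

    def __post_init__(self) -> None:
        if min(self.lambda_r, self.lambda_theta, self.lambda_phi) <= 0:
            raise InvalidArgumentError("stretch ratios must be positive")

    @property
    def volume_ratio(self) -> float:
        """Local volume ratio J = lambda_r * lambda_theta * lambda_phi."""
        return self.lambda_r * self.lambda_theta * self.lambda_phi


def boundary_stretches(a0: float, a: float) -> StretchTriplet:
    """Principal stretches in the matrix at the spheroid boundary.

    Parameters
    ----------
    a0, a
        Initial and current spheroid radius (micrometres, or any common unit).

    Returns
    -------
    StretchTriplet
        ``lambda_theta = lambda_phi = a/a0`` and ``lambda_r = (a0/a)**2``.
    """
    if a0 <= 0 or a <= 0:
        raise InvalidArgumentError("radii must be positive")
    lam_t = a / a0
    lam_r = (a0 / a) ** 2
    return StretchTriplet(lambda_r=lam_r, lambda_theta=lam_t, lambda_phi=lam_t)


def stretch_field(a0: float, a: float, R: float) -> StretchTriplet:
    """Principal stretches at material radius ``R >= a0`` around the spheroid.

    Uses the incompressible cavity-expansion map
    ``r**3 = R**3 + a**3 - a0**3``.
    """
    if a0 <= 0 or a <= 0:
        raise InvalidArgumentError("radii must be positive")
    if R < a0:
        raise InvalidArgumentError(f"material radius R={R} lies inside the spheroid (a0={a0})")
    r = (R**3 + a**3 - a0**3) ** (1.0 / 3.0)
    lam_t = r / R
    lam_r = (R / r) ** 2
    return StretchTriplet(lambda_r=lam_r, lambda_theta=lam_t, lambda_phi=lam_t)


def track_to_stretches(track: SpheroidTrack) -> pd.DataFrame:
    """Boundary stretch time series for a radius track.

    The reference radius is the first sample. Returns a DataFrame with columns
    ``time_s, radius_um, lambda_r, lambda_theta, lambda_phi``.
    """
    a0 = track.a0
    trips = [boundary_stretches(a0, a) for a in track.radii]
    return pd.DataFrame(
        {
            "time_s": track.times,
            "radius_um": track.radii,
            "lambda_r": [t.lambda_r for t in trips],
            "lambda_theta": [t.lambda_theta for t in trips],
            "lambda_phi": [t.lambda_phi for t in trips],
        }
    )


def read_track(path) -> SpheroidTrack:
    """Read a spheroid track from delimited text with columns time_s, radius_um."""
    df = pd.read_csv(path)
    return SpheroidTrack(times=df["time_s"].to_numpy(), radii=df["radius_um"].to_numpy())


def write_track(track: SpheroidTrack, path) -> None:
    """Write a spheroid track as delimited text (time_s, radius_um)."""
    pd.DataFrame({"time_s": track.times, "radius_um": track.radii}).to_csv(path, index=False)
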