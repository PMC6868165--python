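"""Continuous relaxation-time spectrum analysis of stress decays.

A stress-relaxation decay is modeled with a generalized Maxwell continuum,

    sigma(t) = sigma_e + integral H(tau) exp(-t/tau) d ln(tau),

where ``H(tau)`` is the continuous relaxation-time distribution and
``sigma_e`` the equilibrium stress. ``H`` is recovered on a log-spaced grid
of relaxation times (default 10 points per decade over [1e-2, 1e4] s) by
non-negative least squares with second-difference (curvature) Tikhonov
regularization on ln(tau):

    min || sigma - sigma_e - G H ||^2 + w || D2 H ||^2,   H >= 0, sigma_e >= 0,

with ``G_ij = exp(-t_i / tau_j) dln(tau)``. The regularization weight is
chosen by an L-curve corner search by default. The area under the spectrum,
``integral H dln(tau)`` (trapezoidal), recovers the total decaying stress
amplitude and serves as a dissipated-energy proxy; for well-separated modes
the area between flanking minima recovers each mode's amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.signal import find_peaks

from collagenmech.compression import (
    CompressionTrace,
    GelGeometry,
    StepProtocol,
    cauchy_stress,
    segment_steps,
    stretch_from_gap,
)
from collagenmech.errors import InvalidArgumentError

__all__ = [
    "RelaxationSpectrum",
    "fit_spectrum",
    "count_peaks",
    "spectrum_area",
    "peak_modes",
    "per_step_spectra",
]

TAU_MIN = 1e-2
TAU_MAX = 1e4


@dataclass(frozen=True)
class RelaxationSpectrum:
    """Discretized relaxation-time spectrum on a log grid.

    ``H`` is non-negative by construction; ``flagged`` marks fits where the
    signal contained no resolvable decay (zero spectrum returned).
    """

    tau: np.ndarray
    H: np.ndarray
    sigma_e: float
    reg_weight: float
    residual_rms: float
    flagged: bool = False

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        H = np.asarray(self.H, dtype=float)
        if tau.ndim != 1 or tau.shape != H.shape:
            raise InvalidArgumentError("tau and H must be 1-D and equal length")
        if np.any(np.diff(tau) <= 0):
            raise InvalidArgumentError("tau grid must be strictly increasing")
        if np.any(H < 0):
            raise InvalidArgumentError("H must be non-negative")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "H", H)

    @property
    def area(self) -> float:
        """Trapezoidal integral of H over ln(tau) (Pa)."""
        return spectrum_area(self)


def _log_subsample(n: int, max_points: int) -> np.ndarray:
    """Indices 0..n-1 thinned logarithmically (keeps early samples dense)."""
    if n <= max_points:
        return np.arange(n)
    idx = np.unique(np.round(np.geomspace(1, n, max_points)).astype(int) - 1)
    return idx


def _solve_nnls(G: np.ndarray, reg: np.ndarray, sigma: np.ndarray, w: float):
    A = np.vstack([G, np.sqrt(w) * reg])
    b = np.concatenate([sigma, np.zeros(reg.shape[0])])
    coef, _ = nnls(A, b)
    resid = sigma - G @ coef
    seminorm = float(np.linalg.norm(reg @ coef))
    return coef, float(np.linalg.norm(resid)), seminorm


def fit_spectrum(
    times: np.ndarray,
    stresses: np.ndarray,
    grid_points_per_decade: int = 10,
    reg_weight: Optional[float] = None,
    max_points: int = 2000,
) -> RelaxationSpectrum:
    """Invert a stress decay into a relaxation-time spectrum.

    Parameters
    ----------
    times, stresses
        Decay samples; time is re-zeroed at the first sample. At least 50
        samples spanning at least one decade of (positive) time are required.
    grid_points_per_decade
        Resolution of the log-spaced tau grid over [1e-2, 1e4] s.
    reg_weight
        Curvature penalty weight; ``None`` selects it by L-curve corner.
    max_points
        Long records are thinned logarithmically to this many samples before
        inversion (the early decay stays densely sampled).
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(stresses, dtype=float)
    if t.ndim != 1 or t.shape != s.shape:
        raise InvalidArgumentError("times and stresses must be 1-D and equal length")
    if t.size < 50:
        raise InvalidArgumentError("decay must contain at least 50 samples")
    t = t - t[0]
    pos = t[t > 0]
    if pos.size == 0 or pos[-1] / pos[0] < 10.0:
        raise InvalidArgumentError("decay must span at least one decade of time")

    idx = _log_subsample(t.size, max_points)
    t, s = t[idx], s[idx]

    n_decades = np.log10(TAU_MAX / TAU_MIN)
    m = int(round(n_decades * grid_points_per_decade)) + 1
    tau = np.logspace(np.log10(TAU_MIN), np.log10(TAU_MAX), m)
    dlntau = np.log(tau[1] / tau[0])

    G = np.exp(-t[:, None] / tau[None, :]) * dlntau
    G = np.hstack([G, np.ones((t.size, 1))])  # last column: sigma_e
    D2 = np.zeros((m - 2, m + 1))
    for i in range(m - 2):
        D2[i, i : i + 3] = (1.0, -2.0, 1.0)

    if reg_weight is not None:
        coef, rho, _ = _solve_nnls(G, D2, s, reg_weight)
        w = float(reg_weight)
    else:
        # L-curve corner: maximize curvature of (log residual, log seminorm)
        weights = np.logspace(-4, 3, 15) * max(1.0, float(np.ptp(s))) ** 2 * 1e-2
        sols = [_solve_nnls(G, D2, s, wi) for wi in weights]
        rho = np.log(np.maximum([r for _, r, _ in sols], 1e-300))
        eta = np.log(np.maximum([e for _, _, e in sols], 1e-300))
        # discrete curvature; endpoints excluded
        curv = np.full(len(weights), -np.inf)
        for i in range(1, len(weights) - 1):
            x1, x2, x3 = rho[i - 1], rho[i], rho[i + 1]
            y1, y2, y3 = eta[i - 1], eta[i], eta[i + 1]
            a = np.hypot(x2 - x1, y2 - y1)
            b = np.hypot(x3 - x2, y3 - y2)
            c = np.hypot(x3 - x1, y3 - y1)
            area2 = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
            if a * b * c > 0:
                curv[i] = 2.0 * area2 / (a * b * c)
        i_best = int(np.argmax(curv)) if np.isfinite(curv).any() else len(weights) // 2
        w = float(weights[i_best])
        coef, rho, _ = sols[i_best]

    H = coef[:-1]
    sigma_e = float(coef[-1])
    rms = float(rho / np.sqrt(t.size))
    area = float(np.trapezoid(H, np.log(tau)))
    flagged = area < 1e-6 * max(1.0, abs(sigma_e))
    if flagged:
        H = np.zeros_like(H)
    return RelaxationSpectrum(
        tau=tau, H=H, sigma_e=sigma_e, reg_weight=w, residual_rms=rms, flagged=flagged
    )


def count_peaks(spectrum: RelaxationSpectrum, prominence_floor: Optional[float] = None) -> int:
    """Number of local maxima of H with prominence >= floor (default 5% of max)."""
    H = spectrum.H
    if H.max() <= 0:
        return 0
    floor = 0.05 * H.max() if prominence_floor is None else float(prominence_floor)
    peaks, _ = find_peaks(H, prominence=floor)
    return int(peaks.size)


def spectrum_area(spectrum: RelaxationSpectrum) -> float:
    """Trapezoidal integral of H over ln(tau): total decaying amplitude (Pa)."""
    return float(np.trapezoid(spectrum.H, np.log(spectrum.tau)))


def peak_modes(
    spectrum: RelaxationSpectrum, prominence_floor: Optional[float] = None
) -> list[dict]:
    """Decompose the spectrum into modes around its peaks.

    Each detected peak is assigned the spectrum segment between the flanking
    minima (or grid ends); the segment's trapezoidal area recovers that
    mode's stress amplitude when modes are well separated. Returns a list of
    dicts with ``tau_peak``, ``H_peak``, ``prominence``, ``area`` ordered by
    increasing tau.
    """
    H = spectrum.H
    if H.max() <= 0:
        return []
    floor = 0.05 * H.max() if prominence_floor is None else float(prominence_floor)
    peaks, props = find_peaks(H, prominence=floor)
    if peaks.size == 0:
        return []
    lntau = np.log(spectrum.tau)
    # segment boundaries: minima between consecutive peaks
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(int(a + np.argmin(H[a : b + 1])))
    bounds.append(H.size - 1)
    modes = []
    for j, p in enumerate(peaks):
        lo, hi = bounds[j], bounds[j + 1]
        modes.append(
            {
                "tau_peak": float(spectrum.tau[p]),
                "H_peak": float(H[p]),
                "prominence": float(props["prominences"][j]),
                "area": float(np.trapezoid(H[lo : hi + 1], lntau[lo : hi + 1])),
            }
        )
    return modes


def per_step_spectra(
    trace: CompressionTrace,
    protocol: StepProtocol,
    geometry: Optional[GelGeometry] = None,
    **fit_kwargs,
) -> list[dict]:
    """Fit a relaxation spectrum to each hold phase of a staircase trace.

    The hold's time axis is re-zeroed at the hold start and the measured
    force converted to compressive Cauchy stress. Returns one dict per hold
    with ``step``, ``strain`` (1 - lambda at equilibrium), ``spectrum`` and
    ``area``. Holds shorter than ten times the smallest grid tau trigger a
    warning (the short-time decades are then unconstrained).
    """
    geometry = geometry or GelGeometry()
    out = []
    for i, step in enumerate(segment_steps(trace, protocol)):
        if step.hold is None:
            continue
        t = trace.time[step.hold]
        if t[-1] - t[0] < 10.0 * TAU_MIN:
            warnings.warn(f"hold {i + 1} shorter than the smallest tau decade")
        s = cauchy_stress(trace.force[step.hold], geometry)
        spec = fit_spectrum(t, s, **fit_kwargs)
        lam = float(np.mean(stretch_from_gap(trace.gap[step.hold], geometry)))
        out.append(
            {
                "step": i + 1,
                "strain": 1.0 - lam,
                "spectrum": spec,
                "area": spec.area,
            }
        )
    if not out:
        raise InvalidArgumentError("trace contains no hold phases")
    return out
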