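"""Confined-compression data model and preprocessing.

A cylindrical collagen gel of unloaded thickness ``H`` is compressed axially
by a porous indenter of diameter ``D`` inside a rigid impermeable chamber.
The rheometer records gap height and axial force at nominally 100 Hz. The
conversions used throughout are

    compressive stress   -sigma = (f - f_off) / (pi D^2 / 4)
    deformed thickness   h      = gap - coverslip_thickness
    axial stretch        lambda = h / H

with the convention that the Cauchy stress sigma is positive in tension and
negative in compression. A staircase protocol (default 3% strain steps at
1%/s, 180 s holds) is segmented into (ramp, hold) phases from the gap signal,
and per-hold equilibrium points are taken as the average of the last 60 s of
each hold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from collagenmech.errors import InvalidArgumentError

__all__ = [
    "GelGeometry",
    "CompressionTrace",
    "StepProtocol",
    "EquilibriumPoint",
    "Step",
    "cauchy_stress",
    "stretch_from_gap",
    "segment_steps",
    "equilibrium_points",
    "peak_forces",
    "read_trace",
    "write_trace",
]


@dataclass(frozen=True)
class GelGeometry:
    """Geometry and force offset of one confined-compression experiment.

    All lengths in metres, force offset in newtons. Defaults follow the
    standard setup: 3 mm gels under an 8 mm porous indenter on a 170 um
    coverslip.
    """

    unloaded_thickness: float = 3.0e-3
    indenter_diameter: float = 8.0e-3
    coverslip_thickness: float = 1.7e-4
    force_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.unloaded_thickness <= 0 or self.indenter_diameter <= 0:
            raise InvalidArgumentError("thickness and diameter must be positive")
        if self.coverslip_thickness <= 0:
            raise InvalidArgumentError("coverslip thickness must be positive")

    @property
    def indenter_area(self) -> float:
        """Indenter cross-section pi*D^2/4 in m^2."""
        return np.pi * self.indenter_diameter**2 / 4.0


@dataclass(frozen=True)
class CompressionTrace:
    """Time-stamped gap height and axial force record (SI units)."""

    time: np.ndarray
    gap: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        g = np.asarray(self.gap, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if not (t.shape == g.shape == f.shape) or t.ndim != 1:
            raise InvalidArgumentError("time, gap, force must be 1-D and equal length")
        if t.size < 2:
            raise InvalidArgumentError("trace must contain at least two samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")
        if np.any(g <= 0):
            raise InvalidArgumentError("gap heights must be positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "gap", g)
        object.__setattr__(self, "force", f)

    @property
    def sample_rate(self) -> float:
        """Median sampling rate in Hz."""
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass(frozen=True)
class StepProtocol:
    """Staircase compression protocol.

    ``step_strain`` is the engineering strain per step (fraction of H),
    applied at ``ramp_rate`` (strain fraction per second) and followed by a
    constant-gap hold of ``hold_duration`` seconds.
    """

    step_strain: float = 0.03
    ramp_rate: float = 0.01
    hold_duration: float = 180.0
    n_steps: int = 6

    def __post_init__(self) -> None:
        if not (0 < self.step_strain < 1):
            raise InvalidArgumentError("step_strain must lie in (0, 1)")
        if self.ramp_rate <= 0 or self.hold_duration <= 0 or self.n_steps < 1:
            raise InvalidArgumentError("ramp_rate, hold_duration, n_steps must be positive")

    @property
    def ramp_duration(self) -> float:
        return self.step_strain / self.ramp_rate

    def target_stretches(self) -> np.ndarray:
        """Nominal stretch after each step: 1 - i*step_strain."""
        return 1.0 - self.step_strain * np.arange(1, self.n_steps + 1)

    def thickness_history(self, H: float):
        """Piecewise-linear deformed thickness h(t) and its breakpoints.

        Returns ``(breaks, values)`` suitable for ``np.interp``: breakpoints
        at phase boundaries and the thickness at each.
        """
        breaks = [0.0]
        values = [H]
        for lam in self.target_stretches():
            breaks.append(breaks[-1] + self.ramp_duration)
            values.append(lam * H)
            breaks.append(breaks[-1] + self.hold_duration)
            values.append(lam * H)
        return np.asarray(breaks), np.asarray(values)


@dataclass(frozen=True)
class EquilibriumPoint:
    """Equilibrated (stretch, Cauchy stress) pair from one hold phase.

    ``stress`` follows the tension-positive convention, so it is negative
    under compression.
    """

    stretch: float
    stress: float

    def __post_init__(self) -> None:
        if self.stretch <= 0:
            raise InvalidArgumentError("stretch must be positive")


@dataclass(frozen=True)
class Step:
    """Index ranges of one protocol step: a ramp and its (optional) hold."""

    ramp: slice
    hold: Optional[slice] = None


def cauchy_stress(force, geometry: GelGeometry):
    """Compressive Cauchy stress, reported positive: -sigma = (f - f_off)/(pi D^2/4)."""
    return (np.asarray(force, dtype=float) - geometry.force_offset) / geometry.indenter_area


def stretch_from_gap(gap, geometry: GelGeometry):
    """Axial stretch lambda = (gap - coverslip)/H. Raises if gap <= coverslip."""
    gap = np.asarray(gap, dtype=float)
    if np.any(gap <= geometry.coverslip_thickness):
        raise InvalidArgumentError("gap must exceed the coverslip thickness")
    return (gap - geometry.coverslip_thickness) / geometry.unloaded_thickness


def segment_steps(trace: CompressionTrace, protocol: StepProtocol) -> list[Step]:
    """Segment the gap signal into (ramp, hold) phases.

    A sample belongs to a ramp when the gap decreases faster than 1% of the
    nominal ramp speed, estimated from a ~1 s smoothed derivative; contiguous
    runs are then paired ramp -> following hold. At most ``protocol.n_steps``
    steps are returned. Any hold preceding the first ramp (pre-contact
    baseline) is discarded.
    """
    from scipy.ndimage import uniform_filter1d

    fs = trace.sample_rate
    win = max(1, int(round(fs)))  # ~1 s window
    gap_s = uniform_filter1d(trace.gap, size=win, mode="nearest")
    # slope over a full-window baseline: pointwise gradients are far too
    # noisy relative to the 1%-of-ramp-rate threshold
    h = win
    dgap = np.gradient(gap_s, trace.time)
    if trace.time.size > 2 * h:
        dgap[h:-h] = (gap_s[2 * h :] - gap_s[: -2 * h]) / (
            trace.time[2 * h :] - trace.time[: -2 * h]
        )
        dgap[:h] = dgap[h]
        dgap[-h:] = dgap[-h - 1]
    ramp_speed = protocol.ramp_rate * float(trace.gap[0])  # nominal m/s scale
    is_ramp = dgap < -0.01 * ramp_speed
    # majority vote over the window removes single-sample glitches
    is_ramp = uniform_filter1d(is_ramp.astype(float), size=max(3, win), mode="nearest") > 0.5

    # contiguous runs
    runs: list[tuple[bool, int, int]] = []
    start = 0
    for i in range(1, is_ramp.size + 1):
        if i == is_ramp.size or is_ramp[i] != is_ramp[start]:
            runs.append((bool(is_ramp[start]), start, i))
            start = i

    steps: list[Step] = []
    i = 0
    while i < len(runs) and len(steps) < protocol.n_steps:
        flag, s, e = runs[i]
        if not flag:
            i += 1
            continue
        hold = None
        if i + 1 < len(runs) and not runs[i + 1][0]:
            hold = slice(runs[i + 1][1], runs[i + 1][2])
            i += 2
        else:
            i += 1
        steps.append(Step(ramp=slice(s, e), hold=hold))
    if not steps:
        raise InvalidArgumentError("no compression steps detected in trace")
    return steps


def equilibrium_points(
    trace: CompressionTrace,
    protocol: StepProtocol,
    geometry: GelGeometry,
    window_s: float = 60.0,
) -> list[EquilibriumPoint]:
    """Per-hold equilibrium (stretch, Cauchy stress) pairs.

    Stretch and stress are averaged over the final ``window_s`` seconds of
    each hold (fallback: final third if the hold is shorter, with a warning).
    Stress is tension-positive, so compressive holds give negative values.
    """
    pts: list[EquilibriumPoint] = []
    for step in segment_steps(trace, protocol):
        if step.hold is None:
            continue
        t = trace.time[step.hold]
        dur = t[-1] - t[0]
        if dur >= window_s:
            sel = t >= t[-1] - window_s
        else:
            warnings.warn(
                f"hold of {dur:.1f}s shorter than {window_s:.0f}s averaging window;"
                " using final third",
                stacklevel=2,
            )
            sel = t >= t[-1] - dur / 3.0
        gap = float(np.mean(trace.gap[step.hold][sel]))
        force = float(np.mean(trace.force[step.hold][sel]))
        lam = float(stretch_from_gap(gap, geometry))
        sigma = -float(cauchy_stress(force, geometry))
        pts.append(EquilibriumPoint(stretch=lam, stress=sigma))
    if not pts:
        raise InvalidArgumentError("trace contains no hold phases")
    return pts


def peak_forces(
    trace: CompressionTrace,
    protocol: StepProtocol,
    early_hold_s: float = 1.0,
) -> pd.DataFrame:
    """Per-step peak force over the ramp plus early hold.

    Returns a DataFrame with the global per-step maximum (default report) and
    the force at the end of the ramp, per step.
    """
    rows = []
    for i, step in enumerate(segment_steps(trace, protocol)):
        idx_end = step.ramp.stop - 1
        stop = step.ramp.stop
        if step.hold is not None:
            t_hold = trace.time[step.hold]
            stop = step.hold.start + int(np.searchsorted(t_hold, t_hold[0] + early_hold_s))
        window = trace.force[step.ramp.start : max(stop, step.ramp.stop)]
        rows.append(
            {
                "step": i + 1,
                "peak_force_N": float(np.max(window)),
                "ramp_end_force_N": float(trace.force[idx_end]),
            }
        )
    return pd.DataFrame(rows)


def read_trace(path) -> CompressionTrace:
    """Read a trace from delimited text with columns time_s, gap_m, force_N.

    Duplicate timestamps are dropped (first kept) with a warning.
    """
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    keep = np.concatenate([[True], np.diff(t) > 0])
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} duplicate/non-monotonic timestamps")
    return CompressionTrace(
        time=t[keep],
        gap=df["gap_m"].to_numpy(dtype=float)[keep],
        force=df["force_N"].to_numpy(dtype=float)[keep],
    )


def write_trace(trace: CompressionTrace, path) -> None:
    """Write a trace as delimited text (time_s, gap_m, force_N)."""
    pd.DataFrame(
        {"time_s": trace.time, "gap_m": trace.gap, "force_N": trace.force}
    ).to_csv(path, index=False)
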