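"""Nonlinear biphasic (poroelastic) model of confined compression.

The gel is a mixture of an intrinsically incompressible solid network and
interstitial fluid. In confined compression the kinematics are 1-D: a
material point at height ``Z`` (``Z = 0`` at the porous indenter, ``Z = H``
at the impermeable bottom) carries a local axial stretch ``lambda(Z, t)``.
The solid network stress derives from the Yeoh strain-energy function

    W = c1 (I - 3) + c2 (I - 3)^2 + c3 (I - 3)^3,    I = lambda^2 + 2,

with constraints ``c1, c3 > 0`` and ``c2 < 0``, and the effective axial
solid stress is taken as

    sigma_e(lambda) = (2 / lambda) W'(I) (lambda^2 - 1),

which vanishes at lambda = 1, is compressive for lambda < 1, and linearizes
to an aggregate modulus ``H_A = 4 c1``. Fluid transport follows Darcy's law
with a constant isotropic hydraulic permeability ``k`` (m^4 N^-1 s^-1)
applied in the material frame. Mixture equilibrium makes the total stress
``sigma_ZZ(t) = sigma_e - p`` uniform in ``Z``; with free draining at the
indenter (``p(0,t) = 0``) and no flux at the bottom, mass balance gives a
nonlinear diffusion equation

    d(lambda)/dt = d/dZ [ k d(sigma_e(lambda))/dZ ],

driven through a flux boundary condition by the prescribed thickness
history ``h(t)`` (``k d(sigma_e)/dZ|_{Z=0} = -dh/dt``). The measured
boundary stress is ``sigma_e`` evaluated at the drained face and the pore
pressure field is ``p = sigma_e(lambda) - sigma_ZZ``.

Parameters are estimated with a two-step procedure: the Yeoh coefficients
from the equilibrium stress-stretch points (constrained least squares), then
the permeability from the pooled transient response (scalar search in
log10 k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, minimize_scalar

from collagenmech.compression import (
    CompressionTrace,
    EquilibriumPoint,
    GelGeometry,
    StepProtocol,
    cauchy_stress,
    segment_steps,
)
from collagenmech.errors import InvalidArgumentError, SolverError

__all__ = [
    "BiphasicParams",
    "ConsolidationSolution",
    "yeoh_energy",
    "yeoh_stress",
    "shear_modulus",
    "solve_confined_compression",
    "pressure_at_bottom",
    "linear_consolidation_stress",
    "EquilibriumFit",
    "TransientFit",
    "fit_equilibrium",
    "fit_transient",
    "two_step_fit",
]


@dataclass(frozen=True)
class BiphasicParams:
    """Yeoh coefficients (Pa) and hydraulic permeability (m^4 N^-1 s^-1).

    The admissibility constraints ``c1, c3 > 0``, ``c2 < 0``, ``k > 0`` are
    enforced at construction.
    """

    c1: float
    c2: float
    c3: float
    k: float

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c3 <= 0:
            raise InvalidArgumentError("c1 and c3 must be positive")
        if self.c2 >= 0:
            raise InvalidArgumentError("c2 must be negative")
        if self.k <= 0:
            raise InvalidArgumentError("permeability k must be positive")

    @property
    def aggregate_modulus(self) -> float:
        """Small-strain aggregate modulus H_A = 4 c1 (Pa)."""
        return 4.0 * self.c1


def _invariant_excess(lam):
    """I - 3 for confined uniaxial kinematics (I = lambda^2 + 2)."""
    lam = np.asarray(lam, dtype=float)
    return lam * lam - 1.0


def _dW(c1: float, c2: float, c3: float, lam):
    x = _invariant_excess(lam)
    return c1 + 2.0 * c2 * x + 3.0 * c3 * x * x


def yeoh_energy(params: BiphasicParams, lam):
    """Strain-energy density W(lambda) in Pa (zero at lambda = 1)."""
    x = _invariant_excess(lam)
    return params.c1 * x + params.c2 * x**2 + params.c3 * x**3


def yeoh_stress(params: BiphasicParams, lam):
    """Effective axial solid Cauchy stress sigma_e(lambda), tension-positive."""
    lam = np.asarray(lam, dtype=float)
    return (2.0 / lam) * _dW(params.c1, params.c2, params.c3, lam) * (lam * lam - 1.0)


def _yeoh_stress_coeffs(c1: float, c2: float, c3: float, lam):
    """sigma_e from raw coefficients (used inside fits before params exist)."""
    lam = np.asarray(lam, dtype=float)
    return (2.0 / lam) * _dW(c1, c2, c3, lam) * (lam * lam - 1.0)


def shear_modulus(params: BiphasicParams, lam):
    """Strain-dependent shear modulus mu(lambda) = 2 W'(I); mu(1) = 2 c1."""
    return 2.0 * _dW(params.c1, params.c2, params.c3, lam)


@dataclass(frozen=True)
class ConsolidationSolution:
    """Space-time solution of one confined-compression simulation.

    Attributes
    ----------
    Z
        Material cell-centre coordinates in [0, H] (m).
    times
        Output times (s).
    lam
        Local stretch, shape (n_times, n_cells).
    pressure
        Pore pressure p(Z, t) in Pa, shape (n_times, n_cells); zero at the
        drained face by construction.
    sigma_zz0
        Total axial Cauchy stress at the indenter face (Pa, negative under
        compression) — the model counterpart of the measured stress.
    thickness
        Prescribed deformed thickness h(t) (m).
    """

    Z: np.ndarray
    times: np.ndarray
    lam: np.ndarray
    pressure: np.ndarray
    sigma_zz0: np.ndarray
    thickness: np.ndarray
    params: BiphasicParams
    geometry: GelGeometry

    def thickness_residual(self) -> np.ndarray:
        """Mass-conservation audit: integral of lambda dZ minus h(t), per time."""
        dZ = self.Z[1] - self.Z[0]
        return self.lam.sum(axis=1) * dZ - self.thickness


def _default_t_eval(protocol: StepProtocol) -> np.ndarray:
    """Ramp-resolving, hold-log-spaced default output grid."""
    ts: list[np.ndarray] = [np.array([0.0])]
    t = 0.0
    for _ in range(protocol.n_steps):
        ts.append(np.linspace(t, t + protocol.ramp_duration, 25)[1:])
        t += protocol.ramp_duration
        hold = np.geomspace(protocol.hold_duration * 1e-3, protocol.hold_duration, 120)
        ts.append(t + hold)
        t += protocol.hold_duration
    return np.concatenate(ts)


def solve_confined_compression(
    params: BiphasicParams,
    protocol: StepProtocol,
    geometry: GelGeometry,
    n_spatial_nodes: int = 60,
    t_eval: Optional[np.ndarray] = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> ConsolidationSolution:
    """Forward-simulate the staircase confined-compression experiment.

    Finite-volume method of lines on a uniform material grid: fluxes
    ``F = k d(sigma_e)/dZ`` at cell faces, a prescribed flux ``-dh/dt`` at
    the drained face and zero flux at the bottom, integrated phase-by-phase
    (ramps and holds) with LSODA. The scheme conserves ``integral(lambda) dZ
    = h(t)`` to integrator tolerance.
    """
    if n_spatial_nodes < 4:
        raise InvalidArgumentError("need at least 4 spatial cells")
    H = geometry.unloaded_thickness
    N = int(n_spatial_nodes)
    dZ = H / N
    Zc = (np.arange(N) + 0.5) * dZ
    k = params.k

    breaks, values = protocol.thickness_history(H)
    if t_eval is None:
        t_eval = _default_t_eval(protocol)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.size and (t_eval[0] < -1e-12 or t_eval[-1] > breaks[-1] + 1e-9):
        raise InvalidArgumentError("t_eval must lie within the protocol duration")

    def rhs(t, lam, hdot):
        sig = _yeoh_stress_coeffs(params.c1, params.c2, params.c3, lam)
        flux = np.empty(lam.size + 1)
        flux[0] = -hdot
        flux[-1] = 0.0
        flux[1:-1] = k * (sig[1:] - sig[:-1]) / dZ
        return (flux[1:] - flux[:-1]) / dZ

    lam = np.ones(N)
    out_t: list[float] = []
    out_lam: list[np.ndarray] = []
    out_hdot: list[float] = []
    for i in range(len(breaks) - 1):
        t0, t1 = breaks[i], breaks[i + 1]
        hdot = (values[i + 1] - values[i]) / (t1 - t0)
        sel = (t_eval >= t0 - 1e-12) & (t_eval < t1 - 1e-12)
        if i == len(breaks) - 2:
            sel = (t_eval >= t0 - 1e-12) & (t_eval <= t1 + 1e-9)
        phase_pts = np.clip(t_eval[sel], t0, t1)
        grid = np.unique(np.concatenate([phase_pts, [t0, t1]]))
        sol = solve_ivp(
            rhs,
            (t0, t1),
            lam,
            method="LSODA",
            t_eval=grid,
            rtol=rtol,
            atol=atol,
            args=(hdot,),
        )
        if sol.status != 0:
            raise SolverError(f"consolidation integration failed in phase {i}: {sol.message}")
        interp = {t: sol.y[:, j] for j, t in enumerate(sol.t)}
        for t in phase_pts:
            out_t.append(float(t))
            out_lam.append(interp[t])
            out_hdot.append(hdot)
        lam = sol.y[:, -1]

    times = np.asarray(out_t)
    lam_mat = np.vstack(out_lam) if out_lam else np.empty((0, N))
    hdots = np.asarray(out_hdot)

    sig = _yeoh_stress_coeffs(params.c1, params.c2, params.c3, lam_mat)
    # extrapolate sigma_e to the drained face using the known boundary flux
    sigma_face = sig[:, 0] - 0.5 * dZ * (-hdots) / k
    pressure = sig - sigma_face[:, None]
    h_t = np.interp(times, breaks, values)
    return ConsolidationSolution(
        Z=Zc,
        times=times,
        lam=lam_mat,
        pressure=pressure,
        sigma_zz0=sigma_face,
        thickness=h_t,
        params=params,
        geometry=geometry,
    )


def pressure_at_bottom(solution: ConsolidationSolution, decay_fraction: float = 0.1) -> dict:
    """Pore pressure time course at the bottom of the chamber (Z = H).

    Returns a dict with the time series plus the peak pressure and the decay
    time: the time after the peak at which the pressure first falls below
    ``decay_fraction`` of the peak (NaN if it never does). The default 10%
    level probes the consolidation tail rather than the relaxation of the
    ramp-end spike.
    """
    p_bottom = solution.pressure[:, -1]
    i_peak = int(np.argmax(p_bottom))
    peak = float(p_bottom[i_peak])
    decay_time = float("nan")
    below = np.nonzero(p_bottom[i_peak:] <= decay_fraction * peak)[0]
    if peak > 0 and below.size:
        decay_time = float(solution.times[i_peak + below[0]] - solution.times[i_peak])
    return {
        "times": solution.times,
        "pressure": p_bottom,
        "peak_pressure": peak,
        "peak_time": float(solution.times[i_peak]),
        "decay_time": decay_time,
    }


def linear_consolidation_stress(
    H_A: float,
    k: float,
    H: float,
    step_strain: float,
    ramp_duration: float,
    times: np.ndarray,
    n_terms: int = 20000,
) -> np.ndarray:
    """Closed-form boundary stress of linear (Terzaghi-type) consolidation.

    Single ramp of engineering strain ``step_strain`` applied over
    ``ramp_duration`` then held, with free draining at the loaded face and an
    impermeable base. Returns the compressive stress (positive) at the
    drained face, from the classical cosine eigenfunction series with the
    ramp applied by Duhamel superposition. The consolidation time constant is
    ``tau = H^2 / (H_A k)``.

    This expression is independent of the nonlinear solver and serves as its
    small-strain oracle.
    """
    times = np.asarray(times, dtype=float)
    tau = H * H / (H_A * k)
    r = step_strain / ramp_duration  # strain rate
    n = np.arange(1, n_terms + 1)
    mu = (n * np.pi) ** 2 / tau  # modal decay rates
    strain = r * np.minimum(times, ramp_duration)
    transient = np.empty_like(times)
    for i, t in enumerate(times):
        if t <= ramp_duration:
            terms = (1.0 - np.exp(-mu * t)) / mu
        else:
            terms = np.exp(-mu * (t - ramp_duration)) * (1.0 - np.exp(-mu * ramp_duration)) / mu
        transient[i] = 2.0 * r * np.sum(terms)
    return H_A * (strain + transient)


# ---------------------------------------------------------------------------
# Two-step parameter estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EquilibriumFit:
    """Result of the Yeoh equilibrium fit."""

    c1: float
    c2: float
    c3: float
    residual_rms: float
    at_bound: bool

    def coefficients(self) -> tuple[float, float, float]:
        return (self.c1, self.c2, self.c3)


@dataclass(frozen=True)
class TransientFit:
    """Result of the permeability fit to pooled transient data."""

    k: float
    log10_k: float
    sse: float
    n_points: int
    at_bound: bool


def fit_equilibrium(points: Sequence[EquilibriumPoint]) -> EquilibriumFit:
    """Constrained least-squares fit of the Yeoh stress to equilibrium points.

    Minimizes sum of squared stress residuals over ``c1, c3 > 0``,
    ``c2 < 0`` with a deterministic grid of starting points. Solutions with a
    coefficient pinned at its admissibility bound are flagged.
    """
    if len(points) < 3:
        raise InvalidArgumentError("equilibrium fit requires at least 3 points")
    lam = np.array([p.stretch for p in points])
    sig = np.array([p.stress for p in points])

    def resid(c):
        return _yeoh_stress_coeffs(c[0], c[1], c[2], lam) - sig

    # scale from the secant slope at the first point (H_A ~ 4 c1)
    slope = sig[0] / (lam[0] - 1.0) if abs(lam[0] - 1.0) > 1e-12 else 0.0
    c1_scale = max(abs(slope) / 4.0, 1.0)
    lb = np.array([1e-9, -np.inf, 1e-9])
    ub = np.array([np.inf, -1e-9, np.inf])
    best = None
    for f1 in (0.5, 1.0, 2.0):
        for f2 in (0.1, 1.0):
            for f3 in (1.0, 10.0):
                x0 = np.array([c1_scale * f1, -c1_scale * f2, c1_scale * f3])
                sol = least_squares(resid, x0, bounds=(lb, ub), method="trf")
                if best is None or sol.cost < best.cost:
                    best = sol
    c1, c2, c3 = best.x
    # flag solutions pinned at (or collapsed toward) the admissibility
    # bounds; 1e-3 Pa is far below any physical gel stiffness
    at_bound = bool(c1 < max(1e-6 * c1_scale, 1e-3) or c2 > -1e-6 * c1_scale or c3 < 1e-8)
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    if at_bound:
        warnings.warn("equilibrium fit hit an admissibility bound; result flagged")
    return EquilibriumFit(c1=float(c1), c2=float(c2), c3=float(c3), residual_rms=rms, at_bound=at_bound)


def fit_transient(
    trace: CompressionTrace,
    material: tuple[float, float, float],
    geometry: GelGeometry,
    protocol: StepProtocol,
    log10_k_bounds: tuple[float, float] = (-14.0, -8.0),
    n_spatial_nodes: int = 40,
    max_points: int = 1200,
) -> TransientFit:
    """Estimate the permeability from the pooled transient response.

    With the Yeoh coefficients fixed, minimizes the summed squared difference
    between the model boundary stress and the measured stress over all
    compression steps, searching ``log10 k`` on a bounded interval with a
    deterministic scalar optimizer. Points are pooled with equal weight
    (uniform subsampling of the trace).
    """
    c1, c2, c3 = material
    steps = segment_steps(trace, protocol)
    i0 = steps[0].ramp.start
    t_rel = trace.time[i0:] - trace.time[i0]
    total = protocol.n_steps * (protocol.ramp_duration + protocol.hold_duration)
    keep = t_rel <= total
    t_rel = t_rel[keep]
    stress_exp = cauchy_stress(trace.force[i0:][keep], geometry)  # positive compressive
    stride = max(1, t_rel.size // max_points)
    t_sub = t_rel[::stride]
    s_sub = stress_exp[::stride]

    def sse(log10_k: float) -> float:
        params = BiphasicParams(c1=c1, c2=c2, c3=c3, k=10.0**log10_k)
        sol = solve_confined_compression(
            params, protocol, geometry, n_spatial_nodes=n_spatial_nodes, t_eval=t_sub
        )
        model = -sol.sigma_zz0  # positive compressive
        return float(np.sum((model - s_sub) ** 2))

    lo, hi = log10_k_bounds
    edge = (sse(lo), sse(hi))
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded", options={"xatol": 5e-4})
    if not res.success:
        raise SolverError(f"permeability search failed: {res.message}")
    if max(edge) - res.fun <= 1e-9 * max(res.fun, 1e-30):
        raise SolverError(
            "objective is flat in k over the search interval; "
            f"sse range [{res.fun:.3e}, {max(edge):.3e}]"
        )
    at_bound = bool(res.x - lo < 0.05 or hi - res.x < 0.05)
    if at_bound:
        warnings.warn("permeability estimate at the edge of the search interval; flagged")
    return TransientFit(
        k=float(10.0**res.x),
        log10_k=float(res.x),
        sse=float(res.fun),
        n_points=int(t_sub.size),
        at_bound=at_bound,
    )


def two_step_fit(
    trace: CompressionTrace,
    geometry: GelGeometry,
    protocol: StepProtocol,
    **transient_kwargs,
) -> tuple[BiphasicParams, EquilibriumFit, TransientFit]:
    """Full two-step estimation: Yeoh coefficients then permeability.

    Deterministic given the input trace; returns the assembled parameter set
    together with both stage reports.
    """
    from collagenmech.compression import equilibrium_points

    eq_pts = equilibrium_points(trace, protocol, geometry)
    eq = fit_equilibrium(eq_pts)
    tr = fit_transient(trace, eq.coefficients(), geometry, protocol, **transient_kwargs)
    params = BiphasicParams(c1=eq.c1, c2=eq.c2, c3=eq.c3, k=tr.k)
    return params, eq, tr
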