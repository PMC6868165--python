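# Methods notes

This note records the models implemented in `collagenmech`, the assumptions
behind them, the defaults of the synthetic-data generators, and the numerical
and design choices that were genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Spheroid kinematics (`collagenmech.kinematics`)

A growing spheroid is modeled as an expanding spherical inclusion in an
infinite, isotropic, **incompressible** matrix. A material point at
undeformed radius `R ≥ a0` moves to `r` with `r³ = R³ + a³ − a0³`, giving
principal stretches `λ_θ = λ_φ = r/R` and `λ_r = (R/r)²`, so
`λ_r·λ_θ·λ_φ = 1` exactly everywhere. At the boundary this reduces to
`λ_θ = a/a0`, `λ_r = (a0/a)²`: growth compresses the matrix radially and
stretches it tangentially — the kinematic signature of a densifying,
tangentially aligned collagen capsule.

*Design choice.* Whether the matrix should be treated as compressible or
poroelastic is open; the incompressible cavity-expansion solution is the
unique parameter-free choice consistent with radially-compressive /
tangentially-tensile boundary behavior, and it is what the package
implements. The API isolates the map in `stretch_field` so a compressible
variant can be swapped in without touching callers.

## Confined compression data model (`collagenmech.compression`)

Stress and stretch conversions follow the standard confined-compression
conventions: compressive stress `−σ = (f − f_off)/(πD²/4)` with `D = 8 mm`
by default, and `λ = (gap − coverslip)/H` with `H = 3 mm`. Default staircase
protocol: 3% strain steps at 1%/s, 180 s holds, 100 Hz sampling.

Step segmentation classifies a sample as *hold* when the gap slope over a
~1 s baseline stays within 1% of the nominal ramp speed, with a 1 s
majority vote to reject glitches. Pointwise derivatives at 100 Hz are far
too noisy for a 1% threshold (micrometre-level gap noise exceeds it by an
order of magnitude), hence the windowed slope. Equilibrium points average
the final 60 s of each hold; holds shorter than 60 s fall back to the final
third with a warning.

## Relaxation-time spectra (`collagenmech.spectrum`)

The decay is modeled as
`σ(t) = σ_e + ∫ H(τ) e^{−t/τ} d ln τ` with `H ≥ 0` on a log grid of
relaxation times spanning `10⁻²…10⁴ s` (10 points per decade, 61 nodes by
default). The inversion is a non-negative least squares problem with a
second-difference (curvature) Tikhonov penalty on `ln τ`; `σ_e ≥ 0` is
fitted jointly as an extra column rather than pinned to the last sample,
because holds need not fully equilibrate. The regularization weight is
chosen by an L-curve corner search over a fixed log-spaced ladder scaled to
the signal's squared dynamic range; it can also be supplied explicitly.
Long records are thinned logarithmically to ≤2000 samples before inversion
(the early decay stays dense), which conditions the design matrix without
losing short-τ information.

The area `∫H d ln τ` (trapezoidal) is the total decaying amplitude and
serves as the dissipated-energy proxy; the area between flanking minima of
each detected peak recovers that mode's amplitude when modes are well
separated (≳1.5 decades). Peak counting uses a prominence floor of 5% of
the spectrum maximum by default.

*Limits.* Modes closer than about one decade merge under curvature
regularization; τ outside the sampled time window is recovered only as mass
at the nearest grid edge. These are intrinsic to the ill-posed inversion,
not implementation artifacts.

## Biphasic confined-compression model (`collagenmech.biphasic`)

The gel is an incompressible solid network plus interstitial fluid. In 1-D
confined compression with material coordinate `Z ∈ [0, H]` (Z = 0 at the
porous indenter):

* Solid stress from the Yeoh energy `W = c1(I−3) + c2(I−3)² + c3(I−3)³`,
  `I = λ² + 2`, with admissibility `c1, c3 > 0`, `c2 < 0`. The effective
  axial stress form used is `σ_e(λ) = (2/λ) W′(I) (λ² − 1)`: it vanishes at
  `λ = 1`, is compressive for `λ < 1`, and linearizes to an aggregate
  modulus `H_A = 4c1`. The exact reduction of the Yeoh 3-D stress to the
  confined 1-D axial component admits more than one convention; this form is
  isolated in one function so alternatives can be swapped, and all recovery
  machinery is self-consistent with whichever form is configured.
* Darcy flow with constant isotropic permeability `k` (m⁴ N⁻¹ s⁻¹) applied
  in the material frame, giving the nonlinear diffusion equation
  `∂λ/∂t = ∂/∂Z (k ∂σ_e/∂Z)` with flux `−dh/dt` at the drained face and no
  flux at the bottom. Total stress is uniform in `Z`; the measured boundary
  stress is `σ_e` extrapolated to the drained face and the pore pressure is
  `p = σ_e(λ) − σ_ZZ` (zero at the drained face by construction).

*Numerics.* Finite-volume method of lines on a uniform material grid
(60 cells by default; 40 for fitting, 120–150 for oracle comparisons),
integrated per protocol phase with LSODA at `rtol 1e-6`. The scheme
conserves `∫λ dZ = h(t)` to integrator tolerance by construction, which the
tests audit. The linear limit is checked against the classical consolidation
eigenfunction series (cosine modes, ramp loading by Duhamel superposition)
— an oracle implemented independently of the PDE solver.

*Two-step fit.* The Yeoh coefficients come from constrained least squares
on the equilibrium (λ, σ) points over a fixed 12-point grid of starts
(deterministic); solutions pinned at admissibility bounds are flagged, with
an absolute floor of 1e-3 Pa on `c1` to catch degenerate all-zero data. The
permeability then minimizes the pooled squared transient misfit over
`log₁₀ k ∈ [−14, −8]` with a bounded deterministic scalar search; all steps
are pooled with equal weight (uniform subsampling to ≤1200 points). A flat
objective or a bound-hugging optimum raises/flags.

*Known deviation of intuition.* For displacement-controlled ramps the
bottom pressure spikes with the drained-face boundary layer (total stress is
uniform), so there is no plateau at the equilibrium stress jump; the tests
therefore check `p(H, t)` against the exact series
`4 H_A ε Σ_odd e^{−n²π²t/τ}` rather than an undrained-jump heuristic.

## Discrete fiber network (`collagenmech.network`)

Fibers of diameter 155 nm and lognormal length (median 8 µm, σ_log 0.5,
truncated to [2, 25] µm — the measured distribution is not available, and
this is consistent with fiber-tracing-scale lengths) are seeded with uniform
random positions/orientations in a cubic box until the in-box fiber length
reaches the target mass concentration (default 4 mg/mL at collagen density
1.35 g/cm³; 0.296% volume fraction). Fibers are discretized into 1 µm
segments with stretching and bending stiffnesses `k_s = EA/l0`,
`k_b = EI/l0`.

*Cross-links.* A cross-link forms wherever segments of two distinct fibers
pass within `d_xl` (default 0.3 µm), one per fiber pair (straight fibers
cross at most once), realized as a stiff spring (10·k_s, rest length =
formation distance) tying the nearest node pair. The segment-contact rule
matters: with 1 µm node spacing, a node-proximity rule at 0.3 µm misses
most genuine crossings (nodes sit up to half a segment from the crossing
point on each fiber) and leaves the network effectively unlinked. A
near-zero-rest-length stiff spring is numerically equivalent to a welded
node, so one mechanism covers both regimes; the monitored rupture force is
the spring tension, and a cross-link whose tension magnitude exceeds
`f_break` is removed irreversibly. At 4 mg/mL a 25 µm box carries roughly
a hundred cross-links (~0.3 per fiber): the network sits below the
connectivity percolation threshold, and load transmission under
compression combines direct contact, bending and the cross-linked
clusters — consistent with the near-zero equilibrium stresses of weakly
cross-linked collagen gels.

*Boundary conditions.* The indenter is a pure contact plane advancing into
the box: nodes overtaken by it are carried on the plane and released when
the network pulls them back, so material accumulates against the moving
face (no excluded volume exists between fibers, so targeted adhesion of a
slab cannot densify the network it passes through; and fully clamping a
slab fights the contact physics, producing spurious negative reactions).
The bottom 1 µm slab is fully clamped; lateral chamber walls are
impenetrable frictionless constraints. The boundary stress is the summed
axial elastic force of nodes pressing on the plane, divided by the face
area.

*Dynamics and the simulation clock.* Dynamics are overdamped and athermal:
`drag·dx/dt = −∇U`, explicit Euler with `dt ≤ drag/(10·k_max)`. The drag
coefficient only sets the clock (the bending/stretching relaxation-time
ratio is drag-independent), so it is a numerical unit, not the physical
Stokes drag. Protocol durations are therefore expressed in bending
relaxation times `τ_b = drag·l0²/k_b`: ramps and holds default to ~7 τ_b
(`NetworkProtocol.scaled`). Ramping over several τ_b keeps the viscous
"towing" force on carried fibers — `step displacement × k_b/(l0² × ramp
length in τ_b)`, a drag-independent quantity — an order of magnitude below
the pN–nN rupture scale, so rupture reflects transmitted elastic force
rather than the compressed clock. In parameter sweeps the drag is rescaled
proportionally to `E` so that every grid cell runs the same number of
bending times (and costs the same compute); quasi-static comparisons
(equilibrium stresses, rupture counts) are unaffected by the clock.

*Transmitted-force scale and rupture.* The cross-link junction is a
central-force spring, so the monitored transmitted force is a pure tension.
In the 25 µm / 4 mg/mL condition the measured tensions reach only
~1e-10–3e-10 N, so rupture activates for breaking forces below roughly
3e-10 N — within the pN–µN range the model sweeps, but about two decades
below where a rigid (welded) junction would act, since a weld additionally
transmits transverse bending-scale forces (~k_b/l0 ≈ 1e-9 N at
E = 50 MPa). The stiffness/cross-link-strength phenomenology (higher
equilibrium stress only with both stiffer fibers and stronger cross-links;
weak cross-links rupturing under compression) is therefore expressed at a
correspondingly lower f_break scale in this realization. The bending force
implementation is verified against a numerical gradient of the bending
energy, and an earlier sign error found by that check is the reason the
test exists.

*Problem sizes.* The default analysis box is 25 µm (~2.5×10³ segments),
with the 50 µm box available through `NetworkConfig(box_um=50)`; the
25 µm box is the package's standard desk-scale condition for tests and the
acceptance script.

## Synthetic data (`collagenmech.synthetic`)

All generators take a seed and are bit-reproducible. Noise is additive
i.i.d. Gaussian on forces and intensities (multiplicative force noise is
also available for the rheometer channel, where load-cell error scales with
signal); the experimental noise magnitudes are not known, so defaults are
chosen at magnitudes a rheometer/microscope plausibly produces (1%
multiplicative force noise; intensity noise well below fiber contrast).

* Relaxation traces: exact multi-exponential closed form plus noise.
* Biphasic traces: the forward solver on a refined internal grid (ramps
  resolved toward the ramp end where the stress peak is sharpest; holds
  log-spaced), linearly interpolated to the 100 Hz sampling grid; the
  default parameter set (c1 250 Pa, c2 −50 Pa, c3 1000 Pa, k 1e-10
  m⁴N⁻¹s⁻¹) gives tens-to-hundreds of Pa equilibrium stresses over 6×3%
  steps and a ~90 s consolidation time for a 3 mm gel — soft-collagen-gel
  scale.
* SHG-like stacks: straight 3-D segments rasterized per slice, Gaussian
  blur as a PSF stand-in, exponential depth attenuation, optional
  high-density surface slab. Fiber centres are seeded in a half-length
  margin beyond the volume so line density is uniform to the edges. This is
  a geometry generator, **not** a physical SHG model: passing tests show the
  thresholding/profile machinery is correct on known geometry, not that it
  is robust to real optical artifacts (speckle, aberrations, saturation).
* Spheroid time-lapse: textured disk (pixel-scale Gaussian texture, mean
  darkened in proportion to the texture contrast, as spheroids appear in
  transmitted-light imaging) on a smoothly varying background; zero
  contrast produces a featureless frame that the radius detector must
  refuse.

## Image quantification (`collagenmech.imaging`)

* Spheroid centre: exhaustive coarse-to-fine search of the two-phase
  piecewise-constant (Mumford–Shah-type) disk energy, marginalized over
  radius via cumulative ring sums; deterministic.
* Radius: radial profile of "graininess" (squared first-difference
  gradient), count-weighted pooling across neighbouring bins (the inner
  rings hold too few pixels for a max-based rule), reference maximum taken
  over bins with ≥200 pixels, and the 75%-of-maximum rule applied from the
  outside in: the radius is the furthest bin boundary beyond which the
  profile stays below threshold, with sub-bin interpolation of the
  crossing. Guards: a detectability floor (texture gradients ≥1% of mean
  intensity) and an inside/outside graininess contrast ratio ≥3; violating
  either raises an unreliable-detection error rather than returning a
  number.
* Global SHG threshold: per group, mean + 2·sample SD (ddof = 1; zero for a
  single ROI) of per-image background maxima; global = max over groups.
  Whether the original convention used per-image maxima or per-pixel
  statistics is not fully specified; per-image maxima are implemented and
  the statistic is isolated so the convention can be changed.
* Porosity: mask coverage averaged over slices; areal porosity equals
  volumetric porosity for randomly oriented fibers, so the complement of
  the fiber area fraction is reported directly.
* Gel thickness: axial mean profile in three lateral strips; onset = first
  sustained (2-slice) crossing of a configurable fraction (default 0.5) of
  the profile maximum, terminal landmark = last slice above it; mean of the
  three measurements.
* Densified layer: single-exponential attenuation baseline fitted to the
  profile excluding guard bands around candidate peaks; peak search on the
  **relative** residual (attenuation makes noise multiplicative, and a
  densified layer is a multiplicative enhancement), with a floor of
  max(5%, 4×MAD of the relative residual). Ties break to the smaller
  depth. On sparse stacks, bin-count fluctuations near the noise floor can
  still produce borderline layer calls; the detector is meant for the
  strong (severalfold) enhancements seen in densified gels.

## Acceptance script problem sizes

`scripts/acceptance.py` re-measures: the linear-oracle agreement (150-cell
grid, 120 eval times), biphasic parameter recovery (20 noisy 6×3%
staircases), spectrum recovery (3 modes, 6000 s record), the network toys,
the imaging design enumeration and spheroid-radius recovery (6 frames), and
the compressive-remodeling contrast (25 µm box: control 5×3% and
stiff/strong 2×3% cells). These sizes are the package's standard desk-scale
study conditions; the test suite runs the same conditions with a 50-seed
recovery ensemble.
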