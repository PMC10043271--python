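# Methods

`poregel` models and quantifies the rupture of adherent liposomes that
carry a membrane-bound actin (or actomyosin) cortex. This note records
the model, the conventions and calibrations behind the shipped
defaults, what the synthetic data do and do not emulate, and the known
limitations.

## The active-gel pore model

The membrane–cortex composite is treated as a thin active gel on the
adhered contact disk of radius `R_L`, with normalised actin density
`ρ` (reference value `ρ0 ≡ 1`) and radial velocity `v`.

Mass conservation with first-order turnover:

    ∂ρ/∂t + ∇·(ρ v) = −(ρ − ρ0)/τ_a

Quasi-static force balance (radial component):

    η (v″ + v′/r − v/r²) + ∂r[σ_a(ρ) − P(ρ)] = Γ v − f_adh

with the constitutive linearisation `σ_a − P = σ0 + ζ(ρ − ρ0)`.
`σ0` is the contractile active stress at reference density, and `ζ`
is the density sensitivity of the net gel stress: negative for a
passive actin layer (pressure rises with density) and positive when
myosin is present (density amplifies contraction).

**Units.** Symbols are bulk quantities — `σ0`, `ζ` in Pa; `η` in Pa·s;
`Γ` in Pa·s/m²; `f_adh` in N/m³; `γ` (membrane tension at the pore
boundary) in N/m. This is the only assignment that makes the pore-rate
law dimensionally consistent, and it reproduces the familiar
`σ_a·d ~ 1e-7 N/m` myosin tension contribution with a layer thickness
`d = 100 nm`. 2-D (per-length) quantities are these times `d`.

### Reduced pore dynamics

During the early phase of pore opening, the pore radius obeys

    dR/dt = [(σ0 + 2 f_adh R_L / 3) R − 2γ] / η_eff(R),
    η_eff(R) = η + (η − 2 ρ0 τ_a ζ) R² / R_L².

Contractile stress and adhesion open the pore; membrane tension
reseals it. The unstable fixed point is

    R_c = 6γ / (3 σ0 + 2 f_adh R_L):

pores above `R_c` expand to the contact radius, pores below reseal.
`ζ > 0` lowers `η_eff` (myosin fluidises the layer and speeds up
rupture); `ζ < 0` raises it. `η_eff ≤ 0.01·η` raises an error: the
reduced law is an early-phase approximation, and a near-zero or
negative effective viscosity is outside its validity.

Integration is adaptive RK45 (rtol 1e-8, atol 1e-12 m) with event
detection at `R = R_L` and `R = 0`; `R_init = R_c` exactly returns a
constant ("stalled") trajectory. Time zero is pore nucleation; no
nucleation model is included.

### Radial field solver

`fields.solve_velocity` discretises the force balance on a uniform
grid over `[R, R_L]` (default 200 cells, second-order one-sided
boundary stencils) and solves the linear two-point boundary-value
problem. Boundary conditions:

- **Pore edge** (`r = R`): total radial stress equals a
  membrane-tension pull, `η(v′ + v/r) + σ0 + ζ(ρ−ρ0) = c·2γ/R`. The
  single dimensionless constant `c` and the preset friction `Γ` were
  calibrated **once** against the reduced rate law — matching both the
  value and the local slope of `dR/dt` at the reference configuration
  (actin-liposome preset, uniform density, `R = 1 µm`) — and then
  frozen: `c = 0.946`, `Γ = 1.3e15 Pa·s/m²`. With these values the
  uniform-density PDE edge speed tracks the reduced law within ~10%
  over most of the opening range.
- **Contact line** (`r = R_L`): impermeable to mass always. The
  velocity condition defaults to pinned (`v(R_L) = 0`) in the full
  simulation: a stress-free outer velocity with a closed mass boundary
  is inconsistent once density piles up against the contact line — the
  `ζ(ρ−ρ0)` stress then feeds back on the pile-up and blows up. A
  stress-free option remains available in `solve_velocity` (and is the
  right choice for decay-length analyses on open annuli); `Γ = 0` with
  stress conditions at both ends is singular (the `1/r` velocity mode
  carries no stress) and is reported as such.

The density update is a conservative first-order upwind finite-volume
step on the moving (ALE) mesh — the edge face is material and exactly
flux-free, the mesh deforms linearly between the moving edge and the
fixed contact line — followed by an exact exponential turnover
sub-step. Time steps honour CFL 0.45 on `|v − w|` (w = mesh velocity)
and resolve `τ_a/50`. Mass drift with turnover off is < 0.1% per 1000
steps.

**Validity windows worth knowing.** The PDE edge speed matches the
reduced law within 10% while `max|ρ − ρ0| ≲ 1.5%`; at the actin preset
the sensitivity of the edge speed to density deviations is ~5× (the
`|2τ_a ζ/η|` coupling is ~30 there), so a 5% density deviation already
moves the edge speed by ~25%. The mean layer density rises
monotonically with pore area while compression outpaces turnover; in
the bare-liposome run it climbs to ~1.6× before the pore reaches 85%
of the contact radius, while in the (slower) actin run turnover
reverses the rise mid-way. The actomyosin preset's *field* run
develops the contractile density instability expected of a linear
`ζ > 0` closure with no saturation — the field solver should not be
trusted at late times there (the reduced model is unaffected).

## Preset parameter sets

The study system's fitted parameter values are not public, so the
shipped presets are package defaults with literature-scale magnitudes:

| parameter | value | rationale |
|---|---|---|
| `R_L` | 10 µm | typical contact radius |
| `γ` | 1e-4 N/m | near the measured lysis lower bound (0.14 mN/m) |
| `f_adh` | 1e8 N/m³ | strong-adhesion regime, `R_c ≈ 0.3 µm` ≪ `R_L` |
| `τ_a` | 100 s | measured actin turnover time |
| `d` | 100 nm | actin layer thickness |
| `σ0` (actomyosin) | 1 Pa | so that `σ0·d ≈ 1e-7 N/m` |
| `η` (bare) | 5600 Pa·s | calibrated (below) |
| `η` (actin, actomyosin) | 6140 Pa·s | calibrated |
| `ζ` (actin) | −898 Pa | calibrated |
| `ζ` (actomyosin) | +58 Pa | calibrated (95% of the `η_eff > 0` bound) |

The three free mechanical parameters were calibrated **once** so that
the standard rupture-trace protocol (below) reproduces the reported
composition-dependent opening timescales — τ ≈ 20 s (bare), 80 s
(actin), 20 s (actomyosin) — mirroring how the model is fitted to
measured traces; they are frozen and must not be tuned per analysis.
Consequences: `|2τ_a ζ/η| ≈ 29` for the actin layer (strong passive
stiffening) and `1.9` for actomyosin (η_eff at full opening is ~0.1 η,
near-maximal fluidisation).

## Trace kinetics

**Standard rupture trace.** `simulate_rupture_trace` integrates the
reduced model from `R_init = 1 µm`, finds the rupture time `T` (first
`R ≥ 0.995 R_L`), and resamples `[0, 1.2 T]` on 200 points — a trace
recorded through opening plus a short saturated tail, like an
experimental one. The fitted timescale depends (weakly) on this
window, which is why it is frozen as a protocol.

**Pore-opening timescale.** `fit_pore_radius` fits
`R(t) = R_∞ − (R_∞ − R_0) e^{−(t−t0)/τ}` in normalised units (the
bounded least-squares solver stalls when parameter scales differ by
many decades). When the tail is flat (median of the last 10% within 5%
of the span of the preceding 10%), `R_∞` is **anchored** to the
observed saturation plateau (median of the top quintile, ±5%): a fully
free `R_∞` correlates ~0.95 with τ under noise and inflates the τ
estimator by >20% at 5% noise. With anchoring the bias is <3% at 5%
noise. A growing-exponential variant is available behind a flag.

**Center depletion.** `fit_center_depletion` fits
`I(t) = I_∞ + (I_0 − I_∞) e^{−(t−t_on)/τ_a}`. The onset `t_on` starts
from a convention — last time the smoothed trace is within 2% of its
running maximum (smoothing window 5% of the trace) — and is refined by
a small changepoint grid search minimising the whole-trace
plateau+exponential SSE; the rule alone truncates early under noise
and biases τ_a upward by ~10% at 5% noise (the refined estimator's
bias is ~1%).

**Displacement gradient.** Windowed 1-D normalised cross-correlation
(8 px windows, 50% overlap, ±10 px search), Gaussian three-point
sub-pixel interpolation (≈3× less peak-locking than a parabola at
sub-pixel shifts), exact-match short-circuit for static inputs, median
vector validation (1 px against the 5-window median) with neighbour
infill, cumulative sum into `U(x,t)` and a lightly smoothed central
difference for `∂U/∂x`. `U` at fixed `x` estimates the time-integrated
Eulerian velocity, not the Lagrangian tracer displacement; tests
compare against the matching ground truth. Under strong strain
(>10% window compression per frame pair) the windows decorrelate —
keep the frame interval short relative to the strain rate.

**Model-to-trace fitting.** `fit_model_to_trace` runs nonlinear least
squares over reduced-model simulations in scaled parameters, reports
asymptotic standard errors, flags non-identifiable combinations by the
conditioning of J^T J, and emits `σ0·d` plus the fluidisation curve
`η_eff(t)/η_eff(ζ=0)`. Note that at the shipped actomyosin preset `σ0`
is 0.15% of the adhesive drive and is **not identifiable** from a
trace; recovery benchmarks run at a contractility-driven point
(`σ0 = 500 Pa`, `ζ = 100 Pa`, `f_adh = 0`) where both parameters carry
signal.

**Statistics.** Distribution comparisons use the Welch (unequal
variance) two-sided t-test; prevalence tables use Fisher's exact
two-sided test (scipy backends, cross-checked in the test suite
against a closed-form Welch computation and brute-force hypergeometric
enumeration). Stars follow the *, **, *** = p < 0.05, 0.01, 0.001
convention.

## Length scales

- Bendo-capillary length `L_b = √(k_b/γ)`: the distance over which
  membrane bending matters near a contact line. Default
  `k_b = 4e-18 J` (actin-coated membrane, ~100× a bare bilayer) and a
  lysis-tension bracket 0.3–5.0 mN/m give `L_b ≈ 30–100 nm`.
- Thiele length `L_Th = √(D/k)`: penetration depth of ATP entering at
  the permeable contact line before first-order consumption. Defaults
  `D = 1e-10 m²/s` (ATP in a dense actin network, below the free-
  solution ~3e-10) and `k ∈ [1, 100] s⁻¹` are literature-scale values,
  not measured ones; they give `L_Th ≈ 1–10 µm`.
- The verdict rules are deliberately generous to the losing
  hypothesis: mechanosensing is "supported" if the *upper* `L_b`
  endpoint reaches the observed localisation length (boundary
  inclusive); reaction–diffusion if `L_obs` falls within the `L_Th`
  bracket (or within one decade of a scalar `L_Th`).
- The thick-filament force is `n_bound × f_single` (12 × 3.4 pN =
  40.8 pN, often rounded to ~44 pN; both numbers are surfaced, neither
  silently corrected) and its tension contribution is `F/(2π R_L)` —
  a convention (force spread over the contact perimeter) chosen to
  reproduce the ~1e-7 N/m order of magnitude.

## Image quantification

Pixel centers at integer coordinates, origin top-left, all outputs in
meters after calibration. Geometric outputs scale with the pixel size
(the physical-scale filters adapt, so segmented areas agree only to
~10% across calibrations).

- **Radial profile**: bilinear sampling along 360 rays, averaged per
  1-px bin. **Angular profile**: 1° sampling on a circle, plus the
  above-half-max angular fraction as a wave-spread metric.
- **Spots** (~1 µm actin enrichments): local maxima of a 1 µm-scale
  LoG response above `k·MAD` of the response, minimum separation
  0.5 µm. `k = 8` by default: thresholds must be read against the
  number of pixels tested, and a ~4σ cut (k = 5) admits ~10 false
  peaks per 240² frame while SNR-5 spots sit at 16–24 MAD. When the
  liposome center is known, the azimuthally-median background is
  subtracted first; it removes the contact-line edge response exactly
  because it is radially symmetric, while localised spots barely move
  the 360° median.
- **Blisters**: difference-of-Gaussians bandpass at 1–5 µm scales,
  Otsu threshold on the inverted response, components gated on
  circularity ≥ 0.7 and diameter 0.5–10 µm.
- **Spot-ring width**: `w` = 95th percentile of the inward distance
  from the contact line among peripheral spots (within `0.5 R` of the
  edge) — a convention, since no published recipe exists.
- **Pore radius from movies**: threshold midway between the Otsu class
  means, largest dark component **not touching the image border** (the
  pore is enclosed by the layer; the background outside is dark too),
  equivalent-circle radius.
- **Rim tension**: mean `|σ|` over the band within 2 µm inside the
  contact-mask boundary, multiplied by the marching-squares perimeter
  (the printed recipe, implemented literally). The alternative reading
  — integrated rim force divided by perimeter — is available as
  `mode="integrated"`. Marching squares on a pixelated disk
  overestimates the perimeter by ~5%; the synthetic generator uses the
  same measure, so round-trips are exact.

## Synthetic data

Generators are pure functions of (config, seed) — repeated calls are
bit-identical — and every generator returns a machine-readable ground
truth. Defaults emulate the imaging conditions of the study system:
0.1 µm pixels, 10 µm contact radius, spots packed within 2 µm of the
contact line with uniformly drawn onset times, µm-scale dark
blisters, center depletion with τ_a = 100 s, Gaussian read noise at 5%
of dynamic range (Poisson optional), a camera baseline offset (so
background noise is never zero-clipped), and a single-Gaussian PSF
blur (0.15 µm). Not emulated: realistic optics beyond that blur,
photobleaching, drift, out-of-focus light, bead images for traction
inversion. A green recovery test therefore establishes that the
estimator is unbiased under *this* noise model, not that it is robust
to everything a microscope does.

The traction generator inverts the literal rim-tension formula, so the
noise-free readout equals the target tension by construction; the test
content is the noise robustness and the stress scale (~2 Pa on a 70 µm
perimeter for 0.14 mN/m).

## Known limitations

- The constitutive closure is linear in density with no saturation;
  `ζ > 0` field simulations are unstable at late times (contractile
  instability), and strongly negative `η_eff` regimes are refused
  rather than regularised.
- The reduced and field models agree quantitatively only in the
  near-uniform-density window; afterwards they are two different
  approximations of the same physics.
- The viscous operator is the simplified scalar Laplacian, not the
  full compressible viscous tensor; pores are axisymmetric; membrane
  bending does not enter the field model.
- Traction inversion (bead displacements → stresses) is out of scope;
  the rim-tension readout starts from a stress map.
- Fits report asymptotic (not bootstrap) uncertainties.
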