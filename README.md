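# poregel

Active-gel mechanics of pore opening in adherent liposomes — simulation,
trace kinetics, and image quantification.

## The problem

Cell-sized liposomes ("giant unilamellar vesicles") that encapsulate a
membrane-nucleated actin or actomyosin cortex spread on adhesive
substrates, build up membrane tension, and eventually rupture: a pore
nucleates near the contact line and expands across the adhered surface.
Two quantitative questions drive the analysis this package implements:

1. **What localises actin polymerization near the contact line?**
   Candidate length scales: the bendo-capillary length
   `L_b ~ √(k_b/γ)` (how far membrane bending/tension propagates) versus
   the Thiele length `L_Th ~ √(D/k)` (how far ATP entering at the
   permeable contact line diffuses before being consumed). With an
   actin-layer bending stiffness `k_b ≈ 4×10⁻¹⁸ J` and lysis tensions
   0.3–5.0 mN/m, `L_b ≈ 30–100 nm` — far below the ~2 µm spot ring —
   while `L_Th ≈ 1–10 µm` matches it.

2. **How does the cortex set the pore-opening timescale?** The
   membrane–cortex layer is modelled as an active gel with density ρ,
   velocity v, viscosity η, contractile stress σ₀, turnover time τ_a,
   substrate friction Γ and adhesion f_adh. The pore radius obeys

       dR/dt = [(σ₀ + 2 f_adh R_L/3) R − 2γ] / η_eff,
       η_eff = η + (η − 2ρ₀τ_a ζ) R²/R_L²,
       R_c = 6γ / (3σ₀ + 2 f_adh R_L),

   where ζ = d(σ_a − P)/dρ at the reference density. A passive actin
   layer (ζ < 0) stiffens the gel and slows rupture ~4-fold; myosin
   (ζ > 0) fluidises it back to bare-membrane speed. A full
   moving-boundary radial solver for (ρ, v) predicts the density
   pile-up at the pore edge and the friction-screened flow
   localisation over `√(η/Γ)`.

The package is for biophysicists who want to fit pore-radius traces,
test the length-scale hypotheses with their own parameters, quantify
liposome movies (spots, blisters, radial/angular profiles, pore radii)
and traction maps (rim tension), or run the model itself. Raw
microscopy from the original study is not deposited, so a seeded
synthetic-data module generates every input with known ground truth.

## Worked example

```
$ poregel lengths --out runs/lengths
L_b: 28-115 nm
L_Th: 1.0-10.0 um
L_obs: 2.0 um
mechanosensing_supported: False
reaction_diffusion_supported: True
```

Membrane tension cannot propagate tens of nanometres into a
micrometre-wide polymerization ring, but ATP diffusing through the
permeable contact line can cover it: the reaction–diffusion hypothesis
survives, mechanosensing does not.

```
$ poregel simulate --out runs/sim --seed 1
             preset     tau_s  zeta_Pa        R_c_m  tau_over_tau_BL
      bare_liposome 19.981312      0.0 3.000000e-07         1.000000
     actin_liposome 79.996561   -898.0 3.000000e-07         4.003569
actomyosin_liposome 20.043800     58.0 2.995507e-07         1.003127
```

Each row integrates the pore equation for one composition preset and
fits the saturating exponential `R(t) = R_∞ − (R_∞−R_0)e^{−t/τ}`. The
actin liposome opens 4× slower than a bare one (τ/τ_BL = 4.0); adding
myosin restores bare-liposome kinetics (τ/τ_BL = 1.0) even though the
layer's material viscosity is unchanged — fluidisation by the positive
density–stress coupling ζ. The critical pore radius `R_c ≈ 0.3 µm`
confirms the strong-adhesion regime in which spontaneous pores expand.

Library use mirrors the CLI:

```python
from poregel import preset, simulate_rupture_trace, fit_pore_radius, TimeSeries

p = preset("actomyosin_liposome")
traj = simulate_rupture_trace(p)
fit = fit_pore_radius(TimeSeries(traj.times, traj.radii))
print(fit.params["tau"])     # ~20.0 (seconds)
print(p.sigma0 * p.d)        # 1e-07 (N/m): myosin tension contribution
```

Other entry points: `simulate_fields` (moving-boundary density/flow
solver), `detect_spots` / `detect_blisters` / `rim_tension` /
`radial_profile` (image quantification), `displacement_gradient`
(kymograph PIV), `group_compare` / `prevalence_compare` (Welch t-test,
Fisher exact), and the `poregel synth` subcommand for self-describing
synthetic datasets. See `docs/methods.md` for the model conventions,
calibrations and limitations.

## Acceptance script

`scripts/acceptance.py` recomputes the headline quantities from
scratch — the bendo-capillary length at the upper lysis tension, the
upper Thiele endpoint, and the fitted opening timescales of the actin
and actomyosin presets — by running the package (no cached numbers):

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
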