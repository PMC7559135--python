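# Methods

This note records the modelling and numerical choices behind `cedflow`:
what is simulated, which parameters matter, what the synthetic phantom
does and does not emulate, and where the genuinely open design decisions
were settled.

## Model

### Fluid problem

Interstitial flow is Darcy flow in a deformable porous medium.  The steady
pressure field obeys `-∇·(K ∇p) + β² p = q` on the brain parenchyma, with

* **q** — the volumetric catheter source.  Rather than modelling the
  pressure on the catheter wall (which depends on catheter geometry and on
  unpredictable device–tissue interaction), the pump's flow rate is
  imposed as a flux: the backflow segment (tip plus a user-specified
  backflow length along the shaft) is rasterised exactly onto the grid and
  the total flux is distributed over the traversed voxels in proportion to
  intersected length.  Backflow length is an input, not a prediction.
* **p = 0 on CSF** — ventricles and the cortical CSF shell are held at
  baseline pressure (Dirichlet); the outer domain boundary is no-flow.
* **β² = Lp·S/V** — capillary fluid conductance, uniform in unexpanded
  tissue (default 1e-7 Pa⁻¹s⁻¹) and rescaled by the solid-fraction ratio
  (1-φ)/(1-φ₀) as tissue expands, since expansion dilutes the capillaries.
* **K(φ)** — Kozeny–Carman: `K = K₀ (φ/φ₀)³((1-φ₀)/(1-φ))²`, isotropic.
  Anisotropy from DTI is deliberately out of scope: gray matter is close
  to isotropic and white matter becomes so when it expands.

The pore fraction responds to the local pressure rise through the linear
poroelastic relation for incompressible constituents, `dφ/dp =
(α-φ)(1-φ)/B`, integrated exactly by partial fractions (for the Biot–
Willis coefficient α ≠ 1; the α = 1 closed form is used within 1e-6 of
that limit, where the two agree to the same order — an ODE fallback would
add a failure mode without adding accuracy).  The update is monotone in p
and saturates at φ = α.  Where a partial-volume voxel's baseline φ₀
already exceeds the nominal α of its tissue class, α is raised to φ₀ and
the voxel simply does not expand.

A general-ν variant (`pore_fraction_increment_general`) is provided as a
cross-check only.  It coincides with the incompressible form in the
suspension limit (B → 0 with α → φ), which the tests verify numerically.

### Baseline property maps

Baseline φ₀ comes from the ADC map through a monotone piecewise curve
anchored at normal brain (ADC 0.77×10⁻⁵ cm²/s → φ 0.2) and CSF
(≥ 2.6×10⁻⁵ cm²/s → φ 1.0): linear from (0, φ_min) to the first anchor, a
monotone cubic Hermite between the anchors (slope-continuous at the lower
anchor, flat at the CSF anchor), constant 1 above.  The exact curvature
between the anchors is not constrained by available data; the anchors and
the floor φ_min = 0.05 (which prevents K → 0 blow-ups in near-zero-ADC
voxels) are configurable.  Inside the parenchyma φ₀ is additionally capped
at 0.95 so the Kozeny–Carman formula stays finite in partial-volume
voxels.  Gray/white poroelastic constants are interpolated linearly with
the white-matter fraction map when one is provided.

### Solute problem

Free and bound concentrations evolve by

```
∂(φc)/∂t = -∇·(vc) + ∇·(φD∇c) - kc - k₁(B_s-b)c + k₂b
∂b/∂t    =  k₁(B_s-b)c - (k₂+k_irr)b
```

with φ frozen at the converged poroelastic state (quasi-static: the
pressure field equilibrates in minutes, the infusion lasts days).  The
catheter backflow segment is held at the infusate concentration while its
pump runs; CSF is an absorbing sink (c = 0, absorbed mass tallied) —
infusate that reaches CSF is assumed not to return.  No retardation factor
is applied to advection.  Binding is implemented and tested but off by
default: tracer studies measure unbound small/large surrogates.

Drug diffusivity scales from the water value by molecular size,
`D = D_water / (MW/MW_water)^(1/3)` (Stokes–Einstein radius scaling; the
exponent is configurable).  The capillary loss-rate field k comes from the
DCE module: Ktrans is used directly for Gd-DTPA, divided by 200 for
albumin-scale molecules, and voxels without DCE coverage receive the
normal-tissue default 1e-6 s⁻¹.  That default is applied as-is for either
molecule (one could argue for scaling it by 200 for albumin as well; the
constant is exposed as `default_rate`).

### DCE (extended Kety) module

`Ct(t) = vp·Cp(t) + Ktrans·(Cp ∗ e^(-kep·t))`, kep = Ktrans/ve, computed
by trapezoidal convolution on the AIF grid.  Fitting is bounded
least-squares (scipy `least_squares`, trust-region reflective) from three
deterministic starts (low/medium/high Ktrans) to avoid shallow local
minima; box constraints 0 ≤ Ktrans ≤ 0.1 s⁻¹, 1e-3 ≤ ve ≤ 1, 0 ≤ vp < 1.
AIF selection from a large artery is treated as an input problem, not
automated; the phantom supplies a biexponential bolus AIF sampled at 5 s.
All rates are in s⁻¹ internally.

### Quantification

T1 is estimated from the two-flip-angle SPGR pair by the variable-nutation
linearisation `S/sin a = E1·(S/tan a) + M0(1-E1)`; the two angles give the
slope E1 and `T1 = -TR/ln E1`; slopes outside (0,1) are flagged invalid
rather than propagated.  Gd concentration follows `Δ(1/T1) = r1·C` with
r1 = 3.7 mM⁻¹s⁻¹ by default (configurable); negative concentrations from
noise are clamped to zero and counted.  PET thresholds are always
computed from the dose schedule (activity/volume, decayed at half-life
4.18 d; the earliest dose, nearest the distribution boundary, sets the
threshold at 10%), never hard-coded.  Vd counts voxels strictly above
threshold times voxel volume; bias and L1 errors are the signed and
absolute sums of (simulated − measured) volumes over total measured, in
percent.

## Numerics

* **Discretisation** — cell-centered finite volume on the voxel grid;
  harmonic face averaging for discontinuous coefficients.
* **Coupled pressure solve** — the K(φ(p)) feedback spans two to three
  orders of magnitude, and the plain alternation “solve p on frozen
  coefficients → update φ, K → re-solve” is *not* a contraction for the
  default parameters: it oscillates between expanded and unexpanded
  states (we measured spectral radii above 1; damped versions converge
  only at ~0.7/iteration).  The pressure equation is therefore solved as a
  single nonlinear system by damped Newton with face conductivities taken
  as pressure-integrated (Kirchhoff) means, `S_i = [U_i(p_i) -
  U_i(p_j)]/(p_i - p_j)` with `U_i(p) = ∫₀ᵖ K_i`, combined harmonically
  across the face.  This reduces exactly to harmonic point-K averaging for
  pressure-independent K and removes the fold that defeats Picard
  iteration.  U is tabulated per voxel on a 200-point geometric pressure
  ladder up to 1 MPa.  The Jacobian is exact up to table interpolation; a
  backtracking line search guards the early steps.  The outer loop
  (update φ by the integrated relation → update K, β² → re-solve) is kept
  as the algorithm's self-consistency check and converges in one
  (rigid) or two (coupled) iterations, with the per-iteration maximum
  relative φ change recorded.
* **Conservation** — the converged effective face transmissibilities are
  reused for the transport fluxes, so source flux = capillary loss + CSF
  outflux holds to solver tolerance (~1e-12 relative) and the solute mass
  ledger closes to machine precision.
* **Linear solves** — Jacobi-preconditioned CG (relative residual 1e-12)
  for frozen-coefficient solves; sparse LU for the Newton steps.  The
  coupled solve is practical up to ~40³–49³ grids on one CPU; the 65³
  default phantom is used for the (linear) pressure oracle, while coupled
  phantom studies run on the 33³ compact variant.
* **Transport stepping** — operator splitting per step: upwind advection
  on the conservative face fluxes, explicit diffusion (harmonic φD face
  conductances), exact exponential decay for the linear loss, explicit
  binding exchange.  The time step is 0.9× the combined
  advection+diffusion positivity bound, further capped at 1/(10·max
  rate); `step_transport` rejects a dt above the bound and reports the
  admissible value.  First-order upwinding adds numerical diffusion
  ~v·Δx/2; at the distribution front this is of the same order as
  albumin's physical diffusivity, which is acceptable for
  distribution-volume work but means sharp-front comparisons should use
  refined grids.
* **Source voxels as reservoir** — mass accounting treats the
  Dirichlet-held backflow voxels as external: “infused” is the net solute
  flux crossing their boundary; on pump stop their content is released
  into the tissue tally.  This makes the ledger close identically and is
  the reason in-tissue sums exclude the handful of source voxels.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| φ₀ (normal brain) | 0.2 | – | nominal interstitial fraction |
| φ_min | 0.05 | – | numerical floor for the ADC map |
| K_ref at φ₀ | 2e-7 | mm²·Pa⁻¹·s⁻¹ | mid-literature white-matter conductivity; places the simulator in the regime where a 0.2 → ~0.6 expansion occurs at CED-scale pressures (a few kPa) and advection dominates diffusion, which is the regime the underlying measurements show |
| β² = Lp·S/V | 1e-7 | Pa⁻¹·s⁻¹ | literature-scale capillary conductance; sensitivity: larger β² shortens the screening length √(K/β²) and shrinks distributions |
| α gray / white | 0.7 / 0.99 | – | white matter behaves nearly as a suspension |
| B gray / white | 5000 / 500 | Pa | gray barely expands; white expands readily |
| G | 1000 | Pa | only enters the cross-check ν formula |
| D_water | 7.7e-4 | mm²/s | tissue water diffusivity (ADC scale) |
| normal-tissue loss k | 1e-6 | s⁻¹ | baseline capillary loss outside DCE coverage |
| tumor Ktrans (phantom) | 2e-4 | s⁻¹ | enhancing-tumor scale permeability |
| Hct | 0.42 | – | plasma fraction convention vp = (1-Hct)·vb |
| r1 (Gd, 3 T) | 3.7 | mM⁻¹s⁻¹ | relaxivity; configurable |
| ¹²⁴I half-life | 4.18 | d | decay correction and thresholds |

The poroelastic constants are acknowledged placeholders — they are not
measurable from routine imaging — and every one of them is a config knob.

## The phantom, and what passing tests mean

The phantom is a nested-sphere brain: CSF shell, gray rim, expandable
white core, an enhancing tumor (elevated Ktrans, slightly elevated ADC)
and an off-center ventricle; a default catheter enters the tumor with a
backflow segment crossing into white matter.  Synthetic DCE series are
generated voxelwise from known Kety parameters and the biexponential AIF;
synthetic SPGR pairs from a known T1 map.  Everything is deterministic
given the seed.

It emulates: the tissue-class topology that drives the flow problem (CSF
sinks, gray/white contrast, leaky tumor), the anchor chain from ADC to
pore fraction, and imaging-like forward models with known truth.  It does
not emulate: sulcal geometry and thin CSF leak paths (only a closed shell
and one ventricle), anatomical white-matter tracts, tissue tearing or air
bubbles along the catheter, B1 inhomogeneity, PET resolution blur, or
registration error.  Tests passing on the phantom therefore validate the
numerics and the internal consistency of the pipeline — conservation,
oracles, parameter recovery, directional effects of capillary loss — not
the fidelity of any particular patient prediction.

Problem sizes used by the test and acceptance runs: 65³ (2 mm) for the
linear point-source oracle, 33³ (2 mm) for coupled-flow and 24 h transport
studies, 200 replicates for the noisy Kety study.  These sizes were chosen
to exercise every term of the model at desk scale.

## Known limitations

* The diffusion-off ablation changes the 10%-threshold Vd far more than
  the "barely visible" effect reported for patient infusions: measured
  27% on the compact phantom (24 h, albumin D), 19% on a 49³ patient-like
  4-catheter setup at 24 h, and 64% at 72 h.  The mechanism is structural
  under the default parameters: capillary fluid leak (β²) slows the
  advective front while the diffusive tail keeps growing as √(2Dt)
  (~3 mm/day for albumin), so the contour shift never falls below ~10% of
  the distribution radius at any feasible scale — even though Vd/Vi
  (0.5–0.8 for albumin at 72 h) lands in the observed range.
  Reconciling the visual "contours not enlarged" observation would
  require a parameter regime (smaller effective D, or faster advective
  penetration) that the printed values do not pin down.  The acceptance
  suite keeps the strict 10% bound — currently failed — and reports the
  measured change.
* First-order upwind advection (see above): fronts are smeared by ~1–2
  voxels.
* Isotropic K and D; no perivascular/glymphatic pathways; no elevated
  endogenous tumor interstitial pressure; backflow length is an input.
  These are deliberate scope decisions, matching what the measurements
  available to this kind of study can constrain.
* The coupled Newton solve's LU factorisation limits practical coupled
  grids to ~125k parenchymal voxels on modest hardware.
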