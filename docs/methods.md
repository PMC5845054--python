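# Methods

This note documents the model equations, the parameter provenance, the
numerical choices and the known limitations of `proteinpbpk`.

## Model structure

The body is represented by 15 organs (adipose, bone, brain, gonads,
heart, kidney, large and small intestine, liver, lung, muscle, pancreas,
skin, spleen, stomach) plus arterial, venous and portal-vein blood
pools.  Each organ has plasma, blood-cell, interstitial, cellular and
endosomal sub-compartments.  Blood cells and the cellular space carry no
drug (passive cellular permeability is negligible for macromolecules);
they are kept in the state layout for structural fidelity and future
extensions (e.g. receptor-mediated uptake).  The splanchnic organs
(stomach, spleen, pancreas, small and large intestine) drain into the
portal vein, which perfuses the liver together with the hepatic artery;
the lung sits in series on the total cardiac output.  The intestines are
lumped single organs without mucosal sub-segmentation.

States are amounts (µmol); the system also integrates cumulative-loss
ledgers (endosomal catabolism, renal elimination, target
internalization) so that global mass balance can be verified to solver
precision on every run.

### Transcapillary exchange

Extravasation follows the two-pore formalism.  Per organ and pore class
(small/large):

* γ = a_e/r_pore; reflection coefficient
  σ(γ) = 1 − (1−γ)²[2−(1−γ)²](1−γ/3) / (1 − γ/3 + 2/3 γ²);
* restricted-diffusion factor
  ξ(γ) = (1−γ)^{9/2} / (1 − 0.3956 γ + 1.0616 γ²);
* free diffusion coefficient D = RT/(6π N_a a_e η) with
  RT = 2.58E5 N·cm/mol and η = 1.17E−9 N·min/cm² (37 °C);
* pore area per membrane thickness and surface from Poiseuille
  partitioning of the hydraulic conductivity:
  A_L/(L·S) = α_L·8η·Lp/r_L² (and 1−α_L with r_S);
* permeability–surface products PS = ξ·D·(A/(L·S))·S;
* fluid flows J_L = J_iso + α_L·L and J_S = −J_iso + (1−α_L)·L
  (J_L + J_S = L exactly; J_S may be negative under strong
  recirculation);
* Peclet numbers Pe = J(1−σ)/PS weight the diffusive terms by
  φ(Pe) = Pe/(e^Pe − 1).

**Clamping.**  For γ ≥ 1 the polynomial expressions are physically
meaningless; σ is clamped to 1 and ξ to 0, so a pore class smaller than
the solute transmits exactly nothing.  This case occurs in the standard
parameterization: the 5.34 nm antibody radius exceeds the 4.5 nm small
pores of continuous endothelium, making antibody extravasation purely a
large-pore (convection-dominated) process there.

**φ(Pe) evaluation.**  φ uses `expm1`, a first-order series below
|Pe| < 1e-8, the asymptotic 0 above Pe = 700, and the convention
PS·φ(Pe) = 0 when PS = 0 (infinite-Peclet sentinel).  φ is continuous at
0 and monotonically decreasing over the full range.

### Endosomal cycle and FcRn

Uptake into the endosomal space is first order in the organ plasma
concentration (f_vas_up = 1: no uptake from the interstitial space, so
extravasation is carried exclusively by the two-pore pathway).  In the
endosome the drug binds FcRn by mass action (Eq. k_ass·C·C_FcRn −
k_ass·Kd·C_complex); the complex is recycled to plasma (f_vas_rec = 1)
and unbound drug is degraded with rate constant k_up − k_rec
(0.294 − 0.0888 = 0.205 min⁻¹).

**Neutral-pH handling.**  The standard parameterization sets the
neutral-pH Kd to 1e5–1e6 µmol/l ("virtually no binding") while sharing
k_ass, which implies dissociation rate constants of order 1e5 min⁻¹ —
extreme stiffness with no effect on the solution.  The model therefore
takes the exact limit of that parameterization: recycled complex
releases its drug instantly as free drug in plasma, and the FcRn moiety
returns to the free endosomal pool.  An explicit finite-Kd neutral
binding mode (needed only for engineered pH-dependent binders, which
none of the bundled compounds are) would require circulating
drug–FcRn-complex species in every plasma and interstitial compartment
and is not implemented; the configuration toggle exists and is rejected
with a clear error.

**Pooled FcRn.**  One global free-FcRn amount is distributed over the
total endosomal volume; each organ's binding reaction uses the pooled
free-FcRn concentration with its local drug concentration, and per-organ
complex amounts are tracked locally.  Total FcRn (free + IgG-bound +
drug-bound) is exactly conserved by construction of the fluxes and is
monitored as an integration-accuracy invariant (< 1e-8 relative drift).

**Endogenous IgG pool.**  Endogenous IgG competes for FcRn inside a
lumped whole-body sub-model with the same structure as a standard organ;
its volumes, flows and surface area are sums over all organs, its Lp the
surface-area-weighted mean, its pore geometry the continuous-endothelium
standard.  The pooled plasma volume includes the blood-pool plasma,
since endogenous IgG pervades the whole systemic plasma.  A zero-order
synthesis balances IgG catabolism.  The drug-free steady state is solved
algebraically (the system is linear given the fitted free-FcRn
concentration): the complex balance gives C_complex =
k_ass·C_FcRn·C_endo/(k_rec + k_ass·Kd), the endosomal free-IgG balance
then yields C_endo, the interstitial concentration follows from the
two-pore/lymph balance, and synthesis equals catabolism.  Total FcRn is
back-computed as free + equilibrium complex.  Forward simulation from
this state leaves every state variable unchanged (validated to 0.1% over
10,000 min; the right-hand side vanishes to ~1e-12 relative at t = 0).

### Extensions

* **Renal filtration** (domain antibody, inulin): CL_ren = f_GFR·GFR
  acting on the kidney plasma compartment (f_GFR = 0.24 for the 2.43 nm
  domain antibody, 1.0 for inulin; GFR 0.28 ml/min mouse, 1.31 ml/min
  rat).  Tubular reabsorption and catabolism are not represented, so
  total-kidney concentrations of renally filtered proteins are
  underpredicted by design.
* **Tumor and target** (anti-CA-IX ADC): a 0.2 ml tumor organ with
  continuous-endothelium pores, tumor Lp 1.6E−3 ml/min/N and specific
  flow 0.21 ml/min/g receives arterial blood and drains venously.  Its
  interstitial space carries the CA IX target: baseline 0.26 µmol/l,
  turnover half-life 38 h (zero-order synthesis = k_deg × baseline, so
  the drug-free target is exactly homeostatic), reversible drug binding
  with Kd = 4 nM, and first-order internalization of the complex at
  0.027 min⁻¹ eliminating the drug.  The target association rate
  constant is not reported; k_on = 6.0 l/µmol/min (1e5 M⁻¹s⁻¹, a typical
  antibody on-rate) is used.  The terminal half-life is insensitive to
  this choice because tumor elimination is delivery-limited (~4% of the
  1.25 mg/kg dose is target-internalized vs ~96% catabolized).
* **FcRn knockout**: total FcRn set to zero; every pinocytosed molecule
  is degraded.

## Parameters

All mechanism parameters are bundled as YAML under
`src/proteinpbpk/data/` with units stated in each file:

* `endothelium.yaml` — Lp, α_L, r_S, r_L per organ; two endothelium
  classes (continuous: α_L 0.05, 4.5/25 nm; discontinuous for liver and
  spleen: α_L 0.80, 9/33 nm).
* `lymph_factors.yaml` — fitted f_lymph and f_Jiso per organ (plus the
  tumor row).  Liver lymph is driven by the hepatic *arterial* supply
  flow (portal blood has already generated lymph in the splanchnic
  organs); lung lymph by the total cardiac output; brain by its own
  regional flow.  With the bundled human physiology the total lymph flow
  is 0.41% of the cardiac-output plasma flow.
* `fcrn.yaml` — k_up, k_rec, k_ass; species plasma IgG (18/75/70 µmol/l
  mouse/monkey/human), IgG–FcRn Kd (0.75/0.132/0.63 µmol/l) and fitted
  free endosomal FcRn (38.7/21.0/80.8 µmol/l).  Rat FcRn/IgG parameters
  are not separately tabulated in the sources; the mouse values are used
  (rat is exercised only with inulin, which neither binds FcRn nor
  undergoes endosomal uptake, so these values are inert there).
* `compounds.yaml` — radii (5.34 nm antibodies/ADC, 2.43 nm domain
  antibody, 1.39 nm inulin), FcRn Kd values (0.75 for 7E3 on mouse FcRn,
  12.7 for the ADC, 1.196/0.134 for MEDI-524/-YTE on cynomolgus FcRn,
  0.63 for CDA1/tefibazumab on human FcRn, 0.85 for the adapted
  tefibazumab variant; 999,999 = no Fc region), renal coefficients,
  molecular weights (dose conversion only).
* `mouse/rat/monkey/human.yaml` — species physiology, compiled from the
  standard reference compilations (ICRP-89-style human anatomy, flows
  and regional blood distribution; Brown-1997-style rodent organ weights
  and flows; Kawai-1994-style rodent vascular fractions).  Human
  vascular volume fractions are derived from the ICRP regional blood
  distribution, which places ~2.97 l of the 5.3 l blood volume in organ
  microvasculature; with k = 950,000 cm²/l this yields a whole-body
  capillary surface of 282 m², within the 10% compilation variance of
  the 300 m² calibration estimate.  Swapping in a different physiology
  compilation is a data change, not a code change.

Canonical internal units are l, min, µmol and µmol/l, with cm/N/min in
the pore-level math; conversions happen at the data boundary.
K_iv = 0.96 (interstitial/plasma partition at f_u = 1) and f_u = 1 are
kept as explicit parameters for forward compatibility with small
molecules in the same framework.

## Numerics

* Integrator: `scipy.integrate.solve_ivp`, BDF, rtol 1e-9, atol 1e-13
  (µmol); overridable per run.  The slightly tighter-than-customary
  defaults keep the linear conservation invariants (total drug + losses,
  total FcRn) below 1e-8 relative drift over multi-week simulations.
  Halving rtol changes plasma AUC by < 0.1%.
* Doses: bolus state jumps are exact (amount added to venous plasma at
  the event time); infusions enter as a constant rate with integration
  restarted at start/stop.
* Tiny negative solver excursions (< 1e-12 of a state's trajectory
  maximum) are clipped to zero on output.
* Terminal half-life: unweighted log-linear regression over the last 30%
  of the simulated span (or the last 5 samples if more); the estimation
  window is a repository convention, configurable, and its effect on
  multi-exponential curves is documented by test.  AUC: trapezoid, with
  an optional log-trapezoid for decaying tails.
* Simulation horizons in the bundled scenarios (21 d for the
  tumor-bearing mouse, 28 d mouse, 56 d monkey/human) were chosen to
  cover ≥ 3 terminal half-lives of the respective compound.

## What the bundled scenarios do and do not show

The scenarios reproduce the *structure* of the original study
conditions — species, compounds, doses, routes — and every mechanistic
parameter is the printed value.  Because the underlying experimental
concentration–time data exist only as figures, the package validates
against invariants and printed summary quantities instead: mass balance,
FcRn conservation, IgG-pool homeostasis, the wild-type/knockout and
affinity-variant orderings, dose proportionality (dose-normalized CDA1
AUC within 2% from 5 to 20 mg/kg), the 0.205 min⁻¹ clearance constant,
the 300 m² surface and 0.4% lymph calibrations, and the ~48 h ADC
terminal half-life in the tumor-bearing mouse (simulated: 45.9 h).
Agreement with the digitized experimental curves themselves is outside
the scope of the test suite.

## Known limitations

* No subcutaneous dosing, immunogenicity, charge effects,
  tissue-specific FcRn expression, or return of the drug–FcRn complex
  into the endosome.
* No explicit neutral-pH FcRn binding mode (see above).
* Kidney tubular fluid is not represented; renal readouts are
  plasma-side only.
* The physiology is a point estimate per species (no population
  variability, no pediatric/ontogeny scaling).
* Blood-pool volume bookkeeping (organ vascular vs central pools)
  follows the bundled compilation; different compilations shift derived
  quantities (surface areas, endosomal volumes) within ~10%.
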