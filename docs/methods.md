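# Methods

This note records the model assumptions, parameter defaults and numerical
choices behind `lungdep`, and what the synthetic networks do and do not
represent.

## Airway networks

A lung is a bifurcating tree of rigid conducting airways embedded in 3-D
(gravity along −z, upright posture) with one acinus per terminal airway.
Generations count from the trachea (generation 1), incrementing at each
bifurcation; airways with generation < 10 are "central", the rest
"distal". The dead space is the summed conducting volume `sum(pi r^2 L)`.
Networks rescale isotropically to a target FRC by the factor
`(FRC_target/FRC)^(1/3)` applied to lengths, radii and coordinates, so
volumes scale by the factor cubed and aspect ratios are invariant.

### Generator

Anatomically derived geometries are replaced by a parametric stochastic
generator. A fixed central skeleton (trachea 8 mm radius / 10 cm,
main bronchi, bronchus intermedius, five lobar roots with configurable
terminal-count fractions RU/RM/RL/LU/LL = 0.20/0.10/0.25/0.20/0.25)
carries five lobar subtrees grown by recursive splitting of a
terminal-count budget: the split fraction is drawn from N(0.65, 0.10)
clipped to [0.52, 0.80], the budget-major daughter takes radius ratio
0.85 and the minor 0.78, lengths are 3 radii, and branching directions
rotate the parent axis by ~35 degrees in planes that rotate ~90 degrees
per generation. A branch whose budget reaches one becomes a terminal
bronchiole with an acinus.

At the default scale (30 000 terminal airways, ~60 000 conducting
airways, FRC 3.3 l) this yields a conducting dead space of ~120 ml
(within the realistic 101–145 ml adult range), terminal generations
spanning ~10–26, and radii strictly decreasing along every path. The
generator reproduces the *gross* properties that the experiments need —
asymmetric path lengths, five spatially coherent lobes, realistic airway
dimensions — but not patient anatomy: no CT-derived central-airway
shapes, no volume-filling against lobar surfaces, and lobe shapes are
emergent rather than anatomical. Conclusions drawn from it are
structural/directional, not patient-specific.

Fixtures: `symmetric_small` (complete 4-generation tree, closed-form
checks), `asymmetric_medium` (2600 terminals, ~5200 airways — the
desk-scale stand-in used for the convergence and constriction studies),
`asymmetric_small` (120 terminals, unit tests).

## Ventilation

Each airway is a Poiseuille resistor `R = 8 mu L/(pi r^4)`
(air viscosity 1.9e-5 Pa s at 37 C). Constriction severity sigma scales
radii by (1−sigma), hence resistance by (1−sigma)^-4. The optional
Pedley mode multiplies R by `Z = (C/4) sqrt(Re 2r/L)` (C = 1.85) when
Z > 1, making resistance flow-dependent; it is solved by Picard
iteration and is off by default.

Acini are identical linear Kelvin–Voigt bags
`P_a − P_pl = E_a (V_a − V0) + eta_a dV_a/dt` with
`E_a = N · E_total` (parallel compliances; E_total = 6.82 cmH2O/l at
FRC 3.3 l, the measured 5 cmH2O/l at FRC 4.5 l rescaled inversely with
volume), `eta_a = 0` by default, and
`V0 = (FRC − dead space)/N`. Breathing is a prescribed sinusoidal
tracheal flow (Tb = 5 s, VT = 625 ml); the spatially uniform pleural
pressure is an extra unknown whose equation enforces
`sum_a dV_a/dt = Q0(t)`, which guarantees the tidal volume is identical
before and after constriction. Gravity-dependent pleural-pressure
gradients and nonlinear compliance are deliberately out of scope.

Discretization: backward Euler (dt = 0.01 s). With linear resistances
the bordered sparse system (node pressures + pleural pressure) is
constant in time and factorized once (SuperLU); each step is a
back-substitution. One conditioning breath is run before the recorded
breath; the linear system's transient decays with time constant ~R·C,
a few tenths of a second, so the recorded breath is periodic to ~1e-9.

A note on the resistive-divider closed form: backward Euler places an
effective impedance `E_a dt` in series with each path, so the
instantaneous two-branch flow ratio equals the pure Poiseuille
`(1−sigma)^-4` only when `E_a dt << R`; the property test uses a
negligible elastance to isolate the divider.

## Particle transport and deposition

Particles default to 4 um diameter, unit density, with Cunningham slip
correction (mean free path 68 nm), Stokes settling velocity and
Stokes–Einstein diffusivity at 310 K. The cross-sectionally averaged
concentration obeys `dc/dt = d/dz(−u c + D_eff dc/dz) − s` on every
airway with flux continuity at bifurcations. `D_eff = D_mol +
1.08 |u| d` (Scherer-type shear dispersion; additive closures stay
finite for low-diffusivity aerosols where Taylor–Aris diverges).

Each airway is split into `max(8, ceil(L/200 um))` equal edges;
bifurcation nodes are shared. Acinar ducts (below) use at least 32 edges
per duct generation: the conducting grid is already converged at the
8-edge rule (refinement changes total deposition by <0.001%), while the
expanding acinar sleeves converge first-order in edge count, and 32
edges put the default answer within ~0.1% of the grid limit. The
finite-volume scheme uses exponential-fitted (Scharfetter–Gummel)
advection–diffusion fluxes — exact for steady transport on each edge,
reducing to central differencing at zero flow and upwinding at zero
diffusivity — and backward-Euler time stepping (dt = 0.01 s). The
matrix is an M-matrix, so concentrations remain non-negative, and its
graph is the node tree, so each step is solved exactly in O(N) by
leaf-to-root elimination (numba). A BiCGSTAB route (relative tolerance
1e-10, sparse-LU fallback) exists for cross-validation; the dense-matrix
equivalence is asserted to 1e-10 in the tests.

Deposition mechanisms are evaluated per airway (not per edge) and act
through a first-order sink `lambda = −ln(1 − P_tot)|u|/L`
(linearized below P_tot = 1e-6, capped at P_tot = 1 − 1e-12), which
makes the transit efficiency independent of edge subdivision:

- **Impaction**: angle-weighted Stokes-number efficiency
  `P = 1 − (2/pi) arccos(theta St) + (1/pi) sin(2 arccos(theta St))`
  with `St = tau |u| / 2r`, applied on each airway's entrance edge with
  the branching angle from the 3-D parent/daughter axes (35 degrees when
  degenerate). Its tally is assigned to the parent airway, matching how
  bifurcation hot spots are attributed. Neglected inside acini, where
  Stokes numbers are orders of magnitude below the impaction range.
- **Sedimentation**: Pich inclined-tube efficiency with
  `kappa = 3 L v_s cos(phi) / (8 r |u|)`, phi the inclination to the
  horizontal from the edge's 3-D direction (zero deposition for tubes
  parallel to gravity; saturation at kappa = 1).
- **Diffusion**: Ingham laminar-tube formula in
  `Delta = D L/(4 |u| r^2)`.

The exact correlations behind these three efficiencies are pluggable
(`MechanismSet`); the implemented forms are classical and satisfy the
limit/monotonicity contracts the rest of the model relies on. As flow
reverses (|u| → 0) the per-transit probabilities saturate but the rate
`lambda → 0`: deposition during the zero-flow instant is neglected, a
known property of residence-time efficiency models.

Each acinus is a symmetric tree of alveolated ducts collapsed onto a
representative path of 9 generations with multiplicity 2^k carried in
areas and volumes. Duct radii (0.25 → 0.125 mm) and lengths
(1.4 → 0.7 mm) are literature-typical adult acinar morphometry; each
generation has a rigid duct plus an alveolar sleeve treated as radially
well mixed with it, with sleeve volume fractions rising steeply toward
the terminal sacs and slaved to the acinus volume from the ventilation
solution. Duct cross-sections scale with the acinus volume (so duct
velocities and residence times stay realistic whatever the acinus count)
and duct inclination uses the isotropic-average cos(phi) = pi/4.
Sedimentation/diffusion in the acinus are evaluated on the duct
geometry, which understates the extra capture area of alveolar walls.

One breath starts from zero concentration; the inlet carries a fixed
concentration flux `Q0(t) c_in` during inhalation and advective outflow
during exhalation. All results are fractions of the inhaled amount, so
c_in cancels. Mass closure (deposited + exhaled + residual = inhaled)
holds to ~1e-12 by construction of the scheme.

## Constriction patterns

All patterns target generation 12–15 conducting airways at one shared
severity (paper-style CF surrogates): `lobar` (every generation 12–15
airway of one lobe), `clustered` (random generation-12 seeds, all
generation-12 airways whose distal ends lie within R_C of a seed, plus
descendants to generation 15; clusters may not share a generation-12
member — offending seeds are re-drawn with a bounded attempt budget) and
`random` (a uniform sample of generation-12 airways plus descendants).
The cluster anchor point is the airway distal end, and severity 1 (total
blockage) is excluded because it makes the Poiseuille system singular.

## Washout and LCI

Washout reuses the transport stepper with zero sinks, nitrogen-in-oxygen
diffusivity 2.3e-5 m2/s, a uniform initial tracer concentration,
tracer-free inhaled gas and acini as single well-mixed compartments
(gas-phase mixing is far faster than any aerosol's). The ventilation
breath is reused cyclically. The run ends at the first breath whose
end-exhalation tracheal concentration falls below 1/40 of the initial
value, and

```
LCI = V_ce [c0(0) − c0(nL Tb)] / V_tr
```

with V_ce the cumulative expired volume and V_tr the cumulative exhaled
tracer volume — i.e. expired volume normalized by the washout-derived
FRC estimate. For an ideal dead-space-free lung this reduces exactly to
`nL VT / FRC` (22 breaths, LCI 4.167 at FRC 3.3 l, VT 625 ml), which the
simulator reproduces; conducting dead space raises LCI above that bound.
Note the threshold criterion makes even the ideal-lung LCI slightly
*increase* with VT (the overshoot past 1/40 grows with the per-breath
dilution ratio), while larger VT flushes dead space more efficiently;
the tests assert these two oracle-faithful directions rather than a
naive "larger VT, lower LCI".

## Imaging

Simulated scintigraphy bins per-edge deposition by the coronal (x, z)
pixel of the edge midpoint, summed across the whole depth (y), on a
5 mm grid, and smooths with a Gaussian kernel of 8 mm bandwidth (both
configurable). The raw pixel sum equals total deposition exactly; only
the smoothed field is cosmetic. Change maps report per-airway
`(perturbed − baseline)/baseline` with zero-baseline airways flagged
NaN. The planar-graph rendering places every generation-g distal end on
a ring of radius (g−1)R0 with daughters at the parent angle ±2^-g pi,
which provably keeps sibling subtrees angularly disjoint.

## Problem sizes and runtimes

The desk-scale study network (`asymmetric_medium`, 2600 acini, ~5200
conducting airways, ~0.8 M transport edges at the default grid) solves
ventilation in ~1 s and one deposition breath in ~1 minute on one CPU;
the washout studies use dt = 0.02 s and compartment acini. The
qualitative constriction studies in the test suite run the deposition
sweep on a reduced acinar grid (8 edges per duct generation), since the
directional signatures — rise-then-fall of constricted-lobe distal
deposition, monotone acinar loss, the LCI knee near severity 0.8, and
the clustered-versus-random central-airway variance excess — are grid-
robust.

## Known limitations

- Poiseuille resistance understates losses in the largest airways
  (turbulence); the Pedley correction is available but off by default.
- Rigid airway walls: no collapse, no wall compliance, no mucus-layer
  dynamics; constrictions are static.
- No extrathoracic (oral/laryngeal) deposition — relevant for particles
  larger than ~6 um.
- No gravitational pleural-pressure gradient or acinar interdependence;
  all acini are mechanically identical.
- Single-breath deposition only (no multi-breath accumulation);
  particle transport does not feed back on ventilation.
- Alveolar-sleeve deposition uses duct-geometry efficiencies, likely a
  conservative estimate of alveolar capture.
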