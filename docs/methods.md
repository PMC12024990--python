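# Methods

This note documents the model, its closures and calibrations, the synthetic
geometry, the numerical choices, and the known limitations of `nanodiff`.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Tissue geometry

Structures live on a cubic, node-centered voxel lattice (node *(i,j,k)* at
*(i+½)Δx*); occupancy labels distinguish interstitial fluid, fiber,
tumor cell, stromal cell, and validation spheres. Porosity is the exact
fluid-node fraction, so every structural edit has exact bookkeeping.

**Fiber networks (ECM).** Straight rods of diameter 100 nm and length
70 µm (both configurable) with uniformly random positions and
orientations, wrapped periodically, in a 5 µm-scale box at Δx = 50 nm.
Rods may interpenetrate — fiber networks physically do — while the target
porosity is met within ±0.005 by shortening the final rods (an analytic
upper bound on voxels-per-length guarantees the band is approached from
above). Direct primitive placement is used rather than a stochastic
growth algorithm because the target structures are explicitly rod-based.

**Tumor tissue.** Ellipsoidal tumor cells (default semi-axes
7.5 × 5 × 5 µm, volume-matched to the stated 10 µm stromal spheres, since
no axes are stated) and spherical stromal cells at a 4:1 nearest-integer
count ratio, at Δx = 1 µm. Up to a cell volume fraction of ~0.35 the
packing is random sequential addition with Haar-random ellipsoid
orientations (RSA jams near 0.38). Above that, cells sit on a jittered
face-centered arrangement affinely stretched along x: the affine image of
a non-overlapping sphere packing keeps the aligned ellipsoids — and the
stromal spheres inscribed in the pre-image spheres — overlap-free at any
attainable density. The price is aligned ellipsoids and *uniform* gap
widths at high fraction (see Limitations).

**Degradation points** convert all fiber nodes inside a ball of diameter
200 nm (the degraded segment length) centered on a randomly chosen fiber
node to fluid: an ~200 nm stretch of fiber along its axis. Porosity is
non-decreasing; zero points is the identity.

**Sphere arrays** (validation fixture): one simple-cubic unit cell of edge
`pitch`, sphere centered, resolved by `shape[0]` nodes per edge; periodic
boundaries tile it. Voxelized porosity converges to 1 − (π/6)(d/pitch)³.

## Flow and temperature

D3Q19 (flow) / D3Q7 (temperature) BGK lattice Boltzmann; the stencil pair
is the standard accuracy/cost compromise — the source conditions never
name theirs. Guo forcing carries the Boussinesq buoyancy
F = β(T₀ − T)ρg; the macroscopic velocity includes the half-force
correction. Solid nodes couple through halfway bounce-back (wall midway
between node centers); faces are periodic or fixed-density via
non-equilibrium extrapolation (the construction behind "pressure
boundary" is unspecified in the source; this variant is robust at the low
Mach numbers used here, and solid nodes on a pressure face keep their
bounce-back values). Heated particles pin their host nodes to T_p before
streaming. A configurable lattice-Mach guard (default max |u| = 0.1)
aborts with the offending value rather than silently clipping.

Verified properties (test suite): exact mass/heat conservation under
periodic force-free stepping; shear-wave and thermal-wave decay match
c_s²(τ − ½) within 2%; Poiseuille within 1%; two-plate conduction linear
within 0.5%; point-source conduction follows the 1/r Green function
within 5%; mirrored forcing gives mirrored fields.

## Particle forces and adhesion

Wall-interaction sign convention: positive along the *outward* wall
normal (repulsion positive).

- drag: F = k πμd_p (u − u_p), k = 6 as printed in the source model
  (classical Stokes k = 3 by flag). τ_p = m_p/ζ for the *configured* drag
  law — the printed τ_p = ρ_p d_p²/18υ corresponds to the Stokes form and
  is inconsistent with the printed 6πμd_p; we resolve υ as dynamic
  viscosity and derive τ_p from ζ.
- Brownian: magnitude 2k_BT/d_p, fresh uniform random direction each step
  (the printed model); a Gaussian fluctuation–dissipation mode
  (σ_F = √(2k_BTζ/Δt)) exists for quantitative diffusion work.
- magnetic: F = V_p M_sat ∇B for saturated magnetite (M_sat = 4.8×10⁵ A/m).
- van der Waals: −A d_p/12d², clamped at the minimum-contact distance
  d₀ = 0.157 nm.
- electric double layer: constant-potential Hogg–Healy–Fuerstenau
  sphere–plate force
  F = πεε₀κd_p [2Ψ₁Ψ₂ − (Ψ₁²+Ψ₂²)e^{−κd}]/(e^{κd} − e^{−κd});
  this is the algebraic form whose printed structure the source shows.
- Lewis acid–base: πd_p ΔG^AB e^{(d₀−d)/λ} (outward-positive, so
  hydrophilic ΔG^AB > 0 repels); ΔG^AB from the van Oss
  electron-acceptor/donor combining rule, or overridden by a measured
  contact force (used for the polystyrene/silica/PEG cases, whose
  nanoparticle–polymer contact forces are external inputs).

Defaults (all configurable, SI): ε_r = 78.5, μ = 0.7 mPa·s at 310 K,
Debye length 1 nm (physiological saline), λ = 0.6 nm, ρ_p = 5000 kg/m³,
d_p = 50 nm. Hamaker constant A = 1×10⁻²¹ J, the low end of the Lifshitz
range for hydrated biopolymer/polymer interfaces across water: at this
value a double-layer barrier can form at surface potentials of −5…−15 mV,
which is the regime the zeta-potential studies operate in — at
A = 10⁻²⁰ J the 1/d² attraction dominates the screened e^{−κd} repulsion
at every separation for |Ψ| ≤ 15 mV and surface charge could never gate
adhesion. Wall potentials: cell membrane −20 mV, hyaluronic acid −30 mV,
collagen +15 mV (literature-typical; none are stated in the source).

**Adhesion model.** The net wall-force profile F(d) is scanned from the
100 nm cutoff inward. Meeting a repulsive barrier larger than the
Brownian drive first ⇒ the wall cannot capture this chemistry; meeting
net attraction beyond the drive first ⇒ capture is possible. Whether a
*given* wall encounter sticks is a Bernoulli trial with a single
dimensionless per-contact sticking probability p_s = 9.5×10⁻³
(`constants.STICK_PROBABILITY`): the chemistry gates *whether*, p_s sets
*how fast*. p_s was calibrated once
(`experiments.calibrate_sticking_probability`) so the baseline fiber
network (porosity 0.94, standard window below) reproduces the reference
hindered diffusivity of ~3.8×10⁻¹³ m²/s for the baseline particle, and is
held fixed across every experiment. Detachment releases an adhered
particle when the outward drive — magnetic plus sampled Brownian
components along the local wall normal (from the gradient of the
distance-to-solid field) — exceeds the contact attraction. With the
default chemistry the contact attraction (~10⁻¹⁰ N) exceeds the 6000 T/m
magnetic force (~2×10⁻¹³ N) by three orders, so magnetically driven
detachment does not occur under the defaults; the rule is exercised in a
weak-adhesion test scenario.

## The mover and its time step

The exponential integrator is exact for the linear drag ODE at any Δt.
The lattice-gas migration reproduces the continuum displacement in
expectation (unbiasedness is a tested property) but adds Bernoulli hop
variance. Two regimes are handled differently:

- **Fiber scale (Δx = 50 nm, printed fixed-magnitude kicks).** The kick
  magnitude fixes the terminal speed but not the decorrelation time, so
  the free diffusivity grows with Δt. Closure: Δt is calibrated by secant
  iteration on short obstacle-free runs so the free-lattice ensemble D
  equals Stokes–Einstein k_BT/ζ for the configured drag law
  (`transport.calibrate_timestep`; Δt ≈ 0.5 ms for water). This is the
  only reading under which the equivalent-viscosity validation can close.
- **Cell scale (Δx = 1 µm, equivalent-viscosity fluid).** The hop
  variance of the fixed-magnitude kick alone exceeds the target
  diffusivity at this mesh, so cell-scale runs use the Gaussian mode
  (free D = k_BT/ζ by construction) with the macro step sized so the rms
  free displacement spans 2.5 nodes (`experiments.tumor_dt`), keeping the
  hop-variance bias at the few-percent level.

Moves are sub-stepped so no component exceeds one spacing per draw;
sub-voxel positions are unresolved, so entering the voxel layer adjacent
to a wall *is* the wall encounter. Nodes whose wall gap is smaller than
the particle radius are sterically excluded (the 50 nm particle is a
point for transport but a sphere for wall distances).

**Observation windows** are part of the study conditions and the source
never states them: ECM runs use 2000 steps (~1 s, several box crossings);
cell-scale runs use 250 steps, chosen so the baseline tumor condition
(0.21 cell fraction, adhering neutral particle) reproduces the reference
tumor diffusivities (~1.4×10⁻¹³ m²/s). Because capture is irreversible
under the defaults, fitted coefficients in adhering conditions are
window-dependent; ratios between conditions are the meaningful outputs.

## Analysis

MSDs are time-origin-averaged over all overlapping lags (FFT
autocorrelation algorithm), ensemble-averaged over particles and
replicates, from unwrapped coordinates. D comes from the least-squares
slope over a lag window, default 10–50% of the maximum lag (skipping the
ballistic transient and the adhesion-saturated tail); per-axis N = 1,
total N = 3. Ensemble summaries report the mean, SD, and the replicate
closest to the mean (lowest index on ties). Negative fitted slopes are
reported with a flag, never clamped.

The sphere-array validation compares the simulated *composite*
diffusivity ratio ε·D_tracer/D₀ with the Maxwell relation 2ε/(3 − ε) at
the particle-accessible porosity ε (the fluid fraction the particle
*center* can sample): the factor ε is the formation-factor identity
linking MSD-based tracer mobility to composite flux diffusivity, and
using the accessible porosity accounts for the finite particle radius.
D₀ is simulated at the same time step, so calibration bias cancels in the
ratio. The analytic reference choice is a documented package decision;
Maxwell is exact only in the dilute limit, which bounds the agreement at
the larger sphere diameters.

Equivalent-viscosity round trips use classical Stokes drag (k = 3) in the
homogeneous-fluid leg, because μ_e = k_BT/(6πR₀D_sub) is the
Stokes–Einstein inversion for a sphere of radius R₀; with the k = 6 drag
of the explicit run the round trip would be off by exactly 2×.

## What the synthetic data does and does not emulate

The generator reproduces: rod-network ECMs at controlled porosity with
100 nm fibers; non-overlapping mixed-shape cell packings at 4:1 counts;
localized 200 nm fiber degradation; regular sphere arrays with known
analytic behavior. It does not emulate: fiber curvature, bundling, or
cross-linking; cell deformability or size dispersion; vasculature and
lymphatics; spatially varying interstitial pressure; biochemical
heterogeneity of wall chemistry. Passing sweeps therefore demonstrate the
model's structural and physicochemical mechanisms, not quantitative
agreement with any particular real tissue.

## Known limitations

- **Dense cell packings have uniform gaps.** The affine-FCC mode at cell
  fraction 0.54 leaves ~0.85 µm channels everywhere (one voxel at the
  1 µm mesh), so nearly every pore node touches a wall and an adhering
  ensemble is captured almost immediately; the measured reduction of D
  from 0.21 to 0.54 (~95%) is therefore steeper than for grown/clustered
  structures that keep wider channels at equal fraction.
- **Sticking kinetics are per contact attempt, not per unit time**, so
  the effective capture rate depends on mesh spacing and time step; the
  single calibration at the fiber scale and the separate window anchoring
  at the cell scale make conditions comparable within each scale, not
  across scales.
- Fitted D in adhering conditions depends on the observation window
  (capture is irreversible under the defaults); sweep ratios are the
  robust quantities.
- Drag has no hydrodynamic wall correction; particles are mass points for
  transport; no particle–particle interactions, aggregation, or uptake.
- The thermal experiment resolves the flow response (peak buoyant speed
  rises with particle temperature); at the reduced 1.6 µm box the
  convective drift is far below the Brownian displacement, so the D
  enhancement itself is not measurable at desk scale.
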