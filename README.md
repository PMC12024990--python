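# nanodiff

Coupled lattice-Boltzmann / lattice-gas-automata (LBM–LGA) simulation of
ligand-coated nanoparticle diffusion in tumor tissue and its extracellular
matrix (ECM).

## The problem

Nanocarrier drug delivery fails when 50–100 nm particles cannot penetrate the
tumor: a dense collagen/hyaluronic-acid fiber network, tight cell packings,
and adhesive particle–wall interactions trap them near the injection site.
`nanodiff` is a mesoscopic simulator for researchers studying how tissue
structure (porosity, cell volume fraction, fiber degradation), particle
surface chemistry (zeta potential, hydrophilicity), and external fields
(particle heating, static magnetic gradients) control the effective
diffusion coefficient of a nanoparticle ensemble in such media.

## The model

Three coupled layers on one voxelized tissue lattice:

**Interstitial fluid and heat (LBM).** A D3Q19 BGK lattice-Boltzmann
equation for the flow populations f_α and a D3Q7 set g_α for temperature,

    f_α(r + e_α δt, t + δt) − f_α(r, t) = −(f_α − f_α^eq)/τ_f + δt F_α ,
    g_α(r + e_α δt, t + δt) − g_α(r, t) =  (g_α^eq − g_α)/τ_g ,

with Boussinesq buoyancy **F** = β(T₀ − T)ρ**g** entering through Guo
forcing (the discrete F_α carries the 1 − 1/2τ_f prefactor and the
macroscopic velocity the half-force correction). Solid voxels (fibers,
cells) act through halfway bounce-back; domain faces are periodic or
fixed-density (pressure) boundaries. Heated particles are Dirichlet
temperature sources at their host nodes.

**Particle kinetics.** Each nanoparticle obeys
du_p/dt = (u − u_p)/τ_p + Σa, where τ_p = m_p/ζ is the drag relaxation
time (drag law ζ = 6πμd_p by default, classical Stokes 3πμd_p by flag) and
Σa collects Brownian kicks (magnitude 2k_BT/d_p with a fresh random
direction per step, or a Gaussian fluctuation–dissipation mode),
magnetophoresis **F**_mag = V_p M_sat ∇B, and — inside a 100 nm wall
cutoff — van der Waals (−A d_p/12d²), electric double-layer
(Hogg–Healy–Fuerstenau sphere–plate), and Lewis acid–base
(πd_p ΔG^AB e^{(d₀−d)/λ}) wall forces. The velocity/displacement update is
the exact exponential integrator of this linear ODE.

**Lattice-gas migration.** The continuum displacement Δx_p becomes
stochastic hops to the six face neighbors with probabilities
P_i = max(0, Δx_p·e_i/Δx) (sub-stepped when a component exceeds one
spacing). Hops into solid are rejected; a hop into the voxel layer touching
a wall is a wall encounter that immobilizes the particle with a calibrated
sticking probability whenever the net wall force profile is attractive and
unshielded by a double-layer/hydration barrier. Adhered particles detach
when the outward drive (magnetic + Brownian along the wall normal) exceeds
the contact attraction.

Ensembles of replicate trajectories are reduced to time-origin-averaged
mean-squared displacements, ⟨MSD⟩ = 2 D N t, giving per-axis (N = 1) and
total (N = 3) diffusion coefficients, the ensemble mean D, and the
representative replicate. The hindered coefficient D_sub of an explicit ECM
run defines the *equivalent viscosity* μ_e = k_BT/(6πR₀D_sub) used to
homogenize the interstitium in cell-scale tumor simulations.

## Worked example

Hindered diffusion in a porosity-0.94 fiber network and the equivalent
viscosity it defines (`examples/04_hindered_diffusion_ecm.py`):

```text
ECM porosity 0.94: D_sub = 4.980e-13 +/- 1.4e-13 m^2/s
fraction of particles adhered at the end: 1.00
equivalent viscosity mu_e = 0.0182 Pa s (26x water)
```

The fitted D_sub is more than an order of magnitude below the free-fluid
Stokes–Einstein value (6.5e-12 m²/s, see
`examples/03_free_diffusion.py`): fibers obstruct the walk and van der
Waals capture progressively immobilizes the ensemble. μ_e is the fictitious
homogeneous viscosity whose free diffusion reproduces exactly this D_sub.

Switching adhesion off by surface charge
(`examples/05_surface_chemistry.py`):

```text
  zeta =  +0 mV: adheres, capture range 4.9 nm
  zeta = -10 mV: double-layer barrier blocks adhesion
  ...
  zeta =  +0.0 mV: D = 5.715e-13 m^2/s
  zeta = -10.0 mV: D = 5.175e-12 m^2/s
```

Charging the particle to the fiber's sign builds a repulsive barrier that
exceeds the Brownian drive, capture stops, and D rises roughly tenfold —
with no further gain beyond the barrier-forming threshold (saturation).

The other examples cover geometry generation (`01`), the LBM flow/heat
solver against closed forms (`02`), and magnetic guidance (`06`, mean
z-penetration of 40 µm at 6000 T/m while transverse diffusion collapses).

A thin CLI wraps the same library calls:

```bash
nanodiff generate-geometry --kind ecm --porosity 0.94 --seed 1 -o ecm.h5
nanodiff run -c run.yaml -o out/
nanodiff experiment porosity-sweep --seed 1 -o sweep.csv
```

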