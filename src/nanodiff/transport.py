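"""Lattice-gas particle transport: exact exponential drag integrator in
continuous velocity space, stochastic migration between lattice nodes, and
wall adhesion/detachment from the physicochemical force balance.

The mover advances every particle of an ensemble per macro time step:

1. sample the stochastic and deterministic accelerations ``sum(a)``;
2. integrate ``du_p/dt = (u_local - u_p)/tau_p + sum(a)`` exactly over ``dt``
   (the drag term defines the relaxation time ``tau_p``);
3. convert the continuous displacement into hops between face-neighbor nodes
   with probabilities ``P_i = max(0, dx_p . e_i / dx)`` (sub-stepped whenever a
   displacement component exceeds one node spacing);
4. reject hops into solid nodes; a hop into a *contact* node (a fluid node
   whose wall gap is smaller than the particle radius) is a wall encounter
   that either adheres the particle or is rejected.

Positions are tracked both wrapped (periodic lattice) and unwrapped (for
mean-squared displacements).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as c
from .forces import (
    AdhesionProfile,
    FieldConfig,
    NanoparticleProps,
    SurfaceChemistry,
    adhesion_profile,
    brownian_magnitude,
    magnetic_force,
    random_unit_vectors,
)
from .geometry import PorousLattice


# ---------------------------------------------------------------------------
# kinematics (the exponential drag integrator)


def update_velocity(u_p, u_local, sigma_a, tau_p: float, dt: float) -> np.ndarray:
    """Exact solution of ``du/dt = (u_local - u)/tau_p + sigma_a`` after ``dt``:

    ``u* = u_local + tau_p sum(a) + (u_p - u_local - tau_p sum(a)) e^{-dt/tau_p}``.
    """
    if tau_p <= 0:
        raise ValueError("tau_p must be positive")
    u_inf = np.asarray(u_local, float) + tau_p * np.asarray(sigma_a, float)
    return u_inf + (np.asarray(u_p, float) - u_inf) * np.exp(-dt / tau_p)


def update_displacement(u_p, u_local, sigma_a, tau_p: float, dt: float) -> np.ndarray:
    """Exact time integral of the exponential velocity solution over ``dt``:

    ``dx = u_inf dt + (u_p - u_inf) tau_p (1 - e^{-dt/tau_p})`` with
    ``u_inf = u_local + tau_p sum(a)``.  Stable for ``dt >> tau_p`` and
    reduces to ``u dt + O(tau_p)`` as ``tau_p -> 0``.
    """
    if tau_p <= 0:
        raise ValueError("tau_p must be positive")
    u_inf = np.asarray(u_local, float) + tau_p * np.asarray(sigma_a, float)
    relax = -np.expm1(-dt / tau_p)  # 1 - e^{-dt/tau}
    return u_inf * dt + (np.asarray(u_p, float) - u_inf) * tau_p * relax


def migration_probabilities(dx_p, dx: float) -> np.ndarray:
    """Hop probabilities for the six face directions, ordered
    ``(+x, -x, +y, -y, +z, -z)``: ``P_i = max(0, dx_p . e_i / dx)``.

    Components must satisfy ``|dx_p,i| <= dx`` (the engine sub-steps to
    guarantee this; direct callers get an error instead of silent clipping).
    """
    d = np.asarray(dx_p, float)
    if np.any(np.abs(d) > dx * (1 + 1e-12)):
        raise ValueError("|dx_p| exceeds one node spacing; sub-step the move")
    out = np.empty(d.shape[:-1] + (6,))
    out[..., 0::2] = np.maximum(0.0, d / dx)
    out[..., 1::2] = np.maximum(0.0, -d / dx)
    return out


# ---------------------------------------------------------------------------
# single-particle state and rules (the ensemble engine below vectorizes these)


@dataclass
class NanoparticleState:
    """One particle: continuous-space kinematics plus its host lattice node."""

    node: np.ndarray  # integer lattice index (3,)
    velocity: np.ndarray  # m/s
    props: NanoparticleProps = field(default_factory=NanoparticleProps)
    adhered: bool = False
    hops: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.int64))

    def __post_init__(self) -> None:
        self.node = np.asarray(self.node, dtype=np.int64)
        self.velocity = np.zeros(3) if self.adhered else np.asarray(self.velocity, float)

    def position(self, spacing: float) -> np.ndarray:
        """Wrapped position (m): the host node center."""
        return (self.node + 0.5) * spacing


def move_particle(
    state: NanoparticleState,
    dx_p: np.ndarray,
    lattice: PorousLattice,
    rng: np.random.Generator,
    node_classes: np.ndarray | None = None,
    p_stick: float = 0.0,
) -> NanoparticleState:
    """Sample one migration step: each axis hops independently with
    probability ``P_i``; hops into solid nodes are rejected, hops into
    contact nodes adhere with probability ``p_stick`` (else rejected)."""
    if state.adhered:
        return state
    cls = node_classes if node_classes is not None else classify_nodes(
        lattice, 0.5 * state.props.diameter
    )
    shape = np.asarray(lattice.shape)
    probs = migration_probabilities(dx_p, lattice.spacing)
    for ax in range(3):
        p_plus, p_minus = probs[2 * ax], probs[2 * ax + 1]
        sgn = 0
        if p_plus > 0 and rng.random() < p_plus:
            sgn = 1
        elif p_minus > 0 and rng.random() < p_minus:
            sgn = -1
        if sgn == 0:
            continue
        tgt = state.node.copy()
        tgt[ax] = (tgt[ax] + sgn) % shape[ax]
        tcls = cls[tuple(tgt)]
        if tcls == _SOLID:
            continue
        if tcls == _CONTACT:
            if p_stick > 0 and rng.random() < p_stick:
                state.node = tgt
                state.hops[ax] += sgn
                state.adhered = True
                state.velocity = np.zeros(3)
                return state
            continue
        state.node = tgt
        state.hops[ax] += sgn
    return state


def adhesion_update(
    state: NanoparticleState,
    net_wall_force: float,
    mobile_force: float,
    rng: np.random.Generator,
    outward_drive: float = 0.0,
) -> NanoparticleState:
    """Force-balance adhesion/detachment for a particle at wall contact.

    A free particle adheres when the net wall-normal force is attractive
    (negative outward) and its magnitude exceeds the mobile forces trying to
    carry the particle away; an adhered particle is released when the net
    outward drive (magnetic + stochastic components along the normal)
    exceeds the attraction."""
    if not state.adhered:
        if net_wall_force < 0 and -net_wall_force > mobile_force:
            state.adhered = True
            state.velocity = np.zeros(3)
    else:
        if outward_drive > -min(net_wall_force, 0.0):
            state.adhered = False
    return state


# ---------------------------------------------------------------------------
# records


@dataclass
class TrajectoryRecord:
    """Sampled trajectory of one replicate's particle ensemble.

    ``positions`` holds unwrapped coordinates, shape (n_samples, n_particles,
    3) in meters on a uniform time grid ``times``; ``adhered`` the adhesion
    flag at each sample; ``adhesion_events``/``detachment_events`` the summed
    state changes over the run.
    """

    times: np.ndarray
    positions: np.ndarray
    adhered: np.ndarray
    seed: int
    adhesion_events: int = 0
    detachment_events: int = 0

    def __post_init__(self) -> None:
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-9):
            raise ValueError("trajectory sampling must be uniform")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("trajectory contains non-finite positions")


@dataclass
class TransportConfig:
    """Everything one particle-transport run needs (SI units).

    ``lattice`` may be ``None`` for unbounded free-space runs (then
    ``migration`` is ignored and motion is continuous).  ``dt = None``
    triggers the Brownian time-step calibration for the given viscosity.
    """

    props: NanoparticleProps = field(default_factory=NanoparticleProps)
    chem: SurfaceChemistry | None = None
    fieldcfg: FieldConfig = field(default_factory=FieldConfig)
    lattice: PorousLattice | None = None
    viscosity: float = c.WATER_VISCOSITY
    temperature: float = c.BODY_TEMPERATURE
    dt: float | None = None
    n_steps: int = 2000
    n_particles: int = 120
    sample_every: int = 10
    replicates: int = 50
    seed: int = 0
    brownian_mode: str = "fixed"  # "fixed" (2 k_B T / d_p) or "gaussian" (FD)
    migration: bool = True
    init: str = "entrance"  # "entrance" (z=0 face) or "uniform"
    u_field: np.ndarray | None = None  # (3, nx, ny, nz) fluid velocity, m/s
    u_interp: str = "trilinear"  # or "nearest"
    wall_cutoff: float = 100e-9
    stick_probability: float | None = None  # None -> calibrated default

    def __post_init__(self) -> None:
        if self.brownian_mode not in ("fixed", "gaussian"):
            raise ValueError("brownian_mode must be 'fixed' or 'gaussian'")
        if self.init not in ("entrance", "uniform"):
            raise ValueError("init must be 'entrance' or 'uniform'")
        if self.n_steps < 1 or self.n_particles < 1 or self.replicates < 1:
            raise ValueError("n_steps, n_particles and replicates must be >= 1")


@dataclass
class EnsembleResult:
    """All replicate trajectories plus provenance (config and seeds)."""

    records: list[TrajectoryRecord]
    config: TransportConfig
    dt: float

    @property
    def seeds(self) -> list[int]:
        return [r.seed for r in self.records]


# ---------------------------------------------------------------------------
# node classification

_ACCESSIBLE, _CONTACT, _SOLID = 0, 1, 2


def classify_nodes(lattice: PorousLattice, particle_radius: float) -> np.ndarray:
    """Node classes for a finite-size particle.

    *solid* nodes are walls; *contact* nodes are fluid nodes where a wall
    encounter happens — either the particle at the node center would touch or
    overlap the wall (surface gap <= 0) or the node is face-adjacent to solid
    (the sub-node position of the particle is unresolved, so entering the
    voxel layer next to a wall counts as an encounter); the rest are freely
    *accessible*."""
    gap = lattice.wall_gap(particle_radius)
    solid = lattice.solid
    adjacent = np.zeros(lattice.shape, dtype=bool)
    for ax in range(3):
        for sh in (1, -1):
            adjacent |= np.roll(solid, sh, axis=ax)
    cls = np.full(lattice.shape, _ACCESSIBLE, dtype=np.uint8)
    cls[(gap <= 0) | adjacent] = _CONTACT
    cls[solid] = _SOLID
    return cls


def wall_normals(lattice: PorousLattice) -> np.ndarray:
    """Outward (away-from-wall) unit normals per node from the gradient of the
    distance-to-solid field; zero where the gradient vanishes."""
    from scipy import ndimage

    fluid = ~lattice.solid
    dist = ndimage.distance_transform_edt(fluid, sampling=lattice.spacing)
    grad = np.stack(np.gradient(dist, lattice.spacing), axis=0)
    norm = np.sqrt((grad**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        n = np.where(norm[None] > 0, grad / norm[None], 0.0)
    return n


# ---------------------------------------------------------------------------
# the engine


_AXIS_VECS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=np.int64
)


def _brownian_forces(cfg: TransportConfig, zeta_drag: float, n: int,
                     rng: np.random.Generator, dt: float) -> np.ndarray:
    if cfg.temperature <= 0:
        return np.zeros((n, 3))
    if cfg.brownian_mode == "fixed":
        mag = brownian_magnitude(cfg.temperature, cfg.props.diameter)
        return mag * random_unit_vectors(rng, n)
    # fluctuation-dissipation: white-noise force held constant over the step
    sigma = np.sqrt(2.0 * c.K_B * cfg.temperature * zeta_drag / dt)
    return sigma * rng.normal(size=(n, 3))


def _interp_velocity(u_field: np.ndarray, pos: np.ndarray, spacing: float,
                     shape: np.ndarray, mode: str) -> np.ndarray:
    """Fluid velocity at particle positions (periodic lattice)."""
    s = pos / spacing - 0.5  # node-index space
    if mode == "nearest":
        idx = np.rint(s).astype(np.int64) % shape
        return u_field[:, idx[:, 0], idx[:, 1], idx[:, 2]].T
    i0 = np.floor(s).astype(np.int64)
    frac = s - i0
    out = np.zeros((pos.shape[0], 3))
    for corner in range(8):
        off = np.array([(corner >> b) & 1 for b in range(3)])
        w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
        idx = (i0 + off) % shape
        out += w[:, None] * u_field[:, idx[:, 0], idx[:, 1], idx[:, 2]].T
    return out


def _init_positions(cfg: TransportConfig, cls: np.ndarray | None,
                    rng: np.random.Generator) -> np.ndarray:
    """Initial host nodes (lattice runs) or positions (free runs)."""
    if cfg.lattice is None:
        return np.zeros((cfg.n_particles, 3))
    shape = np.asarray(cfg.lattice.shape)
    ok = cls == _ACCESSIBLE
    if cfg.init == "entrance":
        face = ok[:, :, 0]
        cand = np.argwhere(face)
        if len(cand) == 0:
            raise RuntimeError("no accessible nodes on the entrance face")
        pick = cand[rng.integers(0, len(cand), cfg.n_particles)]
        nodes = np.zeros((cfg.n_particles, 3), dtype=np.int64)
        nodes[:, :2] = pick
        return nodes
    cand = np.argwhere(ok)
    if len(cand) == 0:
        raise RuntimeError("no accessible nodes in the lattice")
    return cand[rng.integers(0, len(cand), cfg.n_particles)]


def simulate_replicate(cfg: TransportConfig, seed: int, dt: float) -> TrajectoryRecord:
    """Run one replicate; all randomness comes from ``seed``."""
    rng = np.random.default_rng(seed)
    props = cfg.props
    zeta_drag = props.drag_coefficient(cfg.viscosity)
    tau_p = props.relaxation_time(cfg.viscosity)
    f_mag = magnetic_force(props, cfg.fieldcfg)
    n = cfg.n_particles
    u_p = np.zeros((n, 3))

    lattice = cfg.lattice
    on_lattice = lattice is not None
    if on_lattice:
        dx = lattice.spacing
        shape = np.asarray(lattice.shape)
        cls = classify_nodes(lattice, 0.5 * props.diameter)
        normals = wall_normals(lattice)
        nodes = _init_positions(cfg, cls, rng)
        hops = np.zeros((n, 3), dtype=np.int64)
        x0 = (nodes + 0.5) * dx
        if cfg.chem is not None:
            # capture is gated on the isotropic Brownian drive; directional
            # forces (magnetic) enter the per-node detachment balance below
            mobile = brownian_magnitude(cfg.temperature, props.diameter)
            prof = adhesion_profile(cfg.chem, props, mobile, cutoff=cfg.wall_cutoff)
            p0 = cfg.stick_probability if cfg.stick_probability is not None else c.STICK_PROBABILITY
            p_stick = p0 if prof.can_adhere else 0.0
        else:
            prof = AdhesionProfile(False, 0.0, 0.0)
            p_stick = 0.0
    else:
        pos = _init_positions(cfg, None, rng).astype(float)

    adhered = np.zeros(n, dtype=bool)
    adhesion_events = 0
    detachment_events = 0

    n_samples = cfg.n_steps // cfg.sample_every + 1
    out_pos = np.empty((n_samples, n, 3))
    out_adh = np.zeros((n_samples, n), dtype=bool)
    out_pos[0] = x0 + hops * dx if on_lattice else pos
    times = np.arange(n_samples) * (cfg.sample_every * dt)

    k = 1
    for step in range(1, cfg.n_steps + 1):
        f_sto = _brownian_forces(cfg, zeta_drag, n, rng, dt)
        sigma_a = (f_sto + f_mag) / props.mass

        if on_lattice:
            wrapped = (nodes + 0.5) * dx
            if cfg.u_field is not None:
                u_loc = _interp_velocity(cfg.u_field, wrapped, dx, shape, cfg.u_interp)
            else:
                u_loc = np.zeros((n, 3))
        else:
            u_loc = np.zeros((n, 3))

        free = ~adhered
        u_new = update_velocity(u_p, u_loc, sigma_a, tau_p, dt)
        dxp = update_displacement(u_p, u_loc, sigma_a, tau_p, dt)
        u_p = np.where(free[:, None], u_new, 0.0)

        if not on_lattice:
            pos = pos + dxp
        else:
            # sub-step so every component moves at most one node per draw
            n_sub = np.maximum(1, np.ceil(np.abs(dxp).max(axis=1) / dx)).astype(np.int64)
            n_sub[~free] = 0
            step_d = np.where(free[:, None], dxp / np.maximum(n_sub, 1)[:, None], 0.0)
            p_hop = np.abs(step_d) / dx
            sgn = np.sign(step_d).astype(np.int64)
            max_sub = int(n_sub.max()) if len(n_sub) else 0
            for s in range(max_sub):
                active = free & (n_sub > s)
                if not active.any():
                    break
                do_hop = (rng.random((n, 3)) < p_hop) & active[:, None] & (sgn != 0)
                for ax in range(3):
                    movers = np.where(do_hop[:, ax])[0]
                    if len(movers) == 0:
                        continue
                    tgt = nodes[movers].copy()
                    tgt[:, ax] = (tgt[:, ax] + sgn[movers, ax]) % shape[ax]
                    tcls = cls[tgt[:, 0], tgt[:, 1], tgt[:, 2]]
                    ok = tcls == _ACCESSIBLE
                    contact = tcls == _CONTACT
                    # wall encounter: adhere with the capture probability
                    if contact.any() and p_stick > 0:
                        stick = contact & (rng.random(len(movers)) < p_stick)
                        idx = movers[stick]
                        if len(idx):
                            nodes[idx] = tgt[stick]
                            hops[idx, ax] += sgn[idx, ax]
                            adhered[idx] = True
                            free[idx] = False
                            u_p[idx] = 0.0
                            adhesion_events += len(idx)
                            do_hop[idx] = False
                    idx = movers[ok]
                    nodes[idx] = tgt[ok]
                    hops[idx, ax] += sgn[idx, ax]

            # detachment: outward drive vs adhesive strength at contact
            if adhered.any() and prof.contact_force < 0:
                stuck = np.where(adhered)[0]
                n_out = normals[:, nodes[stuck, 0], nodes[stuck, 1], nodes[stuck, 2]].T
                f_drive = f_sto[stuck] + f_mag
                f_out = (f_drive * n_out).sum(axis=1)
                release = f_out > -prof.contact_force
                idx = stuck[release]
                if len(idx):
                    adhered[idx] = False
                    detachment_events += len(idx)

        if step % cfg.sample_every == 0:
            out_pos[k] = x0 + hops * dx if on_lattice else pos
            out_adh[k] = adhered
            k += 1

    return TrajectoryRecord(
        times=times,
        positions=out_pos[:k],
        adhered=out_adh[:k],
        seed=seed,
        adhesion_events=adhesion_events,
        detachment_events=detachment_events,
    )


def simulate(cfg: TransportConfig) -> EnsembleResult:
    """Run ``cfg.replicates`` independent replicates with seeds derived
    deterministically from ``cfg.seed``; identical configs give identical
    ensembles."""
    dt = cfg.dt if cfg.dt is not None else calibrate_timestep(
        cfg.props, cfg.viscosity, cfg.temperature,
        dx=cfg.lattice.spacing if cfg.lattice is not None else 50e-9,
        brownian_mode=cfg.brownian_mode, seed=cfg.seed,
    )
    child_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
    records = []
    for ss in child_seeds:
        seed = int(ss.generate_state(1)[0] % (2**31))
        records.append(simulate_replicate(cfg, seed, dt))
    return EnsembleResult(records=records, config=cfg, dt=dt)


# ---------------------------------------------------------------------------
# time-step calibration


def free_diffusion_coefficient(
    props: NanoparticleProps, viscosity: float, temperature: float
) -> float:
    """Stokes-Einstein diffusivity ``k_B T / zeta`` for the configured drag
    law (``zeta = k pi mu d_p``)."""
    return c.K_B * temperature / props.drag_coefficient(viscosity)


def _measure_free_d(props, viscosity, temperature, dx, dt, brownian_mode, seed,
                    n_particles=700, n_steps=700) -> float:
    from .analysis import compute_msd, fit_diffusion
    from .geometry import PorousLattice

    lattice = PorousLattice(np.zeros((4, 4, 4), dtype=np.uint8), dx)
    cfg = TransportConfig(
        props=props, lattice=lattice, viscosity=viscosity, temperature=temperature,
        dt=dt, n_steps=n_steps, n_particles=n_particles, sample_every=2,
        replicates=1, seed=seed, brownian_mode=brownian_mode, init="uniform",
    )
    res = simulate(cfg)
    msd = compute_msd(res.records)
    return fit_diffusion(msd).d_total


def calibrate_timestep(
    props: NanoparticleProps,
    viscosity: float,
    temperature: float = c.BODY_TEMPERATURE,
    dx: float = 50e-9,
    brownian_mode: str = "fixed",
    seed: int = 12345,
    rtol: float = 0.015,
    max_iter: int = 6,
) -> float:
    """Choose the macro time step so the obstacle-free lattice ensemble
    reproduces the Stokes-Einstein diffusivity of the configured drag law.

    The magnitude of the Brownian kick (``2 k_B T / d_p``) fixes the terminal
    speed but not the decorrelation time, so the free diffusivity of the
    mover grows with ``dt``; the physical closure adopted here pins it to
    ``k_B T / zeta``.  ``D(dt)`` is affine in ``dt`` to good accuracy, so a
    secant iteration on short free runs converges in a few steps.
    """
    d_target = free_diffusion_coefficient(props, viscosity, temperature)
    v_term = brownian_magnitude(temperature, props.diameter) / props.drag_coefficient(viscosity)
    dt0 = 6.0 * d_target / v_term**2 if v_term > 0 else 1e-4
    if temperature <= 0:
        return dt0
    dt_a = dt0 * 0.5
    dt_b = dt0
    d_a = _measure_free_d(props, viscosity, temperature, dx, dt_a, brownian_mode, seed)
    for _ in range(max_iter):
        d_b = _measure_free_d(props, viscosity, temperature, dx, dt_b, brownian_mode, seed + 1)
        if abs(d_b - d_target) / d_target < rtol:
            return dt_b
        slope = (d_b - d_a) / (dt_b - dt_a)
        if slope <= 0:
            break
        dt_a, d_a = dt_b, d_b
        dt_b = max(0.1 * dt_b, dt_b + (d_target - d_b) / slope)
    return dt_b
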