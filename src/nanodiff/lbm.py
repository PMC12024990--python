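"""BGK lattice-Boltzmann solver for interstitial flow and heat transport.

Two distribution functions live on the same porous lattice: a D3Q19 set
``f`` for mass/momentum and a D3Q7 set ``g`` for temperature, coupled one way
through advection and back through a Boussinesq buoyancy body force
``F = beta (T0 - T) rho g``.  Collisions are single-relaxation-time with
Guo forcing (the discrete force term carries the ``1 - 1/(2 tau)`` prefactor
and the macroscopic velocity includes the half-force correction).  Solid
nodes of the porous lattice are handled by halfway bounce-back, which places
the no-slip wall midway between fluid and solid node centers.

Everything in this module works in lattice units; :class:`UnitSystem`
converts to and from SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PorousLattice


class InstabilityError(RuntimeError):
    """Raised when the solver detects NaN or a lattice-Mach violation."""


# ---------------------------------------------------------------------------
# stencils


def _d3q19_vectors() -> tuple[np.ndarray, np.ndarray]:
    e = [(0, 0, 0)]
    e += [
        (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
    ]
    e += [
        (1, 1, 0), (-1, -1, 0), (1, -1, 0), (-1, 1, 0),
        (1, 0, 1), (-1, 0, -1), (1, 0, -1), (-1, 0, 1),
        (0, 1, 1), (0, -1, -1), (0, 1, -1), (0, -1, 1),
    ]
    w = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12)
    return np.array(e, dtype=np.int64), w


def _d3q7_vectors() -> tuple[np.ndarray, np.ndarray]:
    e = [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    w = np.array([1 / 4] + [1 / 8] * 6)
    return np.array(e, dtype=np.int64), w


@dataclass
class LatticeModel:
    """Discrete velocity set with weights and sound speed (lattice units)."""

    e: np.ndarray  # (Q, 3) integer directions
    w: np.ndarray  # (Q,) weights
    cs2: float  # squared lattice sound speed
    dx: float = 1.0  # node spacing, m
    dt: float = 1.0  # time step, s

    @classmethod
    def d3q19(cls, dx: float = 1.0, dt: float = 1.0) -> "LatticeModel":
        e, w = _d3q19_vectors()
        return cls(e=e, w=w, cs2=1 / 3, dx=dx, dt=dt)

    @classmethod
    def d3q7(cls, dx: float = 1.0, dt: float = 1.0) -> "LatticeModel":
        e, w = _d3q7_vectors()
        return cls(e=e, w=w, cs2=1 / 4, dx=dx, dt=dt)

    @property
    def q(self) -> int:
        return len(self.w)

    @property
    def opposite(self) -> np.ndarray:
        """Index of the reversed direction for each population."""
        opp = np.empty(self.q, dtype=np.int64)
        for i, ei in enumerate(self.e):
            opp[i] = int(np.where((self.e == -ei).all(axis=1))[0][0])
        return opp

    def moment_check(self) -> dict[str, float]:
        """Numerical residuals of the weight/velocity moment identities."""
        w, e = self.w, self.e.astype(float)
        second = np.einsum("q,qi,qj->ij", w, e, e) - self.cs2 * np.eye(3)
        return {
            "sum_w": abs(float(w.sum()) - 1.0),
            "first_moment": float(np.abs(np.einsum("q,qi->i", w, e)).max()),
            "second_moment": float(np.abs(second).max()),
        }


@dataclass
class UnitSystem:
    """Reference scales mapping lattice units to SI and back."""

    length: float  # m per lattice dx
    time: float  # s per lattice dt
    density: float  # kg/m^3 per lattice unit
    temperature: float = 1.0  # K per lattice unit

    def velocity_to_lattice(self, v: float) -> float:
        return v * self.time / self.length

    def velocity_to_si(self, v: float) -> float:
        return v * self.length / self.time

    def kinematic_viscosity_to_lattice(self, nu: float) -> float:
        return nu * self.time / self.length**2

    def acceleration_to_lattice(self, a) -> np.ndarray:
        return np.asarray(a) * self.time**2 / self.length

    @classmethod
    def for_viscosity(
        cls, nu_si: float, dx: float, tau: float = 0.8, cs2: float = 1 / 3,
        density: float = 1e3, temperature: float = 1.0,
    ) -> "UnitSystem":
        """Pick the time scale so the given SI kinematic viscosity maps onto
        relaxation time ``tau`` (must exceed 0.5)."""
        if not tau > 0.5:
            raise ValueError("tau must exceed 0.5")
        dt = cs2 * (tau - 0.5) * dx**2 / nu_si
        return cls(length=dx, time=dt, density=density, temperature=temperature)


# ---------------------------------------------------------------------------
# states


@dataclass
class FluidState:
    """D3Q19 populations plus derived macroscopic fields (lattice units)."""

    f: np.ndarray  # (19, nx, ny, nz)
    tau: float
    model: LatticeModel = field(default_factory=LatticeModel.d3q19)

    def __post_init__(self) -> None:
        if not self.tau > 0.5:
            raise ValueError("tau must exceed 0.5 for stability")

    @classmethod
    def uniform(cls, shape, rho: float = 1.0, tau: float = 0.8) -> "FluidState":
        model = LatticeModel.d3q19()
        f = np.empty((model.q, *shape))
        f[:] = (model.w * rho)[:, None, None, None]
        return cls(f=f, tau=tau, model=model)

    @property
    def nu(self) -> float:
        """Lattice kinematic viscosity implied by tau."""
        return self.model.cs2 * (self.tau - 0.5)

    def macroscopic(self, force: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Density and velocity; with Guo forcing the velocity carries the
        half-force correction ``u = (sum f e + F/2) / rho``."""
        rho = self.f.sum(axis=0)
        mom = np.einsum("qxyz,qi->ixyz", self.f, self.model.e.astype(float))
        if force is not None:
            mom = mom + 0.5 * force
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(rho[None] > 0, mom / rho[None], 0.0)
        return rho, u


@dataclass
class ThermalState:
    """D3Q7 temperature populations (lattice units)."""

    g: np.ndarray  # (7, nx, ny, nz)
    tau: float
    t0: float = 0.0  # reference temperature
    beta: float = 0.0  # thermal expansion coefficient (1/K, lattice)
    model: LatticeModel = field(default_factory=LatticeModel.d3q7)

    def __post_init__(self) -> None:
        if not self.tau > 0.5:
            raise ValueError("tau must exceed 0.5 for stability")

    @classmethod
    def uniform(cls, shape, temperature: float = 0.0, tau: float = 0.8, **kw) -> "ThermalState":
        model = LatticeModel.d3q7()
        g = np.empty((model.q, *shape))
        g[:] = (model.w * temperature)[:, None, None, None] if temperature else 0.0
        if temperature:
            g[:] = (model.w[:, None, None, None]) * temperature
        return cls(g=g, tau=tau, model=model, **kw)

    @property
    def kappa(self) -> float:
        """Lattice thermal diffusivity implied by tau."""
        return self.model.cs2 * (self.tau - 0.5)

    @property
    def temperature(self) -> np.ndarray:
        return self.g.sum(axis=0)


@dataclass
class Boundaries:
    """Domain boundary configuration.

    ``periodic`` wraps every face.  ``pressure`` fixes the density on the
    inlet/outlet faces of ``axis`` (non-equilibrium extrapolation), periodic
    elsewhere; solid nodes on those faces fall back to bounce-back.
    """

    kind: str = "periodic"
    axis: int = 0
    rho_in: float = 1.0
    rho_out: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("periodic", "pressure"):
            raise ValueError("boundary kind must be 'periodic' or 'pressure'")


# ---------------------------------------------------------------------------
# kernels


def equilibrium(model: LatticeModel, rho: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Second-order Maxwell equilibrium for a density-like field.

    ``rho`` has shape (nx,ny,nz) (or scalar), ``u`` shape (3,nx,ny,nz) (or
    (3,)); returns (Q, ...).  For the D3Q7 thermal set the same expression is
    used; its quadratic terms are harmless for advection-diffusion.
    """
    e = model.e.astype(float)
    cs2 = model.cs2
    eu = np.tensordot(e, u, axes=(1, 0))  # (Q, ...)
    u2 = (np.asarray(u) ** 2).sum(axis=0)
    shape_w = (model.q,) + (1,) * (np.ndim(eu) - 1)
    w = model.w.reshape(shape_w)
    return w * rho * (1.0 + eu / cs2 + 0.5 * eu**2 / cs2**2 - 0.5 * u2 / cs2)


def equilibrium_f(rho, u, model: LatticeModel | None = None, mach_limit: float = 0.3,
                  on_violation: str = "raise") -> np.ndarray:
    """Flow equilibrium with a lattice-Mach guard (|u| <= mach_limit * c_s)."""
    model = model or LatticeModel.d3q19()
    umax = float(np.max(np.sqrt((np.asarray(u, dtype=float) ** 2).sum(axis=0))))
    if umax > mach_limit * np.sqrt(model.cs2):
        if on_violation == "raise":
            raise InstabilityError(
                f"velocity {umax:.3g} exceeds the configured lattice Mach limit"
            )
    return equilibrium(model, rho, u)


def guo_force_term(model: LatticeModel, u: np.ndarray, force: np.ndarray, tau: float) -> np.ndarray:
    """Discrete Guo forcing populations F_alpha (lattice units, per time step).

    ``F_alpha = (1 - 1/(2 tau)) w [ (e - u)/cs2 + (e.u) e / cs2^2 ] . F``;
    the zeroth moment vanishes and the first moment is ``(1 - 1/(2 tau)) F``.
    """
    e = model.e.astype(float)
    cs2 = model.cs2
    eu = np.tensordot(e, u, axes=(1, 0))  # (Q, ...)
    ef = np.tensordot(e, force, axes=(1, 0))
    uf = (np.asarray(u) * np.asarray(force)).sum(axis=0)
    shape_w = (model.q,) + (1,) * (np.ndim(eu) - 1)
    w = model.w.reshape(shape_w)
    return (1.0 - 0.5 / tau) * w * (ef / cs2 - uf / cs2 + eu * ef / cs2**2)


def boussinesq_force(tstate: ThermalState, rho: np.ndarray, g_vector) -> np.ndarray:
    """Buoyancy body force ``F = beta (T0 - T) rho g`` per node.

    Returns the macroscopic force field with shape (3, nx, ny, nz); assemble
    the discrete populations with :func:`guo_force_term`.
    """
    temp = tstate.temperature
    g = np.asarray(g_vector, dtype=float)
    return tstate.beta * (tstate.t0 - temp)[None] * rho[None] * g[:, None, None, None]


def _stream(model: LatticeModel, pops: np.ndarray) -> np.ndarray:
    out = np.empty_like(pops)
    for i, ei in enumerate(model.e):
        out[i] = np.roll(pops[i], shift=tuple(ei), axis=(0, 1, 2))
    return out


def _bounce_back(model: LatticeModel, streamed: np.ndarray, post: np.ndarray,
                 solid: np.ndarray) -> None:
    """Halfway bounce-back: populations that streamed out of a fluid node into
    a solid neighbor return reversed; overwrites the (garbage) slots streamed
    out of solid nodes.  In-place on ``streamed``."""
    opp = model.opposite
    fluid = ~solid
    for i, ei in enumerate(model.e):
        if not ei.any():
            continue
        neigh_solid = np.roll(solid, shift=tuple(-ei), axis=(0, 1, 2))
        mask = fluid & neigh_solid
        streamed[opp[i]][mask] = post[i][mask]
    streamed[:, solid] = 0.0


def _pressure_faces(model: LatticeModel, f: np.ndarray, solid: np.ndarray,
                    bc: Boundaries) -> None:
    """Fixed-density faces by non-equilibrium extrapolation from the adjacent
    interior slab; solid nodes on the face keep their bounce-back values."""
    ax = bc.axis
    for side, rho_t in ((0, bc.rho_in), (-1, bc.rho_out)):
        face = [slice(None)] * 3
        face[ax] = 0 if side == 0 else -1
        inner = [slice(None)] * 3
        inner[ax] = 1 if side == 0 else -2
        face_t, inner_t = tuple(face), tuple(inner)
        fn = f[(slice(None), *inner_t)]
        rho_n = fn.sum(axis=0)
        mom = np.einsum("q...,qi->i...", fn, model.e.astype(float))
        with np.errstate(divide="ignore", invalid="ignore"):
            u_n = np.where(rho_n[None] > 0, mom / rho_n[None], 0.0)
        feq_n = equilibrium(model, rho_n, u_n)
        feq_t = equilibrium(model, np.full_like(rho_n, rho_t), u_n)
        fluid_face = ~solid[face_t]
        f[(slice(None), *face_t)][:, fluid_face] = (
            feq_t + (fn - feq_n)
        )[:, fluid_face]


def step_flow(
    state: FluidState,
    lattice: PorousLattice,
    force: np.ndarray | None = None,
    boundaries: Boundaries | None = None,
    mach_limit: float = 0.1,
) -> FluidState:
    """One BGK collide-stream cycle for the flow populations (in place).

    ``force`` is the macroscopic body force per node in lattice units,
    shape (3, nx, ny, nz) or (3,).  Raises :class:`InstabilityError` on NaN
    or when max |u| exceeds ``mach_limit`` (in lattice speed units).
    """
    bc = boundaries or Boundaries()
    model = state.model
    solid = lattice.solid
    if force is not None and np.ndim(force) == 1:
        force = np.broadcast_to(
            np.asarray(force, dtype=float)[:, None, None, None],
            (3, *lattice.shape),
        )
    rho, u = state.macroscopic(force)
    umax = float(np.nanmax(np.abs(u)))
    if not np.isfinite(umax) or umax > mach_limit:
        raise InstabilityError(f"flow unstable: max |u| = {umax:.4g} (lattice units)")
    feq = equilibrium(model, rho, u)
    post = state.f + (feq - state.f) / state.tau
    if force is not None:
        post += guo_force_term(model, u, force, state.tau)
    streamed = _stream(model, post)
    _bounce_back(model, streamed, post, solid)
    if bc.kind == "pressure":
        _pressure_faces(model, streamed, solid, bc)
    state.f = streamed
    return state


def step_temperature(
    tstate: ThermalState,
    u: np.ndarray,
    lattice: PorousLattice,
    dirichlet_mask: np.ndarray | None = None,
    dirichlet_value: float = 0.0,
) -> ThermalState:
    """One advection-diffusion cycle for the temperature populations.

    ``u`` is the advecting velocity field (3, nx, ny, nz) in lattice units.
    Nodes in ``dirichlet_mask`` are pinned to ``dirichlet_value`` before
    streaming (heated-particle sources).  Solid walls bounce back (adiabatic).
    """
    model = tstate.model
    solid = lattice.solid
    temp = tstate.temperature
    if not np.all(np.isfinite(temp)):
        raise InstabilityError("temperature field contains NaN/inf")
    geq = equilibrium(model, temp, u)
    post = tstate.g + (geq - tstate.g) / tstate.tau
    if dirichlet_mask is not None and dirichlet_mask.any():
        pinned = equilibrium(
            model, np.full(lattice.shape, dirichlet_value), np.zeros((3, *lattice.shape))
        )
        post[:, dirichlet_mask] = pinned[:, dirichlet_mask]
    streamed = _stream(model, post)
    _bounce_back(model, streamed, post, solid)
    tstate.g = streamed
    return tstate


def impose_np_heat(
    tstate: ThermalState,
    lattice: PorousLattice,
    particle_nodes: np.ndarray,
    t_p: float,
) -> np.ndarray:
    """Dirichlet mask for heated particles: nodes hosting a particle are
    constrained to ``t_p`` (lattice temperature units) during stepping.

    Returns the boolean mask to pass to :func:`step_temperature`; an empty
    particle list leaves the state untouched (all-False mask).
    """
    mask = np.zeros(lattice.shape, dtype=bool)
    if len(particle_nodes) == 0:
        return mask
    idx = np.asarray(particle_nodes, dtype=np.int64) % np.asarray(lattice.shape)
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    mask &= ~lattice.solid
    return mask


def total_mass(state: FluidState, lattice: PorousLattice) -> float:
    """Global fluid mass (lattice units) over fluid nodes."""
    return float(state.f[:, ~lattice.solid].sum())


def total_heat(tstate: ThermalState, lattice: PorousLattice) -> float:
    return float(tstate.g[:, ~lattice.solid].sum())
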