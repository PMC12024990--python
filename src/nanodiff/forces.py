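"""Forces on a nanoparticle: fluid drag, Brownian kicks, magnetic gradient
pull, and near-wall physicochemical interactions (van der Waals, electric
double layer, Lewis acid-base).

Sign convention for wall interactions: forces are signed scalars along the
*outward* wall normal — positive repels the particle from the wall, negative
attracts it.  (The source expressions written with an inward-positive
convention, e.g. ``F_LW = -A d_p / 12 d^2``, keep their printed sign here
because an attraction is negative-outward.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as c


@dataclass
class NanoparticleProps:
    """Intrinsic particle properties (SI units).

    ``drag_prefactor`` selects the drag law ``F = k pi mu d_p (u - u_p)``:
    ``k = 6`` is the coefficient used by the transport model, ``k = 3`` the
    classical Stokes value for a sphere of diameter ``d_p``.
    """

    diameter: float = c.NP_DIAMETER
    density: float = c.NP_DENSITY
    msat: float = 0.0  # saturation magnetization, A/m
    zeta: float = 0.0  # surface potential Psi_1, V
    drag_prefactor: float = 6.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.density <= 0:
            raise ValueError("diameter and density must be positive")

    @property
    def volume(self) -> float:
        return np.pi / 6.0 * self.diameter**3

    @property
    def mass(self) -> float:
        return self.density * self.volume

    def drag_coefficient(self, mu: float) -> float:
        """Linear drag coefficient zeta with F_drag = zeta (u - u_p)."""
        if mu <= 0:
            raise ValueError("viscosity must be positive")
        return self.drag_prefactor * np.pi * mu * self.diameter

    def relaxation_time(self, mu: float) -> float:
        """Momentum relaxation time tau_p = m_p / zeta for the configured
        drag law (always positive)."""
        return self.mass / self.drag_coefficient(mu)


@dataclass
class SurfaceChemistry:
    """Constants of the particle-wall interaction (SI units).

    ``delta_g_ab`` is the Lewis acid-base interaction energy per unit area at
    contact (J/m^2, positive = hydrophilic repulsion).  It may be given
    directly, recomputed from surface-tension components via
    :meth:`from_gamma_components`, or bypassed entirely by
    ``ab_contact_force`` — the signed outward force at ``d = d0`` — when a
    measured or externally computed contact force is the input.
    """

    hamaker: float = c.HAMAKER  # J
    psi_wall: float = 0.0  # V
    eps_r: float = c.WATER_EPS_R
    kappa: float = 1.0 / c.DEBYE_LENGTH  # inverse Debye length, 1/m
    d0: float = c.CONTACT_DISTANCE  # m
    decay_length: float = c.AB_DECAY_LENGTH  # m
    delta_g_ab: float = 0.0  # J/m^2
    ab_contact_force: float | None = None  # N, outward-positive

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.decay_length <= 0 or self.d0 <= 0:
            raise ValueError("kappa, decay_length and d0 must be positive")

    @staticmethod
    def delta_g_from_gamma(
        gamma1: tuple[float, float],
        gamma2: tuple[float, float],
        gamma_w: tuple[float, float] = (c.GAMMA_W_PLUS, c.GAMMA_W_MINUS),
    ) -> float:
        """Acid-base interaction energy between surfaces 1 and 2 across water
        from electron-acceptor/donor components ``(gamma_plus, gamma_minus)``:

        ``dG = 2 [ sqrt(gw+)(sqrt(g1-) + sqrt(g2-) - sqrt(gw-))
                 + sqrt(gw-)(sqrt(g1+) + sqrt(g2+) - sqrt(gw+))
                 - sqrt(g1+ g2-) - sqrt(g1- g2+) ]``
        """
        g1p, g1m = gamma1
        g2p, g2m = gamma2
        gwp, gwm = gamma_w
        s = np.sqrt
        return 2.0 * (
            s(gwp) * (s(g1m) + s(g2m) - s(gwm))
            + s(gwm) * (s(g1p) + s(g2p) - s(gwp))
            - s(g1p * g2m)
            - s(g1m * g2p)
        )

    @classmethod
    def from_gamma_components(cls, gamma_particle, gamma_wall, **kw) -> "SurfaceChemistry":
        dg = cls.delta_g_from_gamma(gamma_particle, gamma_wall)
        return cls(delta_g_ab=dg, **kw)


@dataclass
class WallProximity:
    """Separation of the particle surface from the nearest solid surface."""

    distance: float  # m, >= 0
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if self.distance < 0:
            raise ValueError("separation distance must be non-negative")
        if not np.isclose(n, 1.0, rtol=1e-6):
            if n == 0:
                raise ValueError("wall normal must be nonzero")
            self.normal = self.normal / n


@dataclass
class FieldConfig:
    """External field settings: magnetic gradient, gravity, particle heating."""

    grad_b: np.ndarray = field(default_factory=lambda: np.zeros(3))  # T/m
    gravity: np.ndarray = field(default_factory=lambda: np.zeros(3))  # m/s^2
    t_p: float | None = None  # heated-particle temperature, K

    def __post_init__(self) -> None:
        self.grad_b = np.asarray(self.grad_b, dtype=float)
        self.gravity = np.asarray(self.gravity, dtype=float)


# ---------------------------------------------------------------------------
# force laws


def drag_force(u_local, u_p, mu: float, d_p: float, prefactor: float = 6.0) -> np.ndarray:
    """Fluid drag ``F = k pi mu d_p (u - u_p)`` pointing from the particle
    velocity toward the local fluid velocity."""
    if mu <= 0:
        raise ValueError("viscosity must be positive")
    return prefactor * np.pi * mu * d_p * (np.asarray(u_local, float) - np.asarray(u_p, float))


def brownian_magnitude(temperature: float, d_p: float) -> float:
    """Magnitude of the stochastic kick force, ``2 k_B T / d_p``."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    return 2.0 * c.K_B * temperature / d_p


def random_unit_vectors(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Isotropic unit vectors; shape (3,) for ``n is None`` else (n, 3)."""
    size = (3,) if n is None else (n, 3)
    v = rng.normal(size=size)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / norm


def brownian_force(temperature: float, d_p: float, rng: np.random.Generator) -> np.ndarray:
    """Fixed-magnitude Brownian force ``2 k_B T / d_p`` with a fresh uniform
    random direction per evaluation."""
    return brownian_magnitude(temperature, d_p) * random_unit_vectors(rng)


def magnetic_force(props: NanoparticleProps, fieldcfg: FieldConfig, x=None) -> np.ndarray:
    """Magnetophoretic body force on a saturated particle,
    ``F = V_p M_sat (dB/dx, dB/dy, dB/dz)``."""
    return props.volume * props.msat * fieldcfg.grad_b


def vdw_force(hamaker: float, d_p: float, distance: float, d_min: float = c.CONTACT_DISTANCE) -> float:
    """Sphere-plate van der Waals force ``-A d_p / (12 d^2)`` (outward-
    positive, so attractive for ``A > 0``); the separation is clamped at the
    minimum-contact distance ``d_min`` to regularize the contact singularity."""
    d = max(distance, d_min)
    return -hamaker * d_p / (12.0 * d * d)


def electrostatic_force(chem: SurfaceChemistry, d_p: float, distance: float,
                        psi_particle: float | None = None) -> float:
    """Electric double-layer force between a sphere and a plate at constant
    potential (Hogg-Healy-Fuerstenau):

    ``F_EL = pi eps eps0 kappa d_p [2 Psi1 Psi2 - (Psi1^2 + Psi2^2) e^{-kd}]
             / (e^{kd} - e^{-kd})``

    Repulsive (positive) for like-sign potentials at moderate separations;
    decays as ``e^{-kappa d}`` for ``kappa d >> 1``.  ``kappa d`` is clamped
    to [1e-4, 60] for numerical safety.
    """
    psi1 = psi_particle
    if psi1 is None:
        raise ValueError("particle potential required")
    psi2 = chem.psi_wall
    kd = np.clip(chem.kappa * max(distance, 0.0), 1e-4, 60.0)
    num = 2.0 * psi1 * psi2 - (psi1**2 + psi2**2) * np.exp(-kd)
    den = np.exp(kd) - np.exp(-kd)
    return np.pi * chem.eps_r * c.EPS0 * chem.kappa * d_p * num / den


def acid_base_force(chem: SurfaceChemistry, d_p: float, distance: float) -> float:
    """Lewis acid-base (hydration/hydrophobic) force,
    ``F_AB = pi d_p dG_AB exp((d0 - d)/lambda)`` outward-positive, so a
    hydrophilic interaction (``dG_AB > 0``) repels and a hydrophobic one
    attracts.  If ``ab_contact_force`` is set it fixes the value at
    ``d = d0`` and the same exponential decay applies.
    """
    # clamp at the contact value for d < d0 (inside the equilibrium distance)
    d = max(distance, chem.d0)
    decay = np.exp(max((chem.d0 - d) / chem.decay_length, -700.0))
    if chem.ab_contact_force is not None:
        return chem.ab_contact_force * decay
    return np.pi * d_p * chem.delta_g_ab * decay


def wall_force(chem: SurfaceChemistry, props: NanoparticleProps, distance: float) -> float:
    """Net physicochemical wall force (outward-positive) at surface gap
    ``distance``: van der Waals + double layer + acid-base."""
    return (
        vdw_force(chem.hamaker, props.diameter, distance, chem.d0)
        + electrostatic_force(chem, props.diameter, distance, props.zeta)
        + acid_base_force(chem, props.diameter, distance)
    )


def total_acceleration(
    props: NanoparticleProps,
    chem: SurfaceChemistry | None,
    fieldcfg: FieldConfig,
    temperature: float,
    prox: WallProximity | None,
    rng: np.random.Generator,
    wall_cutoff: float = 100e-9,
) -> np.ndarray:
    """Sum of accelerations from all forces except fluid drag.

    Drag is handled separately by the exponential integrator (it defines the
    relaxation time).  Near-wall terms act along the outward wall normal and
    are evaluated only inside ``wall_cutoff``.
    """
    force = brownian_force(temperature, props.diameter, rng) if temperature > 0 else np.zeros(3)
    force = force + magnetic_force(props, fieldcfg)
    if prox is not None and prox.distance < wall_cutoff:
        if chem is None:
            raise ValueError("surface chemistry required within the wall-interaction cutoff")
        force = force + wall_force(chem, props, prox.distance) * prox.normal
    return force / props.mass


# ---------------------------------------------------------------------------
# adhesion force balance


@dataclass(frozen=True)
class AdhesionProfile:
    """Outcome of scanning the net wall-force profile along the approach path.

    ``can_adhere``
        the approaching particle reaches a separation where the net attraction
        exceeds the mobile driving force without first meeting a repulsive
        barrier larger than that force;
    ``capture_range``
        outermost separation (m) where attraction exceeds the mobile force;
    ``contact_force``
        net outward force at contact (negative = the adhesive strength that a
        detaching force must overcome).
    """

    can_adhere: bool
    capture_range: float
    contact_force: float


def adhesion_profile(
    chem: SurfaceChemistry,
    props: NanoparticleProps,
    mobile_force: float,
    cutoff: float = 100e-9,
    n_grid: int = 400,
) -> AdhesionProfile:
    """Classify the wall interaction for a particle driven by forces of
    typical magnitude ``mobile_force`` (Brownian + field components).

    The profile ``F(d)`` is scanned from ``cutoff`` inward: the first point
    where ``F < -mobile_force`` marks capture; meeting ``F > +mobile_force``
    first means the barrier reflects the particle and adhesion never occurs.
    """
    d = np.geomspace(chem.d0, cutoff, n_grid)[::-1]  # outside -> inside
    f = np.array([wall_force(chem, props, di) for di in d])
    contact = float(f[-1])
    for di, fi in zip(d, f):
        if fi > mobile_force:
            return AdhesionProfile(False, 0.0, contact)
        if fi < -mobile_force:
            return AdhesionProfile(True, float(di), contact)
    return AdhesionProfile(False, 0.0, contact)
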