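"""Particle transport: the exponential integrator against ODE/quadrature
oracles, the migration rule's unbiasedness, adhesion/detachment, and the
free-diffusion behavior of the full engine."""

import numpy as np
import pytest

from nanodiff import constants as c
from nanodiff.forces import FieldConfig, NanoparticleProps, SurfaceChemistry
from nanodiff.geometry import Label, PorousLattice
from nanodiff.transport import (
    NanoparticleState,
    TransportConfig,
    adhesion_update,
    classify_nodes,
    free_diffusion_coefficient,
    migration_probabilities,
    move_particle,
    simulate,
    update_displacement,
    update_velocity,
)


def _ode_oracle(u0, u_local, a, tau, dt, n_sub=2000):
    """Fine-step RK4 integration of the augmented system
    dx/dt = u, du/dt = (u_local - u)/tau + a."""
    u_local = np.asarray(u_local, float)
    a = np.asarray(a, float)

    def rhs(y):
        x, u = y[:3], y[3:]
        return np.concatenate([u, (u_local - u) / tau + a])

    y = np.concatenate([np.zeros(3), np.asarray(u0, float)])
    h = dt / n_sub
    for _ in range(n_sub):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * h * k1)
        k3 = rhs(y + 0.5 * h * k2)
        k4 = rhs(y + h * k3)
        y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y[3:], y[:3]


class TestIntegrator:
    def test_fixed_point(self):
        u = update_velocity([1e-6, 0, 0], [1e-6, 0, 0], [0, 0, 0], 1e-9, 1e-4)
        assert np.allclose(u, [1e-6, 0, 0])

    def test_terminal_velocity_limit(self):
        """dt >> tau_p drives u toward u_local + tau_p * a."""
        a = np.array([0, 0, 1e3])
        u = update_velocity([5e-6, 0, 0], [1e-6, 0, 0], a, 1e-9, 1e-3)
        assert np.allclose(u, [1e-6, 0, 1e-9 * 1e3], rtol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_velocity_matches_fine_step_ode(self, seed):
        rng = np.random.default_rng(seed)
        u0 = rng.uniform(-1e-5, 1e-5, 3)
        ul = rng.uniform(-1e-5, 1e-5, 3)
        a = rng.uniform(-1e3, 1e3, 3)
        tau = 10 ** rng.uniform(-9, -7)
        dt = 3 * tau * rng.uniform(0.3, 2.0)
        u_exact = update_velocity(u0, ul, a, tau, dt)
        u_num, _ = _ode_oracle(u0, ul, a, tau, dt)
        assert np.allclose(u_exact, u_num, rtol=1e-6, atol=1e-18)

    def test_zero_inputs_zero_displacement(self):
        dx = update_displacement([0, 0, 0], [0, 0, 0], [0, 0, 0], 1e-9, 1e-4)
        assert np.allclose(dx, 0)

    def test_pure_advection(self):
        dx = update_displacement([2e-6, 0, 0], [2e-6, 0, 0], [0, 0, 0], 1e-9, 1e-3)
        assert np.allclose(dx, [2e-9, 0, 0], rtol=1e-12)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_displacement_matches_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        u0 = rng.uniform(-1e-5, 1e-5, 3)
        ul = rng.uniform(-1e-5, 1e-5, 3)
        a = rng.uniform(-1e3, 1e3, 3)
        tau = 10 ** rng.uniform(-9, -7)
        dt = 3 * tau * rng.uniform(0.3, 2.0)
        dx_exact = update_displacement(u0, ul, a, tau, dt)
        _, dx_num = _ode_oracle(u0, ul, a, tau, dt)
        assert np.allclose(dx_exact, dx_num, rtol=2e-6, atol=1e-20)


class TestMigrationRule:
    def test_zero_displacement_zero_probabilities(self):
        assert (migration_probabilities([0, 0, 0], 1.0) == 0).all()

    def test_full_step_along_one_axis(self):
        p = migration_probabilities([1.0, 0, 0], 1.0)
        assert p[0] == 1.0 and (p[1:] == 0).all()

    def test_opposing_directions_zero(self):
        p = migration_probabilities([0.4, -0.2, 0], 1.0)
        assert p[0] == pytest.approx(0.4) and p[1] == 0
        assert p[2] == 0 and p[3] == pytest.approx(0.2)

    def test_oversized_step_is_an_error(self):
        with pytest.raises(ValueError, match="sub-step"):
            migration_probabilities([1.5, 0, 0], 1.0)

    def test_realized_move_is_unbiased(self, empty_lattice):
        """E[realized lattice displacement] equals the continuum displacement
        componentwise (Monte-Carlo oracle)."""
        rng = np.random.default_rng(1)
        dxp = np.array([0.3, -0.45, 0.1]) * empty_lattice.spacing
        n = 100_000
        total = np.zeros(3)
        cls = classify_nodes(empty_lattice, 0.0)
        for _ in range(n):
            st = NanoparticleState(node=[8, 8, 8], velocity=np.zeros(3))
            move_particle(st, dxp, empty_lattice, rng, node_classes=cls)
            total += st.hops
        realized = total / n * empty_lattice.spacing
        se = empty_lattice.spacing * np.sqrt(0.5 / n)  # Bernoulli SE bound
        assert np.all(np.abs(realized - dxp) < 5 * se)


class TestMoveParticle:
    def test_zero_probabilities_no_move(self, empty_lattice, rng):
        st = NanoparticleState(node=[3, 3, 3], velocity=np.zeros(3))
        move_particle(st, np.zeros(3), empty_lattice, rng)
        assert (st.node == [3, 3, 3]).all()

    def test_move_into_fluid_updates_by_one_lattice_vector(self, empty_lattice, rng):
        st = NanoparticleState(node=[3, 3, 3], velocity=np.zeros(3))
        move_particle(st, np.array([empty_lattice.spacing, 0, 0]), empty_lattice, rng)
        assert (st.node == [4, 3, 3]).all() and (st.hops == [1, 0, 0]).all()

    def test_solid_move_rejected(self, rng):
        occ = np.zeros((8, 8, 8), dtype=np.uint8)
        occ[5, :, :] = Label.FIBER
        lat = PorousLattice(occ, 50e-9)
        cls = classify_nodes(lat, 0.0)
        st = NanoparticleState(node=[3, 4, 4], velocity=np.zeros(3))
        # node 4 is contact (adjacent to solid x=5); p_stick=0 -> rejected
        move_particle(st, np.array([lat.spacing, 0, 0]), lat, rng,
                      node_classes=cls, p_stick=0.0)
        assert st.node[0] == 3 and not st.adhered

    def test_contact_with_certain_sticking_adheres(self, rng):
        occ = np.zeros((8, 8, 8), dtype=np.uint8)
        occ[5, :, :] = Label.FIBER
        lat = PorousLattice(occ, 50e-9)
        cls = classify_nodes(lat, 0.0)
        st = NanoparticleState(node=[3, 4, 4], velocity=np.ones(3))
        move_particle(st, np.array([lat.spacing, 0, 0]), lat, rng,
                      node_classes=cls, p_stick=1.0)
        assert st.adhered and st.node[0] == 4
        assert np.allclose(st.velocity, 0)


class TestAdhesionUpdate:
    def test_attractive_wall_at_contact_adheres(self, rng):
        st = NanoparticleState(node=[0, 0, 0], velocity=np.ones(3))
        adhesion_update(st, net_wall_force=-1e-10, mobile_force=1e-13, rng=rng)
        assert st.adhered and np.allclose(st.velocity, 0)

    def test_repulsive_wall_never_adheres(self, rng):
        st = NanoparticleState(node=[0, 0, 0], velocity=np.ones(3))
        adhesion_update(st, net_wall_force=+1e-10, mobile_force=1e-13, rng=rng)
        assert not st.adhered

    def test_outward_drive_releases(self, rng):
        st = NanoparticleState(node=[0, 0, 0], velocity=np.zeros(3), adhered=True)
        adhesion_update(st, net_wall_force=-1e-13, mobile_force=0.0, rng=rng,
                        outward_drive=2e-13)
        assert not st.adhered


class TestEngine:
    def test_zero_forces_zero_flow_stationary(self, empty_lattice):
        cfg = TransportConfig(
            lattice=empty_lattice, temperature=0.0, dt=1e-4, n_steps=50,
            n_particles=10, sample_every=5, replicates=1, seed=0, init="uniform",
        )
        res = simulate(cfg)
        pos = res.records[0].positions
        assert np.allclose(pos, pos[0][None])

    def test_seed_determinism_and_sensitivity(self, small_ecm):
        kw = dict(
            props=NanoparticleProps(), chem=SurfaceChemistry(), lattice=small_ecm,
            dt=5e-4, n_steps=100, n_particles=20, sample_every=5, replicates=2,
        )
        a = simulate(TransportConfig(seed=42, **kw))
        b = simulate(TransportConfig(seed=42, **kw))
        d = simulate(TransportConfig(seed=43, **kw))
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.positions, rb.positions)
            assert np.array_equal(ra.adhered, rb.adhered)
        assert not np.array_equal(a.records[0].positions, d.records[0].positions)

    def test_particles_never_on_solid_nodes(self, small_ecm):
        cfg = TransportConfig(
            props=NanoparticleProps(), chem=None, lattice=small_ecm,
            dt=5e-4, n_steps=200, n_particles=30, sample_every=1, replicates=1, seed=5,
        )
        rec = simulate(cfg).records[0]
        solid = small_ecm.solid
        shape = np.asarray(small_ecm.shape)
        nodes = np.floor(rec.positions / small_ecm.spacing).astype(np.int64) % shape
        flat = nodes.reshape(-1, 3)
        assert not solid[flat[:, 0], flat[:, 1], flat[:, 2]].any()

    def test_free_diffusion_matches_stokes_einstein_gaussian_mode(self):
        """Unbounded Brownian-only run in fluctuation-dissipation mode
        recovers k_B T / (3 pi mu d_p f) within 5%."""
        from nanodiff.analysis import compute_msd, fit_diffusion

        props = NanoparticleProps(drag_prefactor=6.0)
        cfg = TransportConfig(
            props=props, lattice=None, viscosity=7e-4, dt=1e-4, n_steps=2000,
            n_particles=250, sample_every=2, replicates=1, seed=9,
            brownian_mode="gaussian", init="uniform",
        )
        res = simulate(cfg)
        fit = fit_diffusion(compute_msd(res.records))
        expected = free_diffusion_coefficient(props, 7e-4, c.BODY_TEMPERATURE)
        assert fit.d_total == pytest.approx(expected, rel=0.05)

    def test_calibrated_fixed_mode_matches_target_d(self):
        """On-lattice fixed-magnitude mode with the calibrated step diffuses
        at the Stokes-Einstein rate within 5%."""
        from nanodiff.analysis import compute_msd, fit_diffusion
        from nanodiff.experiments import standard_dt

        props = NanoparticleProps()
        lat = PorousLattice(np.zeros((4, 4, 4), dtype=np.uint8), 50e-9)
        cfg = TransportConfig(
            props=props, lattice=lat, dt=standard_dt(), n_steps=1500,
            n_particles=300, sample_every=2, replicates=1, seed=17, init="uniform",
        )
        res = simulate(cfg)
        fit = fit_diffusion(compute_msd(res.records))
        expected = free_diffusion_coefficient(props, 7e-4, c.BODY_TEMPERATURE)
        assert fit.d_total == pytest.approx(expected, rel=0.08)

    def test_magnetic_gradient_biases_z_displacement(self, empty_lattice):
        """+z gradient: mean z displacement exceeds x and y displacements."""
        props = NanoparticleProps(msat=c.NP_MSAT)
        cfg = TransportConfig(
            props=props, lattice=empty_lattice, dt=5e-4, n_steps=300,
            n_particles=100, sample_every=5, replicates=3, seed=3,
            fieldcfg=FieldConfig(grad_b=[0, 0, 6000.0]), init="uniform",
        )
        res = simulate(cfg)
        disp = np.concatenate(
            [r.positions[-1] - r.positions[0] for r in res.records]
        )
        assert disp[:, 2].mean() > abs(disp[:, 0].mean())
        assert disp[:, 2].mean() > abs(disp[:, 1].mean())
        assert disp[:, 2].mean() > 0

    def test_detachment_increases_with_gradient(self):
        """Weak-adhesion scenario: higher magnetic gradient detaches more
        particles."""
        occ = np.zeros((12, 12, 12), dtype=np.uint8)
        occ[:, :, 0] = Label.TUMOR_CELL  # floor wall
        lat = PorousLattice(occ, 50e-9)
        # adhesion barely stronger than the Brownian drive
        chem = SurfaceChemistry(hamaker=2e-24, psi_wall=0.0)
        props = NanoparticleProps(msat=c.NP_MSAT)
        detach = []
        for grad in (0.0, 3000.0, 6000.0):
            cfg = TransportConfig(
                props=props, chem=chem, lattice=lat, dt=5e-4, n_steps=400,
                n_particles=80, sample_every=10, replicates=3, seed=11,
                fieldcfg=FieldConfig(grad_b=[0, 0, grad]), init="uniform",
            )
            res = simulate(cfg)
            detach.append(sum(r.detachment_events for r in res.records))
        assert detach[0] <= detach[1] <= detach[2]
        assert detach[2] > detach[0]

    def test_adhered_fraction_grows_with_stickiness(self, small_ecm):
        fracs = []
        for p_stick in (0.0, 0.05, 1.0):
            cfg = TransportConfig(
                props=NanoparticleProps(), chem=SurfaceChemistry(),
                lattice=small_ecm, dt=5e-4, n_steps=150, n_particles=40,
                sample_every=10, replicates=2, seed=21, stick_probability=p_stick,
            )
            res = simulate(cfg)
            fracs.append(np.mean([r.adhered[-1].mean() for r in res.records]))
        assert fracs[0] == 0.0
        assert fracs[0] < fracs[1] < fracs[2]
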