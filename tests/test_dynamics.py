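"""Kinetics, noise, stencil, and integrator behavior of the excitable medium."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import dictywaves as dw
from dictywaves.lattice import FieldState
from dictywaves.params import ModelParams


def quiet_params(**over):
    """Noise-free parameters for deterministic dynamical tests."""
    over.setdefault("D", 0.0)
    return ModelParams(**over)


# ------------------------------------------------------------- kinetics


class TestThresholdAndRates:
    def test_threshold_direct_substitution(self):
        p = ModelParams(a=0.8, b=0.05)
        assert dw.u_threshold(0.0, p) == pytest.approx(0.0625)
        assert dw.u_threshold(p.a - p.b, p) == pytest.approx(1.0)

    def test_threshold_grid_matches_formula(self):
        p = ModelParams(a=0.63, b=0.11)
        v = np.linspace(-1, 2, 37)
        np.testing.assert_allclose(dw.u_threshold(v, p), (v + 0.11) / 0.63)

    def test_cubic_roots(self):
        p = ModelParams()
        v = np.linspace(0, 0.5, 11)
        assert np.allclose(dw.proactive_rate(0.0, v, p), 0.0)
        assert np.allclose(dw.proactive_rate(1.0, v, p), 0.0)
        uth = dw.u_threshold(v, p)
        assert np.allclose(dw.proactive_rate(uth, v, p), 0.0, atol=1e-12)

    def test_cubic_sign_structure(self):
        """Negative between rest and threshold, positive between threshold and 1."""
        p = ModelParams(a=0.8, b=0.05)
        rng = np.random.default_rng(1)
        for v in rng.uniform(0.0, 0.3, size=20):
            uth = dw.u_threshold(v, p)
            below = rng.uniform(1e-6, uth * (1 - 1e-9), size=50)
            above = rng.uniform(uth * (1 + 1e-9), 1 - 1e-6, size=50)
            assert np.all(dw.proactive_rate(below, v, p) < 0)
            assert np.all(dw.proactive_rate(above, v, p) > 0)

    def test_cubic_matches_bruteforce_evaluation(self):
        p = ModelParams(a=0.7, b=0.04, epsilon=0.03)
        rng = np.random.default_rng(2)
        u = rng.uniform(-0.5, 1.5, size=(6, 6))
        v = rng.uniform(-0.5, 0.8, size=(6, 6))
        expected = np.empty_like(u)
        for i in range(6):
            for j in range(6):
                uth = (v[i, j] + 0.04) / 0.7
                expected[i, j] = u[i, j] * (1 - u[i, j]) * (u[i, j] - uth) / 0.03
        np.testing.assert_allclose(dw.proactive_rate(u, v, p), expected, rtol=1e-12)

    def test_reactive_rate(self):
        p = ModelParams(a=0.8, b=0.05)
        v = np.linspace(0, 0.5, 7)
        uth = dw.u_threshold(v, p)
        assert np.allclose(dw.reactive_rate(uth, v, p), 0.0, atol=1e-15)
        assert dw.reactive_rate(0.0, 0.0, p) == pytest.approx(-0.0625)
        rng = np.random.default_rng(3)
        u, v = rng.normal(size=(2, 5, 5))
        np.testing.assert_allclose(
            dw.reactive_rate(u, v, p), u - (v + 0.05) / 0.8, rtol=1e-12
        )


# ------------------------------------------------------------ OU noise


class TestOUNoise:
    def test_noise_free_limit_decays_exponentially(self):
        p = ModelParams(D=0.0, lam=2.0, dt=0.1, D_u=0.0)
        rng = np.random.default_rng(0)
        eta = np.array(1.0)
        for _ in range(5):
            eta = dw.ou_update(eta, p, rng)
        assert eta == pytest.approx(np.exp(-2.0 * 0.1 * 5))

    def test_stationary_moments(self):
        """Empirical mean and variance match the N(0, D) stationary law."""
        p = ModelParams(D=0.3, lam=1.5, dt=0.05, D_u=0.0)
        rng = np.random.default_rng(42)
        n = 1_000_000
        decay = np.exp(-p.lam * p.dt)
        sd = np.sqrt(p.D * (1 - decay**2))
        # vectorized exact recursion over one long path
        z = rng.standard_normal(n)
        eta = np.empty(n)
        eta[0] = 0.0
        for k in range(1, n):
            eta[k] = eta[k - 1] * decay + sd * z[k]
        tail = eta[1000:]
        # effective sample size accounts for autocorrelation time 1/(lam dt)
        n_eff = len(tail) * np.tanh(p.lam * p.dt / 2) * 2
        assert abs(tail.mean()) < 3 * np.sqrt(p.D / n_eff)
        assert tail.var() == pytest.approx(p.D, rel=0.05)

    def test_autocorrelation_decay(self):
        p = ModelParams(D=0.5, lam=2.0, dt=0.02, D_u=0.0)
        rng = np.random.default_rng(7)
        n = 400_000
        eta = np.empty(n)
        eta[0] = 0.0
        decay = np.exp(-p.lam * p.dt)
        sd = np.sqrt(p.D * (1 - decay**2))
        z = rng.standard_normal(n)
        for k in range(1, n):
            eta[k] = eta[k - 1] * decay + sd * z[k]
        x = eta[1000:] - eta[1000:].mean()
        for lag_steps in (5, 25, 50):
            rho = np.mean(x[:-lag_steps] * x[lag_steps:]) / x.var()
            assert rho == pytest.approx(np.exp(-p.lam * lag_steps * p.dt), abs=0.02)


# ------------------------------------------------------------ laplacian


class TestLaplacian:
    def test_constant_field_harmonic(self):
        assert not dw.laplacian(np.full((5, 5), 2.3), bc="noflux").any()
        assert not dw.laplacian(np.full((5, 5), 2.3), bc="periodic").any()

    def test_periodic_conservation(self):
        f = np.random.default_rng(0).normal(size=(9, 9))
        assert dw.laplacian(f, bc="periodic").sum() == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("bc", ["noflux", "periodic"])
    def test_matches_double_loop_reference(self, bc):
        rng = np.random.default_rng(5)
        f = rng.normal(size=(6, 6))
        h = 0.7
        ref = np.zeros_like(f)
        for i in range(6):
            for j in range(6):
                total = 0.0
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    bi, bj = i + di, j + dj
                    if bc == "periodic":
                        bi, bj = bi % 6, bj % 6
                    else:
                        bi = min(max(bi, 0), 5)
                        bj = min(max(bj, 0), 5)
                    total += f[bi, bj]
                ref[i, j] = (total - 4 * f[i, j]) / h**2
        np.testing.assert_allclose(dw.laplacian(f, bc=bc, h=h), ref, rtol=1e-12)

    def test_unknown_bc_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            dw.laplacian(np.zeros((3, 3)), bc="reflecting")


# ----------------------------------------------------------- integrator


class TestStep:
    def test_all_rest_noise_free_is_fixed_point(self):
        lat = dw.generate_lattice(12, 0.6, 0.2, seed=0)
        p = quiet_params()
        st = FieldState(np.zeros((12, 12)), np.zeros((12, 12)), np.zeros((12, 12)))
        rng = np.random.default_rng(0)
        for _ in range(50):
            st = dw.step(st, lat, p, rng)
        assert not st.u.any() and not st.v.any()

    def test_pure_diffusion_conserves_mass(self):
        """Fully empty lattice, periodic bc: grid sum of u is conserved."""
        lat = dw.generate_lattice(16, 0.0, 0.0, seed=0)
        p = quiet_params(bc="periodic")
        rng = np.random.default_rng(1)
        u0 = np.abs(np.random.default_rng(2).normal(size=(16, 16)))
        st = FieldState(u0.copy(), np.zeros((16, 16)), np.zeros((16, 16)))
        for _ in range(1000):
            st = dw.step(st, lat, p, rng)
        assert st.u.sum() == pytest.approx(u0.sum(), rel=1e-12)

    def test_single_cell_excursion_matches_dense_ode(self):
        """An isolated proactive cell seeded at u=1 performs one excursion and
        relaxes to rest, tracking a dense-step integration of the local ODEs."""
        N = 5
        lat_map = np.zeros((N, N), dtype=np.int8)
        lat_map[2, 2] = 1
        lat = dw.PopulationLattice(N, lat_map, phi1=1 / 25, phi2=0.0, seed=0)
        # isolated (no coupling); dt fine enough that the collapse timing of
        # the semi-implicit scheme stays within the comparison tolerance
        p = quiet_params(D_u=0.0, dt=0.005)

        # seed just off the excited root: u = 1 exactly is a fixed point of
        # the cubic, so an uncoupled cell started there would never collapse
        st = FieldState(np.zeros((N, N)), np.zeros((N, N)), np.zeros((N, N)))
        st.u[2, 2] = 0.95
        rng = np.random.default_rng(0)
        us, vs = [], []
        for _ in range(2400):  # t = 12
            st = dw.step(st, lat, p, rng)
            us.append(st.u[2, 2])
            vs.append(st.v[2, 2])
        us, vs = np.asarray(us), np.asarray(vs)

        # reference: dense integration of the 2-variable local system with the
        # same boundary-layer cutoff
        def rhs(t, y):
            u, v = y
            du = 0.0 if u < p.delta else u * (1 - u) * (u - (v + p.b) / p.a) / p.epsilon
            return [du, u - v]

        ref = solve_ivp(rhs, (0, 12), [0.95, 0.0], dense_output=True,
                        max_step=1e-3, rtol=1e-9, atol=1e-12)
        t_grid = p.dt * np.arange(1, 2401)
        v_ref = ref.sol(t_grid)[1]

        assert us.max() > 0.95                      # stays near the excited branch
        assert us[-1] < 1e-3 and vs[-1] < 1e-3      # back at rest
        collapse = np.argmax(us < p.delta)
        assert 0 < collapse < 2400                  # u collapsed below the layer
        # the slow variable follows the reference excursion closely
        assert np.max(np.abs(vs - v_ref)) < 0.05

    def test_nonfinite_aborts_with_diagnostic(self):
        lat = dw.generate_lattice(8, 0.5, 0.0, seed=0)
        p = quiet_params()
        st = FieldState(np.zeros((8, 8)), np.zeros((8, 8)), np.zeros((8, 8)))
        st.u[3, 3] = np.inf
        with pytest.raises(dw.NumericalInstabilityError, match=r"non-finite u at site \(\d+, \d+\)"):
            dw.step(st, lat, p, np.random.default_rng(0))

    def test_guard_ceiling_aborts(self):
        lat = dw.generate_lattice(8, 0.0, 0.0, seed=0)
        p = quiet_params(u_cap=5.0, D_u=0.0)
        st = FieldState(np.zeros((8, 8)), np.zeros((8, 8)), np.zeros((8, 8)))
        st.u[1, 1] = 7.0
        with pytest.raises(dw.NumericalInstabilityError, match="u_cap"):
            dw.step(st, lat, p, np.random.default_rng(0))


class TestSimulate:
    def test_bookkeeping(self):
        lat = dw.generate_lattice(10, 0.5, 0.0, seed=0)
        p = ModelParams()
        with pytest.raises(ValueError):
            dw.simulate(lat, p, n_iter=0)
        traj = dw.simulate(lat, p, n_iter=1, seed=0)
        assert len(traj.iterations) == 1 and traj.iterations[0] == 1

    def test_same_seed_bit_identical(self):
        lat = dw.generate_lattice(20, 0.5, 0.2, seed=3)
        p = ModelParams()
        a = dw.simulate(lat, p, n_iter=80, seed=11, record_fields=True, record_every=20)
        b = dw.simulate(lat, p, n_iter=80, seed=11, record_fields=True, record_every=20)
        np.testing.assert_array_equal(a.ubar, b.ubar)
        np.testing.assert_array_equal(a.u_snapshots, b.u_snapshots)
        c = dw.simulate(lat, p, n_iter=80, seed=12)
        assert np.any(a.ubar != c.ubar)

    def test_planar_pulse_travels_at_constant_speed(self):
        """phi1=1, no noise: a planar excited stripe becomes a pulse whose
        front advances at constant speed (within 5%)."""
        N = 120
        lat = dw.generate_lattice(N, 1.0, 0.0, seed=0)
        p = quiet_params(h=0.5)
        u = np.zeros((N, N))
        u[:, :4] = 1.0
        st = FieldState(u, np.zeros((N, N)), np.zeros((N, N)))
        traj = dw.simulate(
            lat, p, n_iter=1000, seed=0, state=st, record_fields=True, record_every=40
        )
        pos = []
        for snap in traj.u_snapshots:
            cols = np.where(snap.max(axis=0) > 0.5)[0]
            if len(cols) == 0 or cols.max() >= N - 6:
                break  # pulse reached the far wall (or annihilated there)
            pos.append(cols.max())
        pos = np.asarray(pos, dtype=float)[2:]  # skip the stripe relaxation
        # average the speed over 6-snapshot windows so the +-1 pixel
        # quantisation of the front position does not dominate
        speeds = np.diff(pos[::6]) / 6.0
        assert len(speeds) >= 3
        assert speeds.max() - speeds.min() <= 0.05 * 2 * speeds.mean()

    def test_instability_reports_iteration(self):
        lat = dw.generate_lattice(8, 0.5, 0.5, seed=0)
        # delta > 1 disables the reactive gate's protection entirely while the
        # linear term runs unchecked with a huge dt -> guaranteed blow-up
        p = ModelParams(dt=0.01, u_cap=2.0, D=0.0)
        u = np.full((8, 8), 1.9)
        st = FieldState(u, np.zeros((8, 8)), np.zeros((8, 8)))
        with pytest.raises(dw.NumericalInstabilityError, match="iteration"):
            dw.simulate(lat, p, n_iter=500, seed=0, state=st)


# ----------------------------------------------------------- invariants


class TestInvariants:
    def test_rest_state_stable_below_boundary_layer(self):
        """With no noise and all u < delta the medium stays at rest."""
        lat = dw.generate_lattice(16, 0.7, 0.3, seed=1)
        p = quiet_params()
        rng = np.random.default_rng(0)
        u0 = np.random.default_rng(1).uniform(0, p.delta * 0.9, size=(16, 16))
        st = FieldState(u0, np.zeros((16, 16)), np.zeros((16, 16)))
        for _ in range(2000):
            st = dw.step(st, lat, p, rng)
            assert st.u.max() < p.delta

    def test_refractoriness(self):
        """Immediately after a pulse a supra-threshold kick dies; after full
        recovery the same kick re-excites."""
        N = 5
        lat_map = np.zeros((N, N), dtype=np.int8)
        lat_map[2, 2] = 1
        lat = dw.PopulationLattice(N, lat_map, 1 / 25, 0.0, 0)
        p = quiet_params(D_u=0.0)
        rng = np.random.default_rng(0)

        st = FieldState(np.zeros((N, N)), np.zeros((N, N)), np.zeros((N, N)))
        st.u[2, 2] = 0.95  # off the u = 1 root, which is a true fixed point
        # run until the excursion collapses (u below delta, v still high)
        for _ in range(100_000):
            if st.u[2, 2] < p.delta:
                break
            st = dw.step(st, lat, p, rng)
        assert st.v[2, 2] > 0.3

        # refractory: the same stimulus decays straight back
        st_kick = st.copy()
        st_kick.u[2, 2] = 0.2  # above u_th(0) = 0.04 but below u_th(v_now)
        for _ in range(200):
            st_kick = dw.step(st_kick, lat, p, rng)
        assert st_kick.u[2, 2] < p.delta

        # recovered: wait for v to relax, then the same stimulus fires
        for _ in range(4000):
            st = dw.step(st, lat, p, rng)
        st.u[2, 2] = 0.2
        peak = 0.0
        for _ in range(300):
            st = dw.step(st, lat, p, rng)
            peak = max(peak, st.u[2, 2])
        assert peak > 0.9

    def test_dt_refinement_consistency(self):
        """Halving dt changes the recorded ubar series by < 2% in sup norm."""
        N = 32
        lat = dw.generate_lattice(N, 1.0, 0.0, seed=2)
        u = np.zeros((N, N))
        u[:, :4] = 1.0
        st = FieldState(u, np.zeros((N, N)), np.zeros((N, N)))

        p1 = quiet_params(dt=0.005, h=0.5)
        t1 = dw.simulate(lat, p1, n_iter=200, seed=0, state=st.copy())
        p2 = quiet_params(dt=0.0025, h=0.5)
        t2 = dw.simulate(lat, p2, n_iter=400, seed=0, state=st.copy())
        coarse = t1.ubar
        fine = t2.ubar[1::2]  # same physical times
        err = np.max(np.abs(coarse - fine)) / np.max(np.abs(fine))
        assert err < 0.02

    def test_optional_decay_and_shared_noise_modes(self):
        """Linear decay drains u on empty sites; shared-noise mode gives every
        occupied site the identical OU sample."""
        lat = dw.generate_lattice(12, 0.0, 0.0, seed=0)
        p = quiet_params(decay=0.5, bc="periodic")
        u0 = np.random.default_rng(0).random((12, 12))
        st = FieldState(u0.copy(), np.zeros((12, 12)), np.zeros((12, 12)))
        rng = np.random.default_rng(1)
        for _ in range(200):
            st = dw.step(st, lat, p, rng)
        # all-empty periodic grid: d(sum u)/dt = -decay * sum u exactly
        assert st.u.sum() == pytest.approx(
            u0.sum() * (1 - p.dt * p.decay) ** 200, rel=1e-9
        )

        mixed = dw.generate_lattice(12, 0.6, 0.3, seed=2)
        ps = ModelParams(shared_noise=True)
        st = FieldState(np.zeros((12, 12)), np.zeros((12, 12)), np.zeros((12, 12)))
        st = dw.step(st, mixed, ps, np.random.default_rng(3))
        vals = st.eta[mixed.occupied]
        assert np.ptp(vals) == 0.0 and vals[0] != 0.0
        assert not st.eta[~mixed.occupied].any()

    def test_fields_bounded_under_defaults(self):
        """10000 default-parameter steps keep |u| and |v| below 2."""
        lat = dw.generate_lattice(60, 0.5, 0.1, seed=4)
        p = ModelParams()
        traj = dw.simulate(
            lat, p, n_iter=10_000, seed=4, record_fields=True, record_every=500
        )
        assert np.abs(traj.u_snapshots).max() < 2.0
        assert np.abs(traj.v_snapshots).max() < 2.0
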