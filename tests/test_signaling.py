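import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mechanotaxis.mesh import IntegrityError, shift_down, shift_up
from mechanotaxis.signaling import (CytosolState, MembraneState,
                                    SignalingParams, diffuse_periodic_1d,
                                    filgap_antagonism, gpcr_step,
                                    make_uniform_state, pi_step, rac_rho_step)


def uniform_arc(n=16, L=32.0):
    return np.full(n, L / n)


class TestDiffusion:
    def test_uniform_field_unchanged(self):
        arc = uniform_arc()
        a = 3.0 * arc
        out = diffuse_periodic_1d(a, arc, D=0.5, dt=10.0)
        assert np.allclose(out, a, atol=1e-12)

    def test_mass_conserved_on_nonuniform_lattice(self):
        rng = np.random.default_rng(0)
        arc = rng.uniform(0.5, 1.5, 20)
        a = rng.uniform(0, 2, 20)
        out = diffuse_periodic_1d(a, arc, D=0.3, dt=25.0)
        assert out.sum() == pytest.approx(a.sum(), rel=1e-12)

    def test_cosine_mode_decay_matches_closed_form(self):
        # amplitude of cos(2πs/L) decays as exp(-D (2π/L)^2 t)
        n, L, D = 64, 32.0, 0.1
        arc = uniform_arc(n, L)
        s = np.cumsum(arc) - arc[0] / 2
        c0 = 1.0 + 0.5 * np.cos(2 * np.pi * s / L)
        a = c0 * arc
        t_total, steps = 100.0, 100
        for _ in range(steps):
            a = diffuse_periodic_1d(a, arc, D, t_total / steps)
        amp = (a / arc - 1.0).max()
        expected = 0.5 * np.exp(-D * (2 * np.pi / L) ** 2 * t_total)
        assert amp == pytest.approx(expected, rel=0.01)

    def test_delta_spike_obeys_maximum_principle(self):
        arc = uniform_arc(32)
        a = np.zeros(32)
        a[5] = 1.0
        prev_max = np.inf
        for _ in range(50):
            a = diffuse_periodic_1d(a, arc, 0.2, 1.0)
            assert a.sum() == pytest.approx(1.0, abs=1e-12)
            assert a.max() <= prev_max + 1e-15
            prev_max = a.max()
        assert a.min() >= 0

    def test_nonpositive_arc_rejected(self):
        arc = uniform_arc(8)
        arc[3] = 0.0
        with pytest.raises(IntegrityError):
            diffuse_periodic_1d(np.ones(8), arc, 0.1, 1.0)


class TestGpcrLayer:
    def make(self, n=16):
        params = SignalingParams()
        arc = uniform_arc(n)
        state, cyt = make_uniform_state(arc, params)
        return state, cyt, params

    def test_no_stimulus_stays_dark(self):
        state, cyt, params = self.make()
        for _ in range(50):
            gpcr_step(state, cyt, np.zeros(16), params, 1.0)
        assert np.all(state.a_act == 0)
        assert np.all(state.b_m == 0)
        assert cyt.b_c == 0

    def test_uniform_stimulus_stays_uniform(self):
        state, cyt, params = self.make()
        for _ in range(200):
            gpcr_step(state, cyt, np.ones(16), params, 1.0)
        a = state.conc("a_act")
        assert np.ptp(a) < 1e-12 * max(a.max(), 1)
        assert np.ptp(state.conc("b_m")) < 1e-12

    def test_gradient_localizes_activator_front_inhibitor_back(self):
        state, cyt, params = self.make()
        s = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        stimulus = 1.0 + 0.05 * np.cos(s)   # max at node 0, min at node 8
        for _ in range(400):
            gpcr_step(state, cyt, stimulus, params, 1.0)
        a = state.conc("a_act")
        bm = state.conc("b_m")
        assert int(np.argmax(a)) == 0
        assert int(np.argmax(bm)) == 8
        assert np.all(a >= 0) and np.all(bm >= 0)

    def test_negative_stimulus_rejected(self):
        state, cyt, params = self.make()
        with pytest.raises(IntegrityError):
            gpcr_step(state, cyt, -np.ones(16), params, 1.0)


class TestFilgapAntagonism:
    def test_zero_argument_value(self):
        params = SignalingParams(A_G=9.0)
        q_r, q_rho = filgap_antagonism(0.0, np.zeros(4), params)
        assert np.allclose(q_r, -1.0 / (1.0 + 9.0))

    def test_saturation_limit(self):
        params = SignalingParams()
        q_r, _ = filgap_antagonism(1e6, np.full(4, 1e6), params)
        assert np.allclose(q_r, -1.0, atol=1e-12)

    def test_antisymmetry_exact(self):
        params = SignalingParams()
        rng = np.random.default_rng(1)
        q_r, q_rho = filgap_antagonism(0.02, rng.uniform(0, 5, 12), params)
        assert np.all(q_r + q_rho == 0.0)
        assert np.all((q_r > -1) & (q_r < 0))


class TestRacRhoLayer:
    def params(self):
        return SignalingParams(sigma_noise=0.0, pip3_rac_feedback=0.0)

    def test_uniform_state_stays_uniform(self):
        params = self.params()
        arc = uniform_arc(16)
        state, cyt = make_uniform_state(arc, params)
        q_r, q_rho = filgap_antagonism(0.0, state.conc("pip3"), params)
        for _ in range(200):
            rac_rho_step(state, cyt, q_r, q_rho, params, 1.0)
        assert np.ptp(state.conc("rac")) < 1e-12
        assert np.ptp(state.conc("rho")) < 1e-12

    def test_totals_conserved_under_activity(self):
        params = SignalingParams(sigma_noise=0.4)
        arc = uniform_arc(16)
        state, cyt = make_uniform_state(arc, params)
        rng = np.random.default_rng(3)
        q_r = -rng.uniform(0, 0.9, 16)
        for _ in range(500):
            rac_rho_step(state, cyt, q_r, -q_r, params, 1.0, rng)
        assert state.rac.sum() + cyt.rac_i_amt == pytest.approx(
            params.R_tot, rel=1e-9)
        assert state.rho.sum() + cyt.rho_i_amt == pytest.approx(
            params.rho_tot, rel=1e-9)
        assert np.all(state.rac >= 0) and np.all(state.rho >= 0)
        assert cyt.rac_i >= 0 and cyt.rho_i >= 0

    def test_pool_depletion_without_inactivation(self):
        params = SignalingParams(sigma_noise=0.0, delta_G=0.0, I_R=0.3,
                                 I_rho=0.3, pip3_rac_feedback=0.0)
        arc = uniform_arc(8)
        state, cyt = make_uniform_state(arc, params)
        q = np.zeros(8)
        for _ in range(3000):
            rac_rho_step(state, cyt, q, q, params, 1.0)
        assert cyt.rac_i_amt == pytest.approx(0.0, abs=1e-6 * params.R_tot)
        assert state.rac.sum() == pytest.approx(params.R_tot, rel=1e-9)

    def test_trajectory_matches_dense_ode_oracle(self):
        """8-node fixture vs scipy dense integration of the same ODE system
        (fixed antagonism and activator fields, no noise); the first-order
        split step is Richardson-extrapolated in dt."""
        params = self.params()
        n = 8
        arc = uniform_arc(n, 16.0)
        rng = np.random.default_rng(5)
        q_r = -rng.uniform(0.1, 0.8, n)
        e_p = rng.uniform(0, 0.3, n)

        def run(dt, T=2.0):
            state, cyt = make_uniform_state(arc, params)
            state.a_act = e_p * arc
            steps = int(round(T / dt))
            for _ in range(steps):
                rac_rho_step(state, cyt, q_r, -q_r, params, dt)
            return state.rac / arc

        # oracle: dense ODE for concentrations r_i with conservation pool
        L = arc.sum()
        d = arc[0]

        def rhs(t, r):
            pool = (params.R_tot - np.sum(r * arc)) / L
            lap = params.D_m * (shift_up(r) - 2 * r + shift_down(r)) / d ** 2
            act = params.I_R + params.alpha * e_p
            return lap + act * pool - params.delta_G * r + q_r * r

        r0 = np.full(n, 0.5 * params.R_tot / L)
        sol = solve_ivp(rhs, (0, 2.0), r0, rtol=1e-12, atol=1e-12,
                        dense_output=False, method="DOP853")
        oracle = sol.y[:, -1]
        r1 = run(2e-3)
        r2 = run(1e-3)
        extrapolated = 2 * r2 - r1
        assert np.abs(extrapolated - oracle).max() < 1e-6


class TestPiLayer:
    def test_pure_diffusion_conserves_totals(self):
        params = SignalingParams(sigma_noise=0.0)
        arc = uniform_arc(16)
        state, cyt = make_uniform_state(arc, params)
        cyt.pi3k_free = 0.0
        cyt.pten_free = 0.0
        state.pip3 = np.linspace(1, 3, 16) * arc
        state.pip2 = params.PI_tot / arc.sum() * arc * 2 - state.pip3
        total = state.pip3.sum() + state.pip2.sum()
        for _ in range(100):
            pi_step(state, cyt, params, 1.0, stochastic=False)
        assert state.pip3.sum() + state.pip2.sum() == pytest.approx(
            total, rel=1e-9)

    def test_single_node_conversion_closed_form(self):
        # all PI3K bound at one node, PTEN disabled: PIP2 there decays and
        # PIP3 rises by the same amount
        params = SignalingParams(k_cat2=0.0, D_m=0.0, k_on=0.0, k_off=0.0,
                                 sigma_noise=0.0, cat_half_rac=0.0,
                                 cat_half_rho=0.0)
        arc = uniform_arc(8)
        state, cyt = make_uniform_state(arc, params)
        state.n_pi3k = np.zeros(8)
        state.n_pi3k[2] = 40.0
        cyt.pi3k_free = 0.0
        p2_0 = state.pip2[2]
        p3_0 = state.pip3[2]
        rate = params.k_cat3 * 40.0 / arc[2]
        T = 5.0
        for _ in range(int(T / 0.01)):
            pi_step(state, cyt, params, 0.01, stochastic=False)
        # sub-stepped first-order conversion approximates exponential decay
        assert state.pip2[2] == pytest.approx(p2_0 * np.exp(-rate * T), rel=0.05)
        assert state.pip3[2] + state.pip2[2] == pytest.approx(p3_0 + p2_0,
                                                             rel=1e-12)

    def test_enzyme_counts_conserved_stochastically(self):
        params = SignalingParams()
        arc = uniform_arc(16)
        state, cyt = make_uniform_state(arc, params)
        rng = np.random.default_rng(7)
        for _ in range(300):
            pi_step(state, cyt, params, 1.0, rng, stochastic=True)
        assert state.n_pi3k.sum() + cyt.pi3k_free == params.n_pi3k_total
        assert state.n_pten.sum() + cyt.pten_free == params.n_pten_total
        assert float(state.n_pi3k.sum()).is_integer()

    def test_mc_binding_matches_mean_field_propensity(self):
        """Averaged over many draws, stochastic binding equals the
        deterministic expectation within 3 standard errors."""
        params = SignalingParams()
        arc = uniform_arc(16)
        rng = np.random.default_rng(11)
        base_state, base_cyt = make_uniform_state(arc, params)
        base_state.pip3 = np.linspace(0.5, 3.5, 16) * arc
        base_state.pip2 = 4.0 * arc - base_state.pip3

        import copy
        det = copy.deepcopy(base_state)
        det_c = copy.deepcopy(base_cyt)
        pi_step(det, det_c, params, 1.0, stochastic=False)
        expected = det.n_pi3k

        n_rep = 400
        acc = np.zeros(16)
        for _ in range(n_rep):
            st = copy.deepcopy(base_state)
            cy = copy.deepcopy(base_cyt)
            pi_step(st, cy, params, 1.0, rng, stochastic=True)
            acc += st.n_pi3k
        mean = acc / n_rep
        se = np.sqrt(np.maximum(expected, 1.0)) / np.sqrt(n_rep)
        assert np.all(np.abs(mean - expected) < 3.5 * se + 0.05 * expected)

    def test_mirror_symmetry_of_pip2(self):
        # high-PIP3 nodes are low-PIP2 nodes: the closed pool makes the
        # PIP2 pattern mirror PIP3
        params = SignalingParams()
        arc = uniform_arc(16)
        state, cyt = make_uniform_state(arc, params)
        rng = np.random.default_rng(2)
        for _ in range(300):
            pi_step(state, cyt, params, 1.0, rng, stochastic=True)
        p3 = state.conc("pip3")
        p2 = state.conc("pip2")
        if np.ptp(p3) > 0.2:  # once any pattern has formed
            corr = np.corrcoef(p3, p2)[0, 1]
            assert corr < -0.5
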