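"""Linear stability: Jacobian correctness, conservation null space,
reflection symmetry, dispersion–simulation agreement."""

import numpy as np
import pytest

from minflow import (
    FieldState, Grid, Schedule, dispersion_relation, flow_driven_threshold,
    homogeneous_steady_state, jacobian_at_q, simulate,
)
from minflow.models import _flux_arrays
from minflow.stability import reaction_jacobian


@pytest.fixture(scope="module")
def steady(params):
    return homogeneous_steady_state(params)


class TestJacobian:
    def test_matches_finite_differences(self, params, steady):
        """Analytic reaction Jacobian vs central differences of the fluxes."""
        y0 = steady.as_array().reshape(6)
        R = reaction_jacobian(params, steady)
        num = np.zeros((6, 6))
        scale = max(params.n_D_mean, 1.0)
        h = 1e-6 * scale
        for j in range(6):
            yp, ym = y0.copy(), y0.copy()
            yp[j] += h
            ym[j] -= h
            num[:, j] = (np.array(_flux_arrays(*yp, params))
                         - np.array(_flux_arrays(*ym, params))) / (2 * h)
        assert np.abs(R - num).max() < 1e-6 * max(np.abs(R).max(), 1.0)

    def test_two_zero_eigenvalues_at_q0(self, params, steady):
        """Both conservation laws force a 2D null space of J(0), for any
        flow velocity."""
        for v in (0.0, 3.0):
            J = jacobian_at_q(params.with_(v_f=v), steady, 0.0)
            ev = np.sort(np.abs(np.linalg.eigvals(J)))
            assert ev[0] < 1e-10 and ev[1] < 1e-10
            assert ev[2] > 1e-6

    def test_skeleton_null_space_also_2d(self, params):
        p = params.skeleton()
        ss = homogeneous_steady_state(p)
        J = jacobian_at_q(p, ss, 0.0)
        ev = np.sort(np.abs(np.linalg.eigvals(J)))
        assert ev[0] < 1e-10 and ev[1] < 1e-10

    def test_real_at_zero_flow(self, params, steady):
        J = jacobian_at_q(params.with_(v_f=0.0), steady, 0.3)
        assert np.abs(J.imag).max() == 0.0

    def test_rejects_non_steady_state(self, params, grid1d):
        bogus = FieldState.uniform([100, 100, 100, 100, 100, 100], grid1d)
        with pytest.raises(ValueError, match="fixed point"):
            jacobian_at_q(params, bogus, 0.1)

    def test_advection_mask_enters_minE_rows(self, params, steady):
        q, v = 0.2, 2.0
        J_on = jacobian_at_q(params.with_(v_f=v), steady, q)
        J_off = jacobian_at_q(params.with_(v_f=v, advect_minE=False),
                              steady, q)
        diff = J_on - J_off
        expected = np.zeros((6, 6), complex)
        expected[4, 4] = expected[5, 5] = -1j * q * v
        assert np.allclose(diff, expected)


class TestDispersion:
    def test_reflection_symmetry_at_zero_flow(self, params):
        """At v_f = 0, σ(q) = σ(−q)."""
        p = params.with_(v_f=0.0)
        q = np.linspace(0.05, 0.8, 40)
        d_pos = dispersion_relation(p, q)
        d_neg = dispersion_relation(p, -q)
        assert np.allclose(d_pos.sigma.real, d_neg.sigma.real, atol=1e-10)
        assert np.allclose(np.abs(d_pos.sigma.imag),
                           np.abs(d_neg.sigma.imag), atol=1e-10)

    def test_flow_reversal_mirrors_spectrum(self, params):
        """v_f → −v_f maps σ(q) to σ(−q)."""
        q = np.linspace(0.02, 0.6, 30)
        d_fwd = dispersion_relation(params.with_(v_f=1.5), q)
        d_bwd = dispersion_relation(params.with_(v_f=-1.5), -q)
        assert np.allclose(d_fwd.sigma, d_bwd.sigma, atol=1e-10)

    def test_skeleton_dispersion_equals_full_at_mu0(self, params):
        q = np.linspace(0.0, 0.8, 50)
        d_full = dispersion_relation(params.with_(mu=0.0), q)
        d_skel = dispersion_relation(params.skeleton(), q)
        # skeleton steady state carries no latent pool; leading branches agree
        assert np.allclose(d_full.sigma, d_skel.sigma, atol=1e-9)

    def test_growth_rate_matches_simulation(self, params, growth_check_point):
        """Seed the fastest-growing eigenmode at small amplitude and compare
        the measured exponential growth rate and phase velocity against the
        dispersion relation (within 5%)."""
        p, expected_sigma, q_peak = growth_check_point
        _assert_linear_growth_matches(p, expected_sigma, q_peak)


@pytest.fixture(params=["rest_unstable", "flow_unstable"])
def growth_check_point(request, params):
    if request.param == "rest_unstable":
        p = params.with_(ed_ratio=0.2, v_f=0.0)
    else:
        p = params.with_(ed_ratio=0.05, v_f=3.0)
    q = np.concatenate([[0.0], np.geomspace(5e-4, 1.5, 400)])
    d = dispersion_relation(p, q)
    i = int(np.argmax(d.sigma.real[1:])) + 1
    return p, d.sigma[i], d.q_grid[i]


def _assert_linear_growth_matches(p, sigma, q_peak, rel=0.05):
    from minflow.stability import _jac_unchecked

    n_waves = max(int(round(200 * q_peak / (2 * np.pi))), 1)
    L = 2 * np.pi * n_waves / q_peak              # commensurate domain
    grid = Grid.line(L, 128)
    ss_scalar = homogeneous_steady_state(p)
    ss = homogeneous_steady_state(p, grid)
    # seed the eigenvector of the leading branch: δu = ε·Re(v e^{iqx})
    # evolves as a single exponential e^{σt} in the +q Fourier mode
    J = _jac_unchecked(p, ss_scalar, q_peak)
    w, V = np.linalg.eig(J)
    v = V[:, np.argmax(w.real)]
    ss_vals = ss_scalar.as_array().reshape(6)
    eps = 1e-3 * np.min(np.where(np.abs(v) > 1e-12,
                                 np.maximum(ss_vals, 1e-6) / np.abs(v), np.inf))
    a = ss.as_array()
    wavefield = np.exp(1j * q_peak * grid.x)
    for i in range(6):
        a[i] += eps * np.real(v[i] * wavefield)
    s0 = FieldState.from_array(np.clip(a, 0.0, None))
    t_end = min(2.5 / max(sigma.real, 1e-3), 600.0)
    traj = simulate(s0, p, grid, Schedule(dt=0.02, t_end=t_end,
                                          save_every=int(t_end / 0.02 / 40)))
    spec = np.fft.rfft(traj.species("m_d")
                       - traj.species("m_d").mean(axis=1, keepdims=True),
                       axis=1)[:, n_waves]
    n0 = 2
    t = traj.times[n0:]
    amp_fit = np.polyfit(t, np.log(np.abs(spec[n0:])), 1)[0]
    phase_fit = np.polyfit(t, np.unwrap(np.angle(spec[n0:])), 1)[0]
    assert amp_fit == pytest.approx(sigma.real, rel=rel)
    v_measured = -phase_fit / q_peak
    v_expected = -sigma.imag / q_peak
    assert v_measured == pytest.approx(v_expected, rel=rel, abs=1e-4)


def _domain_modes(L=512.0, q_max=1.0):
    """Discrete wavenumbers admitted by a finite periodic domain; the
    conserved modes at q → 0 are soft, so thresholds are stated on a
    realizable geometry."""
    kmax = int(q_max * L / (2 * np.pi))
    return 2 * np.pi * np.arange(1, kmax + 1) / L


class TestFlowDrivenThreshold:
    def test_unstable_at_rest_rejected(self, params):
        p = params.with_(ed_ratio=0.2, v_f=0.0)
        with pytest.raises(ValueError, match="unstable"):
            flow_driven_threshold(p, np.linspace(0, 3, 4))

    def test_threshold_exists_at_low_ed(self, params):
        """A laterally stable low-E:D point destabilizes at finite flow."""
        p = params.with_(ed_ratio=0.05)
        q = _domain_modes()
        vc = flow_driven_threshold(p, np.linspace(0.0, 4.0, 9), q_grid=q)
        assert vc is not None and 0.0 < vc < 4.0
        from minflow.stability import max_growth_rate
        assert max_growth_rate(p.with_(v_f=1.3 * vc), q) > 0
        assert max_growth_rate(p.with_(v_f=0.7 * vc), q) < 0

    def test_threshold_even_in_flow_sign(self, params):
        p = params.with_(ed_ratio=0.05)
        q = _domain_modes()
        v_pos = flow_driven_threshold(p, np.linspace(0, 4, 9), q_grid=q)
        v_neg = flow_driven_threshold(p, -np.linspace(0, 4, 9), q_grid=q)
        assert v_pos == pytest.approx(v_neg, rel=1e-3)
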