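"""Integrator: exact transport, conservation, symmetry, variant relations."""

import numpy as np
import pytest

from minflow import (
    FieldState, Grid, Schedule, get_parameter_set, homogeneous_steady_state,
    kymograph, simulate, step,
)
from minflow.parameters import KineticParameters


def transport_only_params(D_m=0.1, D_c=10.0, v_f=2.0):
    """All reactions off: pure diffusion + advection."""
    return KineticParameters(
        name="transport", k_D=0, k_dD=0, k_dEr=0, k_dEi=0, k_de=0,
        lambda_=0, mu=0, D_m=D_m, D_c=D_c, v_f=v_f,
        n_D_mean=1.0, n_E_mean=1.0)


def single_mode_state(grid, k=3, amp=0.5):
    q = 2 * np.pi * k / grid.lengths[0]
    f = 1.0 + amp * np.cos(q * grid.x)
    return FieldState(*[f.copy() for _ in range(6)]), q


class TestTransport:
    def test_fourier_mode_decay_rate(self):
        """A single mode of wavenumber q decays as exp(−D q² t)."""
        g = Grid.line(100.0, 128)
        p = transport_only_params(v_f=0.0)
        st, q = single_mode_state(g)
        traj = simulate(st, p, g, Schedule(dt=0.05, t_end=20.0, save_every=400))
        t = traj.times[-1]
        for species, D in (("m_d", p.D_m), ("c_DD", p.D_c)):
            prof = traj.species(species)[-1]
            expected = 1.0 + 0.5 * np.exp(-D * q * q * t) * np.cos(q * g.x)
            assert np.abs(prof - expected).max() < 1e-10

    def test_advection_is_exact_translation(self):
        """Bulk Gaussian translates by v_f·t with no numerical diffusion
        (spectral integrating factor), membrane species do not move."""
        g = Grid.line(200.0, 256)
        p = transport_only_params(D_m=0.0, D_c=0.0, v_f=1.5)
        x = g.x
        blob = 1.0 + np.exp(-((x - 60.0) / 8.0) ** 2)
        st = FieldState(*[blob.copy() for _ in range(6)])
        traj = simulate(st, p, g, Schedule(dt=0.05, t_end=40.0, save_every=800))
        t = traj.times[-1]
        shifted = 1.0 + np.exp(-((np.mod(x - p.v_f * t - 60.0 + 100.0, 200.0)
                                  - 100.0) / 8.0) ** 2)
        assert np.abs(traj.species("c_DT")[-1] - shifted).max() < 1e-8
        assert traj.species("c_DT")[-1].max() == pytest.approx(
            shifted.max(), rel=1e-8)        # no peak decay beyond sampling
        assert np.abs(traj.species("m_d")[-1] - blob).max() < 1e-12

    def test_minE_advection_flag(self):
        g = Grid.line(200.0, 128)
        p = transport_only_params(D_m=0, D_c=0, v_f=1.0).with_(advect_minE=False)
        blob = 1.0 + np.exp(-((g.x - 60.0) / 10.0) ** 2)
        st = FieldState(*[blob.copy() for _ in range(6)])
        out = step(st, p, g, 5.0)
        assert np.abs(out.c_Er - blob).max() < 1e-12       # MinE frozen
        assert np.abs(out.c_DT - blob).max() > 0.1         # MinD advected


class TestSimulate:
    def test_uniform_steady_state_is_fixed_point(self, params, grid1d):
        """Uniform states are advection-invariant: the homogeneous steady
        state does not move even under flow."""
        p = params.with_(v_f=3.0)
        ss = homogeneous_steady_state(p, grid1d)
        traj = simulate(ss, p, grid1d,
                        Schedule(dt=0.02, t_end=100.0, save_every=5000))
        rel = np.abs(traj.frames[-1] - traj.frames[0]).max() / p.n_D_mean
        assert rel < 1e-8

    def test_mass_conservation_under_dynamics(self, params, grid1d, rng):
        """Relative drift of both totals below 1e-6 over 1000 steps."""
        from tests.conftest import random_state
        st = random_state(params, grid1d, rng)
        traj = simulate(st, params.with_(v_f=1.0), grid1d,
                        Schedule(dt=0.02, t_end=20.0, save_every=100))
        cons = traj.conservation
        drift = np.abs(cons - cons[0]).max() / max(params.n_D_mean, 1.0)
        assert drift < 1e-6
        assert traj.valid

    def test_mirror_equivariance(self, params, grid1d, rng):
        """v_f → −v_f with x → −x maps trajectories onto each other."""
        from tests.conftest import random_state
        st = random_state(params, grid1d, rng)
        sched = Schedule(dt=0.02, t_end=10.0, save_every=250)
        fwd = simulate(st, params.with_(v_f=1.0), grid1d, sched)
        bwd = simulate(st.mirrored(), params.with_(v_f=-1.0), grid1d, sched)
        assert np.allclose(fwd.frames[-1],
                           np.flip(bwd.frames[-1], axis=-1), atol=1e-10)

    def test_determinism(self, params, grid1d):
        from minflow.synth import noisy_homogeneous_state
        s0 = noisy_homogeneous_state(params, grid1d, seed=7)
        sched = Schedule(dt=0.05, t_end=5.0, save_every=50)
        a = simulate(s0, params, grid1d, sched)
        b = simulate(s0, params, grid1d, sched)
        assert np.array_equal(a.frames, b.frames)

    def test_skeleton_equals_full_at_mu_zero(self, params, grid1d, rng):
        """The skeleton variant is the full variant with μ=0 and no latent
        pool: matched initial conditions give identical trajectories."""
        from tests.conftest import random_state
        st = random_state(params, grid1d, rng)
        st.c_Ei[:] = 0.0
        sched = Schedule(dt=0.02, t_end=10.0, save_every=500)
        full0 = simulate(st, params.with_(mu=0.0), grid1d, sched)
        skel = simulate(st, params.skeleton(), grid1d, sched)
        assert np.allclose(full0.frames, skel.frames, atol=1e-12)

    def test_blowup_aborts_with_diagnostics(self, grid1d):
        p = transport_only_params().with_(k_dD=50.0, k_D=1.0)
        st = FieldState.uniform([100, 0, 0, 100, 0, 0], grid1d)
        with pytest.raises(FloatingPointError, match="blew up"):
            simulate(st, p, grid1d, Schedule(dt=0.5, t_end=50.0))


class TestKymograph:
    def test_translating_profile_slope(self):
        """Injected traveling profile appears as stripes of slope 1/c."""
        g = Grid.line(100.0, 100)
        c = 0.5
        times = np.arange(0.0, 40.0, 2.0)
        frames = []
        for t in times:
            prof = np.cos(2 * np.pi * (g.x - c * t) / 50.0)
            frames.append(np.stack([prof] * 6))
        from minflow.simulator import Trajectory
        traj = Trajectory(times=times, frames=np.stack(frames), grid=g,
                          params=transport_only_params())
        kymo = kymograph(traj, "m_d")
        assert kymo.shape == (len(times), 100)
        # phase of dominant mode advances by q·c·dt per row
        spec = np.fft.rfft(kymo, axis=1)[:, 2]
        dphi = np.diff(np.unwrap(np.angle(spec)))
        q = 2 * np.pi * 2 / 100.0
        assert np.allclose(-dphi / (q * 2.0), c, rtol=1e-6)

    def test_uniform_state_constant_image(self, params, grid1d):
        ss = homogeneous_steady_state(params, grid1d)
        traj = simulate(ss, params, grid1d,
                        Schedule(dt=0.05, t_end=2.0, save_every=10))
        kymo = kymograph(traj, "m_d")
        assert np.ptp(kymo) < 1e-10 * params.n_D_mean

    def test_unknown_species_rejected(self, params, grid1d):
        ss = homogeneous_steady_state(params, grid1d)
        traj = simulate(ss, params, grid1d,
                        Schedule(dt=0.05, t_end=1.0, save_every=10))
        with pytest.raises(ValueError, match="species"):
            kymograph(traj, "nope")


class TestTrajectoryIO:
    def test_hdf5_roundtrip(self, params, grid1d, tmp_path):
        ss = homogeneous_steady_state(params, grid1d)
        traj = simulate(ss, params, grid1d,
                        Schedule(dt=0.05, t_end=1.0, save_every=10))
        path = tmp_path / "traj.h5"
        traj.save(path)
        from minflow.simulator import Trajectory
        back = Trajectory.load(path)
        assert np.array_equal(back.frames, traj.frames)
        assert back.params == params
        assert back.grid == grid1d


class TestTwoDimensional:
    def test_uniform_fixed_point_2d(self, params):
        g = Grid.plane((64.0, 32.0), (64, 32))
        p = params.with_(v_f=2.0)
        ss = homogeneous_steady_state(p, g)
        traj = simulate(ss, p, g, Schedule(dt=0.05, t_end=5.0, save_every=100))
        assert np.abs(traj.frames[-1] - traj.frames[0]).max() < 1e-9 * p.n_D_mean

    def test_advection_acts_along_first_axis_only(self):
        g = Grid.plane((64.0, 64.0), (64, 64))
        p = transport_only_params(D_m=0.0, D_c=0.0, v_f=1.0)
        yy = np.exp(-((np.arange(64) * 1.0 - 32.0) / 6.0) ** 2)
        blob = np.outer(np.ones(64), yy) + np.outer(
            np.exp(-((np.arange(64) * 1.0 - 20.0) / 6.0) ** 2), np.ones(64))
        st = FieldState(*[blob.copy() for _ in range(6)])
        out = step(st, p, g, 4.0)
        expected = np.outer(np.ones(64), yy) + np.outer(
            np.exp(-((np.mod(np.arange(64) * 1.0 - 4.0, 64.0) - 20.0) / 6.0) ** 2),
            np.ones(64))
        assert np.abs(out.c_DT - expected).max() < 1e-6

    def test_kymograph_2d_policies(self, params):
        g = Grid.plane((64.0, 16.0), (64, 16))
        ss = homogeneous_steady_state(params, g)
        traj = simulate(ss, params, g, Schedule(dt=0.05, t_end=1.0, save_every=10))
        assert kymograph(traj, "m_d", line=3).shape == (len(traj), 64)
        assert kymograph(traj, "m_d", line="mean").shape == (len(traj), 64)
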