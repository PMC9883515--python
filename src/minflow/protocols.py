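"""Shipped verification protocols at desk scale.

Each function runs one self-contained computational experiment on the
default parameter set (overridable) and returns plain dictionaries, so the
same code backs the test suite and the reproduction script.  All
randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from minflow.models import homogeneous_steady_state, reduce_switch_model
from minflow.parameters import KineticParameters, get_parameter_set
from minflow.simulator import Schedule, simulate
from minflow.state import FieldState, Grid
from minflow.stability import _jac_unchecked, dispersion_relation
from minflow.sweeps import (NoPatternError, _segment, classify,
                            minE_advection_ablation, pattern_velocity)
from minflow.synth import noisy_homogeneous_state, seeded_wave_state

DEFAULT_DT = 0.01

#: E:D paths of the upstream-onset sweep: a coarse adiabatic upward march
#: from 0.02, then a downward march densified around the transition.  The
#: upward leg develops the pattern and exposes the hysteresis; the
#: downward leg carries a developed upstream wave to the smallest ratio
#: at which upstream propagation still exists — the onset being measured.
ONSET_ED_UP = (0.02, 0.08, 0.13, 0.18, 0.22)
ONSET_ED_DOWN = (0.22, 0.18, 0.15, 0.13, 0.12, 0.11, 0.10, 0.09, 0.08,
                 0.07, 0.06, 0.05, 0.04)

#: Flow velocity of the onset sweep (μm/s): a few times the intrinsic wave
#: phase speed.  At this moderate flow the downward-carried upstream wave
#: has a genuine, seed-robust existence boundary: below it the
#: long-wavelength flow-driven downstream band outcompetes the weakening
#: upstream wave.  (At much weaker flow finite-amplitude upstream waves are
#: deeply subcritical and persist to arbitrarily small ratios, so no
#: boundary is measurable there.)
ONSET_V_F = 2.0


def _default_params() -> KineticParameters:
    return get_parameter_set("denk2d")


# ---------------------------------------------------------------------------
# Upstream onset (the headline number)
# ---------------------------------------------------------------------------

def upstream_onset_sweep(seed: int = 0, v_f: float = ONSET_V_F,
                         ed_up=ONSET_ED_UP, ed_down=ONSET_ED_DOWN,
                         L: float = 384.0, n: int = 384,
                         dt: float = DEFAULT_DT, t_relax: float = 200.0,
                         t_measure: float = 200.0, t_develop: float = 300.0,
                         t_up_segment: float = 250.0,
                         params: KineticParameters | None = None) -> dict:
    """Adiabatic E:D loop at fixed moderate flow.

    The upward leg is an adiabatic sweep from a noisy homogeneous state at
    the lowest ratio: the low ratios form no pattern at rest, a downstream
    wave develops on the march, and multistability keeps it downstream to
    the top — exposing the sweep-history dependence.  The downward leg
    starts from a seeded upstream wave of the intrinsic wavelength at the
    top ratio (the upstream member of the multistable pair there;
    ``t_develop`` extra dwell lets it settle into the nonlinear wave),
    then carries it down until it converts to the flow-driven downstream
    state; the smallest ratio classified upstream anywhere on the loop is
    the reported onset — the boundary below which upstream propagation no
    longer exists at this flow.
    """
    from minflow.sweeps import _rescale_minE

    p0 = params or _default_params()
    grid = Grid.line(L, n)
    lam_seed = L / round(L / 43.0)     # band-peak wavelength harmonic
    first_upstream = None
    legs = {}
    for leg, path in (("up", ed_up), ("down", ed_down)):
        points = []
        state = None
        for i, ed in enumerate(path):
            p = p0.with_(ed_ratio=float(ed), v_f=float(v_f))
            # the upward leg only exhibits the hysteresis; shorter dwell
            measure = t_measure if leg == "down" else \
                max(t_up_segment - t_relax / 2, 100.0)
            relax = t_relax if leg == "down" else t_relax / 2
            if state is None:
                if leg == "up":
                    state = noisy_homogeneous_state(p, grid, seed=seed)
                else:
                    state = seeded_wave_state(p, grid, lam_seed, -1,
                                              seed=seed, amplitude=0.3)
                    relax = t_relax + t_develop
            else:
                state = _rescale_minE(state, p)
            traj, state = _segment(state, p, grid, dt, relax, measure, 5.0)
            meas = classify(traj, window=1.0)
            points.append({"ed_ratio": float(ed), "leg": leg,
                           "classification": meas.classification,
                           "velocity": meas.velocity,
                           "wavelength": meas.wavelength,
                           "amplitude": meas.amplitude})
            if meas.classification == "upstream" and \
                    (first_upstream is None or ed < first_upstream):
                first_upstream = float(ed)
        legs[leg] = points
    return {"v_f": v_f, "up": legs["up"], "down": legs["down"],
            "points": legs["up"] + legs["down"],
            "upstream_onset": first_upstream}


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

def conservation_check(seed: int = 0, n_steps: int = 1000,
                       params: KineticParameters | None = None) -> dict:
    """Relative drift of both totals over ``n_steps`` of a developed-wave
    trajectory under flow."""
    p = (params or _default_params()).with_(ed_ratio=0.2, v_f=1.0)
    grid = Grid.line(256.0, 256)
    s0 = seeded_wave_state(p, grid, 42.7, +1, seed=seed)
    sched = Schedule(dt=DEFAULT_DT, t_end=n_steps * DEFAULT_DT,
                     save_every=max(n_steps // 20, 1))
    traj = simulate(s0, p, grid, sched)
    cons = traj.conservation
    scale = max(p.n_D_mean, p.n_E_mean)
    drift = float(np.abs(cons - cons[0]).max() / scale)
    return {"relative_drift": drift, "n_steps": n_steps,
            "clipped_points": traj.clipped_points}


# ---------------------------------------------------------------------------
# Dispersion vs simulation
# ---------------------------------------------------------------------------

def growth_rate_agreement(seed: int = 0,
                          points=((0.15, 0.0), (0.2, 0.0), (0.2, 1.0)),
                          params: KineticParameters | None = None) -> list[dict]:
    """Growth rate and phase velocity of the fastest-growing mode, from the
    dispersion relation and from an eigenvector-seeded small-amplitude
    simulation, at several (E:D, v_f) points."""
    p0 = params or _default_params()
    out = []
    q_grid = np.concatenate([[0.0], np.geomspace(5e-4, 1.5, 400)])
    for ed, v in points:
        p = p0.with_(ed_ratio=ed, v_f=v)
        d = dispersion_relation(p, q_grid)
        i = int(np.argmax(d.sigma.real[1:])) + 1
        sigma, q_peak = d.sigma[i], d.q_grid[i]
        n_waves = max(int(round(200 * q_peak / (2 * np.pi))), 1)
        L = 2 * np.pi * n_waves / q_peak
        grid = Grid.line(L, 128)
        ss_scalar = homogeneous_steady_state(p)
        J = _jac_unchecked(p, ss_scalar, q_peak)
        w, V = np.linalg.eig(J)
        vec = V[:, np.argmax(w.real)]
        ss_vals = ss_scalar.as_array().reshape(6)
        eps = 1e-3 * np.min(np.where(np.abs(vec) > 1e-12,
                                     np.maximum(ss_vals, 1e-6) / np.abs(vec),
                                     np.inf))
        a = homogeneous_steady_state(p, grid).as_array()
        wavefield = np.exp(1j * q_peak * grid.x)
        for k in range(6):
            a[k] += eps * np.real(vec[k] * wavefield)
        s0 = FieldState.from_array(np.clip(a, 0.0, None))
        t_end = min(2.5 / max(sigma.real, 1e-3), 600.0)
        traj = simulate(s0, p, grid,
                        Schedule(dt=0.02, t_end=t_end,
                                 save_every=max(int(t_end / 0.02 / 40), 1)))
        spec = np.fft.rfft(traj.species("m_d") -
                           traj.species("m_d").mean(axis=1, keepdims=True),
                           axis=1)[:, n_waves]
        t = traj.times[2:]
        amp_fit = float(np.polyfit(t, np.log(np.abs(spec[2:])), 1)[0])
        phase_fit = float(np.polyfit(t, np.unwrap(np.angle(spec[2:])), 1)[0])
        out.append({
            "ed_ratio": ed, "v_f": v, "q_peak": float(q_peak),
            "growth_predicted": float(sigma.real),
            "growth_measured": amp_fit,
            "phase_velocity_predicted": float(-sigma.imag / q_peak),
            "phase_velocity_measured": float(-phase_fit / q_peak),
        })
    return out


# ---------------------------------------------------------------------------
# Variant dichotomy
# ---------------------------------------------------------------------------

def skeleton_direction_grid(seed: int = 0,
                            eds=(0.02, 0.035, 0.05),
                            vfs=(1.5, 2.5, 3.5),
                            params: KineticParameters | None = None
                            ) -> list[dict]:
    """Propagation direction of the skeleton (no-switch) variant on a grid
    of low ratios and flow speeds, from seeded flow-driven waves."""
    p0 = (params or _default_params()).skeleton()
    grid = Grid.line(512.0, 512)
    out = []
    for ed in eds:
        for v in vfs:
            p = p0.with_(ed_ratio=ed, v_f=v)
            lam = grid.lengths[0] / 2          # flow-driven band is long-wave
            s0 = seeded_wave_state(p, grid, lam, +1 if v > 0 else -1,
                                   seed=seed, amplitude=0.2)
            traj, _ = _segment(s0, p, grid, DEFAULT_DT, 120.0, 200.0, 5.0)
            meas = classify(traj, window=1.0)
            out.append({"ed_ratio": ed, "v_f": v, "variant": "skeleton",
                        "classification": meas.classification,
                        "velocity": meas.velocity})
    return out


def reduced_direction_grid(seed: int = 0,
                           eds=(0.15, 0.2, 0.3),
                           vfs=(1.0, 2.0, 4.0),
                           params: KineticParameters | None = None
                           ) -> list[dict]:
    """Drift direction of the reduced-switch variant on a grid of ratios
    and flow speeds.

    The reduced model's waves are linearly damped for the default rates, so
    each run seeds a finite-amplitude wave and measures the drift of the
    decaying pattern while its amplitude stays above threshold.
    """
    from minflow.simulator import Trajectory
    from minflow.sweeps import AMPLITUDE_THRESHOLD

    p0 = params or _default_params()
    grid = Grid.line(256.0, 256)
    out = []
    for ed in eds:
        for v in vfs:
            p_full = p0.with_(ed_ratio=ed, v_f=v)
            p_red = reduce_switch_model(p_full)
            lam = grid.lengths[0] / round(grid.lengths[0] / 40.0)
            s0 = seeded_wave_state(p_red, grid, lam, +1, seed=seed,
                                   amplitude=0.5)
            sched = Schedule(dt=DEFAULT_DT, t_end=120.0, save_every=200)
            traj = simulate(s0, p_red, grid, sched)
            # waves are damped in this variant: measure the drift over the
            # frames where the pattern amplitude is still above threshold
            amps = [np.std(fr[0]) / np.mean(fr[0]) for fr in traj.frames]
            k = int(np.sum(np.asarray(amps) >= AMPLITUDE_THRESHOLD))
            try:
                if k < 5:
                    raise NoPatternError("decayed too fast")
                sub = Trajectory(times=traj.times[:k], frames=traj.frames[:k],
                                 grid=grid, params=p_red)
                vel = pattern_velocity(sub, window=1.0)
                cls = "upstream" if vel * v < 0 else "downstream"
            except NoPatternError:
                vel, cls = float("nan"), "no_pattern"
            out.append({"ed_ratio": ed, "v_f": v, "variant": "reduced_switch",
                        "classification": cls, "velocity": vel})
    return out


# ---------------------------------------------------------------------------
# MinE-advection ablation
# ---------------------------------------------------------------------------

def ablation_report(seed: int = 0,
                    params: KineticParameters | None = None) -> dict:
    """Direction with and without MinE advection at one high-E:D and one
    low-E:D point."""
    p0 = params or _default_params()
    out = {}
    # high E:D: developed upstream wave regime
    grid = Grid.line(256.0, 256)
    p_hi = p0.with_(ed_ratio=0.2)
    s_hi = seeded_wave_state(p_hi.with_(v_f=1.0), grid, 42.7, -1, seed=seed,
                             amplitude=0.3)
    out["high_ed"] = {
        k: {"classification": m.classification, "velocity": m.velocity}
        for k, m in minE_advection_ablation(
            p_hi, 1.0, grid, s_hi, dt=DEFAULT_DT,
            t_relax=200.0, t_measure=300.0).items()}
    # low E:D: flow-driven downstream regime (long-wavelength seed)
    grid_lo = Grid.line(512.0, 512)
    p_lo = p0.with_(ed_ratio=0.05)
    s_lo = seeded_wave_state(p_lo.with_(v_f=2.5), grid_lo, 256.0, +1,
                             seed=seed, amplitude=0.2)
    out["low_ed"] = {
        k: {"classification": m.classification, "velocity": m.velocity}
        for k, m in minE_advection_ablation(
            p_lo, 2.5, grid_lo, s_lo, dt=DEFAULT_DT,
            t_relax=150.0, t_measure=300.0).items()}
    return out


# ---------------------------------------------------------------------------
# Flow-driven instability
# ---------------------------------------------------------------------------

def flow_driven_report(seed: int = 0, ed: float = 0.05, L: float = 512.0,
                       growth_tol: float = 1e-8,
                       params: KineticParameters | None = None) -> dict:
    """Critical flow speed at a low-E:D point stable at rest, with
    simulations on both sides of the threshold.

    The threshold is computed on the discrete mode spectrum of the finite
    periodic domain (q = 2πk/L): the conserved long-wavelength modes at
    q → 0 are soft, so the infinite-domain threshold is degenerate, while
    any realizable geometry admits only q ≥ 2π/L.
    """
    p = (params or _default_params()).with_(ed_ratio=ed, v_f=0.0)
    kmax = int(1.0 * L / (2 * np.pi))
    q_modes = 2 * np.pi * np.arange(1, kmax + 1) / L

    def gmax(v):
        pv = p.with_(v_f=float(v))
        d = dispersion_relation(pv, q_modes,
                                homogeneous_steady_state(pv))
        return float(d.sigma.real.max())

    g0 = gmax(0.0)
    if g0 > growth_tol:
        raise ValueError(f"point unstable at rest (max growth {g0:.2e})")
    lo, hi = 0.0, None
    for v in np.linspace(0.25, 4.0, 16):
        if gmax(v) > growth_tol:
            hi = v
            break
        lo = v
    result = {"ed_ratio": ed, "domain": L, "rest_max_growth": g0}
    if hi is None:
        result["v_critical"] = None
        return result
    while hi - lo > 1e-3 * hi:
        mid = 0.5 * (lo + hi)
        if gmax(mid) > growth_tol:
            hi = mid
        else:
            lo = mid
    v_c = 0.5 * (lo + hi)
    result["v_critical"] = v_c

    # simulation check: seed the leading discrete eigenmode, fit the growth
    # rate of its Fourier amplitude, compare signs
    grid = Grid.line(L, 256)
    for label, fac in (("above", 1.3), ("below", 0.7)):
        pv = p.with_(v_f=fac * v_c)
        ssv = homogeneous_steady_state(pv)
        d = dispersion_relation(pv, q_modes, ssv)
        i = int(np.argmax(d.sigma.real))
        q_k, sig = q_modes[i], d.sigma[i]
        k_mode = i + 1
        J = _jac_unchecked(pv, ssv, q_k)
        w, V = np.linalg.eig(J)
        vec = V[:, np.argmax(w.real)]
        ss_vals = ssv.as_array().reshape(6)
        eps = 2e-3 * np.min(np.where(np.abs(vec) > 1e-12,
                                     np.maximum(ss_vals, 1e-6) / np.abs(vec),
                                     np.inf))
        a = homogeneous_steady_state(pv, grid).as_array()
        wavefield = np.exp(1j * q_k * grid.x)
        for j in range(6):
            a[j] += eps * np.real(vec[j] * wavefield)
        s0 = FieldState.from_array(np.clip(a, 0.0, None))
        traj = simulate(s0, pv, grid,
                        Schedule(dt=0.02, t_end=500.0, save_every=250))
        spec = np.fft.rfft(traj.species("m_d") -
                           traj.species("m_d").mean(axis=1, keepdims=True),
                           axis=1)[:, k_mode]
        slope = float(np.polyfit(traj.times[1:],
                                 np.log(np.abs(spec[1:])), 1)[0])
        result[label] = {"v_f": fac * v_c, "q_mode": float(q_k),
                         "growth_predicted": float(sig.real),
                         "growth_measured": slope}
    return result


# ---------------------------------------------------------------------------
# Hysteresis / multistability
# ---------------------------------------------------------------------------

def hysteresis_report(seed: int = 0, ed: float = 0.2,
                      v_up=(0.5, 2.5, 4.0, 5.5, 7.0),
                      v_down=(4.0, 2.5, 0.5, -1.0, -2.5, -4.0, -5.5, -7.0),
                      t_relax: float = 200.0, t_measure: float = 200.0,
                      params: KineticParameters | None = None) -> dict:
    """Adiabatic signed-flow loop at an intermediate ratio, plus
    opposite-seeded runs at one multistable point.

    The loop starts from an upstream-propagating wave (moving −x under
    +x flow), increases the flow until the wave is forced to reverse, then
    sweeps back down and through zero into reversed flow (the flow-reversal
    protocol) until the wave reverses again.  Because both propagation
    senses are stable over a broad flow range, the two dynamical reversals
    occur at different control values — a non-empty hysteresis loop; in
    the overlap the direction at a given flow depends on sweep history.
    """
    p0 = (params or _default_params()).with_(ed_ratio=ed)
    grid = Grid.line(384.0, 384)
    dt = DEFAULT_DT

    def sweep(path, state):
        rows = []
        for v in path:
            p = p0.with_(v_f=float(v))
            traj, state = _segment(state, p, grid, dt, t_relax, t_measure,
                                   5.0)
            m = classify(traj, window=1.0)
            rows.append({"v_f": float(v), "classification": m.classification,
                         "velocity": m.velocity})
        return rows, state

    lam = grid.lengths[0] / round(grid.lengths[0] / 40.0)
    s0 = seeded_wave_state(p0.with_(v_f=v_up[0]), grid, lam, -1, seed=seed,
                           amplitude=0.3)       # upstream: moving −x
    up_rows, s_end = sweep(list(v_up), s0)
    down_rows, _ = sweep(list(v_down), s_end)

    def velocity_flip(rows):
        """Control value at which the measured lab-frame velocity changes
        sign (a dynamical reversal of the wave, not a relabeling)."""
        prev = None
        for r in rows:
            v = r["velocity"]
            if np.isfinite(v):
                if prev is not None and v * prev < 0:
                    return r["v_f"]
                prev = v
        return None

    # multistability: opposite seeds at the same point keep their direction
    v_ms = 2.5
    p = p0.with_(v_f=v_ms)
    ms = {}
    for label, sign in (("seed_down", +1), ("seed_up", -1)):
        s = seeded_wave_state(p, grid, lam, sign, seed=seed, amplitude=0.3)
        traj, _ = _segment(s, p, grid, dt, t_relax, t_measure, 5.0)
        m = classify(traj, window=1.0)
        ms[label] = {"classification": m.classification,
                     "velocity": m.velocity}
    return {"ed_ratio": ed, "up": up_rows, "down": down_rows,
            "up_flip_v": velocity_flip(up_rows),
            "down_flip_v": velocity_flip(down_rows),
            "multistable_point": {"v_f": v_ms, **ms}}


# ---------------------------------------------------------------------------
# Coarsening
# ---------------------------------------------------------------------------

def coarsening_report(seed: int = 0, ed: float = 0.12, v_f: float = 1.0,
                      t_end: float = 6000.0,
                      params: KineticParameters | None = None) -> dict:
    """Wavelength growth of a downstream pattern below the upstream onset,
    developing from noise on a small domain and ending in a single pulse
    (wavelength = domain size).

    Just below the onset the short-wavelength band grows first, so the
    run starts as a ~50 μm downstream wave train and coarsens through
    successive pulse mergers; at still lower ratios the flow-driven band
    peaks near the domain scale and the single-pulse state forms directly,
    leaving no visible coarsening sequence."""
    from minflow.sweeps import dominant_wavelength
    p = (params or _default_params()).with_(ed_ratio=ed, v_f=v_f)
    grid = Grid.line(256.0, 256)
    state = noisy_homogeneous_state(p, grid, seed=seed)
    chunk, n_chunks = t_end / 12.0, 12
    times, lams = [], []
    last_traj = None
    for ic in range(n_chunks):
        dt = DEFAULT_DT
        for attempt in range(3):
            try:
                traj = simulate(state, p, grid,
                                Schedule(dt=dt, t_end=chunk,
                                         save_every=int(chunk / dt / 4)))
                break
            except FloatingPointError:
                dt /= 2.0
        else:
            raise FloatingPointError("coarsening run unstable")
        state = traj.state(-1)
        last_traj = traj
        for i in range(1, len(traj)):
            times.append(ic * chunk + traj.times[i])
            try:
                lams.append(float(dominant_wavelength(traj.frames[i][0],
                                                      L=grid.lengths[0])))
            except NoPatternError:
                lams.append(float("nan"))
    meas = classify(last_traj, window=1.0)
    return {"ed_ratio": ed, "v_f": v_f, "times": times,
            "wavelengths": lams, "final_wavelength": lams[-1],
            "domain": grid.lengths[0],
            "classification": meas.classification}


# ---------------------------------------------------------------------------
# Crest-analysis recovery
# ---------------------------------------------------------------------------

def crest_recovery_report(seed: int = 0,
                          cases=((150.0, 20.0), (300.0, 0.0), (450.0, 235.0),
                                 (600.0, 120.0)),
                          params=None) -> list[dict]:
    """Speed/angle recovery on synthetic planar-wave stacks with noise and
    static aggregates, after the 10%-median filter."""
    from minflow.crest import crest_displacements, filter_velocities, \
        direction_summary
    from minflow.synth import SyntheticStackSpec, planar_wave_stack
    out = []
    # last case: a clean 0° stack (no noise, no aggregates) whose
    # direction statistics are exact — downstream fraction is 1
    all_cases = [(s, a, True) for s, a in cases] + [(300.0, 0.0, False)]
    for i, (speed, angle, noisy) in enumerate(all_cases):
        spec = SyntheticStackSpec(
            kind="planar", wavelength=60.0, speed=speed, direction_deg=angle,
            H=128, W=128, T=24, pixel_size=2.0,
            noise_sd=20.0 if noisy else 0.0,
            aggregates=((30, 30, 2500.0, 3.5), (90, 80, 2500.0, 3.5))
            if noisy else (),
            seed=seed + i)
        stack, truth = planar_wave_stack(spec)
        recs = filter_velocities(crest_displacements(stack))
        vx = float(np.mean([r.v_x for r in recs]))
        vy = float(np.mean([r.v_y for r in recs]))
        summ = direction_summary(recs)
        ang = float(np.degrees(np.arctan2(vy, vx)))
        ang_err = (ang - angle + 180.0) % 360.0 - 180.0
        out.append({"speed_true": speed, "angle_true": angle,
                    "noisy": noisy,
                    "speed_measured": float(np.hypot(vx, vy)),
                    "angle_error_deg": float(ang_err),
                    "downstream_fraction": summ.downstream_fraction,
                    "n_records": summ.n_records})
    return out
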