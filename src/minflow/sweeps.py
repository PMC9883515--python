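"""Pattern measurement and parameter sweeps: direction, speed, wavelength,
phase diagram, hysteresis, and the MinE-advection ablation.

Direction convention: pattern velocity is reported in the lab frame along
+x; a pattern is *downstream* when velocity and ``v_f`` have the same sign,
*upstream* when opposite.  A pattern is present when the spatial standard
deviation of ``m_d`` exceeds 1% of its mean; it is *stationary* when the
measured |velocity| is below the resolution bound dx / T_measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from minflow.parameters import KineticParameters
from minflow.simulator import Schedule, Trajectory, simulate
from minflow.state import FieldState, Grid

log = logging.getLogger(__name__)

#: pattern-presence threshold: spatial std of m_d relative to its mean
AMPLITUDE_THRESHOLD = 0.01


class NoPatternError(ValueError):
    """Raised when an operation requires a developed pattern and none exists."""


@dataclass
class PatternMeasurement:
    """Direction, speed and wavelength of a developed pattern."""

    velocity: float              # μm/s, lab frame (+x); nan if no pattern
    velocity_err: float
    wavelength: float            # μm; nan if no pattern
    amplitude: float             # spatial std of m_d relative to its mean
    classification: str          # upstream | downstream | stationary | no_pattern
    period: float = float("nan")   # s, |wavelength / velocity| when defined


@dataclass
class PhasePoint:
    """Measurements at one (E:D, v_f) point, one per initial condition."""

    ed_ratio: float
    v_f: float
    measurements: dict[str, PatternMeasurement]
    multistable: bool = False

    @property
    def classifications(self) -> dict[str, str]:
        return {k: m.classification for k, m in self.measurements.items()}


# ---------------------------------------------------------------------------
# Measurement primitives
# ---------------------------------------------------------------------------

def _pattern_amplitude(frame: np.ndarray) -> float:
    m = float(frame.mean())
    if m <= 0:
        return 0.0
    return float(frame.std()) / m


def _profile(traj: Trajectory) -> np.ndarray:
    """(T, N) m_d profiles along the flow axis (transverse-averaged in 2D)."""
    m = traj.species("m_d")
    if traj.grid.n_dims == 2:
        m = m.mean(axis=2)
    return m


def dominant_wavelength(obj: Trajectory | np.ndarray, L: float | None = None
                        ) -> float:
    """Wavelength 2π/q of the spectral peak of the mean-removed m_d profile,
    with parabolic peak interpolation.

    Accepts a trajectory (uses the final frame) or a 1D profile plus its
    domain length ``L``.
    """
    if isinstance(obj, Trajectory):
        prof = _profile(obj)[-1]
        L = obj.grid.lengths[0]
    else:
        prof = np.asarray(obj, dtype=float)
        if L is None:
            raise ValueError("domain length L required for a bare profile")
    n = len(prof)
    power = np.abs(np.fft.rfft(prof - prof.mean())) ** 2
    power[0] = 0.0
    if power.max() <= 0 or _pattern_amplitude(prof) < AMPLITUDE_THRESHOLD:
        raise NoPatternError("flat spectrum: no pattern present")
    k = int(np.argmax(power))
    # parabolic interpolation on log-power where the neighbors carry real
    # signal (skip for numerically empty side bins of a pure harmonic)
    if 1 <= k < len(power) - 1 and \
            min(power[k - 1], power[k + 1]) > 1e-12 * power[k]:
        y0, y1, y2 = np.log(power[k - 1:k + 2])
        denom = y0 - 2 * y1 + y2
        dk = 0.5 * (y0 - y2) / denom if denom < 0 else 0.0
        dk = float(np.clip(dk, -0.5, 0.5))
    else:
        dk = 0.0
    return L / (k + dk)


def pattern_velocity(traj: Trajectory, window: float = 1.0,
                     with_uncertainty: bool = False):
    """Signed pattern velocity from the phase drift of the dominant spatial
    Fourier mode of m_d, averaged over the measurement window.

    ``window`` is the trailing fraction of the trajectory used.  Raises
    :class:`NoPatternError` when the amplitude is below threshold.
    """
    prof = _profile(traj)
    times = traj.times
    n_use = max(int(np.ceil(len(times) * window)), 3)
    prof, times = prof[-n_use:], times[-n_use:]
    if _pattern_amplitude(prof[-1]) < AMPLITUDE_THRESHOLD:
        raise NoPatternError("amplitude below pattern threshold")
    L = traj.grid.lengths[0]
    spec = np.fft.rfft(prof - prof.mean(axis=1, keepdims=True), axis=1)
    power = (np.abs(spec) ** 2).mean(axis=0)
    power[0] = 0.0
    k = int(np.argmax(power))
    q = 2.0 * np.pi * k / L
    phase = np.unwrap(np.angle(spec[:, k]))
    A = np.vstack([times - times[0], np.ones_like(times)]).T
    coef, res, *_ = np.linalg.lstsq(A, phase, rcond=None)
    slope = coef[0]
    dof = max(len(times) - 2, 1)
    sigma2 = (res[0] / dof) if len(res) else 0.0
    slope_err = np.sqrt(sigma2 / np.sum((times - times.mean()) ** 2))
    v = -slope / q
    v_err = slope_err / q
    if with_uncertainty:
        return float(v), float(v_err)
    return float(v)


def classify(traj: Trajectory, window: float = 1.0) -> PatternMeasurement:
    """Measure a trajectory and classify its propagation direction."""
    try:
        v, v_err = pattern_velocity(traj, window, with_uncertainty=True)
        lam = dominant_wavelength(traj)
    except NoPatternError:
        final = _profile(traj)[-1]
        return PatternMeasurement(float("nan"), float("nan"), float("nan"),
                                  _pattern_amplitude(final), "no_pattern")
    amp = _pattern_amplitude(_profile(traj)[-1])
    t_meas = traj.times[-1] - traj.times[max(0, len(traj.times)
                                             - int(np.ceil(len(traj.times) * window)))]
    v_res = traj.grid.dx[0] / max(t_meas, 1e-12)
    v_f = traj.params.v_f
    if abs(v) < v_res:
        cls = "stationary"
    elif v_f == 0.0:
        cls = "downstream" if v > 0 else "upstream"   # sign of seed, no flow ref
    else:
        cls = "downstream" if v * v_f > 0 else "upstream"
    period = abs(lam / v) if abs(v) > 0 else float("nan")
    return PatternMeasurement(v, v_err, lam, amp, cls, period)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def _segment(state: FieldState, params: KineticParameters, grid: Grid,
             dt: float, t_relax: float, t_measure: float,
             save_dt: float) -> tuple[Trajectory, FieldState]:
    """Relax (unsaved) then measure (saved); returns measured trajectory and
    the final state for continuation.  On integrator blow-up the segment is
    retried with a halved step (twice) before giving up."""
    last = None
    for attempt in range(3):
        try:
            st = state
            if t_relax > 0:
                sched = Schedule(dt=dt, t_end=t_relax, save_every=10 ** 9)
                st = simulate(st, params, grid, sched).state(-1)
            sched = Schedule(dt=dt, t_end=t_measure,
                             save_every=max(int(round(save_dt / dt)), 1))
            traj = simulate(st, params, grid, sched)
            return traj, traj.state(-1)
        except FloatingPointError as e:
            last = e
            log.warning("segment blew up at dt=%g (%s); retrying with dt/2",
                        dt, e)
            dt /= 2.0
    raise last


def adiabatic_sweep(params: KineticParameters, control: str,
                    path: np.ndarray, grid: Grid, initial: FieldState,
                    dt: float = 0.05, t_relax: float = 400.0,
                    t_measure: float = 400.0, save_dt: float = 5.0,
                    window: float = 1.0) -> list[PhasePoint]:
    """Sweep one control parameter adiabatically along ``path``.

    ``control`` is ``"v_f"`` or ``"ed_ratio"``.  At each value the run
    continues from the previous final state, relaxes for ``t_relax``,
    then measures for ``t_measure``.  Loss of pattern is recorded and the
    sweep continues.
    """
    if control not in ("v_f", "ed_ratio"):
        raise ValueError("control must be 'v_f' or 'ed_ratio'")
    points: list[PhasePoint] = []
    state = initial
    for value in np.asarray(path, dtype=float):
        p = params.with_(**{control: float(value)})
        if control == "ed_ratio":
            state = _rescale_minE(state, p)
        traj, state = _segment(state, p, grid, dt, t_relax, t_measure, save_dt)
        meas = classify(traj, window)
        log.info("sweep %s=%g: %s v=%.4g λ=%.4g", control, value,
                 meas.classification, meas.velocity, meas.wavelength)
        points.append(PhasePoint(ed_ratio=p.ed_ratio, v_f=p.v_f,
                                 measurements={"continued": meas}))
    return points


def _rescale_minE(state: FieldState, params: KineticParameters) -> FieldState:
    """Adjust total MinE of a state to ``params.n_E_mean`` by scaling the
    bulk MinE pools (adds/removes protein as in a titration)."""
    from minflow.models import total_densities
    _, nE = total_densities(state)
    target = params.n_E_mean
    bulk = float(np.mean(state.c_Er + state.c_Ei))
    mde = float(np.mean(state.m_de))
    if bulk <= 0:
        a = state.as_array()
        a[4] += max(target - nE, 0.0)
        return FieldState.from_array(a, t=state.t)
    scale = max((target - mde) / bulk, 0.0)
    a = state.as_array()
    a[4] *= scale
    a[5] *= scale
    return FieldState.from_array(a, t=state.t)


def phase_diagram(params: KineticParameters, ed_grid: np.ndarray,
                  v_grid: np.ndarray, grid: Grid,
                  protocol: tuple[str, ...] = ("homogeneous", "seed_down", "seed_up"),
                  seed_wavelength: float | None = None,
                  dt: float = 0.05, t_relax: float = 400.0,
                  t_measure: float = 400.0, save_dt: float = 5.0,
                  rng_seed: int = 0) -> list[PhasePoint]:
    """Classify every (E:D, v_f) grid point under a multi-seed protocol.

    Protocol entries: ``homogeneous`` (noise on the uniform steady state),
    ``seed_down``/``seed_up`` (finite-amplitude wave seeds traveling with /
    against the flow).  A point is multistable when at least two initial
    conditions retain opposite nonzero directions.
    """
    from minflow.synth import noisy_homogeneous_state, seeded_wave_state

    if seed_wavelength is None:
        seed_wavelength = grid.lengths[0] / max(round(grid.lengths[0] / 50.0), 1)
    points = []
    for ed in np.asarray(ed_grid, dtype=float):
        for v in np.asarray(v_grid, dtype=float):
            p = params.with_(ed_ratio=float(ed), v_f=float(v))
            meas: dict[str, PatternMeasurement] = {}
            for proto in protocol:
                try:
                    if proto == "homogeneous":
                        s0 = noisy_homogeneous_state(p, grid, seed=rng_seed)
                    elif proto == "seed_down":
                        s0 = seeded_wave_state(p, grid, seed_wavelength,
                                               +1 if v >= 0 else -1, seed=rng_seed)
                    elif proto == "seed_up":
                        s0 = seeded_wave_state(p, grid, seed_wavelength,
                                               -1 if v >= 0 else +1, seed=rng_seed)
                    else:
                        raise ValueError(f"unknown protocol entry {proto!r}")
                    traj, _ = _segment(s0, p, grid, dt, t_relax, t_measure, save_dt)
                    meas[proto] = classify(traj)
                except Exception as e:   # record, never silently drop
                    log.warning("point ed=%g v=%g proto=%s failed: %s",
                                ed, v, proto, e)
                    meas[proto] = PatternMeasurement(
                        float("nan"), float("nan"), float("nan"), 0.0,
                        f"error:{type(e).__name__}")
            dirs = {m.classification for m in meas.values()}
            points.append(PhasePoint(
                ed_ratio=float(ed), v_f=float(v), measurements=meas,
                multistable=("upstream" in dirs and "downstream" in dirs)))
    return points


def phase_point_label(point: PhasePoint) -> str:
    """Summary label: exclusive direction, multistable, or no_pattern."""
    dirs = [m.classification for m in point.measurements.values()
            if m.classification in ("upstream", "downstream")]
    if point.multistable:
        return "multistable"
    if dirs and all(d == dirs[0] for d in dirs):
        return dirs[0]
    if not dirs:
        return "no_pattern"
    return "mixed"


def wavelength_reversal_correlation(
        results: dict[float, list[PhasePoint]],
        round_to: float = 1e-6) -> dict:
    """Reversal flow velocity per seeded wavelength and its monotonicity.

    ``results`` maps seeded wavelength → upward v_f sweep (PhasePoints in
    ascending v_f, initially downstream).  The reversal velocity is the
    first v_f whose classification is upstream.  Duplicate wavelengths
    (within ``round_to``) are grouped.  Requires ≥ 3 distinct wavelengths.
    """
    grouped: dict[float, list[PhasePoint]] = {}
    for lam, pts in results.items():
        key = round(lam / round_to) * round_to
        if key not in grouped:
            grouped[key] = pts
    if len(grouped) < 3:
        raise ValueError("need >= 3 distinct wavelengths to assess the trend")
    reversal: dict[float, float | None] = {}
    for lam in sorted(grouped):
        v_rev = None
        for pt in grouped[lam]:
            cls = pt.measurements["continued"].classification
            if cls == "upstream":
                v_rev = pt.v_f
                break
        reversal[lam] = v_rev
    lams = sorted(reversal)
    vs = [reversal[l] for l in lams]
    known = [v for v in vs if v is not None]
    monotone = all(b >= a for a, b in zip(known, known[1:]))
    open_ended = any(v is None for v in vs)
    return {"reversal_velocity": reversal, "non_decreasing": monotone,
            "open_ended": open_ended}


def minE_advection_ablation(params: KineticParameters, v_f: float,
                            grid: Grid, initial: FieldState,
                            dt: float = 0.05, t_relax: float = 400.0,
                            t_measure: float = 400.0, save_dt: float = 5.0
                            ) -> dict[str, PatternMeasurement]:
    """Matched pair of runs differing only in whether bulk MinE is advected.

    Used to test whether MinE transport sets the propagation direction: in
    the full model the direction is unchanged when MinE advection is
    switched off, at both high and low E:D.
    """
    out = {}
    for label, flag in (("advected", True), ("not_advected", False)):
        p = params.with_(v_f=float(v_f), advect_minE=flag)
        traj, _ = _segment(initial.copy(), p, grid, dt, t_relax,
                           t_measure, save_dt)
        out[label] = classify(traj)
    return out
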