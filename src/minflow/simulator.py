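"""Time integration of the membrane–bulk dynamics on a periodic lateral grid.

The PDE system couples membrane species (diffusion + reactions, never
advected) to bulk species (diffusion + uniform advection at ``v_f`` +
reactions).  With the bulk dimension integrated out the transport operators
are linear with constant coefficients, so each Strang-splitting substep
applies them *exactly* in Fourier space (integrating factor
``exp(-(D q² + i q·v) Δt)``); the pointwise reaction system is advanced by
classical RK4.  Transport therefore introduces no numerical diffusion, and
both total densities are conserved to machine precision (the zero mode has
multiplier 1 and the reaction fluxes sum to zero pointwise).

Advection acts on bulk MinD always, and on bulk MinE only when
``params.advect_minE`` is set — disabling it is the in-silico ablation used
to test whether MinE transport matters for the propagation direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from minflow.models import _flux_arrays, slaved_minE_pools, total_densities
from minflow.parameters import KineticParameters
from minflow.state import FieldState, Grid, SPECIES

#: per-species (is_membrane, is_bulk_minE) flags in canonical order
_IS_MEMBRANE = np.array([True, True, False, False, False, False])
_IS_BULK_E = np.array([False, False, False, False, True, True])


@dataclass(frozen=True)
class Schedule:
    """Integration schedule: step size, duration, output cadence.

    The reaction substep is the only stability constraint (transport is
    exact); ``dt`` should resolve the fastest kinetic rate, i.e.
    ``dt ≲ 1/max(lambda_, k_de, recruitment rates)``.
    """

    dt: float
    t_end: float
    save_every: int = 20
    drift_check_every: int = 1000
    rng_seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.save_every < 1:
            raise ValueError("save_every must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


@dataclass
class Trajectory:
    """Time-ordered snapshots plus schedule metadata and conservation log."""

    times: np.ndarray                 # (T,)
    frames: np.ndarray                # (T, 6, *grid) canonical species order
    grid: Grid
    params: KineticParameters
    schedule: Schedule | None = None
    conservation: np.ndarray | None = None   # (T, 2): n_D, n_E per frame
    clipped_points: int = 0
    valid: bool = True

    def __post_init__(self):
        if len(self.times) == 0:
            raise ValueError("empty trajectory")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def state(self, i: int) -> FieldState:
        return FieldState.from_array(self.frames[i], t=float(self.times[i]))

    def species(self, name: str) -> np.ndarray:
        """(T, *grid) array for one species."""
        return self.frames[:, SPECIES.index(name)]

    def save(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("frames", data=self.frames, compression="gzip")
            if self.conservation is not None:
                f.create_dataset("conservation", data=self.conservation)
            f.attrs["grid_lengths"] = self.grid.lengths
            f.attrs["grid_shape"] = self.grid.shape
            f.attrs["valid"] = self.valid
            f.attrs["clipped_points"] = self.clipped_points
            for k, v in self.params.items():
                f.attrs[f"param_{k}"] = v

    @classmethod
    def load(cls, path) -> "Trajectory":
        import h5py
        with h5py.File(path, "r") as f:
            pd_ = {k[len("param_"):]: v for k, v in f.attrs.items()
                   if k.startswith("param_")}
            for key in ("variant", "name"):
                if key in pd_:
                    pd_[key] = str(pd_[key])
            if "advect_minE" in pd_:
                pd_["advect_minE"] = bool(pd_["advect_minE"])
            params = KineticParameters.from_dict(pd_)
            grid = Grid(tuple(f.attrs["grid_lengths"]),
                        tuple(int(n) for n in f.attrs["grid_shape"]))
            return cls(times=f["times"][:], frames=f["frames"][:],
                       grid=grid, params=params,
                       conservation=(f["conservation"][:]
                                     if "conservation" in f else None),
                       clipped_points=int(f.attrs["clipped_points"]),
                       valid=bool(f.attrs["valid"]))


# ---------------------------------------------------------------------------
# Exact spectral transport
# ---------------------------------------------------------------------------

class _Transport:
    """Precomputed per-species Fourier multipliers for a half step."""

    def __init__(self, params: KineticParameters, grid: Grid, dt_half: float):
        ks = grid.wavenumbers()
        if grid.n_dims == 1:
            n = grid.shape[0]
            q = 2.0 * np.pi * np.fft.rfftfreq(n, d=grid.dx[0])
            q2 = q ** 2
            iqx = 1j * q
        else:
            qx = ks[0][:, None]
            qy = 2.0 * np.pi * np.fft.rfftfreq(grid.shape[1], d=grid.dx[1])[None, :]
            q2 = qx ** 2 + qy ** 2
            iqx = 1j * qx * np.ones_like(qy)
        adv_E = 1.0 if params.advect_minE else 0.0
        mult = []
        for i, s in enumerate(SPECIES):
            D = params.D_m if _IS_MEMBRANE[i] else params.D_c
            v = 0.0 if _IS_MEMBRANE[i] else (
                params.v_f * (adv_E if _IS_BULK_E[i] else 1.0))
            mult.append(np.exp(dt_half * (-D * q2 - iqx * v)))
        self.mult = mult
        self._rfft_axes = tuple(range(-grid.n_dims, 0))

    def half_step(self, a: np.ndarray, reduced: bool) -> None:
        """Apply transport in place to the (6, *grid) state array."""
        n_fields = 4 if reduced else 6
        for i in range(n_fields):
            spec = np.fft.rfftn(a[i], axes=self._rfft_axes)
            spec *= self.mult[i]
            a[i] = np.fft.irfftn(spec, s=a[i].shape, axes=self._rfft_axes)


# ---------------------------------------------------------------------------
# Reaction substep
# ---------------------------------------------------------------------------

def _apply_qssa(a: np.ndarray, p: KineticParameters) -> None:
    c_Er, c_Ei = slaved_minE_pools(float(a[0].mean()), float(a[1].mean()), p)
    a[4].fill(c_Er)
    a[5].fill(c_Ei)


def _reaction_rhs(a: np.ndarray, p: KineticParameters, reduced: bool) -> np.ndarray:
    if reduced:
        _apply_qssa(a, p)
    f = np.stack(_flux_arrays(a[0], a[1], a[2], a[3], a[4], a[5], p))
    if reduced:
        f[4:] = 0.0     # MinE pools are algebraic, not integrated
    return f


def _rk4_reactions(a: np.ndarray, p: KineticParameters, dt: float,
                   reduced: bool) -> np.ndarray:
    k1 = _reaction_rhs(a, p, reduced)
    k2 = _reaction_rhs(a + 0.5 * dt * k1, p, reduced)
    k3 = _reaction_rhs(a + 0.5 * dt * k2, p, reduced)
    k4 = _reaction_rhs(a + dt * k3, p, reduced)
    out = a + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if reduced:
        _apply_qssa(out, p)
    return out


class _Stepper:
    """Strang splitting: half transport, full reactions, half transport."""

    def __init__(self, params: KineticParameters, grid: Grid, dt: float,
                 abort_tol: float = 1e-3):
        self.params = params
        self.grid = grid
        self.dt = dt
        self.reduced = params.variant == "reduced_switch"
        self.transport = _Transport(params, grid, dt / 2.0)
        scale = max(params.n_D_mean, params.n_E_mean, 1.0)
        self.abort_floor = -abort_tol * scale
        self.clipped = 0

    def __call__(self, a: np.ndarray) -> np.ndarray:
        a = a.copy()
        self.transport.half_step(a, self.reduced)
        a = _rk4_reactions(a, self.params, self.dt, self.reduced)
        self.transport.half_step(a, self.reduced)
        amin = a.min()
        if not np.isfinite(a).all() or amin < self.abort_floor:
            raise FloatingPointError(
                f"integration blew up: min={amin:.3e}, "
                f"finite={np.isfinite(a).all()}, dt={self.dt}")
        if amin < 0.0:
            # Mass-conserving positivity fix: spectral transport can
            # undershoot slightly below zero where a bulk pool is depleted;
            # zero the undershoot and remove the added mass proportionally
            # from the positive part of the same species.
            for i in range(a.shape[0]):
                fi = a[i]
                neg = fi < 0.0
                if not neg.any():
                    continue
                deficit = -fi[neg].sum()
                self.clipped += int(neg.sum())
                fi[neg] = 0.0
                s_pos = fi.sum()
                if s_pos > 0:
                    fi *= 1.0 - deficit / s_pos
        return a


def step(state: FieldState, params: KineticParameters, grid: Grid,
         dt: float) -> FieldState:
    """Advance one Strang step of length ``dt``."""
    stepper = _Stepper(params, grid, dt)
    a = stepper(state.as_array())
    return FieldState.from_array(a, t=state.t + dt)


def simulate(initial: FieldState, params: KineticParameters, grid: Grid,
             schedule: Schedule, drift_tol: float = 1e-4) -> Trajectory:
    """Integrate and record a trajectory.

    Deterministic given (initial, params, schedule).  Total-density drift
    beyond ``drift_tol`` (relative) marks the trajectory invalid rather
    than raising, so sweeps can skip bad points explicitly.
    """
    if initial.shape != grid.shape:
        raise ValueError("initial state does not live on the given grid")
    initial.validate()
    stepper = _Stepper(params, grid, schedule.dt)
    a = initial.as_array()
    t = initial.t

    times = [t]
    frames = [a.copy()]
    nD0, nE0 = total_densities(initial)
    cons = [(nD0, nE0)]
    valid = True
    scale = max(nD0, nE0, 1.0)

    for istep in range(1, schedule.n_steps + 1):
        a = stepper(a)
        t = initial.t + istep * schedule.dt
        if istep % schedule.save_every == 0:
            st = FieldState.from_array(a, t=t)
            nD, nE = total_densities(st)
            times.append(t)
            frames.append(a.copy())
            cons.append((nD, nE))
            if abs(nD - nD0) > drift_tol * scale or \
                    abs(nE - nE0) > drift_tol * scale:
                valid = False

    return Trajectory(times=np.array(times), frames=np.stack(frames),
                      grid=grid, params=params, schedule=schedule,
                      conservation=np.array(cons),
                      clipped_points=stepper.clipped, valid=valid)


def kymograph(traj: Trajectory, species: str = "m_d",
              line: int | str = 0) -> np.ndarray:
    """Space–time map of one species: one row per saved frame.

    For 2D grids, ``line`` selects a row index along the transverse axis or
    ``"mean"`` for the transverse average.
    """
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    data = traj.species(species)
    if traj.grid.n_dims == 1:
        return data.copy()
    if line == "mean":
        return data.mean(axis=2)
    return data[:, :, int(line)].copy()
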