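"""Reaction kinetics of the Min model variants and their uniform steady states.

Three variants of one mass-action scheme:

* **full** — the switch model.  Membrane-bound MinD (``m_d``) recruits
  bulk MinD-ATP and both conformations of bulk MinE; the MinDE complex
  (``m_de``) detaches at ``k_de``, releasing MinD-ADP and reactive MinE;
  bulk MinD-ADP recharges to MinD-ATP at ``lambda_``; bulk reactive MinE
  switches to the latent conformation at ``mu``.
* **skeleton** — no conformational switching: ``mu = 0`` and the latent
  pool is identically zero, so all bulk MinE is reactive.
* **reduced_switch** — the high-E:D limit: bulk MinE gradients are
  negligible, so the MinE pools are spatially uniform and slaved to the
  instantaneous global membrane state by a quasi-steady-state
  approximation plus MinE mass conservation (see
  :func:`slaved_minE_pools`).

Both total densities are conserved by construction; the flux functions
here satisfy the pointwise sum rules exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from minflow.parameters import KineticParameters
from minflow.state import FieldState, Grid, SPECIES


@dataclass
class ReactionFluxes:
    """Per-point rates of change from reactions only (1/μm²/s), including
    the nucleotide-exchange (``lambda_``) and switching (``mu``) transfers."""

    f_d: np.ndarray
    f_de: np.ndarray
    f_DD: np.ndarray
    f_DT: np.ndarray
    f_Er: np.ndarray
    f_Ei: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.stack([self.f_d, self.f_de, self.f_DD, self.f_DT,
                         self.f_Er, self.f_Ei])


def _flux_arrays(m_d, m_de, c_DD, c_DT, c_Er, c_Ei, p: KineticParameters):
    """Raw flux arithmetic on arrays; shared by simulator and Jacobian."""
    attach = (p.k_D + p.k_dD * m_d) * c_DT
    rec_Er = p.k_dEr * m_d * c_Er
    rec_Ei = p.k_dEi * m_d * c_Ei
    det = p.k_de * m_de
    f_d = attach - rec_Er - rec_Ei
    f_de = rec_Er + rec_Ei - det
    f_DD = det - p.lambda_ * c_DD
    f_DT = -attach + p.lambda_ * c_DD
    f_Er = -rec_Er + det - p.mu * c_Er
    f_Ei = -rec_Ei + p.mu * c_Er
    return f_d, f_de, f_DD, f_DT, f_Er, f_Ei


def reaction_fluxes(state: FieldState, params: KineticParameters,
                    tol: float = 1e-9) -> ReactionFluxes:
    """Evaluate the reaction terms at every grid point.

    Raises if any concentration is negative beyond ``tol`` or if the state
    is inconsistent with the variant (skeleton requires a zero latent pool).
    """
    state.validate(tol=tol)
    if params.variant == "skeleton" and np.any(np.abs(state.c_Ei) > tol):
        raise ValueError("skeleton variant carries no latent MinE pool")
    arrs = [np.asarray(getattr(state, s), dtype=float) for s in SPECIES]
    return ReactionFluxes(*_flux_arrays(*arrs, params))


def total_densities(state: FieldState, grid: Grid | None = None
                    ) -> tuple[float, float]:
    """Mean total MinD and MinE densities (1/μm²).

    Spatial means, not integrals, so values are directly comparable across
    grid sizes and to ``n_D_mean``/``n_E_mean``.
    """
    if grid is not None and state.shape != grid.shape:
        raise ValueError(f"state shape {state.shape} != grid shape {grid.shape}")
    n_D = float(np.mean(state.m_d + state.m_de + state.c_DD + state.c_DT))
    n_E = float(np.mean(state.m_de + state.c_Er + state.c_Ei))
    return n_D, n_E


# ---------------------------------------------------------------------------
# Homogeneous steady state
# ---------------------------------------------------------------------------

def _well_mixed_rhs(t, y, p: KineticParameters):
    return np.array(_flux_arrays(*y, p))


def homogeneous_steady_state(params: KineticParameters,
                             grid: Grid | None = None,
                             tol: float = 1e-12,
                             t_relax: float = 2000.0) -> FieldState:
    """Spatially uniform fixed point with the prescribed total densities.

    Uniform states are advection-invariant, so this is a fixed point of the
    full dynamics for any flow velocity.  Possible multiplicity is resolved
    by relaxing the well-mixed rate equations from the uniform partition
    (all MinD as ``c_DT``, all MinE as ``c_Er``) and polishing the end point
    with a Newton solve under both conservation constraints.

    Returns a scalar-per-field uniform :class:`FieldState` if ``grid`` is
    None, else fields filled on the grid.
    """
    nD, nE = params.n_D_mean, params.n_E_mean

    if nE == 0.0:
        # No MinE: no detachment pathway, all MinD ends membrane-bound.
        y = np.array([nD, 0.0, 0.0, 0.0, 0.0, 0.0])
    else:
        y0 = np.array([0.0, 0.0, 0.0, nD, nE, 0.0])
        sol = solve_ivp(_well_mixed_rhs, (0.0, t_relax), y0, args=(params,),
                        method="LSODA", rtol=1e-8, atol=1e-10 * max(nD, 1.0))
        if not sol.success:
            raise RuntimeError(f"well-mixed relaxation failed: {sol.message}")
        y = sol.y[:, -1]

        def residual(u):
            f = _well_mixed_rhs(0.0, u, params)
            # replace the two dependent fluxes by the conservation constraints
            return np.array([
                f[0], f[1], f[2], f[4],
                u[0] + u[1] + u[2] + u[3] - nD,
                u[1] + u[4] + u[5] - nE,
            ])

        # Newton polish; when the well-mixed dynamics are oscillatory the
        # relaxation lands on a cycle, so also seed Newton from the cycle
        # average and the uniform partition.
        guesses = [y, sol.y[:, sol.t > 0.5 * t_relax].mean(axis=1), y0,
                   np.full(6, max(nD, nE) / 6.0)]
        best, best_resid = y, float(np.max(np.abs(_well_mixed_rhs(0, y, params))))
        for guess in guesses:
            for method in ("hybr", "lm"):
                res = root(residual, guess, method=method, tol=1e-13)
                r = float(np.max(np.abs(_well_mixed_rhs(0, res.x, params))))
                feasible = np.all(res.x > -1e-9 * max(nD, nE)) and \
                    abs(res.x[0] + res.x[1] + res.x[2] + res.x[3] - nD) < 1e-6 * nD
                if feasible and r < best_resid:
                    best, best_resid = res.x, r
            if best_resid <= max(1e-11 * max(nD, nE, 1.0), 1e-13):
                break
        y = best

    resid = float(np.max(np.abs(_well_mixed_rhs(0.0, y, params))))
    scale = max(nD, nE, 1.0)
    if resid > max(tol * scale, 1e-9):
        raise RuntimeError(
            f"steady-state residual {resid:.3e} above tolerance "
            f"(state={y}, params={params.name})")
    y = np.clip(y, 0.0, None)

    if grid is None:
        return FieldState(*[np.asarray(v) for v in y], t=0.0)
    return FieldState.uniform(y, grid)


# ---------------------------------------------------------------------------
# Reduced switch model
# ---------------------------------------------------------------------------

def reduce_switch_model(params: KineticParameters) -> KineticParameters:
    """Return the reduced-switch variant of a full-model parameter set.

    In the reduced model the bulk MinE pools carry no gradients: both are
    spatially uniform and determined algebraically from the instantaneous
    global membrane state (quasi-steady state of the switching dynamics
    plus MinE mass conservation).  Only ``m_d``, ``m_de``, ``c_DD`` and
    ``c_DT`` remain dynamical fields.  Because no MinE gradients exist,
    MinE advection cannot affect the dynamics.
    """
    if params.variant != "full":
        raise ValueError("reduce_switch_model expects full-model parameters")
    if params.n_E_mean <= 0:
        raise ValueError("reduced switch model is degenerate at n_E_mean = 0")
    return params.with_(variant="reduced_switch")


def slaved_minE_pools(mean_m_d: float, mean_m_de: float,
                      p: KineticParameters) -> tuple[float, float]:
    """Uniform (c_Er, c_Ei) slaved to the global membrane state.

    Quasi-steady state of the latent-pool balance
    ``k_dEi <m_d> c_Ei = mu c_Er`` combined with MinE mass conservation
    ``c_Er + c_Ei = n_E − <m_de>``.
    """
    free = max(p.n_E_mean - mean_m_de, 0.0)
    denom = p.k_dEi * max(mean_m_d, 0.0)
    if p.mu == 0.0:
        return free, 0.0
    if denom <= 0.0:
        return 0.0, free        # everything switched latent, nothing recruits it back
    c_Er = free / (1.0 + p.mu / denom)
    return c_Er, free - c_Er
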