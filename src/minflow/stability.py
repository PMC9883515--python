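"""Linear stability of the homogeneous steady state under flow.

Perturbations ∝ exp(iqx + σt) about the uniform fixed point obey

    σ u = [R − q² diag(D) − i q diag(v)] u = J(q) u,

with R the reaction Jacobian, diag(D) the per-species diffusivities and
diag(v) the per-species advection velocities (zero for membrane species;
``v_f`` for bulk MinD; ``v_f`` or 0 for bulk MinE depending on the
ablation flag).  Sign conventions, used everywhere in the package:
phase velocity of a mode is −Im σ/q, and a pattern is *downstream* when
its phase velocity has the sign of ``v_f``.

Two conservation laws force a two-dimensional null space of J(0) for the
full and skeleton variants.  The reduced-switch variant carries only the
four MinD fields (MinE is slaved), so its Jacobian is 4×4 and is defined
here for q > 0, where perturbations have zero mean and leave the slaved
MinE pools untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from minflow.models import homogeneous_steady_state, reaction_fluxes
from minflow.parameters import KineticParameters
from minflow.state import FieldState

_D_FIELDS = slice(0, 4)


def reaction_jacobian(params: KineticParameters, steady: FieldState) -> np.ndarray:
    """Analytic Jacobian of the reaction terms at a uniform state (6×6)."""
    p = params
    m_d = float(np.asarray(steady.m_d).flat[0])
    m_de = float(np.asarray(steady.m_de).flat[0])
    c_DT = float(np.asarray(steady.c_DT).flat[0])
    c_Er = float(np.asarray(steady.c_Er).flat[0])
    c_Ei = float(np.asarray(steady.c_Ei).flat[0])
    att = p.k_D + p.k_dD * m_d

    R = np.zeros((6, 6))
    # f_d
    R[0, 0] = p.k_dD * c_DT - p.k_dEr * c_Er - p.k_dEi * c_Ei
    R[0, 3] = att
    R[0, 4] = -p.k_dEr * m_d
    R[0, 5] = -p.k_dEi * m_d
    # f_de
    R[1, 0] = p.k_dEr * c_Er + p.k_dEi * c_Ei
    R[1, 1] = -p.k_de
    R[1, 4] = p.k_dEr * m_d
    R[1, 5] = p.k_dEi * m_d
    # f_DD
    R[2, 1] = p.k_de
    R[2, 2] = -p.lambda_
    # f_DT
    R[3, 0] = -p.k_dD * c_DT
    R[3, 2] = p.lambda_
    R[3, 3] = -att
    # f_Er
    R[4, 0] = -p.k_dEr * c_Er
    R[4, 1] = p.k_de
    R[4, 4] = -p.k_dEr * m_d - p.mu
    # f_Ei
    R[5, 0] = -p.k_dEi * c_Ei
    R[5, 4] = p.mu
    R[5, 5] = -p.k_dEi * m_d
    return R


def _check_steady(params: KineticParameters, steady: FieldState,
                  tol: float = 1e-7) -> None:
    f = reaction_fluxes(steady, params).as_array()
    scale = max(params.n_D_mean, params.n_E_mean, 1.0)
    resid = float(np.max(np.abs(f))) / scale
    if resid > tol:
        raise ValueError(f"state is not a fixed point (residual {resid:.3e})")


def jacobian_at_q(params: KineticParameters, steady: FieldState,
                  q: float) -> np.ndarray:
    """Full linearized operator J(q) about a verified uniform fixed point.

    Returns a complex 6×6 matrix (full/skeleton) or the 4×4 MinD block for
    the reduced-switch variant (valid for q > 0).
    """
    _check_steady(params, steady)
    p = params
    R = reaction_jacobian(p, steady)
    a = 1.0 if p.advect_minE else 0.0
    D = np.array([p.D_m, p.D_m, p.D_c, p.D_c, p.D_c, p.D_c])
    v = p.v_f * np.array([0.0, 0.0, 1.0, 1.0, a, a])
    J = R.astype(complex) - np.diag(q * q * D) - 1j * q * np.diag(v)
    if p.variant == "reduced_switch":
        return J[_D_FIELDS, _D_FIELDS]
    return J


@dataclass
class DispersionRelation:
    """Leading growth rate σ(q) plus continuity-tracked eigenvalue branches."""

    q_grid: np.ndarray
    sigma: np.ndarray                  # leading-by-Re eigenvalue per q
    all_eigenvalues: np.ndarray        # (nq, n) branch-tracked
    params: KineticParameters

    @property
    def growth(self) -> np.ndarray:
        return self.sigma.real

    @property
    def max_growth(self) -> float:
        return float(self.sigma.real.max())

    def sign_changes(self) -> np.ndarray:
        """q values (interpolated) where the leading Re σ crosses zero."""
        g = self.sigma.real
        out = []
        for i in range(len(g) - 1):
            if g[i] == 0.0:
                continue
            if g[i] * g[i + 1] < 0:
                f = g[i] / (g[i] - g[i + 1])
                out.append(self.q_grid[i] + f * (self.q_grid[i + 1] - self.q_grid[i]))
        return np.array(out)

    def bands(self, threshold: float = 1e-12) -> list["InstabilityBand"]:
        return _extract_bands(self, threshold)


@dataclass
class InstabilityBand:
    """One contiguous unstable wavenumber band."""

    q_min: float
    q_max: float
    q_peak: float
    growth_peak: float
    phase_velocity: float            # −Im σ(q_peak)/q_peak, μm/s
    direction: str                   # downstream / upstream / stationary / none

    @property
    def wavelength_peak(self) -> float:
        return 2.0 * np.pi / self.q_peak


def _direction_label(phase_velocity: float, v_f: float,
                     tol: float = 1e-10) -> str:
    if v_f == 0.0:
        return "none"
    s = phase_velocity * np.sign(v_f)
    if abs(phase_velocity) < tol:
        return "stationary"
    return "downstream" if s > 0 else "upstream"


def _extract_bands(disp: DispersionRelation,
                   threshold: float) -> list[InstabilityBand]:
    q, g = disp.q_grid, disp.sigma.real
    pos = q > 0
    unstable = (g > threshold) & pos
    bands: list[InstabilityBand] = []
    i = 0
    n = len(q)
    while i < n:
        if not unstable[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and unstable[j + 1]:
            j += 1
        qlo = q[i] if i == 0 or not pos[i - 1] else _zero_cross(q, g, i - 1)
        qhi = q[j] if j == n - 1 else _zero_cross(q, g, j)
        ip = i + int(np.argmax(g[i:j + 1]))
        qp, gp = _parabolic_peak(q, g, ip)
        ph = -disp.sigma.imag[ip] / q[ip]
        bands.append(InstabilityBand(
            q_min=float(qlo), q_max=float(qhi), q_peak=float(qp),
            growth_peak=float(gp), phase_velocity=float(ph),
            direction=_direction_label(ph, disp.params.v_f)))
        i = j + 1
    return bands


def _zero_cross(q, g, i):
    if g[i] == g[i + 1]:
        return q[i]
    f = g[i] / (g[i] - g[i + 1])
    return q[i] + f * (q[i + 1] - q[i])


def _parabolic_peak(q, g, ip):
    if 0 < ip < len(q) - 1:
        y0, y1, y2 = g[ip - 1], g[ip], g[ip + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            d = 0.5 * (y0 - y2) / denom
            d = np.clip(d, -0.5, 0.5)
            dq = q[ip + 1] - q[ip]
            return q[ip] + d * dq, y1 - 0.25 * (y0 - y2) * d
    return q[ip], g[ip]


def dispersion_relation(params: KineticParameters,
                        q_grid: np.ndarray | None = None,
                        steady: FieldState | None = None) -> DispersionRelation:
    """Eigenvalues of J(q) over a wavenumber grid with branch tracking.

    Branches are matched between adjacent q points by maximal eigenvector
    overlap (greedy assignment on \\|V_i† V_{i+1}\\|); ``sigma`` is the
    leading-by-real-part eigenvalue at each q.
    """
    if q_grid is None:
        q_grid = np.linspace(0.0, 1.0, 201)
    q_grid = np.asarray(q_grid, dtype=float)
    if steady is None:
        steady = homogeneous_steady_state(params)
    _check_steady(params, steady)

    evs = []
    prev_vecs = None
    for q in q_grid:
        J = _jac_unchecked(params, steady, q)
        w, V = np.linalg.eig(J)
        if prev_vecs is not None:
            order = _match_branches(prev_vecs, V)
            w, V = w[order], V[:, order]
        evs.append(w)
        prev_vecs = V
    all_ev = np.array(evs)
    sigma = all_ev[np.arange(len(q_grid)), np.argmax(all_ev.real, axis=1)]
    return DispersionRelation(q_grid=q_grid, sigma=sigma,
                              all_eigenvalues=all_ev, params=params)


def _jac_unchecked(params, steady, q):
    p = params
    R = reaction_jacobian(p, steady)
    a = 1.0 if p.advect_minE else 0.0
    D = np.array([p.D_m, p.D_m, p.D_c, p.D_c, p.D_c, p.D_c])
    v = p.v_f * np.array([0.0, 0.0, 1.0, 1.0, a, a])
    J = R.astype(complex) - np.diag(q * q * D) - 1j * q * np.diag(v)
    if p.variant == "reduced_switch":
        J = J[_D_FIELDS, _D_FIELDS]
    return J


def _match_branches(V_prev: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Greedy eigenvector-overlap matching between adjacent q points."""
    overlap = np.abs(V_prev.conj().T @ V)        # (n_prev_branch, n_new)
    n = overlap.shape[0]
    order = np.full(n, -1)
    used = np.zeros(n, dtype=bool)
    # assign in decreasing overlap order
    flat = np.argsort(overlap, axis=None)[::-1]
    assigned = 0
    for idx in flat:
        i, j = divmod(idx, n)
        if order[i] < 0 and not used[j]:
            order[i] = j
            used[j] = True
            assigned += 1
            if assigned == n:
                break
    return order


def max_growth_rate(params: KineticParameters,
                    q_grid: np.ndarray | None = None,
                    steady: FieldState | None = None) -> float:
    """max over q > 0 of Re σ(q)."""
    d = dispersion_relation(params, q_grid, steady)
    mask = d.q_grid > 0
    return float(d.sigma.real[mask].max())


def flow_driven_threshold(params: KineticParameters,
                          v_grid: np.ndarray,
                          q_grid: np.ndarray | None = None,
                          tol: float = 1e-3) -> float | None:
    """Critical flow speed at which a laterally stable point destabilizes.

    Requires the point to be stable at v_f = 0 (otherwise raises, reporting
    the resting instability).  Scans ``v_grid`` (ascending magnitudes) for
    the first unstable speed and refines by bisection to relative ``tol``.
    Returns None if stable throughout.  The threshold is even in v_f.
    """
    base = params.with_(v_f=0.0)
    steady = homogeneous_steady_state(base)
    g0 = max_growth_rate(base, q_grid, steady)
    if g0 > 0:
        bands = dispersion_relation(base, q_grid, steady).bands()
        raise ValueError(
            f"point is already unstable at v_f = 0 (max growth {g0:.3e}; "
            f"bands {bands})")

    def growth(v):
        p = params.with_(v_f=float(abs(v)))
        return max_growth_rate(p, q_grid, homogeneous_steady_state(p))

    v_grid = np.sort(np.abs(np.asarray(v_grid, dtype=float)))
    lo, hi = 0.0, None
    for v in v_grid:
        if v == 0.0:
            continue
        if growth(v) > 0:
            hi = v
            break
        lo = v
    if hi is None:
        return None
    while (hi - lo) > tol * hi:
        mid = 0.5 * (lo + hi)
        if growth(mid) > 0:
            hi = mid
        else:
            lo = mid
    return float(0.5 * (lo + hi))
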