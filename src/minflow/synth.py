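"""Synthetic inputs: seeded simulation states and fluorescence-like image
stacks with known ground truth.

The stack generators emulate the imaging regime of in vitro Min assays:
15 s frame interval, wavelengths of tens of μm, wave speeds of hundreds of
nm/s, additive Gaussian (optionally Poisson) noise, mono-exponential
bleaching, and static bright aggregates.  Frames are quantized to integer
camera counts so stacks round-trip losslessly through 16-bit TIFF.  Every
generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from minflow.crest import ImageStack
from minflow.models import homogeneous_steady_state
from minflow.parameters import KineticParameters
from minflow.state import FieldState, Grid

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Simulation initial conditions
# ---------------------------------------------------------------------------

def noisy_homogeneous_state(params: KineticParameters, grid: Grid,
                            seed: int = 0, amplitude: float = 1e-3
                            ) -> FieldState:
    """Homogeneous steady state with a seeded multiplicative perturbation
    (uniform in [−amplitude, amplitude], independent per field and point)."""
    ss = homogeneous_steady_state(params, grid)
    rng = np.random.default_rng(seed)
    a = ss.as_array()
    a *= 1.0 + amplitude * rng.uniform(-1.0, 1.0, size=a.shape)
    return FieldState.from_array(a, t=0.0)


def seeded_wave_state(params: KineticParameters, grid: Grid,
                      wavelength: float, direction: int, seed: int = 0,
                      amplitude: float = 0.3,
                      noise_amplitude: float = 1e-3) -> FieldState:
    """Finite-amplitude traveling-wave seed on the homogeneous steady state.

    The membrane MinD field is modulated by ``1 + A cos(qx)`` and the MinDE
    complex by the same modulation shifted a quarter wavelength toward the
    trailing side, mimicking the MinE-rich rear of a Min wave so the seed
    relaxes into a wave moving in the requested ``direction`` (±1 along x).
    Bulk MinD is depleted under the membrane accumulation.  Wavelengths
    incommensurate with the periodic domain are snapped to the nearest
    harmonic (logged).
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    L = grid.lengths[0]
    k = max(int(round(L / wavelength)), 1)
    snapped = L / k
    if abs(snapped - wavelength) > 1e-9 * L:
        log.info("seed wavelength %.4g snapped to harmonic %.4g", wavelength,
                 snapped)
    q = 2.0 * np.pi * k / L
    x = grid.x
    ss = homogeneous_steady_state(params, grid)
    a = ss.as_array()
    mod = amplitude * np.cos(q * x)
    mod_de = amplitude * np.cos(q * x + direction * np.pi / 2.0)
    if grid.n_dims == 2:
        mod = mod[:, None] * np.ones(grid.shape[1])
        mod_de = mod_de[:, None] * np.ones(grid.shape[1])
    a[0] *= 1.0 + mod            # m_d accumulation zone
    a[1] *= 1.0 + mod_de         # MinDE trailing edge
    a[3] *= 1.0 - 0.5 * mod      # bulk MinD-ATP depleted above the zone
    rng = np.random.default_rng(seed)
    a *= 1.0 + noise_amplitude * rng.uniform(-1.0, 1.0, size=a.shape)
    return FieldState.from_array(np.clip(a, 0.0, None), t=0.0)


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticStackSpec:
    """Specification of a synthetic fluorescence time-lapse.

    Angles are degrees from the +x (flow) axis, measured toward +y (rows).
    ``speed`` is in nm/s, ``wavelength`` and ``pixel_size`` in μm,
    ``interval`` in seconds, ``bleach_rate`` per frame, aggregates as
    (x_px, y_px, intensity, radius_px) tuples.
    """

    kind: str = "planar"                  # planar | spiral | static
    wavelength: float = 60.0
    speed: float = 300.0
    direction_deg: float = 0.0
    amplitude: float = 1000.0
    baseline: float = 200.0
    noise_sd: float = 20.0
    bleach_rate: float = 0.0
    aggregates: tuple = ()
    H: int = 160
    W: int = 160
    T: int = 30
    pixel_size: float = 2.0
    interval: float = 15.0
    poisson: bool = False
    psf_sigma_px: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("planar", "spiral", "static"):
            raise ValueError(f"unknown stack kind {self.kind!r}")
        if self.T < 2 or self.H < 8 or self.W < 8:
            raise ValueError("stack too small")
        if self.pixel_size <= 0 or self.interval <= 0:
            raise ValueError("pixel size and interval must be positive")
        if self.kind != "static":
            if self.wavelength <= 2.0 * self.pixel_size:
                raise ValueError("wavelength must exceed 2 pixels")
            if self.speed * 1e-3 * self.interval >= self.wavelength / 2.0:
                raise ValueError(
                    "speed × interval ≥ wavelength/2: temporal aliasing")


@dataclass
class GroundTruth:
    """True velocity (nm/s, lab frame), wavelength (μm) and aggregate mask."""

    velocity: tuple[float, float]
    wavelength: float
    aggregate_mask: np.ndarray

    @property
    def speed(self) -> float:
        return float(np.hypot(*self.velocity))

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.velocity[1], self.velocity[0])))


def _finalize(spec: SyntheticStackSpec, clean: np.ndarray,
              agg_mask: np.ndarray) -> ImageStack:
    rng = np.random.default_rng(spec.seed)
    frames = clean
    if spec.bleach_rate > 0:
        decay = np.exp(-spec.bleach_rate * np.arange(spec.T))
        frames = frames * decay[:, None, None]
    for (ax, ay, inten, rad) in spec.aggregates:
        yy, xx = np.mgrid[0:spec.H, 0:spec.W]
        blob = inten * np.exp(-((xx - ax) ** 2 + (yy - ay) ** 2)
                              / (2.0 * rad ** 2))
        frames = frames + blob[None, :, :]
    if spec.psf_sigma_px > 0:
        from scipy.ndimage import gaussian_filter
        frames = np.stack([gaussian_filter(f, spec.psf_sigma_px)
                           for f in frames])
    if spec.poisson:
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)
    frames = np.clip(np.round(frames), 0, 65535)
    return ImageStack(frames=frames.astype(float),
                      pixel_size=spec.pixel_size, interval=spec.interval)


def _aggregate_mask(spec: SyntheticStackSpec) -> np.ndarray:
    mask = np.zeros((spec.H, spec.W), dtype=bool)
    yy, xx = np.mgrid[0:spec.H, 0:spec.W]
    for (ax, ay, _inten, rad) in spec.aggregates:
        mask |= ((xx - ax) ** 2 + (yy - ay) ** 2) <= (2.0 * rad) ** 2
    return mask


def planar_wave_stack(spec: SyntheticStackSpec
                      ) -> tuple[ImageStack, GroundTruth]:
    """Plane wave  I = baseline + A·(1 + cos(k·r − ωt))/2  plus noise,
    bleaching and static aggregates."""
    if spec.kind != "planar":
        raise ValueError("spec.kind must be 'planar'")
    th = np.radians(spec.direction_deg)
    k = 2.0 * np.pi / spec.wavelength                      # 1/μm
    v = spec.speed * 1e-3                                  # μm/s
    omega = k * v
    yy, xx = np.mgrid[0:spec.H, 0:spec.W]
    x_um = xx * spec.pixel_size
    y_um = yy * spec.pixel_size
    proj = np.cos(th) * x_um + np.sin(th) * y_um
    t = np.arange(spec.T)[:, None, None] * spec.interval
    clean = spec.baseline + 0.5 * spec.amplitude * (
        1.0 + np.cos(k * proj[None, :, :] - omega * t))
    truth = GroundTruth(
        velocity=(spec.speed * np.cos(th), spec.speed * np.sin(th)),
        wavelength=spec.wavelength, aggregate_mask=_aggregate_mask(spec))
    return _finalize(spec, clean, truth.aggregate_mask), truth


def spiral_stack(spec: SyntheticStackSpec) -> tuple[ImageStack, GroundTruth]:
    """Archimedean spiral rotating at ω = k·v; chirality from the sign of
    ``direction_deg`` (±1 arm handedness).  Truth speed is the radial
    phase speed; propagation direction is isotropic."""
    if spec.kind != "spiral":
        raise ValueError("spec.kind must be 'spiral'")
    chirality = -1.0 if spec.direction_deg < 0 else 1.0
    k = 2.0 * np.pi / spec.wavelength
    v = spec.speed * 1e-3
    omega = k * v
    yy, xx = np.mgrid[0:spec.H, 0:spec.W]
    cx, cy = (spec.W - 1) / 2.0, (spec.H - 1) / 2.0
    r = np.hypot(xx - cx, yy - cy) * spec.pixel_size
    th = np.arctan2(yy - cy, xx - cx)
    t = np.arange(spec.T)[:, None, None] * spec.interval
    phase = k * r[None] - chirality * th[None] - omega * t
    clean = spec.baseline + 0.5 * spec.amplitude * (1.0 + np.cos(phase))
    truth = GroundTruth(velocity=(spec.speed, 0.0),
                        wavelength=spec.wavelength,
                        aggregate_mask=_aggregate_mask(spec))
    return _finalize(spec, clean, truth.aggregate_mask), truth


def static_stack(spec: SyntheticStackSpec) -> tuple[ImageStack, GroundTruth]:
    """Constant background plus aggregates and noise: no wave truth."""
    clean = np.full((spec.T, spec.H, spec.W), spec.baseline, dtype=float)
    truth = GroundTruth(velocity=(0.0, 0.0), wavelength=float("nan"),
                        aggregate_mask=_aggregate_mask(spec))
    return _finalize(spec, clean, truth.aggregate_mask), truth


def generate(spec: SyntheticStackSpec) -> tuple[ImageStack, GroundTruth]:
    return {"planar": planar_wave_stack, "spiral": spiral_stack,
            "static": static_stack}[spec.kind](spec)


def trajectory_to_stack(traj, width: int = 64, pixel_size: float | None = None,
                        species: str = "m_d", interval: float | None = None,
                        gain: float = 1.0, offset: float = 0.0) -> ImageStack:
    """Render a 1D simulation trajectory as an image stack by extruding the
    profile along y, for feeding simulated waves to the crest analyzer."""
    prof = traj.species(species)
    if traj.grid.n_dims == 2:
        prof = prof.mean(axis=2)
    if pixel_size is None:
        pixel_size = traj.grid.dx[0]
    if interval is None:
        dts = np.diff(traj.times)
        interval = float(dts[0])
        if not np.allclose(dts, interval):
            raise ValueError("trajectory frames are not equally spaced")
    frames = np.repeat(prof[:, None, :], width, axis=1) * gain + offset
    return ImageStack(frames=frames.astype(float), pixel_size=float(pixel_size),
                      interval=interval)
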