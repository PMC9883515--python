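"""Wave-crest velocimetry for time-lapse stacks.

Pipeline: per-pixel temporal phase images → sub-pixel crest (zero-phase
ridge) detection → frame-to-frame crest translation by patch matching
along the local wave normal → velocity filtering → direction statistics
(2D velocity histogram at 25 nm/s binning, 15° angular histogram,
downstream/upstream fractions, peak speed ± FWHM/2 from a 10 nm/s speed
histogram).

Phase images come from the temporal analytic signal after per-frame bleach
normalization, per-pixel detrending and a band-pass around the dominant
oscillation frequency; pixels without a clear oscillatory component are
masked, never fabricated.  Angle convention: 0° is downstream (+x, image
columns), increasing toward +y (image rows); angular bins are half-open
(a−15°, a].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage import measure

log = logging.getLogger(__name__)


@dataclass
class ImageStack:
    """Single-channel time-lapse: frames (T, H, W), pixel size (μm),
    frame interval (s), flow axis along +x (columns) unless rotated."""

    frames: np.ndarray
    pixel_size: float
    interval: float = 15.0
    flow_angle_deg: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("stack must be (T>=2, H, W)")
        if self.pixel_size <= 0 or self.interval <= 0:
            raise ValueError("pixel size and interval must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def save_tiff(self, path) -> None:
        import tifffile
        data = np.clip(np.round(self.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data, metadata={
            "pixel_size_um": self.pixel_size, "interval_s": self.interval})

    @classmethod
    def load_tiff(cls, path, pixel_size: float | None = None,
                  interval: float | None = None) -> "ImageStack":
        import tifffile
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray().astype(float)
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        return cls(frames=data,
                   pixel_size=pixel_size or float(meta.get("pixel_size_um", 1.0)),
                   interval=interval or float(meta.get("interval_s", 15.0)))


@dataclass
class PhaseStack:
    """Per-pixel oscillation phase (radians, (−π, π]; NaN where masked),
    envelope amplitude, and the dominant angular frequency (rad/s)."""

    phase: np.ndarray
    amplitude: np.ndarray
    omega: float
    mask: np.ndarray            # True where valid


@dataclass
class CrestVelocityRecord:
    """One matched crest point: position (px), velocity (nm/s), frame."""

    x: float
    y: float
    v_x: float
    v_y: float
    frame: int

    @property
    def speed(self) -> float:
        return float(np.hypot(self.v_x, self.v_y))

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.v_y, self.v_x)))


@dataclass
class DirectionSummary:
    """Direction statistics of a set of crest velocity records."""

    hist2d: np.ndarray
    hist2d_edges: np.ndarray            # shared vx/vy bin edges, nm/s
    angular_hist: np.ndarray            # 24 bins, normalized to sum 1
    angular_edges: np.ndarray           # degrees, right edges multiples of 15
    downstream_fraction: float
    upstream_fraction: float
    peak_speed: float                   # nm/s
    speed_fwhm: float                   # nm/s
    n_records: int
    low_confidence: bool


# ---------------------------------------------------------------------------
# Phase images
# ---------------------------------------------------------------------------

def phase_map(stack: ImageStack, band_halfwidth: float = 0.6,
              amplitude_floor: float = 0.2) -> PhaseStack:
    """Temporal analytic-signal phase of the band-passed oscillation.

    Steps: normalize each frame by its spatial median relative to the
    temporal median of those medians (bleach correction); subtract the
    per-pixel temporal mean; find the dominant temporal frequency from the
    pixel-averaged power spectrum; apply a Gaussian band-pass of relative
    half-width ``band_halfwidth`` around it and build the analytic signal
    (positive frequencies only).  Pixels whose mean envelope is below
    ``amplitude_floor`` × the global median envelope are masked.
    """
    T = stack.frames.shape[0]
    med = np.median(stack.frames.reshape(T, -1), axis=1)
    med_ref = np.median(med)
    gain = np.where(med > 0, med_ref / np.where(med > 0, med, 1.0), 1.0)
    data = stack.frames * gain[:, None, None]
    data = data - data.mean(axis=0, keepdims=True)

    freqs = np.fft.rfftfreq(T, d=stack.interval)
    spec = np.fft.rfft(data, axis=0)
    power = (np.abs(spec) ** 2).mean(axis=(1, 2))
    power[0] = 0.0
    if power.max() <= 0 or not np.isfinite(power.max()):
        phase = np.full(stack.frames.shape, np.nan)
        return PhaseStack(phase=phase, amplitude=np.zeros_like(stack.frames),
                          omega=0.0, mask=np.zeros(stack.frames.shape, bool))
    kpeak = int(np.argmax(power))
    f0 = freqs[kpeak]
    bandwidth = max(band_halfwidth * f0, freqs[1])
    window = np.exp(-0.5 * ((freqs - f0) / bandwidth) ** 2)
    window[0] = 0.0
    from scipy.signal import hilbert
    banded = np.fft.irfft(spec * window[:, None, None], n=T, axis=0)
    analytic = np.conj(hilbert(banded, axis=0))
    # conjugation makes the phase of cos(k·r − ωt) come out as k·r − ωt
    # (increasing along the propagation direction, decreasing in time)
    amplitude = np.abs(analytic)
    amp_mean = amplitude.mean(axis=0)
    floor = amplitude_floor * np.median(amp_mean)
    valid2d = amp_mean > max(floor, 1e-12)
    phase = np.angle(analytic)
    mask = np.broadcast_to(valid2d, phase.shape).copy()
    phase = np.where(mask, phase, np.nan)
    return PhaseStack(phase=phase, amplitude=amplitude,
                      omega=2.0 * np.pi * f0, mask=mask)


# ---------------------------------------------------------------------------
# Crest detection
# ---------------------------------------------------------------------------

def detect_crests(phase_frame: np.ndarray, min_points: int = 5
                  ) -> list[np.ndarray]:
    """Sub-pixel zero-phase ridges of one masked phase frame.

    Returns ordered polylines as (n, 2) arrays of (row, col).  The zero
    level set of sin(φ) is intersected with cos(φ) > 0 to keep the crest
    (φ = 0) and drop the trough (φ = ±π); masked regions yield no points.
    """
    valid = np.isfinite(phase_frame)
    if not valid.any():
        return []
    s = np.where(valid, np.sin(phase_frame), 2.0)
    c = np.where(valid, np.cos(phase_frame), -2.0)
    polylines = []
    for contour in measure.find_contours(s, 0.0):
        cvals = map_coordinates(c, contour.T, order=1, mode="nearest")
        keep = cvals > 0.5
        # split the polyline where points are dropped
        start = None
        for i, k in enumerate(np.append(keep, False)):
            if k and start is None:
                start = i
            elif not k and start is not None:
                if i - start >= min_points:
                    polylines.append(contour[start:i].copy())
                start = None
    return polylines


# ---------------------------------------------------------------------------
# Crest translation
# ---------------------------------------------------------------------------

def _dominant_wavelength_px(frame: np.ndarray) -> float | None:
    """Dominant spatial wavelength (pixels) from the radially binned power
    spectrum of one frame; None when no clear peak exists.  More robust
    than local phase gradients for anharmonic wave profiles, whose flat
    troughs bias gradient statistics."""
    f = frame - frame.mean()
    power = np.abs(np.fft.rfftn(f)) ** 2
    H, W = frame.shape
    qy = np.fft.fftfreq(H)[:, None]
    qx = np.fft.rfftfreq(W)[None, :]
    qr = np.hypot(qy, qx)
    nbins = max(min(H, W) // 2, 4)
    edges = np.linspace(0, 0.5, nbins + 1)
    idx = np.clip(np.digitize(qr.ravel(), edges) - 1, 0, nbins - 1)
    radial = np.bincount(idx, weights=power.ravel(), minlength=nbins)
    radial[0] = 0.0
    if radial.max() <= 0:
        return None
    k = int(np.argmax(radial))
    q_peak = 0.5 * (edges[k] + edges[k + 1])
    if q_peak <= 0:
        return None
    return 1.0 / q_peak


def _local_normals(phase_frame: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Unit normals (row, col) along the phase gradient at given points.

    The phase of a wave cos(k·r − ωt) increases along k, so the gradient
    points in the propagation direction.
    """
    gy, gx = _masked_gradient(phase_frame)
    g = np.stack([map_coordinates(gy, points.T, order=1, mode="nearest"),
                  map_coordinates(gx, points.T, order=1, mode="nearest")],
                 axis=1)
    norm = np.linalg.norm(g, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return g / norm


def _masked_gradient(phase: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Wrap-aware phase gradient: differentiate exp(iφ) to avoid ±π jumps."""
    z = np.exp(1j * np.where(np.isfinite(phase), phase, 0.0))
    gy_z, gx_z = np.gradient(z)
    gy = (gy_z / (1j * z)).real
    gx = (gx_z / (1j * z)).real
    bad = ~np.isfinite(phase)
    gy[bad] = np.nan
    gx[bad] = np.nan
    return gy, gx


def crest_displacements(stack: ImageStack, phases: PhaseStack | None = None,
                        stride: int = 3, search_frac: float = 0.25,
                        profile_halfwidth_frac: float = 0.25,
                        n_offsets: int = 81) -> list[CrestVelocityRecord]:
    """Frame-to-frame crest translation by patch matching along the normal.

    For every detected crest point (subsampled every ``stride`` vertices) an
    intensity profile along the local wave normal is extracted in frame i
    and matched against frame i+1 over offsets within ±``search_frac``
    wavelengths, maximizing normalized correlation with sub-pixel parabolic
    refinement.  Velocity = displacement × pixel size / interval (nm/s).
    Points with no admissible match are dropped and counted.
    """
    if phases is None:
        phases = phase_map(stack)
    T = stack.frames.shape[0]
    if phases.omega == 0.0:
        return []
    records: list[CrestVelocityRecord] = []
    dropped = 0

    lam_px = _dominant_wavelength_px(stack.frames[0])
    if lam_px is None:
        # fallback: median phase-gradient magnitude
        gy, gx = _masked_gradient(phases.phase[0])
        gmed = np.nanmedian(np.hypot(gy, gx))
        if not np.isfinite(gmed) or gmed <= 0:
            return []
        lam_px = 2.0 * np.pi / gmed
    search = max(search_frac * lam_px, 1.5)
    half = max(profile_halfwidth_frac * lam_px, 2.0)
    s_axis = np.linspace(-half, half, max(int(2 * half), 9))
    offsets = np.linspace(-search, search, n_offsets)

    for i in range(T - 1):
        polylines = detect_crests(phases.phase[i])
        if not polylines:
            continue
        pts = np.concatenate([pl[::stride] for pl in polylines], axis=0)
        normals = _local_normals(phases.phase[i], pts)
        ok = np.isfinite(normals).all(axis=1)
        pts, normals = pts[ok], normals[ok]
        if len(pts) == 0:
            continue
        f0, f1 = stack.frames[i], stack.frames[i + 1]
        P, S, K = len(pts), len(s_axis), len(offsets)
        base = pts[:, :, None] + normals[:, :, None] * s_axis[None, None, :]
        prof0 = map_coordinates(f0, base.transpose(1, 0, 2).reshape(2, -1),
                                order=1, mode="nearest").reshape(P, S)
        prof0 = prof0 - prof0.mean(axis=1, keepdims=True)
        p0n = np.linalg.norm(prof0, axis=1)
        scores = np.full((P, K), -1.0)
        for j, d in enumerate(offsets):
            c1 = pts[:, :, None] + normals[:, :, None] * (s_axis + d)[None, None, :]
            prof1 = map_coordinates(f1, c1.transpose(1, 0, 2).reshape(2, -1),
                                    order=1, mode="nearest").reshape(P, S)
            prof1 = prof1 - prof1.mean(axis=1, keepdims=True)
            p1n = np.linalg.norm(prof1, axis=1)
            denom = p0n * p1n
            with np.errstate(invalid="ignore", divide="ignore"):
                scores[:, j] = np.where(denom > 0,
                                        (prof0 * prof1).sum(axis=1) / denom,
                                        -1.0)
        jbest = np.argmax(scores, axis=1)
        sbest = scores[np.arange(P), jbest]
        good = (sbest >= 0.3) & (jbest > 0) & (jbest < K - 1) & (p0n > 0)
        dropped += int((~good).sum())
        for ip in np.nonzero(good)[0]:
            jb = jbest[ip]
            y0, y1, y2 = scores[ip, jb - 1:jb + 2]
            denom = y0 - 2 * y1 + y2
            dj = 0.5 * (y0 - y2) / denom if denom < 0 else 0.0
            dj = float(np.clip(dj, -0.5, 0.5))
            d_star = offsets[jb] + dj * (offsets[1] - offsets[0])
            v = d_star * normals[ip] * stack.pixel_size / stack.interval * 1e3
            records.append(CrestVelocityRecord(
                x=float(pts[ip, 1]), y=float(pts[ip, 0]),
                v_x=float(v[1]), v_y=float(v[0]), frame=i))
    if dropped:
        log.info("crest matching dropped %d points without a match", dropped)
    return records


# ---------------------------------------------------------------------------
# Filtering and statistics
# ---------------------------------------------------------------------------

def filter_velocities(records: list[CrestVelocityRecord]
                      ) -> list[CrestVelocityRecord]:
    """Drop records with speed below 10% of the median speed (suppresses
    static bright objects such as protein aggregates)."""
    if not records:
        return []
    speeds = np.array([r.speed for r in records])
    cutoff = 0.1 * np.median(speeds)
    kept = [r for r, s in zip(records, speeds) if s >= cutoff]
    n_removed = len(records) - len(kept)
    if n_removed:
        log.info("velocity filter removed %d of %d records (<%.1f nm/s)",
                 n_removed, len(records), cutoff)
    return kept


def _angular_bin_index(angles_deg: np.ndarray) -> np.ndarray:
    """Half-open 15° bins (a−15, a]; index 0 has right edge −165°."""
    a = np.mod(np.asarray(angles_deg) + 180.0, 360.0) - 180.0  # (−180, 180]
    a = np.where(a == -180.0, 180.0, a)
    idx = np.ceil(a / 15.0 - 1e-12).astype(int) + 11           # right edge/15 + 11
    return np.clip(idx, 0, 23)


def direction_summary(records: list[CrestVelocityRecord],
                      flow_angle_deg: float = 0.0,
                      min_records: int = 10) -> DirectionSummary:
    """All direction statistics of a filtered record set.

    Velocities are rotated so 0° is downstream along the flow axis.  The
    2D histogram uses 25 nm/s bins; the angular histogram 15° half-open
    segments normalized to sum 1; the downstream fraction covers
    (−30°, +30°], the upstream fraction (150°, 210°]; the peak speed and
    its FWHM come from a 10 nm/s speed histogram.
    """
    if not records:
        raise ValueError("no records to summarize")
    vx = np.array([r.v_x for r in records])
    vy = np.array([r.v_y for r in records])
    if flow_angle_deg != 0.0:
        th = np.radians(flow_angle_deg)
        vx, vy = np.cos(th) * vx + np.sin(th) * vy, \
            -np.sin(th) * vx + np.cos(th) * vy

    vmax = max(np.abs(np.concatenate([vx, vy])).max(), 25.0)
    edge = 25.0 * np.ceil(vmax / 25.0)
    edges = np.arange(-edge, edge + 25.0, 25.0)
    h2d, _, _ = np.histogram2d(vx, vy, bins=(edges, edges))

    angles = np.degrees(np.arctan2(vy, vx))
    idx = _angular_bin_index(angles)
    ang_hist = np.bincount(idx, minlength=24).astype(float)
    ang_hist /= ang_hist.sum()
    ang_edges = np.arange(-180.0, 181.0, 15.0)

    a = np.mod(angles + 180.0, 360.0) - 180.0
    a = np.where(a == -180.0, 180.0, a)
    down = np.mean((a > -30.0) & (a <= 30.0))
    up = np.mean((a > 150.0) | (a <= -150.0))

    speeds = np.hypot(vx, vy)
    smax = max(speeds.max(), 10.0)
    s_edges = np.arange(0.0, 10.0 * np.ceil(smax / 10.0) + 10.0, 10.0)
    s_hist, _ = np.histogram(speeds, bins=s_edges)
    kpk = int(np.argmax(s_hist))
    peak_speed = 0.5 * (s_edges[kpk] + s_edges[kpk + 1])
    fwhm = _hist_fwhm(s_hist, s_edges)

    return DirectionSummary(
        hist2d=h2d, hist2d_edges=edges, angular_hist=ang_hist,
        angular_edges=ang_edges, downstream_fraction=float(down),
        upstream_fraction=float(up), peak_speed=float(peak_speed),
        speed_fwhm=float(fwhm), n_records=len(records),
        low_confidence=len(records) < min_records)


def _hist_fwhm(counts: np.ndarray, edges: np.ndarray) -> float:
    """FWHM of a histogram peak by linear interpolation on bin centers."""
    centers = 0.5 * (edges[:-1] + edges[1:])
    kpk = int(np.argmax(counts))
    half = counts[kpk] / 2.0
    left = centers[0]
    for i in range(kpk, 0, -1):
        if counts[i - 1] < half:
            f = (counts[i] - half) / max(counts[i] - counts[i - 1], 1e-12)
            left = centers[i] - f * (centers[i] - centers[i - 1])
            break
    right = centers[-1]
    for i in range(kpk, len(counts) - 1):
        if counts[i + 1] < half:
            f = (counts[i] - half) / max(counts[i] - counts[i + 1], 1e-12)
            right = centers[i] + f * (centers[i + 1] - centers[i])
            break
    return max(right - left, edges[1] - edges[0])


def analyze_stack(stack: ImageStack, **kw) -> tuple[list[CrestVelocityRecord],
                                                    DirectionSummary]:
    """Full pipeline: phase → crests → displacements → filter → summary."""
    records = filter_velocities(crest_displacements(stack, **kw))
    if not records:
        raise ValueError("no crest velocities recovered from stack")
    return records, direction_summary(records,
                                      flow_angle_deg=stack.flow_angle_deg)
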