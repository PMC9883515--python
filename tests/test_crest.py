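"""Crest velocimetry: phase maps, crest detection, displacement recovery,
velocity filtering, direction statistics."""

import numpy as np
import pytest

from minflow.crest import (
    CrestVelocityRecord, ImageStack, analyze_stack, crest_displacements,
    detect_crests, direction_summary, filter_velocities, phase_map,
    _angular_bin_index,
)
from minflow.synth import SyntheticStackSpec, generate


def make_stack(**kw):
    base = dict(kind="planar", wavelength=60.0, speed=300.0, direction_deg=0.0,
                H=128, W=128, T=24, pixel_size=2.0, noise_sd=15.0, seed=7)
    base.update(kw)
    return generate(SyntheticStackSpec(**base))


@pytest.fixture(scope="module")
def planar300():
    return make_stack()


class TestPhaseMap:
    def test_plane_wave_phase_structure(self, planar300):
        """Phase of cos(kx − ωt) advances by ωΔt per frame and kΔx per
        pixel along the propagation axis."""
        stack, truth = planar300
        ph = phase_map(stack)
        # temporal phase decrement per frame equals the band-peak frequency,
        # which sits within one spectral bin of the true frequency
        dphi = np.angle(np.exp(1j * (ph.phase[1:] - ph.phase[:-1])))
        omega_true = 2 * np.pi * (truth.speed * 1e-3) / truth.wavelength
        est = np.nanmedian(-dphi)
        assert est == pytest.approx(ph.omega * stack.interval, rel=0.05)
        bin_width = 2 * np.pi / (stack.frames.shape[0] * stack.interval)
        assert abs(ph.omega - omega_true) <= bin_width
        # spatial phase increment
        dphix = np.angle(np.exp(1j * np.diff(ph.phase[0], axis=1)))
        k_true = 2 * np.pi / truth.wavelength * stack.pixel_size
        assert np.nanmedian(dphix) == pytest.approx(k_true, rel=0.05)

    def test_constant_stack_fully_masked(self):
        stack = ImageStack(frames=np.full((12, 32, 32), 500.0), pixel_size=2.0)
        ph = phase_map(stack)
        assert not ph.mask.any()
        assert np.isnan(ph.phase).all()

    def test_non_oscillatory_pixels_masked(self):
        """A dead corner without oscillation is masked, not fabricated."""
        stack, _ = make_stack(noise_sd=5.0)
        frames = stack.frames.copy()
        frames[:, :20, :20] = 400.0
        dead = ImageStack(frames, stack.pixel_size, stack.interval)
        ph = phase_map(dead)
        assert ph.mask[0, 25:, 25:].mean() > 0.9
        assert ph.mask[0, :15, :15].mean() < 0.2


class TestDetectCrests:
    def test_crest_spacing_matches_wavelength(self, planar300):
        stack, truth = planar300
        ph = phase_map(stack)
        polylines = detect_crests(ph.phase[3])
        assert polylines
        # crests are vertical lines; x positions spaced by one wavelength
        xs = sorted(np.median(pl[:, 1]) for pl in polylines
                    if len(pl) > 30)
        spacings = np.diff(xs) * stack.pixel_size
        expected = truth.wavelength
        assert np.all(np.abs(spacings - expected) / expected < 0.02)

    def test_crest_points_lie_on_intensity_ridge(self, planar300):
        stack, _ = make_stack(noise_sd=0.0)
        ph = phase_map(stack)
        pts = np.concatenate(detect_crests(ph.phase[5]))
        from scipy.ndimage import map_coordinates
        vals = map_coordinates(stack.frames[5], pts.T, order=1)
        assert vals.mean() > 0.9 * stack.frames[5].max()

    def test_masked_frame_empty(self):
        assert detect_crests(np.full((32, 32), np.nan)) == []


class TestCrestDisplacements:
    def test_static_frames_yield_no_fabricated_velocities(self):
        """A stack with no temporal oscillation is fully masked upstream,
        so no displacement records are fabricated."""
        stack, _ = make_stack(speed=0.0, noise_sd=0.0)
        assert crest_displacements(stack) == []

    def test_known_speed_recovered(self, planar300):
        stack, truth = planar300
        recs = crest_displacements(stack)
        vx = np.array([r.v_x for r in recs])
        vy = np.array([r.v_y for r in recs])
        assert abs(vx.mean() - truth.velocity[0]) < 15.0
        assert abs(vy.mean()) < 15.0

    def test_time_reversal_negates_velocities(self):
        stack, _ = make_stack(noise_sd=0.0, T=16)
        fwd = crest_displacements(stack)
        rev_stack = ImageStack(stack.frames[::-1].copy(), stack.pixel_size,
                               stack.interval)
        rev = crest_displacements(rev_stack)
        assert np.mean([r.v_x for r in fwd]) == pytest.approx(
            -np.mean([r.v_x for r in rev]), abs=10.0)


class TestFilterVelocities:
    def test_median_rule_direct(self):
        """Records below 10% of the median magnitude are removed."""
        recs = [CrestVelocityRecord(0, 0, s, 0.0, 0) for s in
                (1.0, 100.0, 100.0, 100.0, 100.0)]
        kept = filter_velocities(recs)
        assert len(kept) == 4
        assert all(r.speed >= 10.0 for r in kept)

    def test_all_equal_magnitudes_kept(self):
        recs = [CrestVelocityRecord(0, 0, 50.0, 0.0, i) for i in range(6)]
        assert len(filter_velocities(recs)) == 6

    def test_empty_input(self):
        assert filter_velocities([]) == []

    def test_static_aggregates_removed_without_biasing_wave(self):
        """Bright static blobs produce near-zero velocities that the filter
        removes; the wave speed estimate is unchanged within 5%."""
        clean_stack, _ = make_stack(seed=21)
        agg_stack, truth = make_stack(
            seed=21, aggregates=((30, 40, 3000.0, 4.0), (90, 70, 3000.0, 4.0)))
        v_clean = np.mean([r.v_x for r in
                           filter_velocities(crest_displacements(clean_stack))])
        v_agg = np.mean([r.v_x for r in
                         filter_velocities(crest_displacements(agg_stack))])
        assert v_agg == pytest.approx(v_clean, rel=0.05)


class TestDirectionSummary:
    def test_single_downstream_record(self):
        s = direction_summary([CrestVelocityRecord(0, 0, 300.0, 0.0, 0)])
        assert s.downstream_fraction == 1.0
        assert s.upstream_fraction == 0.0
        assert s.low_confidence                       # < 10 records
        assert abs(s.peak_speed - 300.0) <= 5.0       # 10 nm/s bins

    def test_angular_bins_are_half_open(self):
        # 30° falls in the (15,30] bin; 30.0001° in the next
        idx30 = _angular_bin_index(np.array([30.0]))[0]
        idx30p = _angular_bin_index(np.array([30.0001]))[0]
        assert idx30p == idx30 + 1

    def test_uniform_angles_flat_histogram(self, rng):
        n = 24000
        ang = rng.uniform(-np.pi, np.pi, n)
        recs = [CrestVelocityRecord(0, 0, 200 * np.cos(a), 200 * np.sin(a), 0)
                for a in ang]
        s = direction_summary(recs)
        assert np.allclose(s.angular_hist, 1 / 24, atol=3 * np.sqrt(
            (1 / 24) * (23 / 24) / n) + 1e-3)
        assert s.downstream_fraction == pytest.approx(4 / 24, abs=0.02)
        assert s.upstream_fraction == pytest.approx(4 / 24, abs=0.02)
        assert s.angular_hist.sum() == pytest.approx(1.0)

    def test_flow_axis_rotation(self):
        recs = [CrestVelocityRecord(0, 0, 0.0, 300.0, 0)] * 12
        s = direction_summary(recs, flow_angle_deg=90.0)
        assert s.downstream_fraction == 1.0

    def test_rotating_stack_rotates_summary(self):
        """90°-rotated input yields the same statistics with the angular
        histogram shifted by 90° (equivariance)."""
        stack, _ = make_stack(T=16)
        rot = ImageStack(np.rot90(stack.frames, axes=(1, 2)).copy(),
                         stack.pixel_size, stack.interval)
        s0 = direction_summary(filter_velocities(crest_displacements(stack)))
        s90 = direction_summary(filter_velocities(crest_displacements(rot)))
        assert s90.peak_speed == pytest.approx(s0.peak_speed, rel=0.05)
        # +x motion becomes −y motion under np.rot90 of (row, col) frames
        ang0 = np.degrees(np.arctan2(0, 1))
        i0 = np.argmax(s0.angular_hist)
        i90 = np.argmax(s90.angular_hist)
        assert (i0 - i90) % 24 == 6 or (i90 - i0) % 24 == 18


class TestEndToEnd:
    @pytest.mark.parametrize("speed,angle", [(150.0, 0.0), (300.0, 135.0),
                                             (600.0, 250.0)])
    def test_speed_and_angle_recovery(self, speed, angle):
        """Across the in vitro speed range and arbitrary orientations the
        pipeline recovers speed within 5% and angle within 5°."""
        stack, truth = make_stack(speed=speed, direction_deg=angle,
                                  noise_sd=20.0,
                                  aggregates=((25, 25, 2000.0, 3.0),))
        recs, summary = analyze_stack(stack)
        vx = np.mean([r.v_x for r in recs])
        vy = np.mean([r.v_y for r in recs])
        assert np.hypot(vx, vy) == pytest.approx(speed, rel=0.05)
        ang_err = (np.degrees(np.arctan2(vy, vx)) - angle + 180) % 360 - 180
        assert abs(ang_err) < 5.0

    def test_spiral_isotropy(self):
        """A rotating spiral has no preferred propagation direction."""
        stack, _ = make_stack(kind="spiral", H=160, W=160, noise_sd=10.0)
        recs, summary = analyze_stack(stack)
        assert summary.angular_hist.max() < 0.2
        assert summary.downstream_fraction < 0.4
        assert summary.upstream_fraction < 0.4
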