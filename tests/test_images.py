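"""Image quantification: profiles, detection, pore radius, rim tension."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from poregel.images import (
    ImageFrame,
    TractionMap,
    angular_profile,
    detect_blisters,
    detect_spots,
    load_stack,
    pore_radius_series,
    radial_profile,
    rim_tension,
    save_stack,
    spot_ring_width,
)
from poregel.synth import (
    SceneConfig,
    gen_brightfield_blisters,
    gen_liposome_movie,
    gen_traction_map,
)

PX = 0.1e-6


def _disk_frame(radius_px=60, n=161, value=1.0, channel="actin"):
    c = (n - 1) / 2
    yy, xx = np.mgrid[0:n, 0:n]
    img = np.where(np.hypot(yy - c, xx - c) <= radius_px, value, 0.0)
    return ImageFrame(img, PX, channel=channel), (c * PX, c * PX)


class TestRadialProfile:
    def test_uniform_disk_flat_inside_with_edge_drop(self):
        frame, center = _disk_frame()
        prof = radial_profile(frame, center)
        inside = prof["I"][prof["r_m"] < 50 * PX]
        assert np.allclose(inside, 1.0, atol=1e-6)
        assert prof["I"][-1] < 0.1

    def test_ring_peaks_at_ring_radius(self):
        n, c = 161, 80.0
        yy, xx = np.mgrid[0:n, 0:n]
        rr = np.hypot(yy - c, xx - c)
        img = np.exp(-0.5 * ((rr - 40.0) / 2.0) ** 2)
        frame = ImageFrame(img, PX)
        prof = radial_profile(frame, (c * PX, c * PX))
        peak_r = prof["r_m"][np.argmax(prof["I"])]
        assert abs(peak_r - 40.0 * PX) <= 1.0 * PX

    def test_rotation_invariance(self):
        rngl = np.random.default_rng(1)
        n, c = 161, 80.0
        yy, xx = np.mgrid[0:n, 0:n]
        img = np.hypot(yy - c, xx - c) + rngl.uniform(0, 0.1, (n, n))
        frame = ImageFrame(img, PX)
        prof = radial_profile(frame, (c * PX, c * PX))
        rot = ImageFrame(np.rot90(img).copy(), PX)
        prof_rot = radial_profile(rot, (c * PX, c * PX))
        keep = prof["r_m"] < 70 * PX
        assert np.allclose(prof["I"][keep], prof_rot["I"][keep], rtol=5e-3)

    def test_center_outside_rejected(self):
        frame, _ = _disk_frame()
        with pytest.raises(ValueError):
            radial_profile(frame, (1.0, 1.0))


class TestAngularProfile:
    def test_uniform_ring_is_flat(self):
        frame, center = _disk_frame()
        prof = angular_profile(frame, center, 30 * PX)
        assert np.allclose(prof["I"], 1.0, atol=1e-6)

    def test_point_source_peaks_at_zero_degrees(self):
        n, c = 161, 80.0
        yy, xx = np.mgrid[0:n, 0:n]
        # source on the circle at theta = 0 (x positive from center)
        img = np.exp(-0.5 * (((yy - c) ** 2 + (xx - (c + 40)) ** 2) / 9.0))
        frame = ImageFrame(img, PX)
        prof = angular_profile(frame, (c * PX, c * PX), 40 * PX)
        assert prof["theta_deg"][np.argmax(prof["I"])] == pytest.approx(
            0.0, abs=2.0)
        # symmetric decay around the peak
        assert prof["I"][10] == pytest.approx(prof["I"][-10], rel=0.05)

    def test_logistic_wave_spread_increases(self):
        """Actin recruiting around a blister rim: the above-half-max
        angular fraction grows as the wave spreads."""
        n, c, r = 161, 80.0, 40.0
        yy, xx = np.mgrid[0:n, 0:n]
        theta_img = np.arctan2(yy - c, xx - c)
        rr = np.hypot(yy - c, xx - c)
        ring = np.exp(-0.5 * ((rr - r) / 2.0) ** 2)
        fracs = []
        for spread in (0.3, 1.0, 2.5):
            wave = 1.0 / (1.0 + np.exp((np.abs(theta_img) - spread) / 0.1))
            frame = ImageFrame(ring * wave + 1e-3, PX)
            fracs.append(angular_profile(frame, (c * PX, c * PX), r * PX)
                         ["above_half_max_fraction"])
        assert fracs[0] < fracs[1] < fracs[2]

    def test_circle_must_stay_inside(self):
        frame, center = _disk_frame()
        with pytest.raises(ValueError):
            angular_profile(frame, center, 200 * PX)


class TestBlisters:
    def test_planted_disks_recovered(self):
        cfg = SceneConfig(seed=5, n_blisters=7)
        frame, truth = gen_brightfield_blisters(cfg)
        found = detect_blisters(frame)
        assert len(found) == truth["n_blisters"]
        d, _ = cKDTree(found.centers).query(truth["centers_m"])
        assert np.all(d < 0.5e-6)
        assert np.all(np.abs(found.radii - truth["radius_m"])
                      < 0.15 * truth["radius_m"])

    def test_blank_frame_empty(self):
        frame = ImageFrame(np.full((64, 64), 0.7), PX, channel="brightfield")
        assert len(detect_blisters(frame)) == 0

    def test_offset_invariance(self):
        cfg = SceneConfig(seed=5, n_blisters=7)
        frame, _ = gen_brightfield_blisters(cfg)
        shifted = ImageFrame(frame.intensity + 10.0, PX,
                             channel="brightfield")
        assert len(detect_blisters(shifted)) == len(detect_blisters(frame))

    def test_wrong_channel_rejected(self):
        frame, _ = _disk_frame(channel="actin")
        with pytest.raises(ValueError):
            detect_blisters(frame)


class TestSpots:
    def _metrics(self, seed):
        frames, truth = gen_liposome_movie(SceneConfig(seed=seed))
        spots = detect_spots(frames[-1], center=truth["center_m"])
        gt = np.column_stack([truth["spots_y_m"], truth["spots_x_m"]])
        if len(spots) == 0:
            return 0.0, 0.0
        d, _ = cKDTree(spots.centers).query(gt)
        d2, _ = cKDTree(gt).query(spots.centers)
        return float(np.mean(d < 0.5e-6)), float(np.mean(d2 < 0.5e-6))

    def test_recall_and_precision_at_snr5(self):
        recalls, precisions = zip(*(self._metrics(s) for s in range(5)))
        assert np.mean(recalls) >= 0.9
        assert np.mean(precisions) >= 0.9

    def test_blank_frame_empty(self):
        frame = ImageFrame(np.full((64, 64), 2.0), PX, channel="actin")
        assert len(detect_spots(frame)) == 0

    def test_gain_invariance(self):
        frames, truth = gen_liposome_movie(SceneConfig(seed=2))
        frame = frames[-1]
        doubled = ImageFrame(2.0 * frame.intensity, PX, channel="actin")
        a = detect_spots(frame, center=truth["center_m"])
        b = detect_spots(doubled, center=truth["center_m"])
        assert len(a) == len(b)


class TestSpotRingWidth:
    def test_planted_annulus_width_recovered(self):
        frames, truth = gen_liposome_movie(
            SceneConfig(seed=1, n_spots=40, ring_width=2e-6))
        spots = detect_spots(frames[-1], center=truth["center_m"])
        out = spot_ring_width(spots, truth["center_m"],
                              truth["R_liposome_m"])
        assert out["w_m"] == pytest.approx(2e-6, rel=0.15)
        assert out["w_over_R"] == pytest.approx(0.2, rel=0.15)

    def test_spots_on_contact_line_give_zero_width(self):
        from poregel.images import SpotSet

        theta = np.linspace(0, 2 * np.pi, 9)[:-1]
        R = 10e-6
        centers = np.column_stack([R * np.sin(theta), R * np.cos(theta)])
        spots = SpotSet(centers, np.full(8, 0.5e-6), np.ones(8))
        out = spot_ring_width(spots, (0.0, 0.0), R)
        assert out["w_m"] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_spots_rejected(self):
        from poregel.images import SpotSet

        spots = SpotSet(np.zeros((2, 2)), np.full(2, 1e-6), np.ones(2))
        with pytest.raises(ValueError):
            spot_ring_width(spots, (0.0, 0.0), 1e-5)


class TestPoreRadiusSeries:
    def _pore_frames(self, radii_px):
        n = 161
        c = (n - 1) / 2
        yy, xx = np.mgrid[0:n, 0:n]
        rr = np.hypot(yy - c, xx - c)
        frames = []
        for i, rp in enumerate(radii_px):
            img = np.where((rr > rp) & (rr <= 75), 1.0, 0.05)
            frames.append(ImageFrame(img, PX, channel="actin", time=10.0 * i))
        return frames

    def test_extracted_radius_matches_truth(self):
        radii_px = np.array([10, 20, 30, 45, 60])
        ts = pore_radius_series(self._pore_frames(radii_px))
        assert np.allclose(ts.y, radii_px * PX, rtol=0.05)
        assert np.all(np.diff(ts.y) > 0)

    def test_frame_without_pore_rejected(self):
        frame = ImageFrame(np.full((64, 64), 1.0), PX)
        with pytest.raises(ValueError, match="dark"):
            pore_radius_series([frame])


class TestRimTension:
    def test_uniform_rim_stress_times_perimeter(self):
        """2 Pa on the rim of a ~70 um perimeter contact gives the
        0.14 mN/m scale."""
        R = 70e-6 / (2 * np.pi)
        tmap, truth = gen_traction_map(1.4e-4, R, 2e-6, 0.0, seed=0)
        # marching-squares on a pixelated disk overestimates slightly
        assert truth["perimeter_m"] == pytest.approx(70e-6, rel=0.08)
        assert truth["rim_stress_pa"] == pytest.approx(2.0, rel=0.08)
        assert rim_tension(tmap) == pytest.approx(1.4e-4, rel=0.01)

    def test_zero_stress_gives_zero(self):
        tmap, _ = gen_traction_map(1.4e-4, 11e-6, 2e-6, 0.0, seed=0)
        zero = TractionMap(np.zeros_like(tmap.stress), tmap.pixel_size,
                           tmap.contact_mask)
        assert rim_tension(zero) == 0.0

    def test_robust_to_rim_width_choice(self):
        # the stress band fills 3 um so every narrower analysis band
        # sees the same mean stress
        tmap, _ = gen_traction_map(1.4e-4, 11e-6, 3e-6, 0.0, seed=0)
        for w in (1e-6, 2e-6, 3e-6):
            assert rim_tension(tmap, rim_width=w) == pytest.approx(
                1.4e-4, rel=0.05)

    def test_integrated_mode_differs_but_same_scale(self):
        tmap, _ = gen_traction_map(1.4e-4, 11e-6, 2e-6, 0.0, seed=0)
        lit = rim_tension(tmap, mode="literal")
        integ = rim_tension(tmap, mode="integrated")
        assert 0.01 * lit < integ < 100 * lit

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            rim_tension(TractionMap(np.zeros((8, 8, 2)), 1e-7,
                                    np.zeros((8, 8), dtype=bool)))


class TestCalibrationScaling:
    def test_geometry_scales_with_pixel_size(self):
        """The same pixel grid at 2x the calibration reports 2x lengths."""
        cfg = SceneConfig(seed=5, n_blisters=7)
        frame, _ = gen_brightfield_blisters(cfg)
        big = ImageFrame(frame.intensity, 2 * frame.pixel_size,
                         channel="brightfield")
        a = detect_blisters(frame)
        b = detect_blisters(big, min_diameter=1e-6, max_diameter=20e-6)
        assert len(a) == len(b)
        # the physical-scale bandpass adapts to the calibration, so the
        # segmented areas agree only approximately
        assert np.allclose(np.sort(b.radii), 2 * np.sort(a.radii), rtol=0.1)


class TestStackIO:
    def test_tiff_roundtrip_with_sidecar(self, tmp_path):
        frames, _ = gen_liposome_movie(SceneConfig(seed=0, n_frames=3))
        fp = tmp_path / "movie.tif"
        save_stack(frames, fp, frame_interval=10.0)
        back = load_stack(fp)
        assert len(back) == 3
        assert back[0].pixel_size == frames[0].pixel_size
        assert np.allclose(back[-1].intensity, frames[-1].intensity,
                           atol=1e-5)

    def test_missing_sidecar_fails(self, tmp_path):
        import tifffile

        fp = tmp_path / "naked.tif"
        tifffile.imwrite(fp, np.zeros((4, 4), dtype=np.float32))
        with pytest.raises(FileNotFoundError):
            load_stack(fp)
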