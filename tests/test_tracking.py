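"""Detection, localization, linking, kymographs and on-axis projection."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter1d

from forceglide import tracking as tk
from forceglide.synthetic import OpticsConfig
from forceglide.synthetic.imaging import _add_spot


def _frame(shape=(32, 48), spots=(), photons=5000.0, background=10.0,
           read_noise=2.0, seed=0):
    """Render a minimal test frame: Gaussian spots + Poisson/read noise."""
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    for (x_px, y_px) in spots:
        _add_spot(img, x_px, y_px, 0.8125, photons)
    img += background
    img = rng.poisson(img).astype(float)
    img += rng.normal(0.0, read_noise, img.shape)
    return np.clip(img, 0, None)


class TestDetection:
    def test_blank_frame_no_spots(self):
        img = _frame(spots=())
        assert len(tk.detect_spots(img)) == 0

    def test_empty_image(self):
        assert len(tk.detect_spots(np.zeros((16, 16)))) == 0

    def test_single_spot_within_one_pixel(self):
        img = _frame(spots=[(20.3, 15.6)])
        det = tk.detect_spots(img)
        assert len(det) == 1
        assert abs(det.x_px[0] - 20.3) <= 1.0
        assert abs(det.y_px[0] - 15.6) <= 1.0

    def test_two_spots_beyond_diffraction_limit(self):
        # 2 µm apart = 12.5 px at 160 nm/px
        img = _frame(shape=(32, 64), spots=[(20.0, 16.0), (32.5, 16.0)])
        assert len(tk.detect_spots(img)) == 2


class TestLocalization:
    def test_noiseless_recovery_to_hundredth_pixel(self):
        img = np.zeros((32, 48))
        _add_spot(img, 20.3, 15.8, 0.8125, 50000.0)
        img += 5.0
        pos, prec = tk.localize_subpixel(img, (16, 20), pixel_size=160.0)
        assert pos[0] / 160.0 - 0.5 == pytest.approx(20.3, abs=0.02)
        assert pos[1] / 160.0 - 0.5 == pytest.approx(15.8, abs=0.02)

    def test_rms_error_shrinks_with_photons(self):
        rng = np.random.default_rng(1)
        errs = []
        for photons in (500.0, 50000.0):
            e = []
            for rep in range(25):
                img = _frame(spots=[(20.3, 15.8)], photons=photons,
                             seed=rng.integers(2**31))
                out = tk.localize_subpixel(img, (16, 20), pixel_size=160.0)
                if out is not None:
                    e.append(np.hypot(out[0][0] - 160.0 * 20.8,
                                      out[0][1] - 160.0 * 16.3))
            errs.append(np.sqrt(np.mean(np.square(e))))
        # ~100x photons -> ~10x precision; allow generous slack
        assert errs[1] < errs[0] / 3.0

    def test_high_snr_localization_under_five_nanometres(self):
        errs = []
        for rep in range(10):
            img = _frame(spots=[(20.3, 15.8)], photons=100000.0, seed=rep)
            out = tk.localize_subpixel(img, (16, 20), pixel_size=160.0)
            errs.append(out[0][0] - 160.0 * 20.8)
        assert np.sqrt(np.mean(np.square(errs))) < 5.0

    def test_symmetric_spot_center_matches_centroid(self):
        img = np.zeros((33, 33))
        _add_spot(img, 16.0, 16.0, 0.8125, 10000.0)
        pos, _ = tk.localize_subpixel(img, (16, 16), pixel_size=160.0)
        yy, xx = np.mgrid[0:33, 0:33]
        cx = (img * xx).sum() / img.sum()
        assert pos[0] / 160.0 - 0.5 == pytest.approx(cx, abs=1e-3)

    def test_edge_spot_dropped(self):
        img = _frame()
        assert tk.localize_subpixel(img, (0, 0), window=7) is None


def _drift_detections(n_frames, step_nm=160.0, start=(1000.0, 2000.0),
                      gap=None):
    rows = []
    for f in range(n_frames):
        if gap and gap[0] <= f < gap[1]:
            continue
        rows.append({"frame": f, "x_nm": start[0] + f * step_nm,
                     "y_nm": start[1]})
    return pd.DataFrame(rows)


class TestLinking:
    def test_single_drifting_spot_one_track(self):
        tracks = tk.link_tracks(_drift_detections(30))
        assert len(tracks) == 1
        assert len(tracks[0]) == 30

    def test_gap_of_ten_frames_stitched(self):
        # disappears 10 frames; reappears within the 4 px gap-close radius
        det = _drift_detections(40, step_nm=30.0, gap=(15, 25))
        tracks = tk.link_tracks(det, max_link=640.0, max_gap_close=640.0,
                                max_gap=20)
        assert len(tracks) == 1

    def test_gap_beyond_twenty_frames_splits(self):
        det = _drift_detections(60, step_nm=10.0, gap=(15, 41))
        tracks = tk.link_tracks(det, max_gap=20)
        assert len(tracks) == 2

    def test_two_parallel_spots_stay_separate(self):
        a = _drift_detections(25, start=(1000.0, 1000.0))
        b = _drift_detections(25, start=(1000.0, 3000.0))
        tracks = tk.link_tracks(pd.concat([a, b], ignore_index=True))
        assert len(tracks) == 2
        assert all(len(t) == 25 for t in tracks)

    def test_frames_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            tk.SpotTrack(0, np.array([0, 0, 1]), np.zeros((3, 2)))


class TestBackboneProjection:
    def test_straight_backbone_arc_equals_x(self):
        bb = tk.BackbonePolyline(np.array([[0.0, 0.0], [5000.0, 0.0]]))
        track = tk.SpotTrack(0, np.array([0]), np.array([[500.0, 30.0]]))
        out = tk.project_onaxis(track, bb)
        assert out.onaxis_nm[0] == pytest.approx(500.0)
        assert not out.off_axis_flag[0]

    def test_bent_backbone_reports_arc_length_not_chord(self):
        # 90-degree bend: a point past the corner maps to corner arc + leg
        bb = tk.BackbonePolyline(np.array([[0.0, 0.0], [1000.0, 0.0],
                                           [1000.0, 1000.0]]))
        track = tk.SpotTrack(0, np.array([0]), np.array([[1000.0, 600.0]]))
        out = tk.project_onaxis(track, bb)
        assert out.onaxis_nm[0] == pytest.approx(1600.0)

    def test_vertex_maps_to_vertex_arc(self):
        bb = tk.BackbonePolyline(np.array([[0.0, 0.0], [1000.0, 0.0],
                                           [1000.0, 1000.0]]))
        track = tk.SpotTrack(0, np.array([0]), np.array([[1000.0, 0.0]]))
        assert tk.project_onaxis(track, bb).onaxis_nm[0] == pytest.approx(1000.0)

    def test_far_point_flagged_off_axis(self):
        bb = tk.BackbonePolyline(np.array([[0.0, 0.0], [1000.0, 0.0]]))
        track = tk.SpotTrack(0, np.array([0]), np.array([[500.0, 900.0]]))
        assert tk.project_onaxis(track, bb).off_axis_flag[0]

    def test_projection_is_contraction_on_straight_backbones(self):
        rng = np.random.default_rng(3)
        bb = tk.BackbonePolyline(np.array([[0.0, 0.0], [8000.0, 0.0]]))
        pts = rng.uniform([0, -300], [8000, 300], (40, 2))
        track = tk.SpotTrack(0, np.arange(40), pts)
        arc = tk.project_onaxis(track, bb).onaxis_nm.to_numpy()
        d2d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.all(np.abs(np.diff(arc)) <= d2d + 1e-9)

    def test_degenerate_backbone_rejected(self):
        with pytest.raises(ValueError):
            tk.BackbonePolyline(np.array([[0.0, 0.0]]))
        with pytest.raises(ValueError):
            tk.BackbonePolyline(np.array([[0.0, 0.0], [0.0, 0.0]]))


def _texture_kymograph(vfun, S=100, T=100, noise=3.0, seed=5):
    """Speckled line translating at vfun(t) nm/s; 160 nm rows, 0.2 s cols."""
    rng = np.random.default_rng(seed)
    ctrl = rng.lognormal(0, 0.7, 800)
    fine = gaussian_filter1d(
        np.interp(np.arange(0, 320000, 20), np.arange(800) * 400.0, ctrl), 8)
    space = np.arange(S) * 160.0
    data = np.empty((S, T))
    shift = 0.0
    for t in range(T):
        data[:, t] = np.interp(space + 100000 - shift,
                               np.arange(fine.size) * 20.0, fine) * 100.0
        data[:, t] += rng.normal(0, noise, S)
        shift += vfun(t) * 0.2
    return tk.Kymograph(data, 160.0, 0.2)


class TestKymograph:
    def test_build_static_line_rows_constant(self):
        rng = np.random.default_rng(0)
        H, W = 24, 60
        frame = np.zeros((H, W))
        profile = rng.lognormal(0, 0.5, W) * 100.0
        frame[H // 2 - 1:H // 2 + 2, :] = profile
        stack = np.repeat(frame[None], 10, axis=0)
        bb = tk.BackbonePolyline(np.array([[320.0, H / 2 * 160.0],
                                           [(W - 3) * 160.0, H / 2 * 160.0]]))
        kym = tk.build_kymograph(stack, bb, linewidth=3)
        assert np.allclose(kym.data, kym.data[:, :1])

    def test_empty_stack_rejected(self):
        bb = tk.BackbonePolyline(np.array([[0.0, 0.0], [1000.0, 0.0]]))
        with pytest.raises(ValueError):
            tk.build_kymograph(np.empty((0, 16, 16)), bb)

    def test_backbone_outside_image_rejected(self):
        bb = tk.BackbonePolyline(np.array([[0.0, 0.0], [100000.0, 0.0]]))
        with pytest.raises(ValueError):
            tk.build_kymograph(np.zeros((2, 16, 16)), bb)

    def test_translating_line_slope(self, rendered):
        # features in a kymograph built from rendered frames move at the
        # cargo speed
        sim, _motors, mt_stack, _truth = rendered
        H = mt_stack.shape[1]
        y = H / 2 * 160.0
        x1 = (mt_stack.shape[2] - 2) * 160.0
        bb = tk.BackbonePolyline(np.array([[160.0, y], [x1, y]]))
        kym = tk.build_kymograph(mt_stack, bb, linewidth=3)
        v = tk.kymograph_velocity(kym)
        target = sim.mt_velocity.mean()
        assert np.nanmean(v) == pytest.approx(target, rel=0.08)


class TestKymographVelocity:
    def test_constant_velocity_recovered_within_three_percent(self):
        kym = _texture_kymograph(lambda t: 800.0)
        v = tk.kymograph_velocity(kym)
        assert np.nanmean(v) == pytest.approx(800.0, rel=0.03)

    def test_constant_velocity_rms_within_five_percent(self):
        kym = _texture_kymograph(lambda t: 800.0, S=160, T=150)
        v = tk.kymograph_velocity(kym)
        rms = np.sqrt(np.nanmean((v - 800.0) ** 2))
        assert rms / 800.0 < 0.05

    def test_stationary_texture_near_zero(self):
        kym = _texture_kymograph(lambda t: 0.0)
        assert abs(np.nanmean(tk.kymograph_velocity(kym))) < 20.0

    def test_step_to_stall_recovered_within_two_frames(self):
        kym = _texture_kymograph(lambda t: 800.0 if t < 50 else 0.0)
        v = tk.kymograph_velocity(kym)
        below = np.flatnonzero(v < 400.0)
        below = below[below > 5]
        assert abs(int(below[0]) - 50) <= 2

    def test_structureless_kymograph_flagged(self):
        kym = tk.Kymograph(np.zeros((40, 30)), 160.0, 0.2)
        v = tk.kymograph_velocity(kym)
        assert np.isnan(v).all()

    def test_too_few_time_samples_rejected(self):
        with pytest.raises(ValueError):
            tk.kymograph_velocity(tk.Kymograph(np.zeros((10, 1)), 160.0, 0.2))


class TestEndToEndOnRenderedFixture:
    def test_track_recovery_matches_truth(self, rendered):
        sim, motor_stack, _mt, truth = rendered
        dets = []
        for f in range(motor_stack.shape[0]):
            for _, r in tk.detect_spots(motor_stack[f]).iterrows():
                loc = tk.localize_subpixel(motor_stack[f], (r.y_px, r.x_px))
                if loc is not None:
                    dets.append({"frame": f, "x_nm": loc[0][0],
                                 "y_nm": loc[0][1]})
        tracks = tk.link_tracks(pd.DataFrame(dets))
        table = tk.tracks_to_table(tracks)
        merged = table.merge(truth, left_on="FRAME", right_on="frame")
        merged["err"] = (merged.POSITION_X - merged.x_nm).abs()
        # each track maps to its best-matching true motor; >= 99% of frames
        # must lie within one pixel of that motor's true position
        ok, total = 0, 0
        for tid, g in merged.groupby("TRACK_ID"):
            med = g.groupby("kinesin").err.median()
            best = med.idxmin()
            sel = g[g.kinesin == best]
            ok += (sel.err < 160.0).sum()
            total += sim.time.size // 1
        n_frames = motor_stack.shape[0]
        assert len(tracks) == sim.n_motors
        assert ok / (sim.n_motors * n_frames) >= 0.99
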