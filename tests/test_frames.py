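"""Frame schedules, truncation, integration and VOI extraction."""

import numpy as np
import pytest

from nafpatlak.frames import (
    FrameSchedule,
    TimeActivityCurve,
    frame_midtimes,
    integrate_tac,
    read_tacs,
    truncate_tac,
    voi_mean_tac,
    write_tacs,
)


class TestSchedules:
    def test_90min_protocol(self, s90):
        assert s90.n_frames == 42
        assert s90.span_s == 5400.0
        # 26 early frames end at 360 s, the 4-min pause follows, frames resume at 600 s
        assert s90.frames[25, 1] == 360.0
        assert s90.frames[26, 0] == 600.0
        # frame 13 is the first 10-s frame, after twelve 5-s frames
        assert tuple(s90.frames[12]) == (60.0, 70.0)

    def test_60min_protocol(self, s60):
        assert s60.n_frames == 35
        assert s60.total_covered_s == 3600.0
        # contiguous: each frame starts where the previous one ends
        assert np.all(s60.frames[1:, 0] == s60.frames[:-1, 1])

    def test_midtimes(self, s90):
        mids = frame_midtimes(s90)
        assert mids[0] == 2.5
        assert mids[26] == 750.0  # (600 + 900) / 2, first frame after the pause
        assert mids.shape == (42,)
        assert np.all(np.diff(mids) > 0)

    @pytest.mark.parametrize(
        "frames, msg",
        [
            ([[0, 5], [4, 10]], "non-overlapping"),
            ([[0, 0]], "end_s > start_s"),
            ([[5, 2]], "end_s > start_s"),
        ],
    )
    def test_invalid_schedules_rejected(self, frames, msg):
        with pytest.raises(ValueError, match=msg):
            FrameSchedule(np.array(frames, dtype=float))


class TestTruncation:
    def test_frame_counts_at_windows(self, s60, s90):
        tac60 = TimeActivityCurve(s60, np.ones(35), "bone")
        tac90 = TimeActivityCurve(s90, np.ones(42), "bone")
        # 60-min protocol: 24 early frames cover 0-300 s, then 300-s frames
        assert truncate_tac(tac60, 30).n_frames == 29
        # 90-min protocol: 26 early frames + the 600-900 s frame ending at 15 min
        assert truncate_tac(tac90, 15).n_frames == 27

    def test_full_duration_is_identity(self, s60):
        tac = TimeActivityCurve(s60, np.arange(35, dtype=float), "bone")
        out = truncate_tac(tac, 60)
        assert out.schedule == tac.schedule
        assert np.array_equal(out.values, tac.values)

    def test_idempotent_and_nested(self, s60):
        tac = TimeActivityCurve(s60, np.arange(35, dtype=float), "bone")
        t30 = truncate_tac(tac, 30)
        assert truncate_tac(t30, 30).n_frames == t30.n_frames
        for lo, hi in [(15, 30), (30, 45), (45, 60)]:
            short, long = truncate_tac(tac, lo), truncate_tac(tac, hi)
            n = short.n_frames
            assert np.array_equal(short.schedule.frames, long.schedule.frames[:n])
            assert np.array_equal(short.values, long.values[:n])

    def test_empty_truncation_errors(self, s60):
        tac = TimeActivityCurve(s60, np.ones(35), "bone")
        with pytest.raises(ValueError, match="empty truncation"):
            truncate_tac(tac, 0.01)


def _fine_grid_oracle(tac, upto_s, n=200001):
    """Independent quadrature of the anchored midtime polyline."""
    t = np.concatenate([[0.0], tac.schedule.mid_s])
    v = np.concatenate([[0.0], tac.values])
    grid = np.linspace(0, upto_s, n)
    return np.trapezoid(np.interp(grid, t, v), grid)


class TestIntegration:
    def test_constant_curve_matches_fine_grid_oracle(self, s60):
        tac = TimeActivityCurve(s60, np.full(35, 7.0), "bone")
        for upto in [10.0, 300.0, 1801.0, 3450.0]:
            assert integrate_tac(tac, upto) == pytest.approx(
                _fine_grid_oracle(tac, upto), rel=1e-6
            )

    def test_linear_curve_matches_closed_form(self, s60):
        # values equal to midtimes: the polyline is exactly v(t) = t
        tac = TimeActivityCurve(s60, s60.mid_s.copy(), "bone")
        for upto in [100.0, 1000.0, 3400.0]:
            assert integrate_tac(tac, upto) == pytest.approx(upto**2 / 2, rel=1e-12)

    def test_zero_curve(self, s60):
        tac = TimeActivityCurve(s60, np.zeros(35), "bone")
        assert integrate_tac(tac, 1800.0) == 0.0

    def test_monotone_for_nonnegative_curves(self, s60, rng):
        tac = TimeActivityCurve(s60, rng.uniform(0, 50, 35), "bone")
        upto = np.linspace(5, 3450, 40)
        vals = [integrate_tac(tac, u) for u in upto]
        assert np.all(np.diff(vals) >= 0)

    def test_bridges_pause_linearly(self, s90):
        tac = TimeActivityCurve(s90, np.full(42, 3.0), "bone")
        # across the 360-600 s pause the constant polyline keeps value 3
        before = integrate_tac(tac, 350.0)
        after = integrate_tac(tac, 650.0)
        assert after - before == pytest.approx(3.0 * 300.0, rel=1e-9)

    def test_extrapolation_refused(self, s60):
        tac = TimeActivityCurve(s60, np.ones(35), "bone")
        with pytest.raises(ValueError, match="extrapolation refused"):
            integrate_tac(tac, 3500.0)  # last midtime is 3450 s
        with pytest.raises(ValueError, match="first frame midtime"):
            integrate_tac(tac, 1.0)


class TestVoiMean:
    def test_uniform_field(self, s60):
        img = np.full((35, 4, 4, 4), 7.0)
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 2, 3] = mask[0, 0, 0] = True
        tac = voi_mean_tac(img, mask, s60, "L1")
        assert np.all(tac.values == 7.0)
        assert tac.region == "L1"

    def test_two_voxel_mean(self, s60):
        img = np.zeros((35, 2, 2, 2))
        img[:, 0, 0, 0], img[:, 1, 1, 1] = 2.0, 4.0
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert np.all(voi_mean_tac(img, mask, s60, "r").values == 3.0)

    def test_brute_force_oracle(self, rng):
        sched = FrameSchedule(np.array([[0.0, 5.0], [5.0, 10.0]]))
        img = rng.uniform(0, 10, size=(2, 2, 2, 2))
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 1] = mask[1, 0, 0] = mask[1, 1, 1] = True
        tac = voi_mean_tac(img, mask, sched, "toy")
        for f in range(2):
            expected = (img[f, 0, 0, 1] + img[f, 1, 0, 0] + img[f, 1, 1, 1]) / 3
            assert tac.values[f] == pytest.approx(expected, rel=1e-15)

    def test_errors(self, s60):
        img = np.zeros((35, 2, 2, 2))
        with pytest.raises(ValueError, match="empty VOI"):
            voi_mean_tac(img, np.zeros((2, 2, 2), bool), s60, "r")
        with pytest.raises(ValueError, match="mask shape"):
            voi_mean_tac(img, np.ones((3, 2, 2), bool), s60, "r")


class TestCsvRoundTrip:
    @pytest.mark.parametrize("which", ["60", "90"])
    def test_bit_identical_round_trip(self, which, s60, s90, tmp_path, rng):
        sched = s60 if which == "60" else s90
        tacs = [
            TimeActivityCurve(sched, rng.uniform(0, 80, sched.n_frames), r)
            for r in ("aorta_IDIF", "lumbar")
        ]
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_tacs(p1, tacs)
        back = read_tacs(p1)
        assert set(back) == {"aorta_IDIF", "lumbar"}
        for tac in tacs:
            assert np.array_equal(back[tac.region].values, tac.values)
            assert np.array_equal(back[tac.region].schedule.frames, sched.frames)
        write_tacs(p2, [back["aorta_IDIF"], back["lumbar"]])
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_column_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("frame_start_s,frame_end_s,region\n0,5,x\n")
        with pytest.raises(ValueError, match="activity_kBq_per_mL"):
            read_tacs(bad)


def test_nifti_voi_extraction_round_trip(tmp_path, rng):
    nib = pytest.importorskip("nibabel")
    sched = FrameSchedule(np.array([[0.0, 5.0], [5.0, 10.0], [10.0, 15.0]]))
    img = rng.uniform(0, 10, size=(3, 2, 4, 3))  # (frame, z, y, x)
    mask = np.zeros((2, 4, 3))
    mask[1, 2, 0] = mask[0, 1, 1] = 1
    # NIfTI keeps time last: (x?, spatial..., t) -- the loader moves it back
    img_path, mask_path = tmp_path / "img.nii", tmp_path / "mask.nii"
    nib.save(nib.Nifti1Image(np.moveaxis(img, 0, -1), np.eye(4)), img_path)
    nib.save(nib.Nifti1Image(mask, np.eye(4)), mask_path)
    from nafpatlak.frames import load_nifti_tac

    tac = load_nifti_tac(str(img_path), str(mask_path), sched, "L2")
    expected = voi_mean_tac(img, mask > 0, sched, "L2").values
    assert np.allclose(tac.values, expected, rtol=1e-6)
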