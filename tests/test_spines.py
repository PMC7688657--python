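import math

import numpy as np
import pytest

from stedpuncta.spines import (
    SpineLandmarks,
    align_spine_crop,
    average_aligned,
    head_centre,
    read_landmarks_csv,
    write_landmarks_csv,
)
from stedpuncta.synth import SynthConfig, make_spine_fixture


def stubby_landmarks(hc=(50.0, 50.0), a=6.0, shaft=(70.0, 50.0), crop_id="s0"):
    r, c = hc
    return SpineLandmarks(
        crop_id=crop_id,
        spine_class="stubby",
        head_top=(r - a, c),
        head_bottom=(r + a, c),
        head_left=(r, c - a),
        head_right=(r, c + a),
        shaft_junction=shaft,
    )


class TestHeadCentre:
    def test_symmetric_points(self):
        lm = stubby_landmarks(hc=(0.0, 0.0), a=4.0, shaft=(10.0, 0.0))
        assert head_centre(lm) == (0.0, 0.0)

    def test_identical_points(self):
        lm = SpineLandmarks(
            crop_id="x", spine_class="stubby",
            head_top=(3.0, 4.0), head_bottom=(3.0, 4.0),
            head_left=(3.0, 4.0), head_right=(3.0, 4.0),
            shaft_junction=(9.0, 4.0),
        )
        assert head_centre(lm) == (3.0, 4.0)

    def test_offset_square(self):
        lm = stubby_landmarks(hc=(5.0, 7.0), a=3.0, shaft=(15.0, 7.0))
        assert head_centre(lm) == (5.0, 7.0)

    def test_mushroom_requires_neck_points(self):
        with pytest.raises(ValueError, match="neck"):
            SpineLandmarks(
                crop_id="m", spine_class="mushroom",
                head_top=(1, 1), head_bottom=(2, 1),
                head_left=(1.5, 0), head_right=(1.5, 2),
                shaft_junction=(5, 1),
            )


class TestAlignSpineCrop:
    def test_identity_for_aligned_spine(self, scfg):
        crops, lms = make_spine_fixture(1, "mushroom", scfg, angles=[0.0],
                                        noise=False)
        a = crops[0].channels["actin"]
        out = align_spine_crop(a, lms[0])
        finite = np.isfinite(out)
        assert finite.all()
        assert np.abs(out - a).max() < 1e-6

    def test_quarter_turn_matches_reference(self, scfg):
        """A spine built at 90 degrees aligns onto the 0-degree reference
        within bilinear-interpolation tolerance."""
        ref_crops, ref_lms = make_spine_fixture(1, "mushroom", scfg,
                                                angles=[0.0], noise=False)
        rot_crops, rot_lms = make_spine_fixture(1, "mushroom", scfg,
                                                angles=[math.pi / 2], noise=False)
        ref = align_spine_crop(ref_crops[0].channels["actin"], ref_lms[0])
        rot = align_spine_crop(rot_crops[0].channels["actin"], rot_lms[0])
        both = np.isfinite(ref) & np.isfinite(rot)
        peak = np.nanmax(ref)
        assert np.abs(ref[both] - rot[both]).max() < 0.02 * peak

    def test_shaft_above_head_gets_half_turn(self):
        img = np.zeros((101, 101))
        img[40, 50] = 1.0  # marker above centre
        lm = stubby_landmarks(hc=(50.0, 50.0), shaft=(30.0, 50.0))
        out = align_spine_crop(img, lm)
        # after the 180 degree turn the marker sits below the centre
        assert out[60, 50] == pytest.approx(1.0, abs=1e-9)
        assert out[40, 50] == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_orientation_rejected(self):
        lm = stubby_landmarks(hc=(50.0, 50.0), shaft=(50.0, 50.0))
        with pytest.raises(ValueError, match="orientation"):
            align_spine_crop(np.ones((101, 101)), lm)

    def test_out_of_field_pixels_are_nan_not_zero(self):
        img = np.ones((101, 101))
        # head far off-centre: alignment translates, leaving a missing rim
        lm = stubby_landmarks(hc=(20.0, 20.0), shaft=(40.0, 20.0))
        out = align_spine_crop(img, lm)
        assert np.isnan(out).any()
        finite = np.isfinite(out)
        assert np.all(out[finite] >= 0)

    def test_rigid_transform_conserves_intensity(self, scfg):
        """Content away from borders keeps its total intensity within 1 %."""
        crops, lms = make_spine_fixture(1, "mushroom", scfg,
                                        angles=[0.7], noise=False)
        a = crops[0].channels["post_marker"]  # compact central punctum
        out = align_spine_crop(a, lms[0])
        bg = scfg.background
        assert np.nansum(out - bg) == pytest.approx(np.sum(a - bg), rel=0.01)


class TestAverageAligned:
    def test_single_crop_is_itself(self, rng):
        crop = rng.uniform(0, 3, size=(21, 21))
        avg = average_aligned([crop], spine_class="stubby")
        np.testing.assert_array_equal(avg.array, crop)

    def test_mirror_pair_average_is_symmetric(self):
        a = np.zeros((9, 9))
        a[4, 2] = 1.0
        avg = average_aligned([a, a[:, ::-1]])
        np.testing.assert_allclose(avg.array, avg.array[:, ::-1])

    def test_mushroom_population_poi_mass_is_dendritic(self, scfg):
        """Aligned-average POI signal below the head-centre row exceeds the
        mass above it: the organelle signal comes from the dendritic side."""
        crops, lms = make_spine_fixture(24, "mushroom", scfg, noise=True,
                                        rng=np.random.default_rng(11))
        aligned = [
            align_spine_crop(c.channels["poi"], lm)
            for c, lm in zip(crops, lms)
        ]
        avg = average_aligned(aligned, spine_class="mushroom", role="poi").array
        mid = avg.shape[0] // 2
        below = np.nansum(avg[mid + 1 :] - scfg.background)
        above = np.nansum(avg[: mid] - scfg.background)
        assert below > above

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_aligned([])


def test_landmark_csv_roundtrip(tmp_path, scfg):
    _, lms = make_spine_fixture(3, "mushroom", scfg, noise=False)
    _, stubby = make_spine_fixture(2, "stubby", scfg, noise=False)
    path = write_landmarks_csv(list(lms) + list(stubby), tmp_path / "lm.csv")
    back = read_landmarks_csv(path)
    assert len(back) == 5
    for orig, rt in zip(list(lms) + list(stubby), back):
        assert rt.spine_class == orig.spine_class
        for name, pt in orig.points().items():
            assert getattr(rt, name) == pytest.approx(pt)
    # stubby rows leave neck columns empty
    assert back[-1].neck_top is None
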