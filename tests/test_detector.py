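import numpy as np
import pytest

from exuscan.detector import (
    DetectionConfig,
    DiffSeries,
    classify_pixel,
    detect,
    is_nonconstant,
    radial_differences,
    semicircle_entrance,
    _longest_circular_run,
    _th3_rule,
)
from exuscan.errors import ConfigError, InputError
from exuscan.geometry import DirectionSpec, PixelCoord, RadialSamples, make_semicircles, sample_direction
from exuscan.image_io import BinaryMask, GrayImage

from _reference import longest_circular_run_bruteforce, naive_detect


def _samples(values):
    d = DirectionSpec(semicircle=1, j=1, phi=0.0)
    values = np.asarray(values, dtype=float)
    return RadialSamples(direction=d, radii=np.arange(len(values), dtype=float), coords=[], values=values)


class TestRadialDifferences:
    def test_constant(self):
        assert radial_differences(_samples([0.5, 0.5, 0.5])).diffs.tolist() == [0.0, 0.0]

    def test_single_subtraction(self):
        np.testing.assert_allclose(radial_differences(_samples([0.9, 0.7])).diffs, [-0.2])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(21)
        values = rng.uniform(0, 1, size=10)
        expected = [values[n] - values[n - 1] for n in range(1, 10)]
        np.testing.assert_allclose(radial_differences(_samples(values)).diffs, expected)

    def test_short_series_empty(self):
        assert len(radial_differences(_samples([0.4]))) == 0
        assert len(radial_differences(_samples([]))) == 0


class TestIsNonconstant:
    def test_qualifying_drop(self):
        assert is_nonconstant(DiffSeries(np.array([-0.02])), 0.015) is True

    def test_rises_never_qualify(self):
        assert is_nonconstant(DiffSeries(np.array([0.5, 0.2])), 1e-9) is False

    def test_boundary_is_strict(self):
        assert is_nonconstant(DiffSeries(np.array([-0.015])), 0.015) is False

    def test_empty(self):
        assert is_nonconstant(DiffSeries(np.empty(0)), 0.015) is False


class TestSemicircleEntrance:
    def test_constant_image(self, default_cfg):
        img = GrayImage(np.full((64, 64), 0.5))
        count, entrance = semicircle_entrance(img, PixelCoord(32, 32), make_semicircles(8)[0], default_cfg)
        assert count == 0 and entrance is False

    def test_th2_strictness(self):
        cfg = DetectionConfig()
        assert (3 > cfg.th2) is True
        assert (2 > cfg.th2) is False

    def test_step_edge_matches_direction_loop_oracle(self, default_cfg):
        # left half 0.2, right half 0.8; center in the bright half, 10 px
        # from the edge; the sector facing the dark side must be an entrance
        img_arr = np.full((64, 64), 0.8)
        img_arr[:, :32] = 0.2
        img = GrayImage(img_arr)
        center = PixelCoord(32, 42)
        sc_left = make_semicircles(8)[3]  # [3pi/4, pi]: points toward -x
        count, entrance = semicircle_entrance(img, center, sc_left, default_cfg)
        # oracle: walk each direction explicitly
        expected = 0
        from exuscan.geometry import make_directions

        for d in make_directions(sc_left, default_cfg.n_dirs):
            s = sample_direction(img, center, d, default_cfg.r0, default_cfg.r1, default_cfg.step)
            vals = list(s.values)
            if any(b - a < -default_cfg.th1 for a, b in zip(vals, vals[1:])):
                expected += 1
        assert count == expected
        assert entrance is True


class TestTh3Rule:
    def test_consecutive_flags_comparators(self):
        flags = np.array([1, 1, 1, 0, 0, 0, 0, 0], dtype=bool).reshape(-1, 1)
        at_least = DetectionConfig(th3=3, comparator_th3="at_least")
        strict = DetectionConfig(th3=3, comparator_th3="strict_greater")
        assert bool(_th3_rule(flags, at_least)[0]) is True
        assert bool(_th3_rule(flags, strict)[0]) is False

    def test_alternating_flags(self):
        flags = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=bool).reshape(-1, 1)
        consecutive = DetectionConfig(th3=3, require_consecutive=True)
        scattered = DetectionConfig(th3=3, require_consecutive=False)
        assert bool(_th3_rule(flags, consecutive)[0]) is False
        assert bool(_th3_rule(flags, scattered)[0]) is True

    def test_circular_wraparound(self):
        flags = np.array([1, 1, 0, 0, 0, 0, 1, 1], dtype=bool).reshape(-1, 1)
        cfg = DetectionConfig(th3=4, require_consecutive=True)
        assert bool(_th3_rule(flags, cfg)[0]) is True

    @pytest.mark.parametrize("seed", range(20))
    def test_run_length_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        flags = rng.uniform(size=8) < 0.5
        got = int(_longest_circular_run(flags.reshape(-1, 1))[0])
        assert got == longest_circular_run_bruteforce(flags.tolist())


class TestClassifyPixel:
    def test_constant_image_negative(self, default_cfg):
        img = GrayImage(np.full((64, 64), 0.5))
        v = classify_pixel(img, PixelCoord(32, 32), default_cfg)
        assert v.is_he is False
        assert v.nonconstant_counts == [0] * 8

    def test_verdict_consistency(self, default_cfg, disc_image):
        img, _ = disc_image
        v = classify_pixel(img, PixelCoord(32, 32), default_cfg)
        assert v.entrance_flags == [c > default_cfg.th2 for c in v.nonconstant_counts]
        assert v.is_he is True

    def test_out_of_bounds_center(self, default_cfg):
        with pytest.raises(InputError):
            classify_pixel(GrayImage(np.zeros((8, 8))), PixelCoord(-1, 0), default_cfg)

    def test_border_pixels_never_error(self, small_cfg):
        img = GrayImage(np.random.default_rng(0).uniform(size=(9, 9)))
        for r, c in [(0, 0), (0, 8), (8, 0), (8, 8), (0, 4), (4, 0)]:
            classify_pixel(img, PixelCoord(r, c), small_cfg)


class TestDetect:
    def test_constant_image_empty(self, default_cfg, constant_image):
        assert detect(constant_image, default_cfg).count() == 0

    def test_disc_scene_matches_reference(self, default_cfg, disc_image):
        img, inside = disc_image
        mask = detect(img, default_cfg)
        assert mask.count() > 0
        # detections form a subset of the disc interior plus a thin margin
        from scipy import ndimage

        margin = ndimage.binary_dilation(inside, iterations=3)
        assert (mask.labels.astype(bool) <= margin).all()
        ref = naive_detect(img.intensities)
        assert (mask.labels == ref).all()

    def test_th1_monotone_on_disc(self, disc_image):
        img, _ = disc_image
        loose = detect(img, DetectionConfig(th1=0.015)).labels
        tight = detect(img, DetectionConfig(th1=0.025)).labels
        assert (tight <= loose).all()

    def test_exclusion_mask_removes_pixels(self, default_cfg, disc_image):
        img, inside = disc_image
        base = detect(img, default_cfg)
        excl = BinaryMask(inside.astype(np.uint8), meaning="optic_disc")
        masked = detect(img, default_cfg, exclusion=excl)
        assert (masked.labels <= base.labels).all()
        assert (masked.labels[inside] == 0).all()

    def test_exclusion_shape_mismatch(self, default_cfg, constant_image):
        with pytest.raises(InputError):
            detect(constant_image, default_cfg, exclusion=BinaryMask(np.zeros((3, 3), dtype=np.uint8)))

    def test_detect_equals_classify_pixel(self, small_cfg):
        rng = np.random.default_rng(17)
        img = GrayImage(rng.uniform(size=(16, 16)))
        mask = detect(img, small_cfg)
        for r in range(16):
            for c in range(16):
                assert mask.labels[r, c] == classify_pixel(img, PixelCoord(r, c), small_cfg).is_he

    def test_determinism(self, default_cfg, disc_image):
        img, _ = disc_image
        a = detect(img, default_cfg).labels
        b = detect(img, default_cfg).labels
        assert (a == b).all()

    def test_fill_radius_superset(self, disc_image):
        img, _ = disc_image
        plain = detect(img, DetectionConfig()).labels
        filled = detect(img, DetectionConfig(fill_radius=True)).labels
        assert (plain <= filled).all()
        assert filled.sum() > plain.sum()


class TestSceneRecovery:
    """Pixel-level behavior on clean synthetic scenes: lesion cores are fully
    recovered and detections stay within a thin margin of true structures."""

    def test_cores_recovered_and_detections_confined(self):
        from scipy import ndimage

        from exuscan.image_io import extract_channel, normalize
        from exuscan.synthetic import SceneSpec, generate_scene

        for seed in (0, 1):
            spec = SceneSpec(
                seed=seed, size=(192, 192), n_lesions=4, lesion_radius_range=(5.0, 12.0),
                noise_sigma=0.0, n_vessels=0,
            )
            scene = generate_scene(spec)
            gray = normalize(extract_channel(scene.image, "green"))
            pred = detect(gray, DetectionConfig(), exclusion=scene.od_mask).labels.astype(bool)
            he = scene.he_mask.labels.astype(bool)
            core = ndimage.binary_erosion(he, iterations=2)
            assert pred[core].mean() >= 0.95
            structures = he | scene.od_mask.labels.astype(bool)
            dist = ndimage.distance_transform_edt(~structures)
            # no evidence can originate beyond the radial search range r1;
            # nearly all detections hug the structures much more tightly
            assert dist[pred].max() <= 25 + 1
            assert (dist[pred] <= 8).mean() >= 0.98


class TestDetectionConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"th1": 0.0},
            {"th2": 5, "n_dirs": 5},
            {"th3": 0},
            {"th3": 9},
            {"r0": 0.5},
            {"r1": 3.0},
            {"step": -1.0},
            {"comparator_th3": "median"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ConfigError):
            DetectionConfig(**kwargs)

    def test_defaults_are_reference_operating_point(self):
        cfg = DetectionConfig()
        assert (cfg.th1, cfg.th2, cfg.th3, cfg.r0, cfg.r1) == (0.015, 2, 3, 4.0, 25.0)
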