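"""Structure-dependent amplification: masks, maps, and the corrected stacks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from skimage.filters import threshold_otsu

from fpmsda import (
    BF,
    DF,
    MaskConstructionError,
    SdAMaps,
    SdAParams,
    amplify_and_build_stacks,
    build_background_mask,
    compute_amplification_map,
    compute_object_map,
    run_sda,
    subtract_initial_background,
)
from conftest import toy_stack


def brute_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Independent disc dilation: nested loops over Euclidean offsets."""
    out = np.zeros_like(mask, dtype=bool)
    n_r, n_c = mask.shape
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    for r, c in zip(*np.nonzero(mask)):
        for dy, dx in offsets:
            y, x = r + dy, c + dx
            if 0 <= y < n_r and 0 <= x < n_c:
                out[y, x] = True
    return out


class TestBackgroundMask:
    def test_two_level_disc_mask(self):
        # bright field with one dark disc: M = complement of the disc grown by s1
        n, r, s1 = 48, 5, 4
        frame = np.full((n, n), 200.0)
        yy, xx = np.indices((n, n))
        disc = (yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= r**2
        frame[disc] = 20.0
        M = build_background_mask(frame, s1_radius=s1)
        assert np.array_equal(M, ~brute_dilate(disc, s1))
        assert M.any() and not (M & disc).any()

    def test_default_radius_is_20(self):
        assert SdAParams().s1_radius == 20

    def test_constant_frame_rejected(self):
        with pytest.raises(MaskConstructionError):
            build_background_mask(np.full((16, 16), 7.0), 3)

    def test_object_filling_frame_gives_empty_mask_error(self):
        frame = np.full((24, 24), 200.0)
        frame[4:20, 4:20] = 10.0
        with pytest.raises(MaskConstructionError):
            build_background_mask(frame, s1_radius=12)

    def test_bright_object_class_swap(self):
        # sample brighter than its background: small bright blob is the object
        frame = np.full((40, 40), 30.0)
        frame[18:23, 18:23] = 220.0
        M = build_background_mask(frame, s1_radius=3)
        assert not M[20, 20]
        assert M[0, 0]

    @pytest.mark.parametrize("seed", range(20))
    def test_otsu_matches_exhaustive_intraclass_variance_search(self, seed):
        """Oracle: scan all 256 histogram cut points, minimizing the weighted
        intra-class variance, independently of skimage."""
        rng = np.random.default_rng(seed)
        frame = np.concatenate(
            [rng.normal(60, 12, 600), rng.normal(180, 20, 400)]
        ).clip(0, 255)
        hist, edges = np.histogram(frame, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2

        def intra_class_variance(t):
            w0, w1 = hist[:t].sum(), hist[t:].sum()
            if w0 == 0 or w1 == 0:
                return np.inf
            m0 = (hist[:t] * centers[:t]).sum() / w0
            m1 = (hist[t:] * centers[t:]).sum() / w1
            v0 = (hist[:t] * (centers[:t] - m0) ** 2).sum() / w0
            v1 = (hist[t:] * (centers[t:] - m1) ** 2).sum() / w1
            return (w0 * v0 + w1 * v1) / (w0 + w1)

        best = min(intra_class_variance(t) for t in range(1, 256))
        lib_threshold = threshold_otsu(frame, nbins=256)
        # the library threshold is the centre of the last below-class bin
        t_lib = int(np.searchsorted(edges, lib_threshold, side="right"))
        assert intra_class_variance(t_lib) <= best * (1 + 1e-9)


class TestInitialSubtraction:
    def test_constant_df_frame_becomes_zero(self):
        frames = [np.full((6, 6), 9.0), np.full((6, 6), 3.0)]
        stack = toy_stack(frames, [BF, DF])
        M = np.ones((6, 6), dtype=bool)
        out = subtract_initial_background(stack, M)
        assert out.role == "S2"
        assert np.all(out.frames[1] == 0)
        assert np.array_equal(out.frames[0], frames[0])  # BF passes through

    def test_manual_4x4_example(self):
        df = np.full((4, 4), 5.0)
        df[1, 2] = 9.0
        M = np.ones((4, 4), dtype=bool)
        M[1, 2] = False
        stack = toy_stack([np.full((4, 4), 7.0), df], [BF, DF])
        out = subtract_initial_background(stack, M)
        expected = np.zeros((4, 4))
        expected[1, 2] = 4.0
        assert np.array_equal(out.frames[1], expected)

    def test_output_non_negative(self):
        rng = np.random.default_rng(0)
        stack = toy_stack([rng.uniform(0, 10, (8, 8)) for _ in range(3)], [BF, DF, DF])
        out = subtract_initial_background(stack, np.ones((8, 8), dtype=bool))
        assert out.frames.min() >= 0


class TestObjectMap:
    def test_uniform_bf_sum_gives_empty_map(self):
        stack = toy_stack([np.full((10, 10), 4.0)], [BF], role="S2")
        M = np.zeros((10, 10), dtype=bool)
        M[:2] = True
        assert not compute_object_map(stack, M, s2_radius=2).any()

    def test_default_s2_radius_is_8(self):
        assert SdAParams().s2_radius == 8

    def test_dark_disc_detected_via_per_pixel_inequality_oracle(self):
        n = 40
        s = np.full((n, n), 100.0)
        yy, xx = np.indices((n, n))
        disc = (yy - 20) ** 2 + (xx - 20) ** 2 <= 36
        s[disc] = 40.0
        M = np.zeros((n, n), dtype=bool)
        M[:4] = True  # outer band
        stack = toy_stack([s], [BF], role="S2")
        s2_radius = 3
        got = compute_object_map(stack, M, s2_radius)
        # oracle: pre-dilation set = pixels strictly below the minimum BF sum
        # over M, then brute-force disc dilation
        pre = s < s[M].min()
        assert np.array_equal(pre, disc)
        assert np.array_equal(got, brute_dilate(pre, s2_radius))

    def test_zero_bf_sum_pixels_handled(self, caplog):
        s = np.full((12, 12), 50.0)
        s[6:8, 6:8] = 20.0  # genuine dark object pixels
        s[5, 5] = 0.0
        M = np.zeros((12, 12), dtype=bool)
        M[:2] = True
        stack = toy_stack([s], [BF], role="S2")
        with caplog.at_level("WARNING"):
            out = compute_object_map(stack, M, 1)
        assert "zero-valued BF-sum" in caplog.text
        assert out[5, 5]  # maximal finite reciprocal -> classed with the object


class TestAmplificationMap:
    def test_zero_df_frames_give_zero_map(self):
        stack = toy_stack([np.ones((5, 5)), np.zeros((5, 5))], [BF, DF], role="S2")
        M = np.ones((5, 5), dtype=bool)
        assert not compute_amplification_map(stack, M).any()

    def test_manual_3x3_example(self):
        half = np.array([[1, 1, 1], [1, 4, 1], [1, 1, 1]], dtype=float)
        stack = toy_stack([np.ones((3, 3)), half, half], [BF, DF, DF], role="S2")
        M = np.ones((3, 3), dtype=bool)
        M[1, 1] = False
        out = compute_amplification_map(stack, M)
        expected = np.zeros((3, 3))
        expected[1, 1] = 6.0
        assert np.array_equal(out, expected)
        assert out.min() >= 0


class TestAmplifyAndBuildStacks:
    def _maps(self, M, I_BF, I_DF):
        return SdAMaps(M=M, I_BF=I_BF, I_DF=I_DF, s1_radius=1, s2_radius=1)

    def test_full_3x3_manual_trace(self):
        s2 = np.array([[1, 1, 1], [1, 50, 1], [1, 1, 1]], dtype=float)
        I_BF = np.zeros((3, 3), dtype=bool)
        I_BF[1, 1] = True
        I_DF = np.zeros((3, 3))
        I_DF[1, 1] = 6.0
        M = ~I_BF
        stack = toy_stack([np.ones((3, 3)), s2], [BF, DF], role="S2")
        s3, s4, sbr = amplify_and_build_stacks(stack, self._maps(M, I_BF, I_DF))
        # hand trace: A(center) = 50*6 = 300; A(border) = 1; threshold = 1 + 3*0 = 1
        # S2'(center) = 300 - 1 = 299 > 0 -> S3(center) = 50; SBR = 50/1 > 1 -> S4 = S3
        expected = np.zeros((3, 3))
        expected[1, 1] = 50.0
        assert np.array_equal(s3.frames[1], expected)
        assert np.array_equal(s4.frames[1], expected)
        assert sbr[1] == pytest.approx(50.0)
        assert np.isnan(sbr[0])  # BF frame carries no SBR
        assert s3.role == "S3" and s4.role == "S4"

    def test_zero_noise_offset_only_exactness(self):
        """Compact-support signal + pure offset: S3 restores the noise-free
        frame exactly on the object support and is zero elsewhere."""
        n = 24
        clean = np.zeros((n, n))
        clean[10:14, 10:14] = [[5, 8, 7, 5]] * 4
        I_BF = np.zeros((n, n), dtype=bool)
        I_BF[8:16, 8:16] = True
        M = ~I_BF
        stack = toy_stack([np.full((n, n), 60.0), clean + 30.0], [BF, DF])
        s2 = subtract_initial_background(stack, M)
        assert np.array_equal(s2.frames[1], clean)  # offset removed exactly
        I_DF = compute_amplification_map(s2, M)
        s3, s4, sbr = amplify_and_build_stacks(s2, self._maps(M, I_BF, I_DF))
        assert np.array_equal(s3.frames[1], clean)
        assert np.isinf(sbr[1])  # zero background -> SBR treated as infinite
        assert np.array_equal(s4.frames[1], s3.frames[1])

    def test_low_sbr_frame_rescaled_to_s2_maximum(self):
        n = 12
        s2f = np.full((n, n), 10.0)
        s2f[4:7, 4:7] = 8.0  # object dimmer than the residual background
        s2f[5, 5] = 14.0  # single distinguishable peak
        I_BF = np.zeros((n, n), dtype=bool)
        I_BF[4:7, 4:7] = True
        M = ~I_BF
        I_DF = np.zeros((n, n))
        I_DF[4:7, 4:7] = 100.0
        stack = toy_stack([np.ones((n, n)), s2f], [BF, DF], role="S2")
        s3, s4, sbr = amplify_and_build_stacks(stack, self._maps(M, I_BF, I_DF))
        assert sbr[1] < 1
        nz = s4.frames[1] > 0
        assert nz.any()
        assert s4.frames[1].max() == pytest.approx(s2f.max())
        assert not np.array_equal(s4.frames[1], s3.frames[1])

    def test_all_zero_s2prime_low_sbr_frame_emits_zeros(self, caplog):
        n = 8
        s2f = np.full((n, n), 10.0)
        s2f[0, 0] = 10.5  # background mean exceeds object mean -> SBR < 1
        I_BF = np.zeros((n, n), dtype=bool)
        I_BF[3:5, 3:5] = True
        M = ~I_BF
        I_DF = np.zeros((n, n))  # no amplification -> S2' support empty
        stack = toy_stack([np.ones((n, n)), s2f], [BF, DF], role="S2")
        s2f[3:5, 3:5] = 5.0
        with caplog.at_level("WARNING"):
            s3, s4, sbr = amplify_and_build_stacks(stack, self._maps(M, I_BF, I_DF))
        assert sbr[1] < 1
        assert not s4.frames[1].any()

    @given(
        frames=hnp.arrays(
            float, (3, 16, 16), elements=st.floats(0, 1000, allow_nan=False)
        ),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_structural_invariants_on_random_stacks(self, frames, seed):
        rng = np.random.default_rng(seed)
        I_BF = np.zeros((16, 16), dtype=bool)
        I_BF[4:12, 4:12] = rng.random((8, 8)) > 0.4
        M = ~I_BF
        M[0, 0] = True  # never empty
        I_DF = rng.uniform(0, 50, (16, 16))
        stack = toy_stack(frames, [BF, DF, DF], role="S2")
        s3, s4, sbr = amplify_and_build_stacks(
            stack, SdAMaps(M=M, I_BF=I_BF, I_DF=I_DF, s1_radius=1, s2_radius=1)
        )
        for i in (1, 2):
            s2f, s3f, s4f = stack.frames[i], s3.frames[i], s4.frames[i]
            # direct reassignment: S3 is 0 or the S2 value, pixelwise
            assert np.all((s3f == 0) | (s3f == s2f))
            assert s3f.min() >= 0 and s4f.min() >= 0
            # support shrinkage
            assert not np.any((s3f > 0) & (s2f == 0))
            if sbr[i] > 1:
                assert np.array_equal(s4f, s3f)


@pytest.fixture(scope="module")
def scene():
    n = 48
    bf = np.full((n, n), 200.0)
    bf[18:30, 18:30] = 40.0
    df = np.zeros((n, n))
    df[20:28, 20:28] = 90.0
    rng = np.random.default_rng(1)
    frames = [bf, df + rng.uniform(0, 2, (n, n)), df * 0.5 + rng.uniform(0, 2, (n, n))]
    return toy_stack(frames, [BF, DF, DF])


class TestRunSda:

    def test_mask_and_object_map_disjoint(self, scene):
        _, _, maps = run_sda(scene, SdAParams(s1_radius=4, s2_radius=2))
        assert not (maps.M & maps.I_BF).any()

    def test_deterministic(self, scene):
        params = SdAParams(s1_radius=4, s2_radius=2)
        a3, a4, _ = run_sda(scene, params)
        b3, b4, _ = run_sda(scene, params)
        assert np.array_equal(a3.frames, b3.frames)
        assert np.array_equal(a4.frames, b4.frames)

    def test_background_mean_of_corrected_stacks_is_zero(self, scene):
        s3, s4, maps = run_sda(scene, SdAParams(s1_radius=4, s2_radius=2))
        for i, lab in enumerate(s3.labels):
            if lab == DF:
                assert s3.frames[i][maps.M].mean() == 0
                assert s4.frames[i][maps.M].mean() == 0
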