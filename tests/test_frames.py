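"""Luminance matching, spatial-frequency equalization and frame
dissimilarity."""

import numpy as np
import pytest

from pigeonpop import (FrameStack, compute_target_luminance,
                       frame_dissimilarity, generate_frame_pair,
                       luminance_match, spatial_frequency_match)
from pigeonpop.frames import _value_channel, radial_profile


def gray(v):
    return np.repeat(np.asarray(v, dtype=float)[:, :, None], 3, axis=2)


def noise_stack(rng, n_frames=2, size=32, fg_frac=0.25):
    frames = [gray(np.clip(rng.uniform(0.2, 0.8, (size, size)), 0, 1))
              for _ in range(n_frames)]
    mask = np.zeros((size, size), bool)
    mask[:int(size * fg_frac)] = True
    return FrameStack(frames=frames, fg_masks=[mask] * n_frames)


class TestTargetLuminance:
    def test_uniform_regions(self):
        v = np.full((8, 8), 0.2)
        v[:4] = 0.8
        mask = np.zeros((8, 8), bool)
        mask[:4] = True
        stack = FrameStack(frames=[gray(v)], fg_masks=[mask])
        assert compute_target_luminance([stack]) == pytest.approx((0.8, 0.2))

    def test_two_frames_average(self):
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        f1, f2 = np.full((4, 4), 0.1), np.full((4, 4), 0.1)
        f1[:2], f2[:2] = 0.6, 0.4
        stack = FrameStack(frames=[gray(f1), gray(f2)], fg_masks=[mask, mask])
        fg, _bg = compute_target_luminance([stack])
        assert fg == pytest.approx(0.5)

    def test_matches_pixel_loop_oracle(self, rng):
        stack = noise_stack(rng)
        fg, bg = compute_target_luminance([stack])
        fg_pix, bg_pix = [], []
        for frame, mask in zip(stack.frames, stack.fg_masks):
            v = _value_channel(frame)
            for i in range(v.shape[0]):
                for j in range(v.shape[1]):
                    (fg_pix if mask[i, j] else bg_pix).append(v[i, j])
        assert fg == pytest.approx(np.mean(fg_pix))
        assert bg == pytest.approx(np.mean(bg_pix))

    def test_empty_region_rejected(self):
        stack = FrameStack(frames=[gray(np.full((4, 4), 0.5))],
                           fg_masks=[np.zeros((4, 4), bool)])
        with pytest.raises(ValueError):
            compute_target_luminance([stack])


class TestLuminanceMatch:
    def test_hits_targets_exactly(self, rng):
        stack = noise_stack(rng)
        out = luminance_match(stack, 0.5, 0.4)
        for frame, mask in zip(out.frames, out.fg_masks):
            v = _value_channel(frame)
            assert v[mask].mean() == pytest.approx(0.5, abs=1e-9)
            assert v[~mask].mean() == pytest.approx(0.4, abs=1e-9)

    def test_idempotent(self, rng):
        stack = noise_stack(rng)
        once = luminance_match(stack, 0.5, 0.4)
        twice = luminance_match(once, 0.5, 0.4)
        for f1, f2 in zip(once.frames, twice.frames):
            assert np.allclose(f1, f2, atol=1e-12)

    def test_clipping_caps_the_mean(self, rng):
        v = np.clip(rng.normal(0.95, 0.1, (16, 16)), 0, 1)
        mask = np.ones((16, 16), bool)
        mask[8:] = False
        stack = FrameStack(frames=[gray(v)], fg_masks=[mask])
        out = luminance_match(stack, 0.99, 0.5)
        assert _value_channel(out.frames[0])[mask].mean() <= 0.99 + 1e-12


class TestSpatialFrequencyMatch:
    def test_single_frame_identity(self, rng):
        stack = noise_stack(rng, n_frames=1)
        (out,) = spatial_frequency_match([stack])
        assert np.allclose(out.frames[0], stack.frames[0], atol=1e-10)

    def test_profiles_equalized(self, rng):
        stacks = [noise_stack(rng, n_frames=2), noise_stack(rng, n_frames=2)]
        out = spatial_frequency_match(stacks)
        profiles = [radial_profile(f) for s in out for f in s.frames]
        ref = profiles[0]
        nz = ref > 1e-9
        nz[0] = False   # DC deliberately conserved per frame
        for p in profiles[1:]:
            assert np.abs(p[nz] - ref[nz]).max() / ref[nz].max() < 1e-6

    def test_phase_and_dc_preserved(self, rng):
        stack = noise_stack(rng, n_frames=3)
        (out,) = spatial_frequency_match([stack])
        for fin, fout in zip(stack.frames, out.frames):
            F_in = np.fft.fft2(_value_channel(fin))
            F_out = np.fft.fft2(_value_channel(fout))
            big = np.abs(F_in) > 1e-6
            dphi = np.angle(F_out / F_in)[big]
            assert np.abs(dphi).max() < 1e-8
            assert _value_channel(fout).mean() == pytest.approx(
                _value_channel(fin).mean(), abs=1e-12)

    def test_non_square_frames_supported(self, rng):
        frames = [gray(rng.uniform(0.2, 0.8, (24, 40))) for _ in range(2)]
        mask = np.zeros((24, 40), bool)
        mask[:8] = True
        stack = FrameStack(frames=frames, fg_masks=[mask, mask])
        (out,) = spatial_frequency_match([stack])
        p0, p1 = (radial_profile(f) for f in out.frames)
        nz = p0 > 1e-9
        nz[0] = False
        assert np.abs(p0[nz] - p1[nz]).max() / p0[nz].max() < 1e-6


class TestDissimilarity:
    def test_identical_stacks_correlate_one(self, rng):
        stack = noise_stack(rng)
        assert frame_dissimilarity(stack, stack) == pytest.approx([1.0, 1.0])

    def test_inverted_frames_anticorrelate(self, rng):
        stack = noise_stack(rng, n_frames=1)
        inv = FrameStack(frames=[1.0 - stack.frames[0]],
                         fg_masks=list(stack.fg_masks))
        assert frame_dissimilarity(stack, inv) == pytest.approx([-1.0])

    def test_independent_noise_near_zero(self, rng):
        size = 100   # 10^4 pixels
        a = FrameStack(frames=[gray(rng.uniform(0, 1, (size, size)))],
                       fg_masks=[np.ones((size, size), bool)])
        b = FrameStack(frames=[gray(rng.uniform(0, 1, (size, size)))],
                       fg_masks=[np.ones((size, size), bool)])
        assert abs(frame_dissimilarity(a, b)[0]) < 0.05

    def test_symmetry_and_bounds(self, rng):
        a, b = noise_stack(rng), noise_stack(rng)
        ab = frame_dissimilarity(a, b)
        ba = frame_dissimilarity(b, a)
        assert ab == pytest.approx(ba)
        assert np.all(np.abs(ab) <= 1.0 + 1e-12)

    def test_zero_variance_frame_is_missing(self, rng):
        flat = FrameStack(frames=[gray(np.full((8, 8), 0.5))],
                          fg_masks=[np.ones((8, 8), bool)])
        other = noise_stack(rng, n_frames=1, size=8)
        assert np.isnan(frame_dissimilarity(flat, other)[0])

    def test_frame_pair_generator_shares_background_not_foreground(self):
        a, b, mask = generate_frame_pair(32, 32, seed=0)
        sa = FrameStack(frames=[a], fg_masks=[mask])
        sb = FrameStack(frames=[b], fg_masks=[mask])
        r = frame_dissimilarity(sa, sb)[0]
        assert -1.0 < r < 1.0
        # backgrounds are the same texture; foreground means differ
        assert np.allclose(a[~mask], b[~mask])
        assert a[..., 0][mask].mean() != pytest.approx(b[..., 0][mask].mean())
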