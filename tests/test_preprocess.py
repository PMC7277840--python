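"""Preprocessing: registration, cropping, windowing, cycle detection,
frame selection."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.transform import rescale

import echoview as ev
from echoview.core import CineClip, ViewLabel, mean_uint8
from echoview.preprocess import (
    CycleDetectionError,
    ReferenceImage,
    estimate_registration,
)


def make_clip(lvef=55.0, view=ViewLabel.AP4, n=56, period=24, **kw):
    return ev.render_clip(lvef, view, "vendorA", n, seed=11,
                          cycle_period=period, **kw)


class TestRegistration:
    def ref_from(self, clip) -> ReferenceImage:
        mean = clip.frames.astype(float).mean(axis=0)
        return ReferenceImage(pixels=mean, field_of_view=19.0)

    def test_aligned_clip_gives_identity(self):
        clip = make_clip(noise_free=True)
        ref = self.ref_from(clip)
        scale, shift = estimate_registration(clip, ref)
        assert scale == pytest.approx(1.0, abs=0.02)
        assert np.all(np.abs(shift) <= 1.0)

    def test_known_shift_recovered(self):
        clip = make_clip(noise_free=True)
        ref = self.ref_from(clip)
        dx, dy = 9, -6
        shifted = clip.with_frames(np.roll(clip.frames, (dy, dx), axis=(1, 2)))
        scale, shift = estimate_registration(shifted, ref)
        # registration must undo the shift: (row, col) estimate = -(dy, dx)
        assert shift[0] == pytest.approx(-dy, abs=1.0)
        assert shift[1] == pytest.approx(-dx, abs=1.0)

    def test_known_scale_recovered(self):
        """A clip whose content is shrunk by 1/1.2 registers back with the
        reciprocal scale."""
        clip = make_clip(noise_free=True)
        ref = self.ref_from(clip)
        h = clip.shape[0]
        small = np.zeros_like(clip.frames)
        for t, f in enumerate(clip.frames):
            sm = rescale(f.astype(float), 1 / 1.2, preserve_range=True)
            small[t, :sm.shape[0], :sm.shape[1]] = sm.astype(np.uint8)
        scaled = clip.with_frames(small)
        scale, _ = estimate_registration(scaled, ref)
        assert scale == pytest.approx(1.2, rel=0.02)

    def test_applied_transform_realigns_content(self):
        clip = make_clip(noise_free=True)
        ref = self.ref_from(clip)
        shifted = clip.with_frames(np.roll(clip.frames, (8, -5), axis=(1, 2)))
        out = ev.register_to_reference(shifted, ref)
        assert out.shape == ref.pixels.shape
        assert out.pixel_spacing == pytest.approx(clip.pixel_spacing, rel=0.05)
        mean = out.frames.astype(float).mean(axis=0)
        a = mean.ravel() - mean.mean()
        b = ref.pixels.ravel() - ref.pixels.mean()
        ncc = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert ncc > 0.98

    def test_unregistrable_clip_raises(self):
        noise = (np.random.default_rng(0).integers(0, 255, (4, 64, 64))
                 .astype(np.uint8))
        clip = CineClip(frames=noise, pixel_spacing=0.1,
                        frame_times=np.arange(4.0))
        ref = ReferenceImage(pixels=np.zeros((64, 64)) + 1.0, field_of_view=10)
        with pytest.raises(ev.RegistrationError):
            ev.register_to_reference(clip, ref, min_ncc=0.99)


class TestCropRescale:
    def test_defaults_give_120px_and_spacing(self):
        clip = make_clip()
        out = ev.crop_rescale(clip)
        assert out.shape == (120, 120)
        assert out.pixel_spacing == pytest.approx(18.07 / 120)

    def test_identity_when_fov_matches_extent(self, rng):
        frames = rng.integers(0, 255, (5, 80, 80)).astype(np.uint8)
        clip = CineClip(frames=frames, pixel_spacing=0.2,
                        frame_times=np.arange(5.0))
        out = ev.crop_rescale(clip, fov_cm=16.0, size_px=80)  # 16/0.2 = 80 px
        assert np.array_equal(out.frames, clip.frames)

    def test_constant_input_stays_constant(self):
        frames = np.full((4, 100, 100), 77, dtype=np.uint8)
        clip = CineClip(frames=frames, pixel_spacing=0.2,
                        frame_times=np.arange(4.0))
        out = ev.crop_rescale(clip, fov_cm=16.0, size_px=60)
        assert np.all(out.frames == 77)

    def test_excessive_fov_rejected(self):
        clip = make_clip()
        with pytest.raises(ValueError, match="exceeds"):
            ev.crop_rescale(clip, fov_cm=60.0)


class TestMaskMetadata:
    def test_burned_pixels_removed(self, one_study):
        clip = one_study.clips[ViewLabel.AP3]  # has burned-in metadata
        clean = ev.mask_metadata(clip)
        margin = 14
        border = np.zeros(clip.shape, dtype=bool)
        border[:margin], border[-margin:] = True, True
        border[:, :margin], border[:, -margin:] = True, True
        from echoview.synthetic import fan_mask
        outside = border & ~fan_mask(clip.shape, half_angle_deg=50.0,
                                     r_min_frac=0.0, r_max_frac=1.0)
        assert np.all(clean.frames[:, outside] == 0)

    def test_identity_window_full_fan(self, rng):
        frames = rng.integers(0, 255, (3, 40, 40)).astype(np.uint8)
        clip = CineClip(frames=frames, pixel_spacing=0.1,
                        frame_times=np.arange(3.0))
        out = ev.mask_metadata(clip, window=(0.0, 255.0),
                               fan=np.ones((40, 40), dtype=bool))
        assert np.array_equal(out.frames, clip.frames)

    def test_zero_clip_stays_zero(self):
        clip = CineClip(frames=np.zeros((3, 40, 40), np.uint8),
                        pixel_spacing=0.1, frame_times=np.arange(3.0))
        assert np.all(ev.mask_metadata(clip).frames == 0)

    def test_empty_window_rejected(self):
        clip = CineClip(frames=np.zeros((3, 40, 40), np.uint8),
                        pixel_spacing=0.1, frame_times=np.arange(3.0))
        with pytest.raises(ValueError, match="window"):
            ev.mask_metadata(clip, window=(100.0, 100.0))


class TestCycleDetection:
    @pytest.mark.parametrize("period", [20, 24, 30, 36])
    def test_recovers_ground_truth_period(self, period):
        clip = make_clip(n=3 * period, period=period)
        detected, start = ev.detect_cycle(clip)
        assert abs(detected - period) <= 1
        assert 0 <= start < clip.n_frames

    def test_constant_clip_raises(self):
        clip = CineClip(frames=np.full((60, 32, 32), 9, np.uint8),
                        pixel_spacing=0.1, frame_times=np.arange(60.0))
        with pytest.raises(CycleDetectionError, match="override"):
            ev.detect_cycle(clip)

    def test_override_returned_verbatim(self):
        clip = CineClip(frames=np.zeros((60, 32, 32), np.uint8),
                        pixel_spacing=0.1, frame_times=np.arange(60.0))
        assert ev.detect_cycle(clip, override=(23, 4)) == (23, 4)


class TestSelectFrames:
    def test_closed_form_indices_period30(self):
        clip = make_clip(n=64, period=30)
        fs = ev.select_frames(clip, period=30, start=0, k=10)
        assert fs.source_indices.tolist() == [0, 3, 6, 9, 12, 15, 18, 21, 24, 27]

    def test_k_equals_period_is_identity(self):
        clip = make_clip(n=48, period=20)
        fs = ev.select_frames(clip, period=10, start=0, k=10)
        assert fs.source_indices.tolist() == list(range(10))

    def test_identical_frames_average_to_themselves(self):
        frames = np.full((30, 16, 16), 123, np.uint8)
        clip = CineClip(frames=frames, pixel_spacing=0.1,
                        frame_times=np.arange(30.0))
        fs = ev.select_frames(clip, period=30, start=0, k=10)
        assert np.all(fs.averaged == 123)

    def test_k_larger_than_period_rejected(self):
        clip = make_clip()
        with pytest.raises(ValueError, match="period"):
            ev.select_frames(clip, period=8, start=0, k=10)

    @given(period=st.integers(10, 40), k=st.integers(1, 10),
           start=st.integers(0, 15))
    @settings(max_examples=60, deadline=None)
    def test_indices_lie_within_one_cycle(self, period, k, start):
        idx = start + (np.arange(k) * period) // k
        assert idx[0] == start
        assert np.all(idx < start + period)
        assert np.all(np.diff(idx) >= 1)

    def test_average_invariant_to_frame_order(self, rng):
        frames = rng.integers(0, 255, (10, 8, 8)).astype(np.uint8)
        perm = rng.permutation(10)
        assert np.array_equal(mean_uint8(frames), mean_uint8(frames[perm]))


def test_preprocess_clip_deterministic(one_study):
    clip = one_study.clips[ViewLabel.PSAX]
    a = ev.preprocess_clip(clip)
    b = ev.preprocess_clip(clip)
    assert np.array_equal(a.frames, b.frames)
    assert np.array_equal(a.averaged, b.averaged)
    assert a.source_indices.tolist() == b.source_indices.tolist()
    assert a.frames.shape == (10, 120, 120)
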