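"""Low-level feature equalization of stimulus frames.

Frames are compared in HSV space and all transformations act on the value
(V) channel only, leaving hue and saturation untouched:

* luminance matching: the mean V of the subject (foreground mask) and of
  the background are shifted additively to common target means, computed
  across all frames of all reference (pigeon) videos;
* spatial-frequency matching: each frame's FFT amplitude is rescaled per
  radial-frequency annulus so that its rotationally averaged amplitude
  profile equals the grand-average profile, with phases untouched, so the
  orientation content of each frame is preserved.  The DC component of each
  frame is left unchanged (luminance is handled by the step above).

Frame-by-frame dissimilarity between a video and its control is the Pearson
correlation of corresponding V channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv


@dataclass
class FrameStack:
    """An ordered list of H x W x 3 color frames in [0, 1] with aligned
    boolean foreground (subject) masks."""

    frames: list = field(default_factory=list)
    fg_masks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.fg_masks):
            raise ValueError("frames and fg_masks must have equal length")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("all frames must share one shape")
        for f, m in zip(self.frames, self.fg_masks):
            if m.shape != f.shape[:2]:
                raise ValueError("mask shape must match frame shape")

    def __len__(self) -> int:
        return len(self.frames)


def _value_channel(frame: np.ndarray) -> np.ndarray:
    return rgb_to_hsv(frame)[..., 2]


def compute_target_luminance(pigeon_stacks: list[FrameStack]) -> tuple[float, float]:
    """Mean V over all foreground pixels and all background pixels across
    every frame of the reference stacks."""
    fg_vals, bg_vals = [], []
    for stack in pigeon_stacks:
        for frame, mask in zip(stack.frames, stack.fg_masks):
            v = _value_channel(frame)
            fg_vals.append(v[mask])
            bg_vals.append(v[~mask])
    fg = np.concatenate(fg_vals) if fg_vals else np.array([])
    bg = np.concatenate(bg_vals) if bg_vals else np.array([])
    if fg.size == 0 or bg.size == 0:
        raise ValueError("empty foreground or background region")
    return float(fg.mean()), float(bg.mean())


def luminance_match(stack: FrameStack, fg_mean: float, bg_mean: float) -> FrameStack:
    """Shift each frame's V channel additively, per mask region, so the
    masked means equal the targets exactly (before clipping to [0, 1])."""
    if not (0.0 <= fg_mean <= 1.0 and 0.0 <= bg_mean <= 1.0):
        raise ValueError("target means must be in [0, 1]")
    out = []
    for frame, mask in zip(stack.frames, stack.fg_masks):
        hsv = rgb_to_hsv(frame)
        v = hsv[..., 2].copy()
        if mask.any():
            v[mask] += fg_mean - v[mask].mean()
        if (~mask).any():
            v[~mask] += bg_mean - v[~mask].mean()
        hsv[..., 2] = np.clip(v, 0.0, 1.0)
        out.append(hsv_to_rgb(hsv))
    return FrameStack(frames=out, fg_masks=[m.copy() for m in stack.fg_masks])


def _radial_bins(shape: tuple[int, int]) -> tuple[np.ndarray, int]:
    """Annulus index per FFT grid cell, from normalized frequency radius.

    Radius is in cycles/pixel (so non-square frames are handled uniformly);
    bin 0 is reserved for the DC component alone.
    """
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    r = np.sqrt(fy * fy + fx * fx)
    n_bins = min(h, w) // 2
    idx = np.minimum((r / 0.5 * n_bins).astype(int) + 1, n_bins + 1)
    idx[0, 0] = 0
    return idx, n_bins + 2


def _amplitude_profile(amp: np.ndarray, idx: np.ndarray, n_bins: int) -> np.ndarray:
    sums = np.bincount(idx.ravel(), weights=amp.ravel(), minlength=n_bins)
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        return sums / np.maximum(counts, 1)


def spatial_frequency_match(stacks: list[FrameStack]) -> list[FrameStack]:
    """Equalize the rotationally averaged FFT amplitude profile of every
    frame (value channel) to the grand-average profile.

    Phase spectra, hence the orientation content of each frame, are left
    untouched, and so is each frame's DC component.  Output V values are
    not clipped, so re-computed profiles match the target to numerical
    precision; clip at export time if needed.
    """
    all_frames = [f for s in stacks for f in s.frames]
    if len(all_frames) < 1:
        raise ValueError("need at least one frame")
    shape = all_frames[0].shape[:2]
    idx, n_bins = _radial_bins(shape)

    ffts, profiles = [], []
    for stack in stacks:
        for frame in stack.frames:
            f = np.fft.fft2(_value_channel(frame))
            ffts.append(f)
            profiles.append(_amplitude_profile(np.abs(f), idx, n_bins))
    target = np.mean(profiles, axis=0)

    out_stacks = []
    k = 0
    for stack in stacks:
        new_frames = []
        for frame in stack.frames:
            f, prof = ffts[k], profiles[k]
            k += 1
            gain = np.ones(n_bins)
            nz = prof > 1e-12
            gain[nz] = target[nz] / prof[nz]
            gain[0] = 1.0            # DC conserved per frame
            v_new = np.fft.ifft2(f * gain[idx]).real
            hsv = rgb_to_hsv(frame)
            hsv[..., 2] = v_new
            new_frames.append(hsv_to_rgb(hsv))
        out_stacks.append(FrameStack(frames=new_frames,
                                     fg_masks=[m.copy() for m in stack.fg_masks]))
    return out_stacks


def radial_profile(frame: np.ndarray) -> np.ndarray:
    """Rotationally averaged FFT amplitude profile of a frame's V channel
    (diagnostic; bin 0 is the DC component)."""
    idx, n_bins = _radial_bins(frame.shape[:2])
    amp = np.abs(np.fft.fft2(_value_channel(frame)))
    return _amplitude_profile(amp, idx, n_bins)


def frame_dissimilarity(stack_a: FrameStack, stack_b: FrameStack) -> np.ndarray:
    """Pearson correlation between corresponding frames' V channels.

    One value per frame index; a zero-variance frame yields NaN (undefined
    correlation, reported as missing).
    """
    if len(stack_a) != len(stack_b):
        raise ValueError("stacks must have equal frame counts")
    out = np.empty(len(stack_a))
    for i, (fa, fb) in enumerate(zip(stack_a.frames, stack_b.frames)):
        if fa.shape != fb.shape:
            raise ValueError("frame shapes must match")
        va = _value_channel(fa).ravel()
        vb = _value_channel(fb).ravel()
        if va.std() == 0 or vb.std() == 0:
            out[i] = np.nan
        else:
            out[i] = float(np.corrcoef(va, vb)[0, 1])
    return out
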