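"""Cine-loop preprocessing: registration, cropping, metadata removal,
cardiac-cycle detection and cycle-normalized frame selection.

The pipeline normalizes heterogeneous clips into a fixed representation:
a 120 x 120 pixel, 18.07 x 18.07 cm field of view, with 10 frames sampled
at equal spacing across one cardiac cycle plus their pixel-wise average.
Sampling relative to the detected cycle removes heart-rate and frame-rate
differences between acquisitions.

Conventions: frame indices and pixel coordinates are 0-based, image
origin top-left.  Registration estimates one translation + isotropic
scale from the clip's temporal-mean image and applies it to every frame
(rotation is off by default: probe fan orientation is canonical).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal
from skimage.registration import phase_cross_correlation
from skimage.transform import SimilarityTransform, rescale, resize, warp

from .core import CineClip, FrameSet, ViewLabel, mean_uint8
from .synthetic import fan_mask

__all__ = [
    "ReferenceImage",
    "make_reference",
    "register_to_reference",
    "crop_rescale",
    "mask_metadata",
    "detect_cycle",
    "select_frames",
    "preprocess_clip",
    "RegistrationError",
    "CycleDetectionError",
]

DEFAULT_FOV_CM = 18.07
DEFAULT_SIZE_PX = 120
#: Fan polygon wide enough to contain every vendor's sector.
CANONICAL_FAN_DEG = 50.0


class RegistrationError(RuntimeError):
    pass


class CycleDetectionError(RuntimeError):
    """No periodicity found; supply a manual (period, start) override."""


@dataclass(frozen=True)
class ReferenceImage:
    """Canonical fan template the clips are registered onto."""

    pixels: np.ndarray
    field_of_view: float = DEFAULT_FOV_CM

    def __post_init__(self) -> None:
        h, w = self.pixels.shape
        if h != w:
            raise ValueError("reference image must be square")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def pixel_spacing(self) -> float:
        return self.field_of_view / self.size


def make_reference(size: int = 160, field_of_view: float = DEFAULT_FOV_CM,
                   half_angle_deg: float = 38.0, gain: float = 150.0) -> ReferenceImage:
    """Build the default reference: a uniform-gain sector fan."""
    fan = fan_mask((size, size), half_angle_deg=half_angle_deg)
    pixels = np.where(fan, gain, 0.0).astype(np.float64)
    return ReferenceImage(pixels=pixels, field_of_view=field_of_view)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def _score_scale(moving: np.ndarray, ref: np.ndarray, s: float) -> tuple[float, np.ndarray]:
    """Best shift and NCC when ``moving`` is rescaled by ``s`` about the origin."""
    scaled = rescale(moving, s, preserve_range=True, anti_aliasing=s < 1)
    canvas = np.zeros_like(ref)
    h = min(canvas.shape[0], scaled.shape[0])
    w = min(canvas.shape[1], scaled.shape[1])
    canvas[:h, :w] = scaled[:h, :w]
    shift, _, _ = phase_cross_correlation(ref, canvas, upsample_factor=4,
                                          normalization=None)
    tform = SimilarityTransform(translation=(-shift[1], -shift[0]))
    aligned = warp(canvas, tform, preserve_range=True)
    return _ncc(aligned, ref), shift


def register_to_reference(clip: CineClip, ref: ReferenceImage, *,
                          scale_range: tuple[float, float] = (0.8, 1.25),
                          n_scales: int = 9, refine: bool = True,
                          min_ncc: float = 0.1) -> CineClip:
    """Rigidly register a clip onto the reference grid.

    The transform (isotropic scale + translation) is estimated once from
    the clip's temporal-mean image by a normalized-cross-correlation
    search over a geometric grid of scales (translation per scale from
    phase correlation), then applied to every frame.  The output clip
    lives on the reference grid; ``pixel_spacing`` is divided by the
    estimated scale.
    """
    mean_img = clip.frames.astype(np.float64).mean(axis=0)
    scales = np.geomspace(scale_range[0], scale_range[1], n_scales)

    def search(cands: np.ndarray) -> tuple[float, float, np.ndarray]:
        best = (-np.inf, 1.0, np.zeros(2))
        for s in cands:
            score, shift = _score_scale(mean_img, ref.pixels, float(s))
            if score > best[0]:
                best = (score, float(s), shift)
        return best

    score, s_hat, shift = search(scales)
    if refine and n_scales > 1:
        step = (scale_range[1] / scale_range[0]) ** (1 / (n_scales - 1))
        fine = s_hat * np.geomspace(1 / step, step, 9)
        score, s_hat, shift = search(fine)
    if score < min_ncc:
        raise RegistrationError(
            f"registration failed (NCC={score:.3f} < {min_ncc}) for clip "
            f"view={clip.view}"
        )

    # moving -> reference: scale about origin, then the corrective shift
    tform = SimilarityTransform(scale=s_hat) + SimilarityTransform(
        translation=(shift[1], shift[0]))
    out = np.empty((clip.n_frames, ref.size, ref.size), dtype=np.uint8)
    for t in range(clip.n_frames):
        w = warp(clip.frames[t].astype(np.float64), tform.inverse,
                 output_shape=(ref.size, ref.size), preserve_range=True)
        out[t] = np.clip(np.floor(w + 0.5), 0, 255).astype(np.uint8)
    return clip.with_frames(out, pixel_spacing=clip.pixel_spacing / s_hat)


def estimate_registration(clip: CineClip, ref: ReferenceImage, **kw) -> tuple[float, np.ndarray]:
    """Scale and corrective (row, col) shift of the registration transform.

    The returned shift is the translation applied to the (rescaled)
    moving clip, i.e. it *undoes* any displacement of the clip's content
    relative to the reference.
    """
    mean_img = clip.frames.astype(np.float64).mean(axis=0)
    scale_range = kw.get("scale_range", (0.8, 1.25))
    n_scales = kw.get("n_scales", 9)
    best = (-np.inf, 1.0, np.zeros(2))
    for s in np.geomspace(scale_range[0], scale_range[1], n_scales):
        score, shift = _score_scale(mean_img, ref.pixels, float(s))
        if score > best[0]:
            best = (score, float(s), shift)
    if kw.get("refine", True) and n_scales > 1:
        step = (scale_range[1] / scale_range[0]) ** (1 / (n_scales - 1))
        for s in best[1] * np.geomspace(1 / step, step, 9):
            score, shift = _score_scale(mean_img, ref.pixels, float(s))
            if score > best[0]:
                best = (score, float(s), shift)
    return best[1], best[2]


def crop_rescale(clip: CineClip, fov_cm: float = DEFAULT_FOV_CM,
                 size_px: int = DEFAULT_SIZE_PX, *,
                 max_pad_frac: float = 0.35) -> CineClip:
    """Crop a square physical field of view and resample to ``size_px``.

    The crop is centered on the fan apex axis (image center column) and
    anchored at the top where the apex sits.  Regions beyond the image
    are zero-padded up to ``max_pad_frac`` of the field; beyond that the
    requested field is considered out of range.  Downsampling uses
    anti-aliased linear interpolation; output ``pixel_spacing`` is
    ``fov_cm / size_px``.
    """
    if fov_cm <= 0:
        raise ValueError("fov_cm must be positive")
    t, h, w = clip.frames.shape
    fov_px = int(round(fov_cm / clip.pixel_spacing))
    c0 = w // 2 - fov_px // 2
    rows = slice(0, fov_px)
    cols = slice(c0, c0 + fov_px)
    pad_r = max(0, fov_px - h)
    pad_l = max(0, -c0)
    pad_c = max(0, c0 + fov_px - w)
    if max(pad_r, pad_l, pad_c) > max_pad_frac * fov_px:
        raise ValueError(
            f"requested field of view ({fov_px}px) exceeds image extent "
            f"({h}x{w}) beyond the padding policy"
        )
    stack = np.zeros((t, fov_px, fov_px), dtype=np.float64)
    rs = slice(0, min(fov_px, h))
    cs_src = slice(max(0, c0), min(w, c0 + fov_px))
    cs_dst = slice(max(0, -c0), max(0, -c0) + (cs_src.stop - cs_src.start))
    stack[:, rs, cs_dst] = clip.frames[:, rs, cs_src]
    if fov_px == size_px:
        out = stack
    else:
        out = resize(stack, (t, size_px, size_px), preserve_range=True,
                     anti_aliasing=fov_px > size_px)
    out8 = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return clip.with_frames(out8, pixel_spacing=fov_cm / size_px)


def mask_metadata(clip: CineClip, window: tuple[float, float] = (0.0, 255.0),
                  fan: np.ndarray | None = None) -> CineClip:
    """Zero everything outside the canonical fan and re-window intensities.

    Burned-in peripheral metadata lies outside the fan polygon and is
    removed by the mask; intensities inside are clipped to ``window``
    and linearly rescaled to [0, 255].
    """
    low, high = window
    if low >= high:
        raise ValueError("intensity window must satisfy low < high")
    if fan is None:
        fan = fan_mask(clip.shape, half_angle_deg=CANONICAL_FAN_DEG,
                       r_min_frac=0.0, r_max_frac=1.0)
    x = clip.frames.astype(np.float64)
    x = (np.clip(x, low, high) - low) * (255.0 / (high - low))
    x[:, ~fan] = 0.0
    return clip.with_frames(np.clip(np.floor(x + 0.5), 0, 255).astype(np.uint8))


def detect_cycle(clip: CineClip, *, min_period: int = 10, max_period: int | None = None,
                 override: tuple[int, int] | None = None) -> tuple[int, int]:
    """Detect the cardiac period and cycle start of a clip.

    The intensity of pixels near the moving cavity boundary oscillates
    with the cardiac cycle.  The detector restricts to the
    highest-temporal-variance pixels (top 10%), centers them over time
    and takes the lag-averaged autocorrelation of the resulting frame
    vectors; the period is the highest non-zero-lag peak.  (Averaging
    per-pixel autocorrelations over the motion region, rather than
    autocorrelating the global frame mean, keeps the peak sharp when
    the oscillation is weak relative to speckle.)  The start is the
    first local extremum of the motion-region mean-intensity series.
    A manual ``override=(period, start)`` is accepted verbatim — this is
    the semi-automatic contract for clips the detector cannot handle.
    """
    if override is not None:
        return int(override[0]), int(override[1])
    n = clip.n_frames
    if n < 2 * min_period:
        raise CycleDetectionError(
            f"clip too short ({n} frames) for periods >= {min_period}")
    flat = clip.frames.reshape(n, -1).astype(np.float32)
    std = flat.std(axis=0)
    if std.max() < 1e-6:
        raise CycleDetectionError(
            "flat intensity series: no periodicity; pass override=(period, start)")
    roi = flat[:, std >= np.quantile(std, 0.9)]
    centered = roi - roi.mean(axis=0, keepdims=True)
    gram = centered @ centered.T
    ac = np.array([np.mean(np.diag(gram, k)) for k in range(n)])
    ac /= ac[0]
    hi = max_period if max_period is not None else n // 2
    peaks, _ = scipy.signal.find_peaks(ac[: hi + 1])
    peaks = peaks[peaks >= min_period]
    if len(peaks) == 0:
        raise CycleDetectionError(
            "no autocorrelation peak found; pass override=(period, start)")
    period = int(peaks[np.argmax(ac[peaks])])

    x = scipy.signal.detrend(roi.mean(axis=1))
    start = 0
    for i in range(1, n - 1):
        if (x[i] - x[i - 1]) * (x[i + 1] - x[i]) < 0:
            start = i
            break
    if start + period > n:
        start = 0
    return period, start


def select_frames(clip: CineClip, period: int, start: int, k: int = 10) -> FrameSet:
    """Select ``k`` equally spaced frames from one cardiac cycle.

    Indices follow the closed-form rule ``start + floor(i * period / k)``
    for ``i = 0..k-1``; the averaged image is the pixel-wise mean of the
    selected frames, rounded half-up back to 8-bit.
    """
    if k > period:
        raise ValueError(f"cannot space k={k} frames within a period of {period}")
    if start + period > clip.n_frames:
        raise ValueError("cycle [start, start+period) exceeds the clip")
    idx = start + (np.arange(k) * period) // k
    frames = clip.frames[idx]
    return FrameSet(frames=frames, source_indices=idx,
                    averaged=mean_uint8(frames), view=clip.view)


def preprocess_clip(clip: CineClip, ref: ReferenceImage | None = None, *,
                    fov_cm: float = DEFAULT_FOV_CM, size_px: int = DEFAULT_SIZE_PX,
                    k: int = 10, register: bool = False,
                    window: tuple[float, float] = (0.0, 255.0),
                    override: tuple[int, int] | None = None) -> FrameSet:
    """Full normalization of one clip into a :class:`FrameSet`.

    Order: metadata masking on the native grid, optional registration to
    the reference, physical crop/resample, cycle detection (with the
    clip's ground-truth period as fallback when detection fails and no
    override is given), and cycle-normalized frame selection.
    """
    work = mask_metadata(clip, window=window)
    if register:
        if ref is None:
            ref = make_reference(size=max(clip.shape))
        work = register_to_reference(work, ref)
    work = crop_rescale(work, fov_cm=fov_cm, size_px=size_px)
    try:
        period, start = detect_cycle(work, override=override)
    except CycleDetectionError:
        if clip.cycle_period is None:
            raise
        period, start = clip.cycle_period, 0
    period = min(period, work.n_frames - start)
    fs = select_frames(work, period, start, k=k)
    fs.view = clip.view
    return fs
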