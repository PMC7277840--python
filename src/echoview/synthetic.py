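"""Synthetic echocardiographic cine-loop generator.

Real echocardiographic studies are short ultrasound videos of the heart
acquired from five standard probe positions.  This module renders a
stylized but statistically structured stand-in for such data:

* a sector-fan field of view with burned-in peripheral metadata,
* view-specific chamber geometry (different cavity counts and layouts so
  the five views are visually distinguishable),
* periodic cardiac motion whose fractional cavity-area change encodes the
  patient's left-ventricular ejection fraction (LVEF),
* multiplicative Rayleigh speckle, the standard first-order model of
  ultrasound texture,
* vendor-to-vendor variation in fan angle, imaging depth and mean gain.

The LVEF -> motion mapping is linear: the end-diastolic to end-systolic
fractional area change of the cavities is ``0.01 * LVEF``, attenuated per
view (apical views carry the full longitudinal signal; parasternal views
carry a reduced one).  This keeps the view-classification task learnable
and makes a wrong-view clip a *biased* LVEF signal, which is what the
label-noise experiment probes.

Nothing here attempts physical wave simulation; the target is the
statistical structure the downstream pipeline assumes.
"""

from __future__ import annotations

import math
from collections.abc import Iterator

import numpy as np

from .core import (
    STUDY_STRATA,
    VIEW_ORDER,
    CineClip,
    CohortSpec,
    EchoStudy,
    ViewLabel,
)

__all__ = [
    "VendorStyle",
    "VENDOR_STYLES",
    "fan_mask",
    "chamber_mask",
    "fractional_area_change",
    "render_clip",
    "burn_metadata",
    "make_cohort",
    "iter_cohort",
    "paper_cohort_spec",
]

#: End-diastolic -> end-systolic fractional area change per unit LVEF (%).
FAC_PER_LVEF = 0.01

#: Per-view attenuation of the LVEF-driven motion amplitude.  Apical views
#: image the long axis and carry the full signal; the parasternal views
#: see a different cross-section with reduced apparent area change.
VIEW_MOTION_FACTOR: dict[ViewLabel, float] = {
    ViewLabel.AP2: 1.0,
    ViewLabel.AP3: 1.0,
    ViewLabel.AP4: 1.0,
    ViewLabel.PLAX: 0.7,
    ViewLabel.PSAX: 0.5,
}

#: Standard deviation (LVEF points) of the per-patient, per-view apparent-EF
#: measurement error.  AP4, the conventional EF view, is the most faithful;
#: the parasternal cross-sections constrain EF only loosely.
APPARENT_LVEF_SIGMA: dict[ViewLabel, float] = {
    ViewLabel.AP4: 1.5,
    ViewLabel.AP2: 5.0,
    ViewLabel.AP3: 5.0,
    ViewLabel.PLAX: 9.0,
    ViewLabel.PSAX: 11.0,
}

DEFAULT_IMAGE_SIZE = 160


class VendorStyle:
    """Acquisition style of one ultrasound vendor.

    Parameters are in physical/display units: fan half-angle in degrees,
    imaging depth in cm (sets the pixel spacing for a fixed image size),
    mean tissue gain in 8-bit intensity, and the baseline cardiac period
    in frames per cycle.
    """

    def __init__(self, name: str, half_angle_deg: float, depth_cm: float,
                 gain: float, base_period: int):
        self.name = name
        self.half_angle_deg = half_angle_deg
        self.depth_cm = depth_cm
        self.gain = gain
        self.base_period = base_period

    def __repr__(self) -> str:  # pragma: no cover
        return f"VendorStyle({self.name!r})"


VENDOR_STYLES: dict[str, VendorStyle] = {
    "vendorA": VendorStyle("vendorA", half_angle_deg=38.0, depth_cm=19.0,
                           gain=170.0, base_period=24),
    "vendorB": VendorStyle("vendorB", half_angle_deg=33.0, depth_cm=21.0,
                           gain=145.0, base_period=34),
    "vendorC": VendorStyle("vendorC", half_angle_deg=42.0, depth_cm=18.0,
                           gain=190.0, base_period=28),
}


def fan_mask(shape: tuple[int, int], half_angle_deg: float = 38.0,
             apex: tuple[float, float] | None = None,
             r_min_frac: float = 0.04, r_max_frac: float = 0.94) -> np.ndarray:
    """Boolean sector-fan mask with the apex near the top-center.

    The fan opens downward from the apex, spanning ``+/- half_angle_deg``
    around the vertical, between radii ``r_min_frac`` and ``r_max_frac``
    of the image height.
    """
    h, w = shape
    if apex is None:
        apex = (2.0, w / 2.0)
    rows, cols = np.mgrid[0:h, 0:w]
    dy = rows - apex[0]
    dx = cols - apex[1]
    r = np.hypot(dx, dy)
    # angle from the downward vertical
    ang = np.degrees(np.arctan2(np.abs(dx), np.maximum(dy, 1e-9)))
    return (dy > 0) & (ang <= half_angle_deg) & (r >= r_min_frac * h) & (r <= r_max_frac * h)


def _ellipse(rows: np.ndarray, cols: np.ndarray, cy: float, cx: float,
             ry: float, rx: float) -> np.ndarray:
    return ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0


#: Per-view linear size factors equalizing end-diastolic total cavity
#: area across views (one heart, different cross-sections): without them
#: a regressor could read the view off aggregate dark-area statistics.
_AREA_NORM: dict[ViewLabel, float] = {
    ViewLabel.PLAX: 0.9661,
    ViewLabel.PSAX: 1.0863,
    ViewLabel.AP3: 1.0328,
    ViewLabel.AP4: 0.9195,
    ViewLabel.AP2: 1.0202,
}


def chamber_mask(view: ViewLabel, shape: tuple[int, int], scale: float = 1.0) -> np.ndarray:
    """Noise-free cavity (blood-pool) mask of one view at motion phase ``scale``.

    ``scale`` multiplies every cavity's linear dimensions, so cavity area
    scales with ``scale**2``; ``scale=1`` is end-diastole.  Layouts are
    stylized: PLAX shows two stacked elongated cavities, PSAX an annular
    cavity, and the apical views 2/3/4 elliptical cavities fanning from
    the apex.  All views share the same end-diastolic total cavity area.
    """
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    u = h / 160.0  # geometry is authored at 160 px and rescaled
    s = scale * _AREA_NORM[view]
    m = np.zeros(shape, dtype=bool)
    if view is ViewLabel.PLAX:
        m |= _ellipse(rows, cols, 0.42 * h, 0.40 * w, 30 * u * s, 18 * u * s)
        m |= _ellipse(rows, cols, 0.72 * h, 0.58 * w, 16 * u * s, 22 * u * s)
    elif view is ViewLabel.PSAX:
        r = np.hypot(rows - 0.52 * h, cols - 0.50 * w)
        m |= (r <= 30 * u * s) & (r >= 14 * u * s)
    elif view is ViewLabel.AP2:
        m |= _ellipse(rows, cols, 0.38 * h, 0.50 * w, 34 * u * s, 17 * u * s)
        m |= _ellipse(rows, cols, 0.76 * h, 0.50 * w, 15 * u * s, 15 * u * s)
    elif view is ViewLabel.AP3:
        m |= _ellipse(rows, cols, 0.38 * h, 0.42 * w, 32 * u * s, 15 * u * s)
        m |= _ellipse(rows, cols, 0.74 * h, 0.40 * w, 14 * u * s, 13 * u * s)
        m |= _ellipse(rows, cols, 0.62 * h, 0.70 * w, 12 * u * s, 10 * u * s)
    elif view is ViewLabel.AP4:
        m |= _ellipse(rows, cols, 0.38 * h, 0.36 * w, 30 * u * s, 14 * u * s)
        m |= _ellipse(rows, cols, 0.38 * h, 0.66 * w, 26 * u * s, 11 * u * s)
        m |= _ellipse(rows, cols, 0.74 * h, 0.36 * w, 13 * u * s, 12 * u * s)
        m |= _ellipse(rows, cols, 0.74 * h, 0.66 * w, 12 * u * s, 10 * u * s)
    else:  # pragma: no cover
        raise ValueError(f"unknown view {view}")
    return m


def fractional_area_change(lvef: float, view: ViewLabel) -> float:
    """The cavity-area fraction lost from end-diastole to end-systole."""
    fac = FAC_PER_LVEF * lvef * VIEW_MOTION_FACTOR[view]
    return float(np.clip(fac, 0.01, 0.95))


def _phase_scale(lvef: float, view: ViewLabel, phase: float) -> float:
    """Linear-dimension scale of the cavities at cycle phase ``phase`` in [0,1)."""
    fac = fractional_area_change(lvef, view)
    area_fraction = 1.0 - fac * (1.0 - math.cos(2 * math.pi * phase)) / 2.0
    return math.sqrt(area_fraction)


def render_clip(lvef: float, view: ViewLabel, vendor: str, n_frames: int,
                seed: int, *, image_size: int = DEFAULT_IMAGE_SIZE,
                cycle_period: int | None = None, speckle_sigma: float = 0.35,
                lvef_jitter: float = 0.0, heart_scale: float = 1.0,
                noise_free: bool = False) -> CineClip:
    """Render one synthetic cine loop.

    The clip shows the view's chamber geometry inside a vendor-styled
    sector fan.  Cavity area oscillates sinusoidally over the cardiac
    cycle with a fractional change proportional to the *apparent* LVEF
    ``lvef + lvef_jitter`` (the jitter models view-dependent measurement
    error: the EF apparent in a given cross-section differs from the
    reference biplane value, least for AP4, most for the parasternal
    views); tissue gets multiplicative Rayleigh speckle of width
    ``speckle_sigma`` (set ``noise_free=True`` for the pure geometry
    rendering used by oracles).  ``heart_scale`` multiplies all chamber
    dimensions: per-patient anatomical size variation.
    """
    if n_frames < 2:
        raise ValueError("a cine clip needs at least 2 frames")
    style = VENDOR_STYLES[vendor]
    rng = np.random.default_rng(seed)
    period = int(cycle_period) if cycle_period is not None else style.base_period
    if n_frames < 2 * period:
        raise ValueError(
            f"n_frames={n_frames} must cover two cycles (period {period})"
        )
    shape = (image_size, image_size)
    fan = fan_mask(shape, half_angle_deg=style.half_angle_deg)
    pixel_spacing = style.depth_cm / image_size
    gain = style.gain * float(rng.uniform(0.85, 1.15))
    cavity_level = 14.0

    # Rayleigh mode sigma -> unit-mean multiplicative field
    rayleigh_mean = speckle_sigma * math.sqrt(math.pi / 2.0)

    lvef_app = float(np.clip(lvef + lvef_jitter, 5.0, 90.0))
    frames = np.empty((n_frames,) + shape, dtype=np.uint8)
    for t in range(n_frames):
        phase = (t % period) / period
        cav = chamber_mask(view, shape,
                           heart_scale * _phase_scale(lvef_app, view, phase))
        img = np.full(shape, gain, dtype=np.float64)
        if noise_free:
            img[cav] = cavity_level
        else:
            speckle = rng.rayleigh(scale=speckle_sigma, size=shape) / rayleigh_mean
            img *= speckle
            img[cav] = cavity_level * speckle[cav]
        img[~fan] = 0.0
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)

    dt = 1.0 / period  # one cardiac cycle per second
    times = np.arange(n_frames) * dt
    return CineClip(frames=frames, pixel_spacing=pixel_spacing,
                    frame_times=times, view=view, cycle_period=period)


def burn_metadata(clip: CineClip, seed: int, *, margin: int = 14,
                  intensity: int = 230) -> CineClip:
    """Burn text-like high-intensity blocks into the clip's periphery.

    Blocks are confined to a ``margin``-pixel border *outside* the fan
    (emulating vendor overlays: patient name, date, scale bars); the fan
    interior is untouched.  ``margin=0`` returns the clip unchanged.
    """
    if margin <= 0:
        return clip.with_frames(clip.frames.copy())
    rng = np.random.default_rng(seed)
    h, w = clip.shape
    border = np.zeros((h, w), dtype=bool)
    border[:margin, :] = True
    border[-margin:, :] = True
    border[:, :margin] = True
    border[:, -margin:] = True
    # never touch the fan, whatever the vendor geometry was
    widest = fan_mask((h, w), half_angle_deg=50.0, r_min_frac=0.0, r_max_frac=1.0)
    border &= ~widest

    overlay = np.zeros((h, w), dtype=np.uint8)
    n_blocks = rng.integers(4, 9)
    for _ in range(n_blocks):
        bh = int(rng.integers(3, max(4, margin // 2 + 1)))
        bw = int(rng.integers(8, 30))
        r0 = int(rng.integers(0, h - bh))
        c0 = int(rng.integers(0, w - bw))
        block = np.zeros((bh, bw), dtype=np.uint8)
        # dashed pattern: text-like alternation of glyphs and gaps
        cuts = rng.random(bw) < 0.8
        block[:, cuts] = intensity
        overlay[r0:r0 + bh, c0:c0 + bw] = np.maximum(
            overlay[r0:r0 + bh, c0:c0 + bw], block)
    overlay[~border] = 0

    frames = np.maximum(clip.frames, overlay[None, :, :])
    return clip.with_frames(frames)


def paper_cohort_spec(seed: int = 0) -> CohortSpec:
    """The study's stratified design: 340 patients over LVEF 10-80%."""
    return CohortSpec(strata=STUDY_STRATA, seed=seed)


def _patient_params(spec: CohortSpec, index: int,
                    stratum: tuple[float, float, int]) -> tuple[float, str, int, int]:
    """LVEF, vendor, cycle period and render seed of patient ``index``.

    One RNG stream per patient, derived from (cohort seed, patient index),
    so cohort composition does not depend on render order.
    """
    rng = np.random.default_rng([spec.seed, index])
    lo, hi, _ = stratum
    lvef = float(rng.uniform(lo, hi))
    names = [v for v, _ in spec.vendors]
    props = np.array([p for _, p in spec.vendors], dtype=float)
    vendor = str(rng.choice(names, p=props / props.sum()))
    base = VENDOR_STYLES[vendor].base_period
    period = int(np.clip(base + rng.integers(-3, 4), 20, 40))
    render_seed = int(rng.integers(0, 2**31 - 1))
    return lvef, vendor, period, render_seed


def iter_cohort(spec: CohortSpec, *, image_size: int = DEFAULT_IMAGE_SIZE,
                render_clips: bool = True, burn: bool = True,
                speckle_sigma: float = 0.35) -> Iterator[EchoStudy]:
    """Yield the cohort's studies one at a time (memory-friendly).

    Patients are drawn stratum by stratum; LVEF uniform within each
    stratum, vendor by the spec's mixing proportions.  With
    ``render_clips=False`` only the study metadata (IDs, LVEF, vendor)
    is produced — enough for cohort bookkeeping and fold design.
    """
    index = 0
    for stratum in spec.strata:
        lo, hi, n = stratum
        for _ in range(n):
            lvef, vendor, period, render_seed = _patient_params(spec, index, stratum)
            study = EchoStudy(patient_id=f"P{index:04d}", lvef=lvef, vendor=vendor)
            if render_clips:
                n_frames = 2 * period + 6
                jrng = np.random.default_rng([spec.seed, index, 1])
                heart_scale = float(jrng.uniform(0.80, 1.25))
                for k, view in enumerate(VIEW_ORDER):
                    jitter = float(jrng.normal(0.0, APPARENT_LVEF_SIGMA[view]))
                    clip = render_clip(lvef, view, vendor, n_frames,
                                       seed=render_seed + k, image_size=image_size,
                                       cycle_period=period, lvef_jitter=jitter,
                                       heart_scale=heart_scale,
                                       speckle_sigma=speckle_sigma)
                    if burn:
                        clip = burn_metadata(clip, seed=render_seed + 100 + k)
                    study.clips[view] = clip
                study.validate()
            yield study
            index += 1


def make_cohort(spec: CohortSpec, *, image_size: int = DEFAULT_IMAGE_SIZE,
                render_clips: bool = True, burn: bool = True,
                speckle_sigma: float = 0.35) -> list[EchoStudy]:
    """Materialize the full cohort as a list of studies.

    Fully reproducible from ``spec.seed``.  For large cohorts prefer
    :func:`iter_cohort` and stream studies through preprocessing.
    """
    return list(iter_cohort(spec, image_size=image_size,
                            render_clips=render_clips, burn=burn,
                            speckle_sigma=speckle_sigma))
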