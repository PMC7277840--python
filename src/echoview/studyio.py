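"""Reading and writing echo studies.

Two on-disk layouts are supported, both one directory per study:

``fixture`` (default)
    One lossless multi-page TIFF per view (``PLAX.tiff`` ...) plus a
    ``study.json`` sidecar holding patient_id, LVEF, vendor and, per
    view, pixel_spacing (cm/px), frame_times (s) and the simulator's
    ground-truth cycle_period if known.

``dicom``
    One multi-frame ultrasound DICOM per view (``PLAX.dcm`` ...) carrying
    the pixel data, PixelSpacing and FrameTimeVector, plus the same
    ``study.json`` sidecar for the fields DICOM has no natural slot for
    (LVEF, vendor tag, ground-truth period).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
import tifffile
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import VIEW_ORDER, CineClip, EchoStudy, ViewLabel

__all__ = ["write_study", "read_study", "write_frameset", "read_frameset"]

US_MULTIFRAME_SOP = "1.2.840.10008.5.1.4.1.1.3.1"


class StudyIOError(IOError):
    """Raised when a study directory cannot be read or is malformed."""


def _clip_meta(clip: CineClip) -> dict:
    return {
        "pixel_spacing": clip.pixel_spacing,
        "frame_times": clip.frame_times.tolist(),
        "cycle_period": clip.cycle_period,
    }


def _write_dicom(clip: CineClip, path: Path, patient_id: str) -> None:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = US_MULTIFRAME_SOP
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = US_MULTIFRAME_SOP
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.PatientID = patient_id
    ds.NumberOfFrames = clip.n_frames
    ds.Rows, ds.Columns = clip.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    spacing_mm = clip.pixel_spacing * 10.0
    ds.PixelSpacing = [f"{spacing_mm:.8f}", f"{spacing_mm:.8f}"]
    # inter-frame increments in ms, as DICOM's FrameTimeVector expects
    dt = np.diff(clip.frame_times, prepend=clip.frame_times[0]) * 1000.0
    ds.FrameTimeVector = [f"{v:.6f}" for v in dt]
    ds.PixelData = clip.frames.tobytes()
    ds.save_as(path, enforce_file_format=True)


def _read_dicom(path: Path) -> tuple[np.ndarray, float, np.ndarray]:
    ds = pydicom.dcmread(path)
    frames = ds.pixel_array
    if frames.ndim == 2:
        frames = frames[None]
    spacing_cm = float(ds.PixelSpacing[0]) / 10.0
    dt_ms = np.array([float(v) for v in ds.FrameTimeVector])
    times = np.cumsum(dt_ms) / 1000.0
    times -= times[0]
    return frames.astype(np.uint8), spacing_cm, times


def write_study(study: EchoStudy, path: str | Path, *, fmt: str = "fixture") -> Path:
    """Write one study to directory ``path``; returns the directory."""
    if fmt not in ("fixture", "dicom"):
        raise ValueError(f"unknown study format {fmt!r}")
    study.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "patient_id": study.patient_id,
        "lvef": study.lvef,
        "vendor": study.vendor,
        "format": fmt,
        "views": {v.value: _clip_meta(study.clips[v]) for v in VIEW_ORDER},
    }
    for view in VIEW_ORDER:
        clip = study.clips[view]
        if fmt == "fixture":
            tifffile.imwrite(path / f"{view.value}.tiff", clip.frames,
                             compression="zlib")
        else:
            _write_dicom(clip, path / f"{view.value}.dcm", study.patient_id)
    (path / "study.json").write_text(json.dumps(sidecar, indent=1))
    return path


def write_frameset(fs, path: str | Path) -> Path:
    """Write a preprocessed FrameSet: lossless stack + JSON index manifest.

    Layout: ``frames.tiff`` (the k selected frames), ``averaged.tiff``
    and ``frameset.json`` (source indices, ids, view).
    """
    from .core import FrameSet  # local import to avoid cycle at module load

    assert isinstance(fs, FrameSet)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path / "frames.tiff", fs.frames, compression="zlib")
    tifffile.imwrite(path / "averaged.tiff", fs.averaged, compression="zlib")
    manifest = {
        "clip_id": fs.clip_id,
        "patient_id": fs.patient_id,
        "view": fs.view.value if fs.view is not None else None,
        "source_indices": fs.source_indices.tolist(),
    }
    (path / "frameset.json").write_text(json.dumps(manifest, indent=1))
    return path


def read_frameset(path: str | Path):
    """Read a FrameSet directory written by :func:`write_frameset`."""
    from .core import FrameSet

    path = Path(path)
    try:
        manifest = json.loads((path / "frameset.json").read_text())
        frames = tifffile.imread(path / "frames.tiff")
        averaged = tifffile.imread(path / "averaged.tiff")
    except Exception as e:
        raise StudyIOError(f"cannot read frameset at {path}: {e}") from e
    view = manifest.get("view")
    return FrameSet(
        frames=frames.astype(np.uint8),
        source_indices=np.array(manifest["source_indices"], dtype=int),
        averaged=averaged.astype(np.uint8),
        clip_id=manifest.get("clip_id", ""),
        patient_id=manifest.get("patient_id", ""),
        view=ViewLabel(view) if view else None,
    )


def read_study(path: str | Path) -> EchoStudy:
    """Read a study directory written by :func:`write_study`.

    Raises :class:`StudyIOError` naming the offending file on any
    missing, truncated or malformed input; never returns a partial study.
    """
    path = Path(path)
    sidecar_path = path / "study.json"
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except FileNotFoundError as e:
        raise StudyIOError(f"missing sidecar {sidecar_path}") from e
    except json.JSONDecodeError as e:
        raise StudyIOError(f"malformed sidecar {sidecar_path}: {e}") from e

    fmt = sidecar.get("format", "fixture")
    study = EchoStudy(patient_id=sidecar["patient_id"], lvef=sidecar["lvef"],
                      vendor=sidecar["vendor"])
    for view in VIEW_ORDER:
        meta = sidecar["views"][view.value]
        ext = "tiff" if fmt == "fixture" else "dcm"
        fpath = path / f"{view.value}.{ext}"
        try:
            if fmt == "fixture":
                frames = tifffile.imread(fpath)
                spacing = float(meta["pixel_spacing"])
                times = np.array(meta["frame_times"], dtype=float)
            else:
                frames, spacing, times = _read_dicom(fpath)
        except Exception as e:
            raise StudyIOError(f"cannot read clip {fpath}: {e}") from e
        if frames.ndim == 2:
            frames = frames[None]
        if frames.shape[0] != len(times):
            raise StudyIOError(f"frame/time count mismatch in {fpath}")
        study.clips[view] = CineClip(
            frames=frames.astype(np.uint8), pixel_spacing=spacing,
            frame_times=times, view=view,
            cycle_period=meta.get("cycle_period"),
        )
    study.validate()
    return study
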