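"""Write/read simulated CT images as a DICOM series, one file per slice.

Stored pixel values are unsigned 16-bit with RescaleSlope 1 and
RescaleIntercept -1024, so HU round-trips within the 0.5 HU integer
quantization.  Simulation metadata that has no standard tag (noise SD,
seed, phantom shape) rides in ImageComments as a small JSON blob.  UIDs are
derived deterministically from the acquisition metadata so that re-running
a configuration reproduces byte-identical series.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .phantom import CTImage

__all__ = ["write_image_series", "read_image_series"]

_INTERCEPT = -1024.0
_ROOT = "1.2.826.0.1.3680043.10.1467"  # fixed private UID root for this package


def _uid(*entropy: object) -> str:
    return generate_uid(prefix=_ROOT + ".", entropy_srcs=[repr(e) for e in entropy])


def write_image_series(img: CTImage, path: str | Path) -> list[Path]:
    """Write one DICOM file per slice into ``path``; returns the file list."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = _uid("series", img.phantom_shape, img.kvp, img.seed, img.noise_sd, img.values.shape)
    study_uid = _uid("study", img.phantom_shape, img.kvp)
    frame_uid = _uid("frame", img.phantom_shape)
    meta_json = json.dumps(
        {"noise_sd": img.noise_sd, "seed": img.seed, "phantom_shape": img.phantom_shape}
    )
    files: list[Path] = []
    for k in range(img.n_slices):
        stored = np.round(img.values[k] - _INTERCEPT).astype(np.uint16)

        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = _uid("sop", series_uid, k)
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM^SYNTHETIC"
        ds.PatientID = "HUCORR"
        ds.InstanceNumber = k + 1
        ds.ImageComments = meta_json
        ds.KVP = img.kvp
        ds.ExposureInmAs = img.mas
        ds.Rows, ds.Columns = stored.shape
        ds.PixelSpacing = [f"{img.spacing * 10:.6f}", f"{img.spacing * 10:.6f}"]  # mm
        ds.SliceThickness = f"{img.slice_thickness * 10:.6f}"
        z_mm = k * img.slice_thickness * 10.0
        ds.ImagePositionPatient = ["0", "0", f"{z_mm:.6f}"]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.SliceLocation = f"{z_mm:.6f}"
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = f"{_INTERCEPT:.0f}"
        ds.RescaleType = "HU"
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = stored.tobytes()

        fm = FileMetaDataset()
        fm.MediaStorageSOPClassUID = CTImageStorage
        fm.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        fm.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = fm

        fname = out / f"slice_{k + 1:04d}.dcm"
        pydicom.dcmwrite(fname, ds, enforce_file_format=True)
        files.append(fname)
    return files


def read_image_series(path: str | Path) -> CTImage:
    """Read a DICOM series written by :func:`write_image_series` back to a CTImage.

    Slices are ordered by InstanceNumber; a gap or an unreadable file is a
    hard error naming the offending slice.
    """
    folder = Path(path)
    files = sorted(folder.glob("*.dcm"))
    if not files:
        raise ValueError(f"no DICOM slices found in {folder}")
    slices: dict[int, Dataset] = {}
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:  # corrupt slice
            raise ValueError(f"corrupt DICOM slice {f.name}: {exc}") from exc
        slices[int(ds.InstanceNumber)] = ds
    expected = range(1, len(slices) + 1)
    missing = [n for n in expected if n not in slices]
    if missing:
        raise ValueError(f"missing slice InstanceNumber {missing[0]} in {folder}")
    ordered = [slices[n] for n in expected]
    first = ordered[0]
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    values = np.stack(
        [ds.pixel_array.astype(float) * slope + intercept for ds in ordered]
    )
    meta = {}
    if getattr(first, "ImageComments", ""):
        try:
            meta = json.loads(first.ImageComments)
        except json.JSONDecodeError:
            meta = {}
    return CTImage(
        values=values,
        spacing=float(first.PixelSpacing[0]) / 10.0,
        slice_thickness=float(first.SliceThickness) / 10.0,
        kvp=float(first.KVP),
        mas=float(getattr(first, "ExposureInmAs", 0.0)),
        noise_sd=float(meta.get("noise_sd", 0.0)),
        seed=meta.get("seed"),
        phantom_shape=str(meta.get("phantom_shape", "")),
    )
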