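"""Reading and writing the on-disk cohort layout.

A cohort on disk is a directory with one image triple per lesion (LE, RC,
mask), a ``labels.csv`` histology table and a ``manifest.json`` binding
file paths to lesion ids and recording provenance (generator config and
seed, or an external source description).

Images are 16-bit grayscale PNG by default; minimal single-frame DICOM
secondary-capture files are supported as an alternative dialect, with
``RescaleSlope``/``RescaleIntercept`` applied on read so that subtraction
(RC) images may carry negative values.  Masks are 8-bit PNG with foreground
255.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "LesionRecord",
    "ImagePair",
    "CohortManifest",
    "MIN_ROI_PIXELS",
    "write_cohort",
    "load_cohort",
    "load_records_csv",
    "write_records_csv",
    "extract_roi_pixels",
]

#: minimum ROI size for stable third/fourth moments
MIN_ROI_PIXELS = 16

_GRADES = ("G1", "G2", "G3")


@dataclass(frozen=True)
class LesionRecord:
    """Histology labels of one lesion: receptor percentages, HER2, grade."""

    lesion_id: str
    patient_id: str
    er_pct: float
    pr_pct: float
    ki67_pct: float
    her2: str   # "+" or "-"
    grade: str  # "G1" | "G2" | "G3"

    def __post_init__(self) -> None:
        for name in ("er_pct", "pr_pct", "ki67_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{self.lesion_id}: {name}={v} outside [0,100]")
        if self.her2 not in ("+", "-"):
            raise ValueError(f"{self.lesion_id}: her2 must be '+' or '-', got {self.her2!r}")
        if self.grade not in _GRADES:
            raise ValueError(f"{self.lesion_id}: grade must be one of {_GRADES}, got {self.grade!r}")


@dataclass
class ImagePair:
    """LE and RC views of one lesion with their shared binary ROI mask."""

    lesion_id: str
    le: np.ndarray
    rc: np.ndarray
    mask: np.ndarray
    bit_depth: int = 16
    pixel_value_range: tuple[float, float] = (0.0, 65535.0)

    def validate(self) -> None:
        if not (self.le.shape == self.rc.shape == self.mask.shape):
            raise ValueError(
                f"{self.lesion_id}: LE/RC/mask shapes differ "
                f"({self.le.shape}, {self.rc.shape}, {self.mask.shape})"
            )
        if self.le.ndim != 2:
            raise ValueError(f"{self.lesion_id}: images must be 2-D")
        n_fg = int(np.count_nonzero(self.mask))
        if n_fg < MIN_ROI_PIXELS:
            raise ValueError(
                f"{self.lesion_id}: mask has {n_fg} foreground pixels "
                f"(minimum {MIN_ROI_PIXELS})"
            )
        if np.any(np.asarray(self.le) < 0):
            raise ValueError(f"{self.lesion_id}: LE image contains negative values")


@dataclass
class CohortManifest:
    """File-level index of a cohort plus provenance metadata."""

    entries: list[dict]             # lesion_id, le_path, rc_path, mask_path
    labels_path: str
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        ids = [e["lesion_id"] for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate lesion_ids in manifest: {dupes}")


def extract_roi_pixels(pair: ImagePair, which: str) -> np.ndarray:
    """Return the in-mask pixel values of one view, in row-major order."""
    if which == "LE":
        img = pair.le
    elif which == "RC":
        img = pair.rc
    else:
        raise ValueError(f"which must be 'LE' or 'RC', got {which!r}")
    return np.asarray(img)[np.asarray(pair.mask, dtype=bool)]


# -- labels CSV --------------------------------------------------------------

_CSV_COLUMNS = ["lesion_id", "patient_id", "er_pct", "pr_pct", "ki67_pct", "her2", "grade"]


def write_records_csv(records: list[LesionRecord], path) -> None:
    df = pd.DataFrame(
        [{
            "lesion_id": r.lesion_id, "patient_id": r.patient_id,
            "er_pct": repr(r.er_pct), "pr_pct": repr(r.pr_pct),
            "ki67_pct": repr(r.ki67_pct), "her2": r.her2, "grade": r.grade,
        } for r in records],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def load_records_csv(path) -> list[LesionRecord]:
    # percentages parsed with python's float() for exact repr round trips
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"labels CSV {path} missing columns: {missing}")
    records = [
        LesionRecord(
            lesion_id=row.lesion_id, patient_id=row.patient_id,
            er_pct=float(row.er_pct), pr_pct=float(row.pr_pct),
            ki67_pct=float(row.ki67_pct), her2=row.her2, grade=row.grade,
        )
        for row in df.itertuples(index=False)
    ]
    return records


# -- image files -------------------------------------------------------------

def _write_png16(path, arr: np.ndarray) -> None:
    a = np.rint(np.clip(arr, 0, 65535)).astype(np.uint16)
    iio.imwrite(path, a, extension=".png")


def _write_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8),
                extension=".png")


def _write_dicom(path, arr: np.ndarray) -> None:
    """Write a minimal secondary-capture DICOM (16-bit, rescale 1/0)."""
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    a = np.rint(np.clip(arr, 0, 65535)).astype(np.uint16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = a.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "0"
    ds.PixelData = a.tobytes()
    ds.save_as(path, enforce_file_format=True)


def _read_image(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return arr.astype(np.float64)


# -- cohort-level write/load -------------------------------------------------

def write_cohort(records, pairs, out_dir, image_format: str = "png",
                 provenance: dict | None = None) -> Path:
    """Write a cohort directory and return the manifest path.

    Pixel values are rounded to integers on write, so a round trip is exact
    for integer-valued images.
    """
    if image_format not in ("png", "dicom"):
        raise ValueError("image_format must be 'png' or 'dicom'")
    if len(records) != len(pairs):
        raise ValueError("records and pairs must be aligned")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)

    ext = ".png" if image_format == "png" else ".dcm"
    writer = _write_png16 if image_format == "png" else _write_dicom
    entries = []
    for rec, pair in zip(records, pairs):
        if rec.lesion_id != pair.lesion_id:
            raise ValueError(f"record/pair mismatch: {rec.lesion_id} vs {pair.lesion_id}")
        pair.validate()
        le_path = f"images/{rec.lesion_id}_LE{ext}"
        rc_path = f"images/{rec.lesion_id}_RC{ext}"
        mask_path = f"images/{rec.lesion_id}_mask.png"
        writer(out / le_path, pair.le)
        writer(out / rc_path, pair.rc)
        _write_mask_png(out / mask_path, pair.mask)
        entries.append({"lesion_id": rec.lesion_id, "le_path": le_path,
                        "rc_path": rc_path, "mask_path": mask_path})

    labels_path = "labels.csv"
    write_records_csv(records, out / labels_path)
    manifest = CohortManifest(entries=entries, labels_path=labels_path,
                              provenance=provenance or {})
    manifest.validate()
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump({"entries": manifest.entries, "labels_path": manifest.labels_path,
                   "provenance": manifest.provenance}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path


def load_cohort(manifest_path) -> tuple[list[LesionRecord], list[ImagePair]]:
    """Load a cohort directory into aligned records and image pairs.

    Returns both lists sorted by ``lesion_id``.  Raises with the offending
    lesion named on shape mismatches, undersized masks or manifest/labels
    disagreement.
    """
    mpath = Path(manifest_path)
    if not mpath.exists():
        raise FileNotFoundError(f"manifest not found: {mpath}")
    root = mpath.parent
    with open(mpath) as fh:
        doc = json.load(fh)
    manifest = CohortManifest(entries=doc["entries"], labels_path=doc["labels_path"],
                              provenance=doc.get("provenance", {}))
    manifest.validate()

    records = load_records_csv(root / manifest.labels_path)
    rec_by_id = {r.lesion_id: r for r in records}
    manifest_ids = {e["lesion_id"] for e in manifest.entries}
    missing_in_labels = sorted(manifest_ids - set(rec_by_id))
    if missing_in_labels:
        raise ValueError(f"lesions in manifest missing from labels CSV: {missing_in_labels}")
    missing_in_manifest = sorted(set(rec_by_id) - manifest_ids)
    if missing_in_manifest:
        raise ValueError(f"lesions in labels CSV missing from manifest: {missing_in_manifest}")

    bit_depth = int(manifest.provenance.get("bit_depth", 16))
    vmax = float(2 ** bit_depth - 1)
    pairs = []
    for entry in manifest.entries:
        lid = entry["lesion_id"]
        try:
            le = _read_image(root / entry["le_path"])
            rc = _read_image(root / entry["rc_path"])
            mask_img = _read_image(root / entry["mask_path"])
        except Exception as err:  # backends raise format-specific errors
            raise ValueError(f"lesion {lid}: unreadable image file ({err})") from err
        mask = mask_img > 0
        pair = ImagePair(lesion_id=lid, le=le, rc=rc, mask=mask,
                         bit_depth=bit_depth, pixel_value_range=(0.0, vmax))
        try:
            pair.validate()
        except ValueError as err:
            raise ValueError(f"lesion {lid}: {err}") from err
        pairs.append(pair)

    order = np.argsort([e["lesion_id"] for e in manifest.entries], kind="stable")
    pairs = [pairs[i] for i in order]
    records = sorted(records, key=lambda r: r.lesion_id)
    assert all(r.lesion_id == p.lesion_id for r, p in zip(records, pairs))
    return records, pairs
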