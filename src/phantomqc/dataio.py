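"""Reading and writing: DICOM, lossless arrays, label/score CSVs."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .images import MONOCHROME1, MONOCHROME2, UNKNOWN, RawImage
from .layout import DEFAULT_LAYOUT, GridLayout
from .scores import Score

_ROOT_UID = "1.2.826.0.1.3680043.10.1457."  # arbitrary private root


def write_dicom(img: RawImage, path, case_id: str = "PHANTOM", bits: int = 12):
    """Write a secondary-capture DICOM with the photometric tag set.

    Float images on [0, 1] are scaled to the ``bits``-deep integer
    range; integer images are stored as-is.
    """
    path = Path(path)
    pix = np.asarray(img.pixels)
    if np.issubdtype(pix.dtype, np.floating):
        arr = np.round(np.clip(pix, 0, 1) * (2**bits - 1)).astype(np.uint16)
        stored = bits
    else:
        arr = pix.astype(np.uint16)
        stored = img.bit_depth

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    # deterministic UID so identical content writes identical files
    meta.MediaStorageSOPInstanceUID = generate_uid(
        _ROOT_UID, entropy_srcs=[case_id, str(arr.shape), str(int(arr.sum()))]
    )
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.PatientName = case_id
    ds.PatientID = case_id
    ds.PhotometricInterpretation = (
        "MONOCHROME1" if img.photometric == MONOCHROME1 else "MONOCHROME2"
    )
    ds.SamplesPerPixel = 1
    ds.Rows, ds.Columns = arr.shape
    ds.BitsAllocated = 16
    ds.BitsStored = stored
    ds.HighBit = stored - 1
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    ds.save_as(path, enforce_file_format=True)


def read_dicom(path) -> RawImage:
    """Read a DICOM into a :class:`RawImage`, tolerating missing tags
    (photometric defaults to unknown, bit depth to the allocated
    size)."""
    ds = pydicom.dcmread(path, force=True)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-frame grayscale image")
    photo = str(getattr(ds, "PhotometricInterpretation", "")).upper()
    photometric = {
        "MONOCHROME1": MONOCHROME1,
        "MONOCHROME2": MONOCHROME2,
    }.get(photo, UNKNOWN)
    bits = int(getattr(ds, "BitsStored", 0) or arr.dtype.itemsize * 8)
    return RawImage(arr, photometric=photometric, bit_depth=bits)


def write_array(img: RawImage, path):
    np.save(path, np.asarray(img.pixels))


def read_array(path) -> RawImage:
    arr = np.load(path)
    return RawImage(arr, photometric=MONOCHROME2,
                    bit_depth=16 if np.issubdtype(arr.dtype, np.integer) else 16)


# ---------------------------------------------------------------------------
# label / score tables


def lesion_id(lesion_type: str, rank: int) -> str:
    return f"{lesion_type}-{rank}"


def labels_frame(
    case_ids, scores_per_case, layout: GridLayout = DEFAULT_LAYOUT
) -> pd.DataFrame:
    """Long-format label table: one row per (case, lesion)."""
    rows = []
    for cid, scores in zip(case_ids, scores_per_case):
        for cell, s in enumerate(scores):
            t, rank = layout.lesion_at(cell)
            rows.append(
                {
                    "case_id": cid,
                    "grid_cell": cell + 1,
                    "lesion_id": lesion_id(t, rank),
                    "lesion_type": t,
                    "rank": rank,
                    "score": str(Score.from_value(s)),
                }
            )
    return pd.DataFrame(rows)


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"score": str})
    df["score"] = df["score"].map(Score.from_value)
    return df


def scores_by_case(df: pd.DataFrame) -> dict:
    """case_id -> 16 scores in grid order, from a label table."""
    out = {}
    for cid, grp in df.groupby("case_id", sort=False):
        grp = grp.sort_values("grid_cell")
        if len(grp) != 16:
            raise ValueError(f"case {cid}: expected 16 lesion rows, got {len(grp)}")
        out[cid] = [Score.from_value(s) for s in grp["score"]]
    return out


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
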