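"""Reading and writing ultrasound frames and ROI polygons.

Coordinate convention (used everywhere in this package): pixel coordinates
are 0-based ``(col, row)`` pairs with the pixel *center* at integer
coordinates; ``row 0`` is the shallowest tissue and depth increases
downward.  Physical positions are ``(col * spacing_x, row * spacing_y)`` in
centimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import (
    CalibrationError,
    RoiFormatError,
    RoiGeometryError,
    UnsupportedFormatError,
)

_DICOM_SUFFIXES = {".dcm", ".dcom", ".dicom"}


@dataclass
class UltrasoundFrame:
    """A calibrated single-frame grayscale ultrasound image.

    Parameters
    ----------
    pixels
        2-D array of intensities, row-major; kept at native bit depth.
    bit_depth
        8 or 16.  Grayscale statistics rescale to the 0-255 scale later;
        the frame itself is never re-quantized.
    spacing_x, spacing_y
        Physical size of one pixel column / row in **cm**.
    source_id
        Free-text identifier (file stem, phantom seed, ...).
    metadata
        Acquisition metadata carried along but never interpreted.
    """

    pixels: np.ndarray
    bit_depth: int
    spacing_x: float
    spacing_y: float
    source_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise UnsupportedFormatError(
                f"frame must be 2-D grayscale, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise UnsupportedFormatError(
                f"frame must be at least 16x16 pixels, got {self.pixels.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise UnsupportedFormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not (self.spacing_x > 0 and self.spacing_y > 0):
            raise CalibrationError("pixel spacings must be positive")
        vmax = 2**self.bit_depth - 1
        if self.pixels.min() < 0 or self.pixels.max() > vmax:
            raise UnsupportedFormatError(
                f"intensities outside [0, {vmax}] for declared bit depth"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class RoiPolygon:
    """A manually drawn region of interest, implicitly closed.

    ``vertices`` is an ordered ``(n, 2)`` array of fractional ``(col, row)``
    pixel coordinates; the last vertex connects back to the first.
    """

    vertices: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise RoiFormatError("vertices must be an (n, 2) list of (col, row) pairs")
        if len(self.vertices) < 3:
            raise RoiFormatError(f"polygon needs >= 3 vertices, got {len(self.vertices)}")
        if not np.isfinite(self.vertices).all():
            raise RoiFormatError("vertices must be finite")
        if not self.as_shapely().is_valid:
            raise RoiGeometryError("polygon is self-intersecting")

    def as_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    def check_within_frame(self, frame: UltrasoundFrame) -> None:
        """Vertices must lie within the frame extended by half a pixel."""
        c, r = self.vertices[:, 0], self.vertices[:, 1]
        if (c < -0.5).any() or (r < -0.5).any() or (c > frame.width - 0.5).any() or (
            r > frame.height - 0.5
        ).any():
            raise RoiGeometryError("polygon vertices fall outside the frame bounds")


def _read_dicom(path: Path, spacing_override=None) -> UltrasoundFrame:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"{path}: multi-channel or multi-frame DICOM unsupported")
    if spacing_override is not None:
        sx, sy = float(spacing_override[0]), float(spacing_override[1])
    elif "PixelSpacing" in ds:
        # PixelSpacing is (row spacing, column spacing) in mm -> cm
        row_mm, col_mm = float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])
        sx, sy = col_mm / 10.0, row_mm / 10.0
    else:
        raise CalibrationError(f"{path}: no PixelSpacing tag and no spacing override")
    bits = int(getattr(ds, "BitsStored", 8 if arr.dtype.itemsize == 1 else 16))
    bit_depth = 8 if bits <= 8 else 16
    meta = {"modality": str(getattr(ds, "Modality", ""))}
    return UltrasoundFrame(arr, bit_depth, sx, sy, source_id=path.stem, metadata=meta)


def _read_raster(path: Path, spacing_override=None) -> UltrasoundFrame:
    from PIL import Image

    img = Image.open(path)
    if img.mode in ("L", "I;16", "I;16B"):
        arr = np.asarray(img)
    elif img.mode in ("I", "F"):
        arr = np.asarray(img.convert("I")).astype(np.uint16)
    else:
        raise UnsupportedFormatError(
            f"{path}: mode {img.mode!r} is not single-channel grayscale"
        )
    if spacing_override is None:
        raise CalibrationError(f"{path}: raster images carry no spacing; pass an override")
    sx, sy = float(spacing_override[0]), float(spacing_override[1])
    bit_depth = 8 if arr.dtype.itemsize == 1 else 16
    return UltrasoundFrame(arr, bit_depth, sx, sy, source_id=path.stem)


def read_frame(path, spacing_override=None) -> UltrasoundFrame:
    """Read a DICOM or PNG/TIFF grayscale frame with physical calibration.

    ``spacing_override`` is ``(spacing_x, spacing_y)`` in cm/px and, when
    given, wins over any DICOM PixelSpacing tag (sonographer-calibrated
    devices often carry wrong or missing tags).  DICOM spacing tags are in
    mm and are converted to cm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _DICOM_SUFFIXES:
        return _read_dicom(path, spacing_override)
    return _read_raster(path, spacing_override)


def write_frame_png(frame: UltrasoundFrame, path) -> None:
    from PIL import Image

    arr = frame.pixels
    if frame.bit_depth == 8:
        Image.fromarray(arr.astype(np.uint8), mode="L").save(path)
    else:
        Image.fromarray(arr.astype(np.uint16), mode="I;16").save(path)


def write_frame_dicom(frame: UltrasoundFrame, path) -> None:
    """Write a minimal secondary-capture DICOM with spacing tags (cm -> mm)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.PatientName = ""
    ds.PatientID = frame.source_id or "synthetic"
    ds.Rows, ds.Columns = frame.pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = frame.bit_depth
    ds.BitsStored = frame.bit_depth
    ds.HighBit = frame.bit_depth - 1
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [frame.spacing_y * 10.0, frame.spacing_x * 10.0]
    dtype = np.uint8 if frame.bit_depth == 8 else np.uint16
    ds.PixelData = np.ascontiguousarray(frame.pixels, dtype=dtype).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_roi(path) -> RoiPolygon:
    """Read an ROI polygon from a JSON document.

    Expected structure: ``{"image_id": str, "vertices": [[col, row], ...]}``.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise RoiFormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "vertices" not in doc:
        raise RoiFormatError(f"{path}: missing 'vertices' field")
    return RoiPolygon(np.asarray(doc["vertices"], dtype=float), image_id=str(doc.get("image_id", "")))


def write_roi(roi: RoiPolygon, path) -> None:
    doc = {"image_id": roi.image_id, "vertices": [[float(c), float(r)] for c, r in roi.vertices]}
    Path(path).write_text(json.dumps(doc, indent=1))
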