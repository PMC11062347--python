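"""Per-image muscle morphometry: the semi-automated measurement engine.

Given a calibrated frame and a manually drawn ROI, this module labels the
pixels under the polygon and derives every metric of the rectus femoris
cross-section: area (CSA, cm²), the classic axis-aligned X/Y caliper
extents, the centroid, the PCA eigen-axes and the extents measured along
them (rotation-invariant analogues of X and Y), the mean grayscale value on
the 0–255 echogenicity scale, and a lateral-overflow flag for muscles wider
than the transducer footprint.

The classic X/Y axes are bounding extents (max − min labelled column/row,
scaled to cm), emulating where a sonographer would place calipers laterally
and anteroposteriorly.  The eigen-extents are spans of the labelled pixel
coordinates projected onto the principal axes of their covariance in
*physical* coordinates, so anisotropic pixel spacing is handled correctly.
No smoothing or speckle filtering is applied before measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import shapely
from scipy import ndimage

from .errors import DegenerateAxesError, DegenerateRoiError, EchomorphError
from .image_io import RoiPolygon, UltrasoundFrame

#: 4-connectivity structuring element for component labelling
_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: relative eigenvalue gap below which the axes are treated as tied
_TIE_RTOL = 1e-9


@dataclass
class MuscleMask:
    """Labelled muscle pixels, congruent with the source frame."""

    labelled: np.ndarray
    frame_ref: str = ""

    def __post_init__(self) -> None:
        self.labelled = np.asarray(self.labelled, dtype=bool)
        if self.labelled.ndim != 2:
            raise DegenerateRoiError("mask must be 2-D")
        if self.n_pixels < 1:
            raise DegenerateRoiError("mask labels no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.labelled.sum())

    def physical_coords(self, frame: UltrasoundFrame) -> np.ndarray:
        """(n, 2) array of labelled pixel-center positions (x_cm, y_cm)."""
        rows, cols = np.nonzero(self.labelled)
        return np.column_stack([cols * frame.spacing_x, rows * frame.spacing_y])


@dataclass
class MorphometryRecord:
    """All per-image metrics produced by one measurement."""

    image_id: str
    area_cm2: float
    x_cm: float
    y_cm: float
    x_eigen_cm: float
    y_eigen_cm: float
    centroid_xy_cm: tuple
    eigvecs: np.ndarray  # rows = unit axis directions, major first
    eigvals: np.ndarray  # variances along the axes, cm², descending
    gray_mean: float
    gray_sd: float
    overflow: bool
    sub_fat_cm: Optional[float] = None

    def __post_init__(self) -> None:
        self.eigvecs = np.asarray(self.eigvecs, dtype=float)
        self.eigvals = np.asarray(self.eigvals, dtype=float)
        if not self.area_cm2 > 0:
            raise EchomorphError("area must be positive")
        if self.eigvals[0] < self.eigvals[1] - 1e-12 or self.eigvals[1] < -1e-12:
            raise EchomorphError("eigenvalues must be descending and non-negative")
        if not np.allclose(self.eigvecs @ self.eigvecs.T, np.eye(2), atol=1e-9):
            raise EchomorphError("eigenvectors must be orthonormal")
        if not (0.0 <= self.gray_mean <= 255.0):
            raise EchomorphError("gray_mean outside the 0-255 scale")

    def as_row(self) -> dict:
        """One delimited-table row of the per-image metrics."""
        return {
            "image_id": self.image_id,
            "area_cm2": self.area_cm2,
            "x_cm": self.x_cm,
            "y_cm": self.y_cm,
            "x_eigen_cm": self.x_eigen_cm,
            "y_eigen_cm": self.y_eigen_cm,
            "gray_mean": self.gray_mean,
            "gray_sd": self.gray_sd,
            "sub_fat_cm": self.sub_fat_cm if self.sub_fat_cm is not None else np.nan,
            "overflow": self.overflow,
        }


def rasterize(roi: RoiPolygon, frame: UltrasoundFrame) -> MuscleMask:
    """Label every pixel whose center lies inside or on the ROI boundary.

    Boundary-inclusive at pixel centers; if the rasterization fragments,
    only the largest 4-connected component is kept.
    """
    poly = roi.as_shapely()
    minc, minr, maxc, maxr = poly.bounds
    c0 = max(int(np.ceil(minc - 1e-9)), 0)
    c1 = min(int(np.floor(maxc + 1e-9)), frame.width - 1)
    r0 = max(int(np.ceil(minr - 1e-9)), 0)
    r1 = min(int(np.floor(maxr + 1e-9)), frame.height - 1)
    if c1 < c0 or r1 < r0:
        raise DegenerateRoiError("polygon covers no pixel centers inside the frame")
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    inside = shapely.intersects_xy(poly, cols.ravel(), rows.ravel()).reshape(cols.shape)
    mask = np.zeros((frame.height, frame.width), dtype=bool)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    if not mask.any():
        raise DegenerateRoiError("polygon falls between pixel centers")
    labels, n = ndimage.label(mask, structure=_FOUR_CONN)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return MuscleMask(mask, frame_ref=frame.source_id)


def area_cm2(mask: MuscleMask, frame: UltrasoundFrame) -> float:
    """Cross-sectional area: labelled pixel count × pixel area."""
    return mask.n_pixels * frame.spacing_x * frame.spacing_y


def centroid(mask: MuscleMask, frame: UltrasoundFrame) -> tuple:
    """Center of the labelled pixels in physical coordinates (cm)."""
    pts = mask.physical_coords(frame)
    cx, cy = pts.mean(axis=0)
    return float(cx), float(cy)


def principal_axes(mask: MuscleMask, frame: UltrasoundFrame):
    """PCA of the labelled pixel coordinates.

    Returns ``(eigvecs, eigvals, x_eigen_cm, y_eigen_cm)`` where the first
    eigenvector is the direction of highest positional variance (the long
    axis of the muscle ellipse) and the extents are raw max−min spans of
    the pixel coordinates projected onto each axis (no pixel-diagonal
    correction).  Sign convention: each axis has a non-negative image-x
    component; when the eigenvalues tie (circular mask) the first axis is
    the one closest to the image x-direction.
    """
    if mask.n_pixels < 2:
        raise DegenerateAxesError("principal axes need at least 2 labelled pixels")
    pts = mask.physical_coords(frame)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)  # population covariance
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order].T  # rows are axes, major first
    if vals[0] - vals[1] <= _TIE_RTOL * max(vals[0], 1e-300):
        vecs = np.eye(2)  # tied: align with the image axes
    for i in range(2):
        if vecs[i, 0] < 0 or (vecs[i, 0] == 0 and vecs[i, 1] < 0):
            vecs[i] = -vecs[i]
    proj = centered @ vecs.T
    spans = proj.max(axis=0) - proj.min(axis=0)
    return vecs, vals, float(spans[0]), float(spans[1])


def classic_axes(mask: MuscleMask, frame: UltrasoundFrame) -> tuple:
    """Axis-aligned caliper extents: lateral (X) and anteroposterior (Y)."""
    rows, cols = np.nonzero(mask.labelled)
    x = (cols.max() - cols.min()) * frame.spacing_x
    y = (rows.max() - rows.min()) * frame.spacing_y
    return float(x), float(y)


def gray_stats(frame: UltrasoundFrame, mask: MuscleMask) -> tuple:
    """Mean and population SD of labelled intensities on the 0-255 scale.

    Native bit depth is rescaled linearly by its full range
    (0 → 0, 2^depth − 1 → 255), not by the observed min/max, so absolute
    echogenicity stays comparable across images.
    """
    scale = 255.0 / (2**frame.bit_depth - 1)
    vals = frame.pixels[mask.labelled].astype(float) * scale
    return float(vals.mean()), float(vals.std())


def overflow_flag(mask: MuscleMask, frame: UltrasoundFrame, margin_px: int = 2) -> bool:
    """True iff the labelled region touches the lateral image borders.

    Overflow means the muscle is wider than the transducer footprint, so
    only contact within ``margin_px`` of the left or right border counts;
    top/bottom (depth) contact never triggers the flag.
    """
    cols = np.nonzero(mask.labelled)[1]
    return bool(cols.min() < margin_px or cols.max() >= frame.width - margin_px)


def measure(
    frame: UltrasoundFrame,
    roi: RoiPolygon,
    sub_fat_points: Optional[Sequence] = None,
) -> MorphometryRecord:
    """Run the full measurement pipeline on one frame + ROI.

    ``sub_fat_points``, when given, is a pair of (col, row) annotation
    points whose Euclidean physical distance is reported as the
    subcutaneous fat thickness.
    """
    roi.check_within_frame(frame)
    mask = rasterize(roi, frame)
    vecs, vals, x_eig, y_eig = principal_axes(mask, frame)
    x_cm, y_cm = classic_axes(mask, frame)
    gmean, gsd = gray_stats(frame, mask)
    sub_fat = None
    if sub_fat_points is not None:
        (c1, r1), (c2, r2) = sub_fat_points
        sub_fat = float(
            np.hypot((c2 - c1) * frame.spacing_x, (r2 - r1) * frame.spacing_y)
        )
    return MorphometryRecord(
        image_id=roi.image_id or frame.source_id,
        area_cm2=area_cm2(mask, frame),
        x_cm=x_cm,
        y_cm=y_cm,
        x_eigen_cm=x_eig,
        y_eigen_cm=y_eig,
        centroid_xy_cm=centroid(mask, frame),
        eigvecs=vecs,
        eigvals=vals,
        gray_mean=gmean,
        gray_sd=gsd,
        overflow=overflow_flag(mask, frame),
        sub_fat_cm=sub_fat,
    )


def _orthonormalize(m: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(m.T)
    vecs = q.T
    for i in range(2):
        if vecs[i, 0] < 0 or (vecs[i, 0] == 0 and vecs[i, 1] < 0):
            vecs[i] = -vecs[i]
    return vecs


def average_replicates(records: Sequence[MorphometryRecord]) -> MorphometryRecord:
    """Field-wise mean of replicate measurements of the same subject.

    All numeric metrics are averaged arithmetically; the overflow flag is
    OR-combined (one truncated replicate taints the pair).  The protocol
    this mirrors takes the average of two consecutive acquisitions.
    """
    if not records:
        raise EchomorphError("need at least one replicate")
    if len(records) == 1:
        return records[0]

    def fmean(attr):
        return float(np.mean([getattr(r, attr) for r in records]))

    sub_fats = [r.sub_fat_cm for r in records if r.sub_fat_cm is not None]
    return MorphometryRecord(
        image_id=records[0].image_id,
        area_cm2=fmean("area_cm2"),
        x_cm=fmean("x_cm"),
        y_cm=fmean("y_cm"),
        x_eigen_cm=fmean("x_eigen_cm"),
        y_eigen_cm=fmean("y_eigen_cm"),
        centroid_xy_cm=tuple(np.mean([r.centroid_xy_cm for r in records], axis=0)),
        eigvecs=_orthonormalize(np.mean([r.eigvecs for r in records], axis=0)),
        eigvals=np.mean([r.eigvals for r in records], axis=0),
        gray_mean=fmean("gray_mean"),
        gray_sd=fmean("gray_sd"),
        overflow=any(r.overflow for r in records),
        sub_fat_cm=float(np.mean(sub_fats)) if sub_fats else None,
    )
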