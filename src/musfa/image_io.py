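"""Calibrated B-mode image and polygonal ROI input/output.

B-mode ultrasound frames arrive as 8- or 16-bit grayscale rasters (PNG/TIFF
exports) or single-frame DICOM. Pixels are rarely square: the axial (depth)
and lateral (beam) spacings are carried separately in mm/pixel and the image
is resampled to an isotropic grid before any spectral analysis, so that a
kernel defined in mm is a square block of pixels.

Coordinate convention: 0-based (row, col) with pixel centers at integer
coordinates. Rows run along the axial direction, columns along the lateral
direction. Polygon interiors include the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import InputError, UnsupportedFormatError, ValidationError

__all__ = [
    "ROI_LABELS",
    "BModeImage",
    "PolygonROI",
    "SaturationReport",
    "load_bmode",
    "resample_isotropic",
    "detect_saturation",
    "polygon_mask",
    "read_roi_file",
    "write_roi_file",
]

#: Region labels: ``injured``/``adjacent`` on the involved limb,
#: ``mirrored_injury``/``mirrored_adjacent`` at the matched locations on the
#: contralateral limb.
ROI_LABELS = ("injured", "adjacent", "mirrored_injury", "mirrored_adjacent")

# BT.601 luma weights used to collapse RGB-encoded grayscale exports.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class BModeImage:
    """A calibrated grayscale B-mode frame.

    Parameters
    ----------
    pixels
        2-D array of gray intensities, stored as float64. Values live in
        ``[0, bit_max]``.
    spacing_axial, spacing_lateral
        Physical pixel size in mm along rows (depth) and columns (width).
    image_id
        Opaque identifier used to link ROIs and manifest rows.
    bit_max
        Maximum representable intensity of the source format (255 for 8-bit).
    """

    pixels: np.ndarray
    spacing_axial: float
    spacing_lateral: float
    image_id: str = ""
    bit_max: float = 255.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ValidationError("pixels must be a 2-D grid with >= 2 rows and columns")
        if not (self.spacing_axial > 0 and self.spacing_lateral > 0):
            raise ValidationError("pixel spacings must be positive")
        if self.pixels.min() < 0 or self.pixels.max() > self.bit_max:
            raise ValidationError("intensities must lie in [0, bit_max]")

    @property
    def is_isotropic(self) -> bool:
        return np.isclose(self.spacing_axial, self.spacing_lateral, rtol=1e-9, atol=0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class PolygonROI:
    """A simple polygon in pixel coordinates with a region label."""

    vertices: list[tuple[float, float]]
    label: str
    image_id: str = ""
    _shape: _ShapelyPolygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = [(float(r), float(c)) for r, c in self.vertices]
        if len(self.vertices) < 3:
            raise ValidationError(
                f"ROI '{self.label}' on '{self.image_id}': needs >= 3 vertices"
            )
        if self.label not in ROI_LABELS:
            raise ValidationError(
                f"ROI on '{self.image_id}': unknown label {self.label!r}"
            )
        # shapely works in (x, y) = (col, row)
        poly = _ShapelyPolygon([(c, r) for r, c in self.vertices])
        if not poly.is_valid:
            raise ValidationError(
                f"ROI '{self.label}' on '{self.image_id}': polygon is self-intersecting"
            )
        if poly.area <= 0:
            raise ValidationError(
                f"ROI '{self.label}' on '{self.image_id}': polygon area must be > 0"
            )
        self._shape = poly

    @property
    def shapely(self) -> _ShapelyPolygon:
        return self._shape

    def bounds(self) -> tuple[float, float, float, float]:
        """(min_row, min_col, max_row, max_col) of the polygon."""
        minx, miny, maxx, maxy = self._shape.bounds
        return miny, minx, maxy, maxx


@dataclass
class SaturationReport:
    """Outcome of the image-saturation screen for one ROI."""

    fraction_saturated: float
    threshold: float
    saturated: bool


def load_bmode(
    path: str | Path,
    spacing_axial: float | None = None,
    spacing_lateral: float | None = None,
    image_id: str | None = None,
) -> BModeImage:
    """Load a grayscale raster or single-frame DICOM as a :class:`BModeImage`.

    RGB inputs are collapsed to gray with BT.601 luma. For DICOM, pixel
    spacing is read from the standard ``PixelSpacing`` tag (row, col order)
    when present; explicit ``spacing_*`` arguments always override.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if image_id is None:
        image_id = path.stem

    if path.suffix.lower() in (".dcm", ".dicom"):
        pixels, bit_max, dcm_ax, dcm_lat = _load_dicom(path)
        spacing_axial = spacing_axial if spacing_axial is not None else dcm_ax
        spacing_lateral = spacing_lateral if spacing_lateral is not None else dcm_lat
    else:
        pixels, bit_max = _load_raster(path)

    if spacing_axial is None or spacing_lateral is None:
        raise ValidationError(f"{path}: pixel spacing not provided and not in metadata")
    if spacing_axial <= 0 or spacing_lateral <= 0:
        raise ValidationError(f"{path}: pixel spacings must be positive")
    return BModeImage(pixels, float(spacing_axial), float(spacing_lateral), image_id, bit_max)


def _load_raster(path: Path) -> tuple[np.ndarray, float]:
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:  # unreadable / truncated file
        raise InputError(f"cannot read image {path}: {exc}") from exc
    bit_max = 65535.0 if arr.dtype == np.uint16 else 255.0
    arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA  # drop alpha, BT.601 luma
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"{path}: expected a single 2-D frame")
    return arr, bit_max


def _load_dicom(path: Path) -> tuple[np.ndarray, float, float | None, float | None]:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:
        raise InputError(f"cannot read DICOM {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] not in (3, 4):
        raise UnsupportedFormatError(f"{path}: multi-frame DICOM is not supported")
    bit_max = float(2 ** int(getattr(ds, "BitsStored", 8)) - 1)
    arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
        bit_max = 255.0
    spacing = getattr(ds, "PixelSpacing", None)
    ax = float(spacing[0]) if spacing is not None else None
    lat = float(spacing[1]) if spacing is not None else None
    return arr, bit_max, ax, lat


def resample_isotropic(img: BModeImage) -> BModeImage:
    """Resample to square pixels at ``min(spacing_axial, spacing_lateral)``.

    Bilinear interpolation on pixel centers; a no-op when the grid is already
    isotropic. The physical extent is preserved to within one output pixel in
    each axis.
    """
    if img.is_isotropic:
        return img
    target = min(img.spacing_axial, img.spacing_lateral)
    n_r, n_c = img.shape
    out_r = int(round(n_r * img.spacing_axial / target))
    out_c = int(round(n_c * img.spacing_lateral / target))
    rows = np.arange(out_r) * (target / img.spacing_axial)
    cols = np.arange(out_c) * (target / img.spacing_lateral)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = ndimage.map_coordinates(
        img.pixels, [rr.ravel(), cc.ravel()], order=1, mode="nearest"
    ).reshape(out_r, out_c)
    out = np.clip(out, 0.0, img.bit_max)
    return BModeImage(out, target, target, img.image_id, img.bit_max)


def polygon_mask(shape: tuple[int, int], roi: PolygonROI) -> np.ndarray:
    """Boolean mask of pixel centers inside or on the boundary of ``roi``.

    Evaluated only within the polygon's bounding box for speed; the even-odd
    interior plus boundary corresponds to shapely's ``covers`` predicate.
    """
    n_r, n_c = shape
    min_r, min_c, max_r, max_c = roi.bounds()
    r0 = max(0, int(np.floor(min_r)))
    c0 = max(0, int(np.floor(min_c)))
    r1 = min(n_r - 1, int(np.ceil(max_r)))
    c1 = min(n_c - 1, int(np.ceil(max_c)))
    mask = np.zeros(shape, dtype=bool)
    if r1 < r0 or c1 < c0:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    pts = shapely.points(cc.ravel().astype(float), rr.ravel().astype(float))
    inside = shapely.covers(roi.shapely, pts).reshape(rr.shape)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside
    return mask


def detect_saturation(
    img: BModeImage, roi: PolygonROI, threshold: float = 0.01
) -> SaturationReport:
    """Fraction of ROI pixels pinned at ``bit_max`` (display saturation).

    Saturated regions carry clipped texture whose spectrum is unusable, so
    saturated frames are excluded from analysis upstream.
    """
    mask = polygon_mask(img.shape, roi)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError(
            f"ROI '{roi.label}' on '{roi.image_id}' contains no pixel centers"
        )
    frac = float(np.count_nonzero(img.pixels[mask] == img.bit_max)) / n
    return SaturationReport(frac, threshold, frac > threshold)


def write_roi_file(rois: Sequence[PolygonROI], path: str | Path) -> None:
    """Serialise ROIs as JSON: list of {image_id, label, vertices=[[r,c],...]}."""
    payload = [
        {"image_id": r.image_id, "label": r.label, "vertices": [list(v) for v in r.vertices]}
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_roi_file(path: str | Path) -> list[PolygonROI]:
    """Read ROIs written by :func:`write_roi_file`; validates each polygon."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such ROI file: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"malformed ROI file {path}: {exc}") from exc
    rois = []
    for i, entry in enumerate(payload):
        try:
            rois.append(
                PolygonROI(
                    vertices=[tuple(v) for v in entry["vertices"]],
                    label=entry["label"],
                    image_id=entry.get("image_id", ""),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"{path}: ROI #{i} is malformed: {exc}") from exc
        except ValidationError as exc:
            raise ValidationError(f"{path}: ROI #{i}: {exc}") from exc
    return rois
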