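"""Segmentation and shape QC of isolated cardiomyocytes.

Cell outlines are detected from the weak UV-evoked autofluorescence in the
405-nm channel, nuclear masks from the bright Hoechst signal in the same
channel.  Detected particles are quantified by area and long/short-axis length
(second-central-moment equivalent ellipse) and filtered: healthy isolated
myocytes are rod-shaped (elongated), while hypercontracted dead cells are
near-circular and are excluded by the axis-ratio criterion.  Only particles
entirely within the field of view are analysed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = [
    "SegmentationError",
    "ImageField",
    "ParticleMask",
    "ShapeMetrics",
    "FilterCriteria",
    "MyocyteRecord",
    "segment_cells",
    "measure_shape",
    "filter_rod_myocytes",
    "segment_nuclei",
    "nucleus_passes",
    "analyze_field",
]

# rejection reasons, checked in this order
REASON_BORDER = "border"
REASON_AREA = "area"
REASON_RATIO = "ratio"


class SegmentationError(ValueError):
    """Raised for invalid image input (e.g. non-finite pixels)."""


@dataclass
class ImageField:
    """One two-channel field: 405-nm (Hoechst + autofluorescence) and 488-nm (NeonGreen2).

    Coordinates are row-major with the origin at the top-left pixel; masks use
    half-open bounding boxes, matching ``skimage`` conventions.
    """

    channel_405: np.ndarray
    channel_488: np.ndarray
    pixel_size: float  # um per pixel
    heart_id: str = ""
    treatment: str = ""
    session_id: str = ""

    def validate(self) -> None:
        if self.channel_405.shape != self.channel_488.shape:
            raise SegmentationError("channel shapes differ")
        if self.pixel_size <= 0:
            raise SegmentationError("pixel_size must be positive")
        for name, ch in (("channel_405", self.channel_405), ("channel_488", self.channel_488)):
            if not np.all(np.isfinite(ch)):
                raise SegmentationError(f"{name} contains non-finite pixels")
            if np.any(ch < 0):
                raise SegmentationError(f"{name} contains negative intensities")


@dataclass
class ParticleMask:
    """Boolean mask of one connected particle within a field."""

    mask: np.ndarray
    label: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open
    touches_border: bool

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise SegmentationError("empty particle mask")


@dataclass
class ShapeMetrics:
    """Area and moment-ellipse axes of a particle, in physical units (um, um^2)."""

    area: float
    long_axis: float
    short_axis: float

    @property
    def axis_ratio(self) -> float:
        return self.long_axis / self.short_axis


@dataclass
class FilterCriteria:
    """QC criteria for rod-shaped myocytes and their nuclei.

    Cell criteria are inclusive bounds; the nuclear size (>30 um^2) and
    long/short axis ratio (>3) criteria are strict inequalities.
    """

    cell_area_min: float = 1500.0  # um^2
    cell_area_max: float = 6000.0  # um^2
    cell_ratio_min: float = 2.5
    nucleus_area_min: float = 30.0  # um^2, strict ">"
    nucleus_ratio_min: float = 3.0  # strict ">"

    def validate(self) -> None:
        if not (0 <= self.cell_area_min < self.cell_area_max):
            raise ValueError("require 0 <= cell_area_min < cell_area_max")
        if self.cell_ratio_min < 0 or self.nucleus_area_min < 0 or self.nucleus_ratio_min < 0:
            raise ValueError("criteria must be non-negative")


@dataclass
class MyocyteRecord:
    """A segmented particle with its QC verdict and any qualifying nuclei."""

    cell: ParticleMask
    shape: ShapeMetrics
    nuclei: list[tuple[ParticleMask, ShapeMetrics]] = field(default_factory=list)
    accepted: bool = False
    rejection_reason: str | None = None


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any())


def _resolve_threshold(image: np.ndarray, threshold_spec) -> float | None:
    """Resolve a threshold spec to an intensity value.

    ``"otsu"`` applies Otsu's method twice: a first pass separates the bright
    Hoechst nuclei from everything else, a second pass on the sub-nuclear
    intensity range separates weak cell-body autofluorescence from background.
    Returns None when the image is too degenerate to threshold.
    """
    if isinstance(threshold_spec, (int, float)) and not isinstance(threshold_spec, bool):
        return float(threshold_spec)
    if threshold_spec != "otsu":
        raise ValueError(f"unknown threshold spec: {threshold_spec!r}")
    if np.unique(image).size < 2:
        return None
    t_hi = threshold_otsu(image)
    sub = image[image < t_hi]
    if sub.size >= 2 and np.unique(sub).size >= 2:
        return float(threshold_otsu(sub))
    return float(t_hi)


def segment_cells(
    field: ImageField,
    threshold_spec="otsu",
    min_object_area: float = 50.0,
) -> list[ParticleMask]:
    """Detect candidate cell particles from the 405-nm channel.

    Above-threshold pixels are hole-filled (nuclei are brighter than the
    threshold and lie inside cells, so filling is a no-op for them but closes
    genuine holes), despeckled by removing components smaller than
    ``min_object_area`` (um^2), and labelled.  Border contact is recorded on
    each particle.
    """
    field.validate()
    img = np.asarray(field.channel_405, dtype=float)
    thr = _resolve_threshold(img, threshold_spec)
    if thr is None:
        return []
    binary = img > thr
    if not binary.any():
        return []
    binary = ndimage.binary_fill_holes(binary)
    labels = sk_label(binary, connectivity=2)
    min_px = int(np.ceil(min_object_area / field.pixel_size**2))
    particles: list[ParticleMask] = []
    out_label = 0
    for prop in regionprops(labels):
        if prop.num_pixels < min_px:
            continue
        mask = labels == prop.label
        out_label += 1
        particles.append(
            ParticleMask(
                mask=mask,
                label=out_label,
                bbox=tuple(prop.bbox),
                touches_border=_touches_border(mask),
            )
        )
    return particles


def measure_shape(mask, pixel_size: float) -> ShapeMetrics:
    """Area and moment-ellipse axes of a mask, converted to um.

    Degenerate masks (single pixel, or a perfect line whose minor moment axis
    is zero) have both axes floored at one pixel width so the axis ratio is
    always defined.
    """
    arr = mask.mask if isinstance(mask, ParticleMask) else np.asarray(mask, dtype=bool)
    if not arr.any():
        raise SegmentationError("cannot measure an empty mask")
    prop = regionprops(arr.astype(np.uint8))[0]
    area = float(prop.num_pixels) * pixel_size**2
    long_axis = max(float(prop.axis_major_length), 1.0) * pixel_size
    short_axis = max(float(prop.axis_minor_length), 1.0) * pixel_size
    return ShapeMetrics(area=area, long_axis=long_axis, short_axis=short_axis)


def filter_rod_myocytes(
    particles: Sequence[tuple[ParticleMask, ShapeMetrics]],
    criteria: FilterCriteria | None = None,
) -> tuple[list[MyocyteRecord], list[MyocyteRecord]]:
    """Split measured particles into accepted rod-shaped myocytes and rejects.

    A particle is accepted iff it does not touch the field border, its area
    lies within [cell_area_min, cell_area_max] (inclusive) and its long/short
    axis ratio is >= cell_ratio_min.  The first failing criterion, in the
    order border, area, ratio, is recorded as the rejection reason.
    """
    criteria = criteria or FilterCriteria()
    criteria.validate()
    accepted: list[MyocyteRecord] = []
    rejected: list[MyocyteRecord] = []
    for particle, shape in particles:
        reason = None
        if particle.touches_border:
            reason = REASON_BORDER
        elif not (criteria.cell_area_min <= shape.area <= criteria.cell_area_max):
            reason = REASON_AREA
        elif shape.axis_ratio < criteria.cell_ratio_min:
            reason = REASON_RATIO
        record = MyocyteRecord(
            cell=particle, shape=shape, accepted=reason is None, rejection_reason=reason
        )
        (accepted if record.accepted else rejected).append(record)
    return accepted, rejected


def nucleus_passes(shape: ShapeMetrics, criteria: FilterCriteria) -> bool:
    """Strict nuclear criteria: area > 30 um^2 and axis ratio > 3 (defaults)."""
    return shape.area > criteria.nucleus_area_min and shape.axis_ratio > criteria.nucleus_ratio_min


def segment_nuclei(
    field: ImageField,
    cell: ParticleMask,
    criteria: FilterCriteria | None = None,
    threshold: float | None = None,
) -> list[tuple[ParticleMask, ShapeMetrics]]:
    """Nuclear masks within one cell, from the Hoechst signal in the 405 channel.

    Within-cell pixels above the nuclear threshold (Otsu on the within-cell
    intensities unless a fixed value is given) are labelled; components are
    kept only if they pass the strict nuclear size/ratio criteria.  An empty
    result is valid: downstream nuclear statistics are then missing, not zero.
    """
    criteria = criteria or FilterCriteria()
    img = np.asarray(field.channel_405, dtype=float)
    inside = img[cell.mask]
    if threshold is None:
        if np.unique(inside).size < 2:
            return []
        threshold = float(threshold_otsu(inside))
    nuc_binary = (img > threshold) & cell.mask
    if not nuc_binary.any():
        return []
    labels = sk_label(nuc_binary, connectivity=2)
    nuclei: list[tuple[ParticleMask, ShapeMetrics]] = []
    for prop in regionprops(labels):
        mask = labels == prop.label
        shape = measure_shape(mask, field.pixel_size)
        if nucleus_passes(shape, criteria):
            nuclei.append(
                (
                    ParticleMask(
                        mask=mask,
                        label=prop.label,
                        bbox=tuple(prop.bbox),
                        touches_border=_touches_border(mask),
                    ),
                    shape,
                )
            )
    return nuclei


def analyze_field(
    field: ImageField,
    criteria: FilterCriteria | None = None,
    cell_threshold="otsu",
    nuclear_threshold: float | None = None,
    min_object_area: float = 50.0,
) -> list[MyocyteRecord]:
    """Full per-field segmentation: cells, shape QC, then nuclei for accepted cells.

    Returns all records (accepted and rejected); nuclei are segmented only for
    accepted cells.
    """
    criteria = criteria or FilterCriteria()
    particles = segment_cells(field, threshold_spec=cell_threshold, min_object_area=min_object_area)
    measured = [(p, measure_shape(p, field.pixel_size)) for p in particles]
    accepted, rejected = filter_rod_myocytes(measured, criteria)
    for record in accepted:
        record.nuclei = segment_nuclei(field, record.cell, criteria, threshold=nuclear_threshold)
    records = accepted + rejected
    records.sort(key=lambda r: r.cell.label)
    return records


def records_to_table(records: Sequence[MyocyteRecord], field: ImageField) -> list[dict]:
    """Flatten records to one dict per particle (for the per-particle CSV)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "heart_id": field.heart_id,
                "treatment": field.treatment,
                "session_id": field.session_id,
                "label": rec.cell.label,
                "area_um2": rec.shape.area,
                "long_axis_um": rec.shape.long_axis,
                "short_axis_um": rec.shape.short_axis,
                "axis_ratio": rec.shape.axis_ratio,
                "touches_border": rec.cell.touches_border,
                "n_nuclei": len(rec.nuclei),
                "accepted": rec.accepted,
                "rejection_reason": rec.rejection_reason or "",
            }
        )
    return rows


def record_as_dict(record: MyocyteRecord) -> dict:
    return dataclasses.asdict(record)
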