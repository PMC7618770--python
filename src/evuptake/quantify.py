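"""Per-cell intensity and texture readouts of the 488-nm NeonGreen2 channel.

For each accepted myocyte: the mean cytoplasmic signal (cell minus nuclei),
its grey-level co-occurrence matrix (GLCM) homogeneity, and the mean nuclear
signal.  Homogeneity is

    Homogeneity = sum_{i,j} P(i,j) / (1 + |i - j|)

where P is the pair-probability matrix over quantized grey levels, masked to
the region of interest and normalized to sum to 1.  A readout of 1 indicates a
perfectly uniform texture; lower values indicate heterogeneity.  Intensities
are quantized per-region between the masked minimum and maximum, which makes
homogeneity invariant to intensity rescaling — it measures texture, not
brightness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .segmentation import ImageField, MyocyteRecord

__all__ = [
    "DegenerateRegionError",
    "GLCMParams",
    "GLCMatrix",
    "CellMeasurement",
    "mean_intensity",
    "quantize",
    "build_glcm",
    "homogeneity",
    "measure_cell",
    "measure_field",
]

logger = logging.getLogger(__name__)


class DegenerateRegionError(ValueError):
    """Raised when a mask admits no valid pixel pair under the given offsets."""


@dataclass
class GLCMParams:
    """GLCM construction parameters.

    Default: 32 grey levels; the four unit displacements (right, down,
    down-right, down-left) accumulated into one matrix; symmetric counting.
    """

    n_levels: int = 32
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
    symmetric: bool = True

    def validate(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least 2 grey levels")
        if not self.offsets:
            raise ValueError("need at least one offset")
        if any(dr == 0 and dc == 0 for dr, dc in self.offsets):
            raise ValueError("zero offset is not a neighbour relation")


@dataclass
class GLCMatrix:
    """Normalized pair-probability matrix P(i,j) over ``n_levels`` grey levels."""

    p: np.ndarray
    n_levels: int
    params: GLCMParams = dc_field(default_factory=GLCMParams)

    def validate(self) -> None:
        if self.p.shape != (self.n_levels, self.n_levels):
            raise ValueError("P must be n_levels x n_levels")
        if np.any(self.p < 0):
            raise ValueError("P must be non-negative")
        if abs(float(self.p.sum()) - 1.0) > 1e-12:
            raise ValueError("P must sum to 1")
        if self.params.symmetric and not np.allclose(self.p, self.p.T):
            raise ValueError("symmetric GLCM must equal its transpose")


@dataclass
class CellMeasurement:
    """Per-cell readouts with hierarchy keys (nuclear_mean is NaN when missing)."""

    heart_id: str
    treatment: str
    cell_label: int
    cytoplasmic_mean: float
    cytoplasmic_homogeneity: float
    nuclear_mean: float
    n_nuclei: int
    session_id: str = ""


def mean_intensity(image: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of masked pixels; NaN for an empty mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return float("nan")
    return float(np.asarray(image, dtype=float)[mask].mean())


def quantize(image: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Linear min-max quantization of masked intensities to levels 0..n_levels-1.

    A constant region maps every pixel to the first level.  Values outside the
    mask are left at 0 and must never be read.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    levels = np.zeros(image.shape, dtype=np.intp)
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        scaled = (image[mask] - lo) / (hi - lo) * n_levels
        levels[mask] = np.minimum(scaled.astype(np.intp), n_levels - 1)
    return levels


def build_glcm(
    image: np.ndarray, mask: np.ndarray, params: GLCMParams | None = None
) -> GLCMatrix:
    """Co-occurrence counts over masked pixel pairs, normalized to sum 1.

    A pair is counted only when BOTH pixels lie in the mask (pairs crossing
    the mask boundary are dropped — the mask eliminates background).  Counts
    from all offsets are accumulated into one matrix and symmetrized when
    requested.
    """
    params = params or GLCMParams()
    params.validate()
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise DegenerateRegionError("mask needs at least 2 pixels")
    n = params.n_levels
    levels = quantize(image, mask, n)
    counts = np.zeros((n, n), dtype=np.int64)
    h, w = mask.shape
    for dr, dc in params.offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a_mask = mask[r0:r1, c0:c1]
        b_mask = mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = a_mask & b_mask
        a = levels[r0:r1, c0:c1][valid]
        b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc][valid]
        counts += np.bincount(a * n + b, minlength=n * n).reshape(n, n)
    if params.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DegenerateRegionError("no in-mask pixel pair under the given offsets")
    glcm = GLCMatrix(p=counts / total, n_levels=n, params=params)
    glcm.validate()
    return glcm


def homogeneity(glcm: GLCMatrix) -> float:
    """Homogeneity = sum_{i,j} P(i,j)/(1+|i-j|); 1 iff all mass is diagonal."""
    glcm.validate()
    idx = np.arange(glcm.n_levels)
    weights = 1.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]))
    return float((glcm.p * weights).sum())


def measure_cell(
    record: MyocyteRecord,
    field: ImageField,
    params: GLCMParams | None = None,
) -> CellMeasurement | None:
    """Cytoplasmic mean + homogeneity and nuclear mean on the 488 channel.

    The cytoplasmic mask is the cell mask minus all qualifying nuclear pixels
    (pooled).  If the cytoplasmic mask is empty, the cell is skipped with a
    logged warning.  The nuclear mean is NaN when no nucleus qualified.
    """
    if not record.accepted:
        raise ValueError("measure_cell expects an accepted myocyte record")
    params = params or GLCMParams()
    nuclear_mask = np.zeros_like(record.cell.mask)
    for nuc, _shape in record.nuclei:
        nuclear_mask |= nuc.mask
    cyto_mask = record.cell.mask & ~nuclear_mask
    if not cyto_mask.any():
        logger.warning(
            "cell %s in heart %s has an empty cytoplasmic mask; skipped",
            record.cell.label,
            field.heart_id,
        )
        return None
    ch = field.channel_488
    return CellMeasurement(
        heart_id=field.heart_id,
        treatment=field.treatment,
        session_id=field.session_id,
        cell_label=record.cell.label,
        cytoplasmic_mean=mean_intensity(ch, cyto_mask),
        cytoplasmic_homogeneity=homogeneity(build_glcm(ch, cyto_mask, params)),
        nuclear_mean=mean_intensity(ch, nuclear_mask) if nuclear_mask.any() else float("nan"),
        n_nuclei=len(record.nuclei),
    )


def measure_field(
    records, field: ImageField, params: GLCMParams | None = None
) -> list[CellMeasurement]:
    """Measure every accepted record in a field, skipping degenerate cells."""
    out = []
    for rec in records:
        if not rec.accepted:
            continue
        m = measure_cell(rec, field, params)
        if m is not None:
            out.append(m)
    return out
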