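"""Tissue-section compartment analysis.

Immunostained sections carry three channels: DAPI (nuclei), sarcomeric
alpha-actinin (cardiomyocyte bodies) and the red NeonGreen2 immunostain.  The
red signal is profiled by compartment: nuclear (DAPI-positive), cytoplasmic
(actinin-positive minus nuclear) and extracellular (the remainder).  The three
masks always partition the field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["CompartmentMasks", "CompartmentProfile", "compartment_masks", "compartment_profile"]

COMPARTMENTS = ("extracellular", "cytoplasmic", "nuclear")


@dataclass
class CompartmentMasks:
    extracellular: np.ndarray
    cytoplasmic: np.ndarray
    nuclear: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "extracellular": self.extracellular,
            "cytoplasmic": self.cytoplasmic,
            "nuclear": self.nuclear,
        }

    def validate(self) -> None:
        total = (
            self.extracellular.astype(int) + self.cytoplasmic.astype(int) + self.nuclear.astype(int)
        )
        if not np.all(total == 1):
            raise ValueError("compartment masks must partition the field")


@dataclass
class CompartmentProfile:
    """Per-compartment pixel counts, mean red intensity and histograms (shared bins)."""

    pixel_counts: dict[str, int]
    means: dict[str, float]  # NaN for an empty compartment
    histograms: dict[str, np.ndarray]
    bin_edges: np.ndarray


def _channel_mask(channel: np.ndarray, threshold) -> np.ndarray:
    channel = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite pixels")
    if threshold is None or threshold == "otsu":
        if np.unique(channel).size < 2:
            return np.zeros(channel.shape, dtype=bool)
        threshold = threshold_otsu(channel)
    return channel > float(threshold)


def compartment_masks(
    dapi: np.ndarray,
    actinin: np.ndarray,
    dapi_threshold=None,
    actinin_threshold=None,
) -> CompartmentMasks:
    """Disjoint nuclear / cytoplasmic / extracellular masks from DAPI and actinin.

    Each channel is binarized (Otsu by default, fixed values overridable):
    nuclear = DAPI-above-threshold, cytoplasmic = actinin-above-threshold
    minus nuclear, extracellular = remainder.
    """
    dapi = np.asarray(dapi, dtype=float)
    actinin = np.asarray(actinin, dtype=float)
    if dapi.shape != actinin.shape:
        raise ValueError("channel shapes differ")
    nuclear = _channel_mask(dapi, dapi_threshold)
    cyto = _channel_mask(actinin, actinin_threshold) & ~nuclear
    extracellular = ~(nuclear | cyto)
    masks = CompartmentMasks(extracellular=extracellular, cytoplasmic=cyto, nuclear=nuclear)
    masks.validate()
    return masks


def compartment_profile(
    red: np.ndarray,
    masks: CompartmentMasks,
    bin_edges: np.ndarray | None = None,
    n_bins: int = 64,
) -> CompartmentProfile:
    """Mean and histogram of the red channel per compartment, over shared bins.

    Bin edges default to ``n_bins`` equal bins over the red channel's global
    range so histograms are directly comparable across compartments.  An empty
    compartment reports a missing (NaN) mean and a zero histogram.
    """
    red = np.asarray(red, dtype=float)
    if not np.all(np.isfinite(red)):
        raise ValueError("red channel contains non-finite pixels")
    masks.validate()
    if bin_edges is None:
        lo, hi = float(red.min()), float(red.max())
        if hi <= lo:
            hi = lo + 1.0
        bin_edges = np.linspace(lo, hi, n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)

    counts: dict[str, int] = {}
    means: dict[str, float] = {}
    hists: dict[str, np.ndarray] = {}
    for name, mask in masks.as_dict().items():
        vals = red[mask]
        counts[name] = int(mask.sum())
        means[name] = float(vals.mean()) if vals.size else float("nan")
        hists[name], _ = np.histogram(vals, bins=bin_edges)
    return CompartmentProfile(
        pixel_counts=counts, means=means, histograms=hists, bin_edges=bin_edges
    )
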