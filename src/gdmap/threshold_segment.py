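"""Symmetric-histogram statistics and seeded contrast segmentation.

Contrast shortens T1, so a tissue's post-delivery T1 histogram has a
contaminated left tail.  The symmetric-histogram construction estimates the
native-tissue spread from the clean right half only: the values at or above
the histogram peak are mirrored about the peak, and the standard deviation of
that mirrored sample stands in for the native SD.  The segmentation threshold
is one SD below the peak; voxels at or below it are candidate contrast.

Segmentation then keeps only candidates connected (face or full connectivity)
to the implant, together with NA voxels inside the tissue — cement and very
high concentrations both fit as NA — mirroring a seeded region grow from the
implant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_model import BinaryMask, T1Map

__all__ = [
    "SymmetricHistogramStats",
    "ContrastRegion",
    "symmetric_histogram",
    "tissue_threshold",
    "segment_contrast",
]


@dataclass(frozen=True)
class SymmetricHistogramStats:
    """Mode, mirrored-sample SD and the derived segmentation threshold (ms).

    ``threshold == peak_t1 - sigma`` holds exactly.  ``mean_t1`` is the mean
    of the mirrored sample (equal to the peak by construction up to float
    rounding); it is the statistic used for concentration sensitivity
    analysis, while ``peak_t1`` is used for thresholding.
    """

    peak_t1: float
    sigma: float
    threshold: float
    bin_width: float
    n_voxels: int
    mean_t1: float

    def __post_init__(self) -> None:
        if self.threshold != self.peak_t1 - self.sigma:
            raise ValueError("threshold must equal peak_t1 - sigma exactly")

    @classmethod
    def from_peak_sigma(
        cls, peak_t1: float, sigma: float, bin_width: float = 50.0, n_voxels: int = 0
    ) -> "SymmetricHistogramStats":
        """Stats object from externally known peak and SD (e.g. a published
        precontrast tissue distribution); the threshold is derived."""
        return cls(
            peak_t1=float(peak_t1),
            sigma=float(sigma),
            threshold=float(peak_t1) - float(sigma),
            bin_width=float(bin_width),
            n_voxels=int(n_voxels),
            mean_t1=float(peak_t1),
        )


def symmetric_histogram(values, bin_width: float = 50.0) -> SymmetricHistogramStats:
    """Build symmetric-histogram statistics from a sample of T1 values (ms).

    The histogram uses bins of ``bin_width`` anchored at integer multiples of
    the width; the peak is the center of the fullest bin (ties break toward
    the lower bin).  The mirrored sample is
    ``{v : v >= peak} ∪ {2*peak - v : v >= peak}`` and sigma is its sample
    standard deviation computed from the raw values, not from binned counts.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if np.unique(values).size < 2:
        raise ValueError("need at least 2 distinct finite values")
    # bins anchored at the sample minimum, so the statistics are invariant
    # under shifting every value by a constant
    lo = float(values.min())
    nbins = max(1, int(np.ceil((values.max() - lo) / bin_width)))
    counts, edges = np.histogram(values, bins=nbins, range=(lo, lo + nbins * bin_width))
    peak_bin = int(np.argmax(counts))  # argmax returns the first (lowest) maximal bin
    peak = float(0.5 * (edges[peak_bin] + edges[peak_bin + 1]))

    upper = values[values >= peak]
    mirrored = np.concatenate([upper, 2.0 * peak - upper])
    sigma = float(np.std(mirrored, ddof=1))
    mean = float(np.mean(mirrored))
    return SymmetricHistogramStats(
        peak_t1=peak,
        sigma=sigma,
        threshold=peak - sigma,
        bin_width=float(bin_width),
        n_voxels=int(values.size),
        mean_t1=mean,
    )


def tissue_threshold(
    t1_map: T1Map, tissue_mask: BinaryMask, bin_width: float = 50.0
) -> SymmetricHistogramStats:
    """Symmetric-histogram stats over the defined T1 values inside a tissue.

    For the intramedullary canal the stats should come from the contralateral
    canal without contrast; pass that canal's mask here.
    """
    if t1_map.shape != tissue_mask.shape:
        raise ValueError("T1 map and tissue mask shapes differ")
    sel = tissue_mask.mask & t1_map.defined()
    if not sel.any():
        raise ValueError("tissue mask selects no defined T1 voxels")
    return symmetric_histogram(t1_map.t1[sel], bin_width=bin_width)


@dataclass(frozen=True)
class ContrastRegion:
    """Implant plus every connected subthreshold/NA voxel in its tissue."""

    mask: BinaryMask
    implant_mask: BinaryMask
    tissue: str = "muscle"


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def segment_contrast(
    t1_map: T1Map,
    stats: SymmetricHistogramStats,
    tissue_mask: BinaryMask,
    implant_mask: BinaryMask,
    connectivity: int = 6,
    tissue: str = "muscle",
) -> ContrastRegion:
    """Extract the contrast region connected to the implant.

    Candidate voxels are the implant itself plus any voxel inside the tissue
    whose T1 is defined and at or below ``stats.threshold``, or whose T1 is
    NA (cement / high-concentration artifact).  The returned region is the
    union of connected components of the candidate set that touch the
    implant.
    """
    if implant_mask.n_voxels == 0:
        raise ValueError("implant mask is empty")
    if not (t1_map.shape == tissue_mask.shape == implant_mask.shape):
        raise ValueError("geometry mismatch between map and masks")
    sub = np.zeros(t1_map.shape, dtype=bool)
    defined = t1_map.defined()
    sub[defined] = t1_map.t1[defined] <= stats.threshold
    candidates = implant_mask.mask | (tissue_mask.mask & (sub | t1_map.na_mask))
    labels, _n = ndimage.label(candidates, structure=_structure(connectivity))
    seed_labels = np.unique(labels[implant_mask.mask])
    seed_labels = seed_labels[seed_labels > 0]
    region = np.isin(labels, seed_labels)
    return ContrastRegion(
        mask=BinaryMask(region, t1_map.spacing, t1_map.origin),
        implant_mask=implant_mask,
        tissue=tissue,
    )
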