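"""Otsu-masked fluorescence quantification and cell-count ratios.

The workflow follows marker-in-mask intensity analysis: a binary mask of
marker-positive pixels (e.g. GFAP for astrocytes, Iba1 for microglia) is
built from the mask channel with Otsu's method, then the mean, median,
standard deviation and signal-to-noise ratio of a second marker (e.g.
S100A10, iNOS) are computed over the masked pixels.  Thresholding always
uses a 256-bin histogram with intensities rescaled to [0, 255], so 8-bit and
16-bit inputs are treated identically.

SNR is defined as (in-mask mean - out-of-mask mean) / out-of-mask SD, the
standard contrast-to-noise form, computable from the image pair alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

__all__ = [
    "FluorescenceImage",
    "MaskStats",
    "ViabilityCount",
    "otsu_threshold",
    "otsu_mask",
    "masked_intensity_stats",
    "count_nuclei",
    "viability",
    "marker_positive_fraction",
]

N_BINS = 256


@dataclass(frozen=True)
class FluorescenceImage:
    """Aligned mask / target / nuclei channel triple for one field of view."""

    mask_channel: np.ndarray
    target_channel: np.ndarray
    nuclei_channel: np.ndarray | None = None
    bit_depth: int = 16
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        m = np.asarray(self.mask_channel, dtype=float)
        t = np.asarray(self.target_channel, dtype=float)
        if m.ndim != 2 or t.shape != m.shape:
            raise ValueError("mask and target channels must be 2-D and same shape")
        if self.nuclei_channel is not None:
            n = np.asarray(self.nuclei_channel, dtype=float)
            if n.shape != m.shape:
                raise ValueError("nuclei channel must match the other channels")
            object.__setattr__(self, "nuclei_channel", n)
        object.__setattr__(self, "mask_channel", m)
        object.__setattr__(self, "target_channel", t)


@dataclass(frozen=True)
class MaskStats:
    """Within-mask intensity statistics of the target channel."""

    threshold: float
    mask_fraction: float
    mean: float
    median: float
    sd: float
    snr: float


@dataclass(frozen=True)
class ViabilityCount:
    """Dead-cell ratio from PI-positive vs total (Hoechst) counts."""

    total: int
    dead: int

    def __post_init__(self):
        if self.total <= 0:
            raise ValueError("total count must be positive")
        if not 0 <= self.dead <= self.total:
            raise ValueError("dead count must lie in [0, total]")

    @property
    def proportion_dead(self) -> float:
        return self.dead / self.total

    @property
    def proportion_alive(self) -> float:
        return 1.0 - self.proportion_dead


def _histogram_256(channel: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """256-bin histogram of intensities rescaled to [0, 255]."""
    x = np.asarray(channel, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("constant image: no threshold exists")
    scaled = (x - lo) * (255.0 / (hi - lo))
    counts = np.bincount(
        np.clip(scaled.astype(np.int64), 0, 255).ravel(), minlength=N_BINS
    )
    centers = np.arange(N_BINS, dtype=float)
    return counts.astype(float), centers, lo, hi


def otsu_threshold(channel: np.ndarray) -> float:
    """Otsu's threshold: the 256-bin split maximizing between-class variance.

    Returns the threshold on the original intensity scale; pixels strictly
    above it form the mask.  Between-class variance is
    ``w0 * w1 * (mu0 - mu1)^2`` evaluated at every bin boundary; ties go to
    the lowest bin.
    """
    counts, centers, lo, hi = _histogram_256(channel)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m0 = np.cumsum(counts * centers)
    total_m = m0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (total_m - m0) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between[:-1], nan=0.0)  # split after bin k
    k = int(np.argmax(var_between))
    # Bin-edge threshold mapped back to the original scale.
    return lo + (k + 0.5) * (hi - lo) / 255.0


def otsu_mask(channel: np.ndarray) -> np.ndarray:
    """Boolean marker-positive mask: pixels above the Otsu threshold."""
    return np.asarray(channel, dtype=float) > otsu_threshold(channel)


def masked_intensity_stats(image: FluorescenceImage) -> MaskStats:
    """Quantify the target channel inside the Otsu mask of the mask channel.

    Raises if the mask is empty or covers the whole image, since the SNR
    needs a non-empty background.
    """
    thr = otsu_threshold(image.mask_channel)
    mask = image.mask_channel > thr
    n_in = int(mask.sum())
    if n_in == 0:
        raise ValueError(f"empty Otsu mask (threshold {thr:.3g}); check the mask channel")
    inside = image.target_channel[mask]
    outside = image.target_channel[~mask]
    if outside.size == 0:
        raise ValueError("mask covers the whole image; background undefined")
    bg_sd = float(outside.std())
    snr = float((inside.mean() - outside.mean()) / bg_sd) if bg_sd > 0 else np.inf
    return MaskStats(
        threshold=float(thr),
        mask_fraction=n_in / mask.size,
        mean=float(inside.mean()),
        median=float(np.median(inside)),
        sd=float(inside.std()),
        snr=snr,
    )


def count_nuclei(nuclei_channel: np.ndarray, min_size: int = 20) -> int:
    """Count nuclei as connected components of the Otsu-binarized channel.

    Components smaller than ``min_size`` pixels are treated as noise.
    A blank (constant) channel counts as zero nuclei.
    """
    x = np.asarray(nuclei_channel, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        return 0
    labels = measure.label(otsu_mask(x))
    sizes = np.bincount(labels.ravel())[1:]  # skip background label 0
    return int(np.count_nonzero(sizes >= min_size))


def viability(total: int, dead: int) -> ViabilityCount:
    """Proportion of dead cells: PI-positive count over total nuclei count."""
    return ViabilityCount(total=total, dead=dead)


def marker_positive_fraction(positive: int, total: int) -> float:
    """Fraction of marker-positive cells among all counted cells."""
    if total <= 0:
        raise ValueError("total count must be positive")
    if not 0 <= positive <= total:
        raise ValueError("positive count must lie in [0, total]")
    return positive / total
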