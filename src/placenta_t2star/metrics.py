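"""Derived placental measures from a T2* map and a binary mask.

The metric suite:

mean T2*, skewness, excess kurtosis
    Histogram statistics of the valid fitted T2* values inside the mask.
volume (ml)
    Mask voxel count times the voxel volume.
morphological map (mm)
    Per placental voxel, the Euclidean distance to the nearest
    non-placental voxel (center-to-center, anisotropy-aware; the grid
    border counts as non-placental).
non-uniformity (mm, reported as a.u.)
    Mean plus standard deviation of the morphological-map values — a
    shape-regularity score: thin, ragged placentas score low.
maximal thickness (mm)
    Twice the maximum of the morphological map.

Morphology and volume are properties of the segmentation alone, so voxels
whose T2* fit failed still count there; they are excluded only from the
histogram statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import PlacentaMask
from .relaxometry import T2StarMap

__all__ = [
    "MorphMap",
    "PlacentalMetrics",
    "compute_volume",
    "histogram_stats",
    "morphological_map",
    "non_uniformity",
    "max_thickness",
    "compute_all",
]

#: Minimum number of valid voxels for meaningful histogram statistics.
MIN_HISTOGRAM_VOXELS = 8


@dataclass
class MorphMap:
    """Distance (mm) from each placental voxel to the nearest non-placental
    voxel; NaN outside the placenta."""

    distance_mm: np.ndarray
    voxel_dims_mm: tuple[float, float, float]

    def values(self) -> np.ndarray:
        vals = self.distance_mm[np.isfinite(self.distance_mm)]
        if vals.size == 0:
            raise ValueError("morphological map is empty")
        return vals


@dataclass
class PlacentalMetrics:
    mean_t2star_ms: float
    skewness: float
    kurtosis: float
    volume_ml: float
    non_uniformity: float
    max_thickness_mm: float
    n_voxels: int
    n_valid_fit_voxels: int
    degenerate_histogram: bool = False

    def as_dict(self) -> dict:
        return {
            "mean_t2star_ms": self.mean_t2star_ms,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "volume_ml": self.volume_ml,
            "non_uniformity": self.non_uniformity,
            "max_thickness_mm": self.max_thickness_mm,
            "n_voxels": self.n_voxels,
            "n_valid_fit_voxels": self.n_valid_fit_voxels,
            "degenerate_histogram": self.degenerate_histogram,
        }


def compute_volume(mask: PlacentaMask) -> float:
    """Mask voxel count x voxel volume, in ml (1 ml = 1000 mm^3)."""
    mask.require_nonempty()
    return mask.n_voxels * mask.voxel_volume_mm3 / 1000.0


def histogram_stats(
    t2map: T2StarMap, mask: PlacentaMask
) -> tuple[float, float, float, int, bool]:
    """Mean, skewness and excess (Fisher) kurtosis of valid masked T2*.

    Returns ``(mean, skewness, kurtosis, n_valid, degenerate)``. Moments
    use the population (divide-by-n) convention. A zero-variance sample is
    degenerate: skewness and kurtosis are reported as 0 with the flag set.
    """
    if t2map.t2star_ms.shape != mask.data.shape:
        raise ValueError("T2* map and mask grids differ")
    vals = t2map.valid_values(mask.data)
    if vals.size < MIN_HISTOGRAM_VOXELS:
        raise ValueError(
            f"only {vals.size} valid voxels inside the mask; "
            f"need at least {MIN_HISTOGRAM_VOXELS}"
        )
    mean = float(vals.mean())
    # numerically constant samples have undefined shape moments
    if np.std(vals) <= 1e-10 * max(1.0, abs(mean)):
        return mean, 0.0, 0.0, int(vals.size), True
    skew = float(stats.skew(vals, bias=True))
    kurt = float(stats.kurtosis(vals, fisher=True, bias=True))
    return mean, skew, kurt, int(vals.size), False


def morphological_map(mask: PlacentaMask) -> MorphMap:
    """Euclidean distance transform of the mask in millimetres.

    Center-to-center convention: an isolated voxel lies one voxel spacing
    from the background. The array border is treated as non-placental, so
    masks touching the edge stay bounded.
    """
    mask.require_nonempty()
    padded = np.pad(mask.data, 1)  # border = background
    dist = ndimage.distance_transform_edt(padded, sampling=mask.voxel_dims_mm)
    dist = dist[1:-1, 1:-1, 1:-1]
    out = np.where(mask.data, dist, np.nan)
    return MorphMap(distance_mm=out, voxel_dims_mm=mask.voxel_dims_mm)


def non_uniformity(morph: MorphMap, ddof: int = 0) -> float:
    """mean + SD of the morphological-map values (population SD by
    default; ``ddof=1`` switches to the sample convention)."""
    vals = morph.values()
    return float(vals.mean() + vals.std(ddof=ddof))


def max_thickness(morph: MorphMap) -> float:
    """2 x the maximum inscribed distance — the organ's maximal thickness."""
    return float(2.0 * morph.values().max())


def compute_all(t2map: T2StarMap, mask: PlacentaMask) -> PlacentalMetrics:
    """Aggregate the full metric suite for one scan."""
    mean, skew, kurt, n_valid, degenerate = histogram_stats(t2map, mask)
    morph = morphological_map(mask)
    return PlacentalMetrics(
        mean_t2star_ms=mean,
        skewness=skew,
        kurtosis=kurt,
        volume_ml=compute_volume(mask),
        non_uniformity=non_uniformity(morph),
        max_thickness_mm=max_thickness(morph),
        n_voxels=mask.n_voxels,
        n_valid_fit_voxels=n_valid,
        degenerate_histogram=degenerate,
    )
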