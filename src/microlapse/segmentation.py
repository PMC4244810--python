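"""Brightfield microcolony segmentation and per-object measurement.

Foreground objects are pixels significantly darker than the local background
(cells appear dark on a light field).  Areas are counted in raw pixels, so
interior holes of rough colonies are excluded from the area by construction;
``filled_area`` additionally counts hole pixels.  PI positivity is scored
against robust background statistics of the fluorescence channel, because a
healthy field may contain no PI signal at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .config import AnalysisConfig, SegmentationConfig

__all__ = ["ObjectMeasure", "segment_brightfield", "measure_objects",
           "pi_positive_pixels"]

#: a LabelMask is a 2-D int array; 0 = background, labels contiguous 1..K
LabelMask = np.ndarray


@dataclass(frozen=True)
class ObjectMeasure:
    """Geometry and PI score of one labelled object."""

    label: int
    area: int          # pixels, holes excluded
    filled_area: int   # pixels, holes included
    centroid: tuple[float, float]
    major_axis_length: float
    mean_pi: float
    pi_positive: bool

    def __post_init__(self) -> None:
        if self.area <= 0 or self.area > self.filled_area:
            raise ValueError("need 0 < area <= filled_area")


def _robust_sigma(values: np.ndarray) -> float:
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def segment_brightfield(image: np.ndarray, config: AnalysisConfig | SegmentationConfig) -> LabelMask:
    """Segment dark foreground objects from a brightfield frame.

    Returns an 8-connected label mask with contiguous labels 1..K.  Interior
    holes are deliberately not filled.  Blank or saturated frames yield an
    empty mask with a warning, never an exception.
    """
    cfg = config.segmentation if isinstance(config, AnalysisConfig) else config
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    # depth below background; cells are dark on a light field, and colonies
    # can cover most of a late frame, so the background level is taken from a
    # high percentile rather than the median.  Subtracting it makes the mask
    # invariant to a constant intensity shift.
    inv = np.percentile(img, 90) - img
    if np.ptp(inv) == 0:
        warnings.warn("blank or saturated frame: empty segmentation", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)

    if cfg.fixed_threshold is not None:
        thr = float(cfg.fixed_threshold)
    else:
        thr = float(threshold_otsu(inv))
        fg = inv > thr
        # Otsu needs a substantial dark class; when the foreground is absent
        # or only a few cells, it just splits the background noise in half.
        # Detect that (no significant depth separation) and fall back to a
        # robust-background tail threshold, which handles sparse frames and
        # leaves truly blank frames empty.
        sep = (float(np.median(inv[fg]) - np.median(inv[~fg]))
               if fg.any() and not fg.all() else 0.0)
        if sep < cfg.min_depth_sigmas * _robust_sigma(inv[~fg] if fg.any() else inv):
            thr = float(np.median(inv)) + cfg.min_depth_sigmas * _robust_sigma(inv)
    fg = inv > thr
    lbl = sk_label(fg, connectivity=2)
    counts = np.bincount(lbl.ravel())
    keep = counts >= cfg.min_object_size
    keep[0] = False
    remap = np.zeros(len(counts), dtype=np.int32)
    remap[keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
    out = remap[lbl]
    if out.max() == 0:
        warnings.warn("frame segmented empty", stacklevel=2)
    return out


def pi_positive_pixels(pi_image: np.ndarray, k: float = 6.0,
                       background: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of pixels with PI signal above background median + k*MAD.

    ``background`` optionally restricts the background statistics to the
    given pixels (e.g. outside segmented colonies).
    """
    pi = np.asarray(pi_image, dtype=float)
    bg = pi if background is None else pi[background]
    med = float(np.median(bg))
    sigma = max(_robust_sigma(bg), 0.5)
    return pi > med + k * sigma


def measure_objects(mask: LabelMask, pi_image: np.ndarray,
                    config: AnalysisConfig | None = None) -> list[ObjectMeasure]:
    """Measure every labelled object: pixel areas (holes excluded), the
    hole-filled area, centroid, major axis, and the PI-positivity flag."""
    k = config.pi_k if config is not None else 6.0
    pi = np.asarray(pi_image, dtype=float)
    if mask.shape != pi.shape:
        raise ValueError(f"mask shape {mask.shape} != PI shape {pi.shape}")
    if mask.max() == 0:
        return []
    bg_pixels = pi[mask == 0]
    med = float(np.median(bg_pixels)) if bg_pixels.size else 0.0
    sigma = max(_robust_sigma(bg_pixels), 0.5) if bg_pixels.size else 0.5
    pi_thr = med + k * sigma

    out = []
    for rp in regionprops(mask, intensity_image=pi):
        mean_pi = float(rp.intensity_mean)
        # fill on the full frame, not the bbox crop: a background pocket is
        # a hole whenever the object encloses it in the image
        filled = int(ndi.binary_fill_holes(mask == rp.label).sum())
        out.append(ObjectMeasure(
            label=int(rp.label),
            area=int(rp.area),
            filled_area=filled,
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            major_axis_length=float(rp.axis_major_length),
            mean_pi=mean_pi,
            pi_positive=bool(mean_pi > pi_thr),
        ))
    return out
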