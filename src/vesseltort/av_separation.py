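"""Artery-vein separation and skeletonization.

Ground-truth label maps color arteries red, veins blue and
artery-vein crossings green.  Classification runs in HSV space with
disjoint hue bands, so a pixel belongs to at most one class; crossing
pixels are then included in BOTH the artery and the vein mask to keep each
class topologically connected through the crossing.  Each class mask is
intersected with the binary segmentation, closed with a small disk, and
thinned to a one-pixel-wide centerline (two-subiteration thinning to a
fixed point) ready for path tracing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from skimage import color, morphology

from .preprocess import VesselMask, resize_mask_nearest
from .optic_disc import OpticDisc

logger = logging.getLogger(__name__)

__all__ = ["AVLabelMap", "Skeleton", "classify_hsv", "build_av_masks", "skeletonize", "overlay_od"]

# HSV decision bands (H, S, V all in [0, 1])
ARTERY_HUE = ((0.0, 0.1), (0.9, 1.0))
VEIN_HUE = (0.55, 0.75)
OVERLAP_HUE = (0.2, 0.45)


def classify_hsv(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classify an RGB label map into artery / vein / overlap binary masks.

    Arteries (red): H in [0, 0.1] or [0.9, 1], S > 0.4, V > 0.3.
    Veins (blue):   H in [0.55, 0.75],          S > 0.4, V > 0.3.
    Overlap (green): H in [0.2, 0.45],          S > 0.3, V > 0.3.

    The hue bands are pairwise disjoint, so the three masks are pairwise
    disjoint for every input.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB input, got shape {rgb.shape}")
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    hsv = color.rgb2hsv(rgb)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    sat_val = (s > 0.4) & (v > 0.3)
    m_artery = (((h >= ARTERY_HUE[0][0]) & (h <= ARTERY_HUE[0][1]))
                | ((h >= ARTERY_HUE[1][0]) & (h <= ARTERY_HUE[1][1]))) & sat_val
    m_vein = (h >= VEIN_HUE[0]) & (h <= VEIN_HUE[1]) & sat_val
    m_overlap = (h >= OVERLAP_HUE[0]) & (h <= OVERLAP_HUE[1]) & (s > 0.3) & (v > 0.3)
    return m_artery, m_vein, m_overlap


@dataclass
class AVLabelMap:
    """RGB ground truth plus its three derived class masks."""

    rgb: np.ndarray
    m_artery: np.ndarray
    m_vein: np.ndarray
    m_overlap: np.ndarray

    @classmethod
    def from_rgb(cls, rgb: np.ndarray) -> "AVLabelMap":
        a, v, o = classify_hsv(rgb)
        return cls(rgb=np.asarray(rgb), m_artery=a, m_vein=v, m_overlap=o)


@dataclass
class Skeleton:
    """One-pixel-wide centerline map for a vessel class."""

    grid: np.ndarray  # H x W bool
    vessel_class: str = "artery"  # artery | vein
    od: OpticDisc | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)


def build_av_masks(
    seg: VesselMask, labels: AVLabelMap, closing_radius: int = 2
) -> tuple[VesselMask, VesselMask]:
    """Intersect the segmentation with the class masks and close each result.

    artery = seg AND (artery OR overlap); vein = seg AND (vein OR overlap).
    Crossing (overlap) pixels end up in both masks so each class stays
    connected through artery-vein crossings.  Each mask is then closed with
    disk(closing_radius).
    """
    a, v, o = labels.m_artery, labels.m_vein, labels.m_overlap
    if a.shape != seg.shape:
        a = resize_mask_nearest(a, seg.shape)
        v = resize_mask_nearest(v, seg.shape)
        o = resize_mask_nearest(o, seg.shape)
    selem = morphology.disk(closing_radius) if closing_radius > 0 else None
    artery = seg.mask & (a | o)
    vein = seg.mask & (v | o)
    if selem is not None:
        artery = morphology.closing(artery, selem)
        vein = morphology.closing(vein, selem)
    logger.info("build_av_masks: artery=%d px, vein=%d px", int(artery.sum()), int(vein.sum()))
    return (
        VesselMask(mask=artery, provenance="gt_restored"),
        VesselMask(mask=vein, provenance="gt_restored"),
    )


def skeletonize(mask: VesselMask, vessel_class: str = "artery") -> Skeleton:
    """Thin a binary vessel mask to a one-pixel-wide centerline.

    Uses iterative thinning to a fixed point (Lee's variant, which unlike
    the classic two-subiteration scheme never leaves a stable 2x2 block),
    preserving connectivity (component count); idempotent on already-thin
    lines.
    """
    grid = morphology.skeletonize(mask.mask.astype(bool), method="lee")
    return Skeleton(grid=grid, vessel_class=vessel_class)


def overlay_od(skel: Skeleton, od: OpticDisc) -> Skeleton:
    """Attach the optic disc circle to a skeleton as metadata.

    The analysis grid itself is not modified; the circle is only drawn in
    visualization exports.  Downstream start-point detection requires the
    attached OD.
    """
    return dc_replace(skel, od=od)
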