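"""Fundus image normalization, resizing and vessel segmentation.

The working representation is a :class:`FundusImage` holding intensities in
[0, 1] together with the acquisition metadata (field of view, cumulative
resize factor) needed to express spatial resolution as pixels-per-degree
(ppd = image height / FOV).  Vessel segmentation proceeds through LAB-b
extraction, ISODATA intermeans thresholding, small-object cleanup, an
optional tube-enhancement union, and a ground-truth-guided restoration
step that re-inserts annotated vessel pixels and closes small gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from skimage import color, morphology, transform
from skimage.filters import sato

logger = logging.getLogger(__name__)

__all__ = [
    "FundusImage",
    "VesselMask",
    "normalize_image",
    "apply_resize_policy",
    "extract_b_channel",
    "isodata_threshold",
    "segment_vessels",
    "enhance_vessels",
    "restore_with_gt",
]


@dataclass(frozen=True)
class FundusImage:
    """An RGB fundus image with intensities in [0, 1] plus acquisition metadata."""

    pixels: np.ndarray  # H x W x 3 float64 in [0, 1]
    fov_deg: float
    resize_factor: float = 1.0
    source_path: str = ""

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def ppd(self) -> float:
        """Pixels per degree of visual angle at the current resolution."""
        return self.height_px / self.fov_deg


@dataclass
class VesselMask:
    """Binary vessel map aligned with the image it annotates."""

    mask: np.ndarray  # H x W bool
    provenance: str = "isodata"  # isodata | enhanced | gt_restored | synthetic

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def count(self) -> int:
        return int(self.mask.sum())


def normalize_image(raw_image: np.ndarray, fov_deg: float, source_path: str = "") -> FundusImage:
    """Convert an 8-bit RGB image to double precision in [0, 1].

    Parameters
    ----------
    raw_image : (H, W, 3) array with values in [0, 255].
    fov_deg : field of view of the acquisition, in degrees.
    """
    raw = np.asarray(raw_image)
    if raw.size == 0:
        raise ValueError("empty image")
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {raw.shape}")
    if raw.min() < 0 or raw.max() > 255:
        raise ValueError("pixel values outside [0, 255]")
    if fov_deg <= 0:
        raise ValueError("fov_deg must be positive")
    pixels = raw.astype(np.float64) / 255.0
    return FundusImage(pixels=pixels, fov_deg=float(fov_deg), source_path=source_path)


def apply_resize_policy(
    img: FundusImage,
    max_dim: int = 1000,
    resize_factor: float = 0.5,
    ppd_limit: float = 50.0,
) -> FundusImage:
    """Standardize spatial resolution across datasets.

    Images whose largest dimension exceeds ``max_dim`` are rescaled by
    ``resize_factor``; if the resulting pixels-per-degree still exceeds
    ``ppd_limit`` the image is rescaled by a further 50%.  The cumulative
    scale is recorded in ``resize_factor`` and ppd is recomputed from the
    post-resize height.  Idempotent on its own output for typical fundus
    FOVs (the conditions can no longer fire once enforced).
    """
    if img.fov_deg <= 0:
        raise ValueError("fov_deg must be positive")

    pixels = img.pixels
    factor = img.resize_factor
    # the size rule fires only for native-scale images (resize_factor == 1),
    # so enforcing the policy on its own output is a no-op
    if factor == 1.0 and max(pixels.shape[0], pixels.shape[1]) > max_dim:
        pixels = _rescale_rgb(pixels, resize_factor)
        factor *= resize_factor
    ppd = pixels.shape[0] / img.fov_deg
    if ppd > ppd_limit:
        pixels = _rescale_rgb(pixels, 0.5)
        factor *= 0.5
    logger.info(
        "resize policy: %dx%d -> %dx%d (factor %.3f, ppd %.2f)",
        img.height_px, img.width_px, pixels.shape[0], pixels.shape[1],
        factor, pixels.shape[0] / img.fov_deg,
    )
    return replace(img, pixels=pixels, resize_factor=factor)


def _rescale_rgb(pixels: np.ndarray, scale: float) -> np.ndarray:
    out = transform.rescale(
        pixels, scale, channel_axis=-1, order=1, anti_aliasing=True, mode="reflect"
    )
    return np.clip(out, 0.0, 1.0)


def extract_b_channel(img: FundusImage) -> np.ndarray:
    """LAB 'b' (blue-yellow) channel of the image, min-max normalized to [0, 1].

    A constant b channel (e.g. a uniformly colored image) maps to all zeros.
    """
    if img.pixels.ndim != 3 or img.pixels.shape[2] != 3:
        raise ValueError("extract_b_channel requires a 3-channel image")
    lab = color.rgb2lab(img.pixels)
    b = lab[..., 2]
    span = b.max() - b.min()
    if span == 0:
        return np.zeros_like(b)
    return (b - b.min()) / span


def isodata_threshold(grid: np.ndarray, tol: float = 1e-6, max_iter: int = 100) -> float:
    """ISODATA (iterative intermeans) threshold of a real-valued grid.

    Iterates T_{k+1} = (mean(values < T_k) + mean(values >= T_k)) / 2 from
    the global mean until |dT| < ``tol`` or ``max_iter`` iterations.  The
    fixed point is equidistant from the means of the two induced classes.
    """
    values = np.asarray(grid, dtype=np.float64).ravel()
    if values.size == 0 or values.max() == values.min():
        raise ValueError("degenerate histogram: grid needs at least two distinct values")
    t = values.mean()
    for _ in range(max_iter):
        lo = values[values < t]
        hi = values[values >= t]
        if lo.size == 0 or hi.size == 0:
            break
        t_next = 0.5 * (lo.mean() + hi.mean())
        if abs(t_next - t) < tol:
            t = t_next
            break
        t = t_next
    return float(t)


def segment_vessels(
    grid: np.ndarray,
    threshold: float,
    min_size: int = 20,
    invert: bool = False,
) -> VesselMask:
    """Threshold the (normalized) b channel into a binary vessel mask.

    Foreground is ``grid >= threshold`` (or ``grid < threshold`` when
    ``invert`` is set, for phantoms/datasets where vessels are dark in the
    b channel), followed by removal of 8-connected components smaller than
    ``min_size`` pixels.
    """
    grid = np.asarray(grid, dtype=np.float64)
    mask = (grid < threshold) if invert else (grid >= threshold)
    if min_size > 0:
        mask = morphology.remove_small_objects(mask, max_size=min_size - 1, connectivity=2)
    logger.info("segment_vessels: threshold=%.6f foreground=%d px", threshold, int(mask.sum()))
    return VesselMask(mask=mask, provenance="isodata")


def enhance_vessels(
    mask: VesselMask,
    img: FundusImage,
    method: str = "vesselness",
    scales: tuple[int, ...] = (1, 2, 3),
    response_threshold: float = 0.15,
    closing_radius: int = 1,
) -> VesselMask:
    """Union the mask with a multiscale tube-filter response.

    ``method='vesselness'`` runs a Sato tube-enhancement filter (dark
    ridges) on the mean intensity, normalizes the response to [0, 1], and
    adds pixels above ``response_threshold``; a small closing of the input
    mask is unioned in as well so 1-px gaps are bridged.  The output
    foreground is always a superset of the input (monotone).
    ``method='none'`` is the identity.
    """
    if method == "none":
        return VesselMask(mask=mask.mask.copy(), provenance=mask.provenance)
    if method != "vesselness":
        raise ValueError(f"unknown enhancement method: {method!r}")
    if mask.shape != img.pixels.shape[:2]:
        raise ValueError("mask and image dimensions differ")
    gray = img.pixels.mean(axis=-1)
    response = sato(gray, sigmas=scales, black_ridges=True, mode="reflect")
    peak = response.max()
    if peak > 0:
        response = response / peak
    out = mask.mask | (response > response_threshold)
    if closing_radius > 0:
        out |= morphology.closing(mask.mask, morphology.disk(closing_radius))
    logger.info("enhance_vessels: %d -> %d px", mask.count(), int(out.sum()))
    return VesselMask(mask=out, provenance="enhanced")


def restore_with_gt(mask: VesselMask, labels, closing_radius: int = 2) -> VesselMask:
    """Restore vessel continuity using the annotated artery/vein/overlap masks.

    The segmentation is unioned with the three ground-truth class masks
    (resized to the mask resolution with nearest-neighbor interpolation if
    needed) and then morphologically closed with a disk structuring
    element, so annotated vessel pixels missing from the segmentation are
    re-inserted and small gaps sealed.  Output foreground is a superset of
    the input.
    """
    union = mask.mask.copy()
    for gt in (labels.m_artery, labels.m_vein, labels.m_overlap):
        gt = np.asarray(gt, dtype=bool)
        if gt.shape != mask.shape:
            gt = resize_mask_nearest(gt, mask.shape)
        union |= gt
    if closing_radius > 0:
        union = morphology.closing(union, morphology.disk(closing_radius))
        union |= mask.mask  # closing of a union is extensive, but be explicit
    logger.info("restore_with_gt: %d -> %d px", mask.count(), int(union.sum()))
    return VesselMask(mask=union, provenance="gt_restored")


def resize_mask_nearest(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize of a binary mask (preserves binarity)."""
    out = transform.resize(
        np.asarray(mask, dtype=np.float64), shape, order=0, anti_aliasing=False,
        preserve_range=True,
    )
    return out > 0.5
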