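"""End-to-end orchestration: image -> segmentation -> AV skeletons ->
traced paths -> tortuosity records -> comparison report.

``process_image`` runs the full per-eye chain on in-memory arrays;
``run_pipeline`` batches it over directories pairing fundus images with
ground-truth label maps by filename stem, writes per-image intermediates,
a consolidated records CSV and a report CSV.  Identical inputs and config
produce byte-identical outputs (there is no random stage).
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import preprocess as pp
from . import av_separation as av
from . import tracing as tr
from . import stats as st
from .config import PipelineConfig
from .optic_disc import OpticDisc, detect_od, od_from_json

logger = logging.getLogger(__name__)

__all__ = ["process_image", "run_pipeline", "read_rgb"]

IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".gif")


def read_rgb(path) -> np.ndarray:
    """Read an image file as an H x W x 3 uint8 RGB array."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = (np.clip(arr, 0, 255)).astype(np.uint8)
    return arr


def process_image(
    raw_rgb: np.ndarray,
    gt_rgb: np.ndarray,
    config: PipelineConfig,
    image_id: str = "",
    manual_od: OpticDisc | None = None,
):
    """Run the full chain on one image; returns (records, intermediates)."""
    img = pp.normalize_image(raw_rgb, fov_deg=config.fov_deg, source_path=image_id)
    img = pp.apply_resize_policy(
        img, max_dim=config.resize_max_dim, resize_factor=config.resize_factor,
        ppd_limit=config.ppd_limit,
    )
    b = pp.extract_b_channel(img)
    threshold = pp.isodata_threshold(b, tol=config.isodata_tol,
                                     max_iter=config.isodata_max_iter)
    seg = pp.segment_vessels(b, threshold, min_size=config.min_object_px,
                             invert=config.invert_b)
    seg = pp.enhance_vessels(
        seg, img, method=config.enhance_method,
        scales=tuple(config.vesselness_scales),
        response_threshold=config.vesselness_threshold,
    )
    gt = np.asarray(gt_rgb, dtype=np.float64)
    if gt.max() > 1.0:
        gt = gt / 255.0
    if gt.shape[:2] != seg.shape:
        gt = _resize_rgb_nearest(gt, seg.shape)
    labels = av.AVLabelMap.from_rgb(gt)
    seg = pp.restore_with_gt(seg, labels, closing_radius=config.closing_radius_restore)

    od = detect_od(
        img, mask=seg, manual=manual_od,
        od_diameter_deg=config.od_diameter_deg,
        radius_factors=tuple(config.od_radius_factors),
    )

    artery_mask, vein_mask = av.build_av_masks(
        seg, labels, closing_radius=config.closing_radius_av
    )
    records = []
    skeletons = {}
    for cls, mask in (("artery", artery_mask), ("vein", vein_mask)):
        skel = av.overlay_od(av.skeletonize(mask, vessel_class=cls), od)
        skeletons[cls] = skel
        pixels = tr.extract_skeleton_pixels(skel)
        starts = tr.candidate_starts(pixels, od, delta=config.delta_px)
        endpoints = tr.detect_endpoints(skel)
        pairs = tr.validate_pairs(skel, starts, endpoints, od, delta=config.delta_px)
        paths = [tr.curve_length(skel, pair) for pair in pairs]
        records.extend(
            st.records_from_paths(image_id, paths, arc_mode=config.arc_mode,
                                  stride=config.polyline_stride)
        )
    intermediates = {
        "image": img, "b_channel": b, "threshold": threshold, "seg": seg,
        "labels": labels, "od": od, "artery_mask": artery_mask,
        "vein_mask": vein_mask, "skeletons": skeletons,
    }
    return records, intermediates


def _resize_rgb_nearest(rgb: np.ndarray, shape) -> np.ndarray:
    from skimage.transform import resize

    return resize(rgb, shape, order=0, anti_aliasing=False, preserve_range=True)


def run_pipeline(
    config: PipelineConfig,
    image_dir,
    gt_dir,
    out_dir,
    fov_by_stem: dict[str, float] | None = None,
) -> dict:
    """Batch-process a directory of images paired with GT maps by stem.

    Writes per-image intermediates (segmentation, class masks, skeletons as
    PNG, OD as JSON, pair tables), a consolidated ``records.csv`` and a
    ``report.csv`` comparing per-image artery vs vein mean tortuosity.
    An image whose GT or OD cannot be resolved is skipped with a warning.
    A sidecar ``<stem>.od.json`` next to an image supplies a manual OD.
    """
    image_dir, gt_dir, out_dir = Path(image_dir), Path(gt_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
    )
    if not images:
        raise FileNotFoundError(f"no inputs: no images found in {image_dir}")

    all_records = []
    processed = 0
    for img_path in images:
        stem = img_path.stem
        gt_path = _match_stem(gt_dir, stem)
        if gt_path is None:
            logger.warning("no ground truth for %s; skipped", stem)
            continue
        manual = None
        od_sidecar = img_path.with_suffix(".od.json")
        if od_sidecar.exists():
            manual = od_from_json(od_sidecar)
        cfg = config
        if fov_by_stem and stem in fov_by_stem:
            from dataclasses import replace as _dc_replace

            cfg = _dc_replace(config, fov_deg=fov_by_stem[stem])
        try:
            records, inter = process_image(
                read_rgb(img_path), read_rgb(gt_path), cfg,
                image_id=stem, manual_od=manual,
            )
        except ValueError as exc:
            logger.warning("image %s skipped: %s", stem, exc)
            continue
        processed += 1
        all_records.extend(records)
        _write_intermediates(out_dir / stem, inter, records)

    if not all_records:
        raise RuntimeError("pipeline produced no tortuosity records")
    rec_df = st.records_frame(all_records)
    rec_df.to_csv(out_dir / "records.csv", index=False)

    report_path = None
    per_image = st.aggregate(all_records)
    wide = per_image.pivot(index="image_id", columns="vessel_class", values="mean_t")
    if {"artery", "vein"} <= set(wide.columns):
        paired = wide.dropna()
        if len(paired) >= 3:
            seg_counts = rec_df.groupby("vessel_class").size()
            rep = st.compare_groups(
                paired["artery"].to_numpy(), paired["vein"].to_numpy(),
                alpha=config.alpha, label=image_dir.name,
                segments_a=int(seg_counts.get("artery", 0)),
                segments_b=int(seg_counts.get("vein", 0)),
            )
            report = st.build_report([rep])
            report_path = out_dir / "report.csv"
            report.to_csv(report_path, index=False)

    logger.info("run_pipeline: %d/%d images processed, %d records",
                processed, len(images), len(all_records))
    return {
        "n_images": processed,
        "records": all_records,
        "records_csv": out_dir / "records.csv",
        "report_csv": report_path,
    }


def _match_stem(directory: Path, stem: str):
    for suffix in IMAGE_SUFFIXES:
        p = directory / f"{stem}{suffix}"
        if p.exists():
            return p
    # fall back to any file sharing the stem
    for p in sorted(directory.iterdir()):
        if p.stem == stem and p.suffix.lower() in IMAGE_SUFFIXES:
            return p
    return None


def _write_intermediates(prefix: Path, inter: dict, records) -> None:
    prefix.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(f"{prefix}_seg.png", _to_u8(inter["seg"].mask))
    iio.imwrite(f"{prefix}_artery.png", _to_u8(inter["artery_mask"].mask))
    iio.imwrite(f"{prefix}_vein.png", _to_u8(inter["vein_mask"].mask))
    for cls, skel in inter["skeletons"].items():
        iio.imwrite(f"{prefix}_{cls}_skel.png", _to_u8(skel.grid))
    from .optic_disc import od_to_json

    od_to_json(inter["od"], f"{prefix}_od.json")
    pairs = [r.traced.pair for r in records]
    tr.write_pair_table(pairs, f"{prefix}_pairs.csv")


def _to_u8(mask: np.ndarray) -> np.ndarray:
    return (np.asarray(mask, dtype=np.uint8) * 255)
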