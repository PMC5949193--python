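"""End-to-end orchestration: filter → detect → fit → interpolate → evaluate.

The stages compose in the order a slice travels through the system:
preprocessing (upsampling, IIH correction, selective denoising), cascade
vertebra detection with the size post-filter, per-detection AAM landmark
fitting, closed Catmull-Rom interpolation into contours and masks, and —
when references are available — overlap-fraction evaluation.

Two initialization modes exist for the AAM stage: ``deploy`` places the
model mean shape into each detected box; ``evaluation`` starts from a
perturbed ground-truth shape, the protocol used to study convergence
behaviour in isolation from detector accuracy.
"""

from __future__ import annotations

import copy
import logging

import numpy as np

from spineseg import aam as aam_mod
from spineseg import augment as augment_mod
from spineseg import cascade as cascade_mod
from spineseg import contour as contour_mod
from spineseg import metrics as metrics_mod
from spineseg import preprocess as preprocess_mod
from spineseg.imgio import BinaryMask, BoundingBox, GrayImage, LandmarkSet

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "log_level": "INFO",
    "preprocess": {
        "enabled": True,
        "upsample_factor": 1,
        "kernel_a": -0.5,
        "skin_side": "left",
        "quantile": 0.90,
        "sigma_px": 1.0,
        "edge_threshold": 25.0,
    },
    "detector": {
        "n_stages": 10,
        "min_hit_rate": 0.995,
        "max_false_alarm": 0.5,
        "window": [24, 24],
        "feature_stride": 3,
        "n_neg_per_stage": 600,
        "min_neg_per_stage": 50,
        "include_tilted": False,
        "scale_factor": 1.1,
        "step_px": 2,
        "min_neighbors": 3,
    },
    "augment": {
        "n_positives_factor": 4,
        "sigma_px": None,
        "rot_deg": 8.0,
        "scale": 0.10,
    },
    "aam": {
        "patch_shape": [17, 17],
        "var_retained": 0.90,
        "shape_var_retained": 0.95,
        "scales": [0.5, 1.0],
        "algorithm": "WIC",
        "n_iterations": 25,
        "n_shape": None,
        "n_appearance": None,
    },
    "init": {"trans_frac": 0.05, "scale_sigma": 0.02, "rot_deg": 3.0},
    "contour": {"alpha": 0.5, "samples_per_segment": 20},
}


class ConfigError(ValueError):
    """The run configuration holds unknown or inconsistent keys."""


def resolve_config(overrides: dict | None = None) -> dict:
    """Merge user overrides into the defaults, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(base: dict, extra: dict, path: str = "") -> None:
        for key, val in extra.items():
            if key not in base:
                raise ConfigError(f"unknown config key {path + key!r}")
            if isinstance(base[key], dict) and isinstance(val, dict):
                merge(base[key], val, path + key + ".")
            else:
                base[key] = val

    if overrides:
        merge(cfg, overrides)
    return cfg


def preprocess_image(image: GrayImage, config: dict) -> GrayImage:
    """Initial filtration: upsample, correct the exponential bias, denoise."""
    p = config["preprocess"]
    if not p["enabled"]:
        return image
    out = preprocess_mod.upsample(image, int(p["upsample_factor"]), kernel_a=p["kernel_a"])
    try:
        _, depth = preprocess_mod.detect_skin_boundary(
            out, side=p["skin_side"], quantile=p["quantile"]
        )
        gain = preprocess_mod.fit_exponential_gain(out, depth)
    except preprocess_mod.EstimationError as exc:
        logger.warning("IIH correction skipped: %s", exc)
        return out
    out = preprocess_mod.correct_iih(out, gain)
    out = preprocess_mod.selective_gaussian(
        out, gain, sigma_px=p["sigma_px"], edge_threshold=p["edge_threshold"]
    )
    return out


def _scaled_truths(truths: list, factor: int, shape: tuple[int, int]) -> list:
    """Map ground-truth boxes/landmarks/masks into the upsampled frame."""
    if factor == 1:
        return truths
    out = []
    for box, lms, mask in truths:
        box2 = BoundingBox(
            box.x * factor, box.y * factor, box.width * factor, box.height * factor, box.score
        )
        lms2 = LandmarkSet(lms.points * factor, frame=lms.frame)
        cont = contour_mod.catmull_rom_closed(lms2.points)
        mask2 = contour_mod.rasterize(cont, shape, mask.spacing)
        out.append((box2, lms2, mask2))
    return out


def prepare_training(manifest: dict, config: dict):
    """Preprocess a phantom manifest into detector and AAM training inputs.

    Returns ``(pos_crops, annotated_crops, neg_images, aam_pairs)`` where
    negatives are the same slices with every vertebral body removed by
    harmonic inpainting of its exact mask — the surrounding discs, canal
    and fat band remain, which yields hard (context-rich) negatives.
    """
    factor = int(config["preprocess"]["upsample_factor"]) if config["preprocess"]["enabled"] else 1
    pos_crops: list[np.ndarray] = []
    annotated: list[tuple[GrayImage, LandmarkSet]] = []
    neg_images: list[GrayImage] = []
    aam_pairs: list[tuple[GrayImage, LandmarkSet]] = []
    for item in manifest["items"]:
        image = preprocess_image(item["image"], config)
        truths = _scaled_truths(item["truths"], factor, image.shape)
        body = np.zeros(image.shape, dtype=bool)
        for box, lms, mask in truths:
            x0 = int(max(0, np.floor(box.x)))
            y0 = int(max(0, np.floor(box.y)))
            x1 = int(min(image.shape[1], np.ceil(box.x + box.width)))
            y1 = int(min(image.shape[0], np.ceil(box.y + box.height)))
            crop = image.pixels[y0:y1, x0:x1]
            pos_crops.append(crop)
            annotated.append(
                (
                    GrayImage(crop, image.spacing, image.source_id),
                    LandmarkSet(lms.points - np.array([x0, y0]), frame=lms.frame),
                )
            )
            body |= mask.pixels
            aam_pairs.append((image, lms))
        neg_images.append(augment_mod.inpaint(image, BinaryMask(body, image.spacing)))
    return pos_crops, annotated, neg_images, aam_pairs


def train_detector(manifest: dict, config: dict, seed: int | None = None) -> cascade_mod.CascadeModel:
    """Train the cascade on a phantom manifest (with TPS positive augmentation)."""
    cfg = config
    seed = cfg["seed"] if seed is None else seed
    pos_crops, annotated, neg_images, _ = prepare_training(manifest, cfg)
    a = cfg["augment"]
    n_aug = int(a["n_positives_factor"]) * len(annotated)
    if n_aug:
        aug = augment_mod.generate_positives(
            annotated,
            n_out=n_aug,
            jitter={"sigma_px": a["sigma_px"], "rot_deg": a["rot_deg"], "scale": a["scale"]},
            seed=seed,
        )
        pos_all = pos_crops + [im.pixels for im, _ in aug]
    else:
        pos_all = pos_crops
    d = cfg["detector"]
    params = {
        "n_stages": d["n_stages"],
        "min_hit_rate": d["min_hit_rate"],
        "max_false_alarm": d["max_false_alarm"],
        "window": tuple(d["window"]),
        "feature_stride": d["feature_stride"],
        "n_neg_per_stage": d["n_neg_per_stage"],
        "min_neg_per_stage": d["min_neg_per_stage"],
        "include_tilted": d["include_tilted"],
        "seed": seed,
    }
    return cascade_mod.train_cascade(pos_all, neg_images, params)


def train_aam(manifest: dict, config: dict) -> aam_mod.AAMModel:
    """Train the patch AAM on the preprocessed manifest images."""
    _, _, _, aam_pairs = prepare_training(manifest, config)
    a = config["aam"]
    return aam_mod.build_appearance_model(
        aam_pairs,
        patch_shape=tuple(a["patch_shape"]),
        var_retained=a["var_retained"],
        scales=tuple(a["scales"]),
        shape_var_retained=a["shape_var_retained"],
    )


def segment_image(
    image: GrayImage,
    detector: cascade_mod.CascadeModel,
    model: aam_mod.AAMModel,
    config: dict,
    gt_truths: list | None = None,
    mode: str = "deploy",
    seed: int = 0,
) -> dict:
    """Run the full per-slice pipeline.

    Returns a dict with the (possibly empty) detections, per-vertebra
    landmark fits, contours and masks, all mapped back to the input frame;
    with ``gt_truths`` given, per-vertebra overlap fractions are included.
    In ``evaluation`` mode initialization uses perturbed ground truth
    instead of the detector boxes.
    """
    if mode not in ("deploy", "evaluation"):
        raise ValueError("mode must be 'deploy' or 'evaluation'")
    factor = int(config["preprocess"]["upsample_factor"]) if config["preprocess"]["enabled"] else 1
    pre = preprocess_image(image, config)
    d = config["detector"]
    detections = cascade_mod.filter_by_size(
        cascade_mod.detect(
            pre,
            detector,
            scale_factor=d["scale_factor"],
            step_px=d["step_px"],
            min_neighbors=d["min_neighbors"],
        )
    )
    if not detections:
        logger.warning("no vertebrae detected in %s", image.source_id)

    truths = (
        _scaled_truths(gt_truths, factor, pre.shape) if gt_truths is not None else None
    )
    rng = np.random.default_rng(seed)
    inits: list[LandmarkSet] = []
    if mode == "deploy":
        for box in detections:
            inits.append(aam_mod.mean_shape_in_box(model, box))
    else:
        if truths is None:
            raise ValueError("evaluation mode needs ground-truth annotations")
        for _box, lms, _mask in truths:
            inits.append(
                aam_mod.perturb_shape(
                    lms, noise=config["init"], seed=int(rng.integers(2**31))
                )
            )

    a = config["aam"]
    fit_cfg = {
        "algorithm": a["algorithm"],
        "n_iterations": a["n_iterations"],
        "n_shape": a["n_shape"],
        "n_appearance": a["n_appearance"],
    }
    c = config["contour"]
    vertebrae = []
    for i, init in enumerate(inits):
        res = aam_mod.fit(pre, model, init, fit_cfg)
        pts = res.final.points / factor
        cont = contour_mod.catmull_rom_closed(
            pts, alpha=c["alpha"], samples_per_segment=int(c["samples_per_segment"])
        )
        mask = contour_mod.rasterize(cont, image.shape, image.spacing)
        entry = {
            "landmarks": LandmarkSet(pts, frame=image.source_id),
            "contour": cont,
            "mask": mask,
            "converged": res.converged,
            "costs": res.costs,
            "fit": res,
        }
        if mode == "deploy" and i < len(detections):
            b = detections[i]
            entry["box"] = BoundingBox(
                b.x / factor, b.y / factor, b.width / factor, b.height / factor, b.score
            )
        if truths is not None and mode == "evaluation":
            ref = gt_truths[i][2]
            entry["fractions"] = metrics_mod.fractions(mask, ref)
        vertebrae.append(entry)

    out = {
        "source_id": image.source_id,
        "detections": [
            BoundingBox(b.x / factor, b.y / factor, b.width / factor, b.height / factor, b.score)
            for b in detections
        ],
        "vertebrae": vertebrae,
        "mode": mode,
    }
    return out


def detection_metrics(
    detections: list, gt_boxes: list, iou_threshold: float = 0.5
) -> dict:
    """Recall and false-positive count of detections against truth boxes."""
    from spineseg.imgio import iou

    hits = 0
    for g in gt_boxes:
        if detections and max(iou(d, g) for d in detections) >= iou_threshold:
            hits += 1
    false_pos = sum(
        1 for d in detections if not gt_boxes or max(iou(d, g) for g in gt_boxes) < iou_threshold
    )
    return {"n_truth": len(gt_boxes), "n_hit": hits, "n_false_positive": false_pos}
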