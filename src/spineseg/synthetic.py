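"""Seeded sagittal lumbar-spine phantom generator.

The generator emulates, at phantom fidelity, the appearance a T1-weighted
sagittal lumbar slice presents to this pipeline: a column of bright
vertebral bodies separated by darker intervertebral discs, a dark spinal
canal posterior to the column, a bright subcutaneous fat band at the skin,
a multiplicative exponential intensity-inhomogeneity (coil falloff) field,
and additive Gaussian noise.  Every image carries exact per-vertebra ground
truth: a bounding box, a 16-point landmark set, and the body mask obtained
by rasterizing the closed centripetal Catmull-Rom contour through those
landmarks — so the contour model and the generator agree by construction.

The 16-point template is an artifact convention used consistently across
the package: 4 rounded-corner points plus 3 equally spaced points per edge
of the vertebral-body outline, ordered clockwise from the anterior-superior
corner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from spineseg import contour as contour_mod
from spineseg.imgio import (
    BinaryMask,
    BoundingBox,
    GrayImage,
    LandmarkSet,
    write_image,
    write_mask,
    write_pts,
)


@dataclass
class PhantomSpec:
    """Parameters of one phantom slice.

    Intensity levels are on an 8-bit-like scale; they are ordered so the
    vertebral bodies contrast with the background (fat > body > disc >
    canal > background).  ``seed`` fully determines the output.
    """

    shape: tuple[int, int] = (256, 256)
    spacing: tuple[float, float] = (1.0, 1.0)
    n_vertebrae: int = 5
    vertebra_size: tuple[float, float] = (34.0, 42.0)  # (h, w) px
    size_jitter: float = 0.08  # relative sigma on h and w
    rot_jitter_deg: float = 4.0
    landmark_sigma_px: float = 0.8  # smooth per-landmark boundary jitter
    disc_height: float = 12.0
    column_x: float = 150.0
    column_curve_px: float = 10.0
    skin_side: str = "left"
    skin_offset: int = 12
    fat_band_px: int = 5
    bias_lam: float = 0.004  # 1/mm
    noise_sigma: float = 4.0
    levels: dict = field(
        default_factory=lambda: {
            "background": 25.0,
            "canal": 45.0,
            "disc": 95.0,
            "body": 175.0,
            "fat": 235.0,
        }
    )
    seed: int = 0


def landmark_template() -> LandmarkSet:
    """The 16-point vertebral-body outline template in the unit square.

    Four corner points pulled diagonally inward (rounded corners) and three
    equally spaced points on each edge, clockwise from the anterior-superior
    (top-left) corner.  The centroid sits at (0.5, 0.5).
    """
    c = 0.08
    pts = [
        (c, c),  # anterior-superior corner
        (0.25, 0.0),
        (0.50, 0.0),
        (0.75, 0.0),
        (1.0 - c, c),  # posterior-superior corner
        (1.0, 0.25),
        (1.0, 0.50),
        (1.0, 0.75),
        (1.0 - c, 1.0 - c),  # posterior-inferior corner
        (0.75, 1.0),
        (0.50, 1.0),
        (0.25, 1.0),
        (c, 1.0 - c),  # anterior-inferior corner
        (0.0, 0.75),
        (0.0, 0.50),
        (0.0, 0.25),
    ]
    return LandmarkSet(points=np.array(pts, dtype=float), frame="template")


def _pose_template(
    center: np.ndarray, size_hw: tuple[float, float], angle_rad: float
) -> np.ndarray:
    """Map the unit-square template to an oriented box at ``center``."""
    tpl = landmark_template().points - 0.5
    h, w = size_hw
    scaled = tpl * np.array([w, h])
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[ca, -sa], [sa, ca]])
    return scaled @ rot.T + center


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[GrayImage, list[tuple[BoundingBox, LandmarkSet, BinaryMask]]]:
    """Render one phantom slice and its per-vertebra ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    vh, vw = spec.vertebra_size
    total = spec.n_vertebrae * vh + (spec.n_vertebrae - 1) * spec.disc_height
    margin = 14.0
    if total > h - 2 * margin or vw + spec.skin_offset + spec.fat_band_px + 10 > w:
        raise ValueError("vertebrae cannot fit in the requested image shape")

    levels = spec.levels
    img = np.full((h, w), levels["background"], dtype=float)

    # bright subcutaneous fat band at the skin side
    if spec.skin_side == "left":
        img[:, spec.skin_offset : spec.skin_offset + spec.fat_band_px] = levels["fat"]
    else:
        img[:, w - spec.skin_offset - spec.fat_band_px : w - spec.skin_offset] = levels["fat"]

    y0 = (h - total) / 2.0
    centers_y = y0 + vh / 2.0 + np.arange(spec.n_vertebrae) * (vh + spec.disc_height)
    # gently curved column axis
    phase = rng.uniform(0, 2 * np.pi)
    centers_x = spec.column_x + spec.column_curve_px * np.sin(
        np.linspace(0, np.pi, spec.n_vertebrae) + phase
    )

    # spinal canal: dark band posterior (right) of the column
    canal_x = centers_x.mean() + vw / 2 + 6
    img[:, int(canal_x) : int(canal_x) + 10] = levels["canal"]

    truths: list[tuple[BoundingBox, LandmarkSet, BinaryMask]] = []
    for i in range(spec.n_vertebrae):
        size = (
            vh * (1.0 + spec.size_jitter * rng.standard_normal()),
            vw * (1.0 + spec.size_jitter * rng.standard_normal()),
        )
        angle = np.deg2rad(spec.rot_jitter_deg) * rng.standard_normal()
        center = np.array([centers_x[i], centers_y[i]])
        pts = _pose_template(center, size, angle)
        pts = pts + spec.landmark_sigma_px * rng.standard_normal(pts.shape)
        lms = LandmarkSet(points=pts, frame=f"phantom-{spec.seed}")

        # disc above this body (skip the first)
        if i > 0:
            dy0 = centers_y[i - 1] + size[0] / 2
            dy1 = centers_y[i] - size[0] / 2
            dx0 = int(center[0] - size[1] / 2 + 3)
            dx1 = int(center[0] + size[1] / 2 - 3)
            img[int(dy0) : int(dy1) + 1, dx0:dx1] = levels["disc"]

        cont = contour_mod.catmull_rom_closed(pts, alpha=0.5, samples_per_segment=20)
        mask = contour_mod.rasterize(cont, (h, w), spec.spacing)
        img[mask.pixels] = levels["body"]

        x0, y0b = pts[:, 0].min(), pts[:, 1].min()
        bw, bh = pts[:, 0].max() - x0, pts[:, 1].max() - y0b
        pad_x, pad_y = 0.08 * bw, 0.08 * bh
        box = BoundingBox(
            x=x0 - pad_x, y=y0b - pad_y, width=bw + 2 * pad_x, height=bh + 2 * pad_y
        )
        truths.append((box, lms, mask))

    # soften structure edges a little, as partial volume would
    img = gaussian_filter(img, 0.7)

    # multiplicative exponential falloff with depth from the skin
    cols = np.arange(w, dtype=float)
    if spec.skin_side == "left":
        depth_px = np.maximum(cols - spec.skin_offset, 0.0)
    else:
        depth_px = np.maximum((w - 1 - spec.skin_offset) - cols, 0.0)
    depth_mm = depth_px * spec.spacing[1]
    img = img * np.exp(-spec.bias_lam * depth_mm)[None, :]

    img = img + spec.noise_sigma * rng.standard_normal((h, w))
    img = np.clip(img, 0.0, None)

    image = GrayImage(img, spec.spacing, source_id=f"phantom-seed-{spec.seed}")
    return image, truths


def generate_dataset(
    n_images: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Generate ``n_images`` phantoms with per-image seeds derived from ``seed``.

    Returns a manifest dict.  When ``out_dir`` is given, PNG images, PTS
    landmark files, mask PNGs, and ``manifest.json`` are written there and
    the manifest records the relative paths; otherwise the manifest holds
    the in-memory objects under ``items``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    base = spec if spec is not None else PhantomSpec()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_images) % (2**31)

    items = []
    records = []
    for i in range(n_images):
        ispec = replace(base, seed=int(child_seeds[i]))
        image, truths = generate_phantom(ispec)
        items.append({"image": image, "truths": truths, "seed": ispec.seed})
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            img_name = f"phantom_{i:04d}.png"
            write_image(image, out / img_name)
            vert_records = []
            for j, (box, lms, mask) in enumerate(truths):
                pts_name = f"phantom_{i:04d}_v{j}.pts"
                mask_name = f"phantom_{i:04d}_v{j}_mask.png"
                write_pts(lms, out / pts_name)
                write_mask(mask, out / mask_name)
                vert_records.append(
                    {"pts_path": pts_name, "mask_path": mask_name, "box": box.as_dict()}
                )
            records.append(
                {
                    "image_path": img_name,
                    "origin": f"phantom seed {ispec.seed}",
                    "seed": ispec.seed,
                    "spacing": list(base.spacing),
                    "vertebrae": vert_records,
                }
            )

    manifest = {
        "n_images": n_images,
        "master_seed": seed,
        "spacing": list(base.spacing),
        "items": items,
    }
    if out_dir is not None:
        disk_manifest = {
            "n_images": n_images,
            "master_seed": seed,
            "spacing": list(base.spacing),
            "images": records,
        }
        (Path(out_dir) / "manifest.json").write_text(
            json.dumps(disk_manifest, indent=1, sort_keys=True)
        )
        manifest["images"] = records
        manifest["out_dir"] = str(out_dir)
    return manifest


def split_dataset(manifest: dict, test_fraction: float, seed: int = 0) -> tuple[dict, dict]:
    """Split a manifest into disjoint train/test sets by image (never by vertebra)."""
    n = manifest["n_images"]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test_idx = set(order[:n_test].tolist())

    def subset(keep):
        sub = {k: v for k, v in manifest.items() if k not in ("items", "images", "n_images")}
        sub["items"] = [it for i, it in enumerate(manifest["items"]) if (i in keep)]
        sub["n_images"] = len(sub["items"])
        return sub

    train = subset(set(range(n)) - test_idx)
    test = subset(test_idx)
    return train, test
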