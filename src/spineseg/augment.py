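"""Training-data synthesis: TPS positive augmentation, inpainted negatives.

Detector training needs far more positive examples than annotated vertebrae
exist, and negative images that are guaranteed vertebra-free.  Positives
are multiplied by warping annotated crops with thin-plate-spline (TPS)
deformations built from jittered landmark correspondences; negatives are
reconstructed from the very same images by inpainting the vertebra regions
with the harmonic (Laplace) diffusion solution, which removes the object
while keeping the surrounding anatomy and intensity statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from spineseg.imgio import BinaryMask, BoundingBox, GrayImage, LandmarkSet
from spineseg.preprocess import sample_cubic

logger = logging.getLogger(__name__)


@dataclass
class TpsWarp:
    """A fitted thin-plate-spline map from source to target points.

    The map is ``f(p) = affine(p) + sum_i w_i U(|p - s_i|)`` per coordinate
    with kernel ``U(r) = r^2 log r`` (``U(0) = 0``).  The bending energy is
    ``trace(W^T K W)``; it is zero iff the warp is affine.
    """

    source: np.ndarray
    target: np.ndarray
    affine: np.ndarray  # (3, 2): rows [const, x, y]
    weights: np.ndarray  # (n, 2)
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        K = _tps_kernel_matrix(pts, self.source)
        ones = np.ones((len(pts), 1))
        P = np.hstack([ones, pts])
        return P @ self.affine + K @ self.weights


def _tps_U(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r, written in terms of r^2; U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


def _tps_kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    return _tps_U(d2)


def fit_tps(source_pts: np.ndarray, target_pts: np.ndarray, reg: float = 0.0) -> TpsWarp:
    """Solve the standard TPS linear system for paired control points.

    ``reg`` adds ``lambda I`` to the kernel block (smoothing spline);
    with ``reg = 0`` the warp interpolates the control points exactly.
    Collinear or duplicate source points make the system singular.
    """
    src = np.asarray(source_pts, dtype=float)
    tgt = np.asarray(target_pts, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("source and target must be matching (n, 2) arrays")
    n = len(src)
    if n < 3:
        raise ValueError("need at least 3 control points")
    K = _tps_kernel_matrix(src, src) + reg * np.eye(n)
    P = np.hstack([np.ones((n, 1)), src])
    L = np.zeros((n + 3, n + 3))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = tgt
    if np.linalg.cond(L) > 1e12:
        raise np.linalg.LinAlgError(
            "singular TPS system (collinear or duplicate source points?)"
        )
    sol = np.linalg.solve(L, rhs)
    w = sol[:n]
    affine = sol[n:]
    bend = float(np.trace(w.T @ (K - reg * np.eye(n)) @ w))
    return TpsWarp(source=src, target=tgt, affine=affine, weights=w, bending_energy=max(bend, 0.0))


def warp_image(
    image: GrayImage, landmarks: LandmarkSet, warp: TpsWarp
) -> tuple[GrayImage, LandmarkSet]:
    """Apply a TPS warp to an image and its landmarks.

    Landmarks are mapped forward through the warp.  Pixels are filled by
    backward mapping (a reverse TPS fitted from target to source control
    points) with cubic-convolution interpolation.
    """
    reverse = fit_tps(warp.target, warp.source, reg=1e-9)
    h, w = image.shape
    yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    grid = np.stack([xx.ravel(), yy.ravel()], axis=1)
    src = reverse(grid)
    out = sample_cubic(image.pixels, src[:, 1].reshape(h, w), src[:, 0].reshape(h, w))
    out = np.clip(out, image.pixels.min(), image.pixels.max())
    new_lms = LandmarkSet(points=warp(landmarks.points), frame=landmarks.frame)
    return GrayImage(out, image.spacing, image.source_id), new_lms


def generate_positives(
    annotated: list[tuple[GrayImage, LandmarkSet]],
    n_out: int,
    jitter: dict | None = None,
    seed: int = 0,
) -> list[tuple[GrayImage, LandmarkSet]]:
    """Emit ``n_out`` TPS-warped variants of annotated vertebra crops.

    Inputs are cycled; each variant samples per-landmark Gaussian control
    displacements (``sigma_px``) plus a global rotation/scale jitter about
    the landmark centroid, fits a TPS from the original landmarks to the
    perturbed ones, and warps image and landmarks.  Fully seeded.
    """
    if not annotated:
        raise ValueError("need at least one annotated example")
    j = {"sigma_px": None, "rot_deg": 8.0, "scale": 0.10}
    if jitter:
        j.update(jitter)
    rng = np.random.default_rng(seed)
    out: list[tuple[GrayImage, LandmarkSet]] = []
    for i in range(n_out):
        image, lms = annotated[i % len(annotated)]
        sigma = j["sigma_px"]
        if sigma is None:
            width = lms.points[:, 0].max() - lms.points[:, 0].min()
            sigma = 0.02 * width
        src = lms.points
        centroid = src.mean(axis=0)
        angle = np.deg2rad(j["rot_deg"]) * rng.uniform(-1, 1)
        scale = 1.0 + j["scale"] * rng.uniform(-1, 1)
        ca, sa = np.cos(angle), np.sin(angle)
        rot = scale * np.array([[ca, -sa], [sa, ca]])
        tgt = (src - centroid) @ rot.T + centroid
        tgt = tgt + sigma * rng.standard_normal(src.shape)
        if np.allclose(tgt, src):
            out.append((GrayImage(image.pixels.copy(), image.spacing, image.source_id),
                        LandmarkSet(src.copy(), lms.frame)))
            continue
        warp = fit_tps(src, tgt, reg=1e-6)
        out.append(warp_image(image, lms, warp))
    return out


def inpaint(image: GrayImage, mask: BinaryMask, tol: float = 1e-4) -> GrayImage:
    """Fill masked pixels with the discrete harmonic (Laplace) solution.

    Masked pixels are relaxed to the average of their 4-neighbors with
    red-black Gauss-Seidel sweeps (plus Chebyshev-style over-relaxation,
    which only accelerates the same fixed point) until the largest update
    falls below ``tol`` or ``10 * |mask|`` sweeps; unmasked pixels are
    untouched.  Out-of-image neighbors replicate the edge pixel.  The
    result obeys the discrete maximum principle: filled values lie within
    the range of the boundary values.
    """
    if mask.shape != image.shape:
        raise ValueError("mask shape must match the image")
    m = mask.pixels
    if not m.any():
        return GrayImage(image.pixels.copy(), image.spacing, image.source_id)
    if m.all():
        raise ValueError("mask covers the entire image; nothing to anchor the fill")
    px = image.pixels.copy()
    # initialize the hole at the boundary mean for faster relaxation
    px[m] = image.pixels[~m].mean()

    h, w = px.shape
    yy, xx = np.nonzero(m)
    flat = px.ravel()

    def nbr(dy: int, dx: int) -> np.ndarray:
        return np.clip(yy + dy, 0, h - 1) * w + np.clip(xx + dx, 0, w - 1)

    up, down, left, right = nbr(-1, 0), nbr(1, 0), nbr(0, -1), nbr(0, 1)
    center = yy * w + xx
    color = (yy + xx) % 2
    groups = [
        (center[color == c], up[color == c], down[color == c], left[color == c], right[color == c])
        for c in (0, 1)
    ]
    # over-relaxation factor from the hole extent (optimal SOR for Laplace)
    extent = max(yy.max() - yy.min(), xx.max() - xx.min()) + 2
    omega = 2.0 / (1.0 + np.sin(np.pi / extent))
    max_iter = 10 * int(m.sum())
    for _ in range(max_iter):
        delta = 0.0
        for c_idx, u, d, l, r in groups:
            gs = 0.25 * (flat[u] + flat[d] + flat[l] + flat[r])
            new = flat[c_idx] + omega * (gs - flat[c_idx])
            delta = max(delta, float(np.abs(new - flat[c_idx]).max(initial=0.0)))
            flat[c_idx] = new
        if delta < tol:
            break
    out = flat.reshape(h, w)
    # over-relaxation can overshoot transiently; the converged solution is
    # harmonic, so clamp any residual overshoot to the boundary range
    out[m] = np.clip(out[m], image.pixels[~m].min(), image.pixels[~m].max())
    return GrayImage(out, image.spacing, image.source_id)


def generate_negatives(
    images: list[GrayImage],
    vertebra_boxes: list[list[BoundingBox]],
    seed: int = 0,
) -> list[GrayImage]:
    """Reconstruct vertebra-free negatives by inpainting each vertebra box.

    Boxes are dilated by 10% before inpainting.  Deterministic; ``seed`` is
    recorded for manifest provenance only.
    """
    out = []
    for image, boxes in zip(images, vertebra_boxes):
        if not boxes:
            out.append(GrayImage(image.pixels.copy(), image.spacing, image.source_id))
            continue
        m = np.zeros(image.shape, dtype=bool)
        h, w = image.shape
        for b in boxes:
            dx, dy = 0.05 * b.width, 0.05 * b.height
            x0 = max(0, int(np.floor(b.x - dx)))
            y0 = max(0, int(np.floor(b.y - dy)))
            x1 = min(w, int(np.ceil(b.x + b.width + dx)))
            y1 = min(h, int(np.ceil(b.y + b.height + dy)))
            m[y0:y1, x0:x1] = True
        out.append(inpaint(image, BinaryMask(m, image.spacing)))
    return out
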