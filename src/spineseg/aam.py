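"""Patch-based Active Appearance Model for 16-landmark vertebra fitting.

The shape model is a Point Distribution Model: training landmark sets are
brought into a common frame by generalized Procrustes analysis (similarity
alignment) and the aligned shapes are summarized by PCA.  The appearance
model is *patch-based*: instead of a whole warped texture, a fixed-size
rectangular patch is extracted around each of the 16 landmarks (bilinear
sub-pixel sampling, z-scored per landmark), the patches are concatenated
into one appearance vector, and PCA is applied per pyramid scale.

Fitting minimizes the appearance residual over shape parameters with
Lucas-Kanade style Gauss-Newton iterations using fixed template gradients
(the inverse-compositional economy).  Five variants are provided, differing
in how the linear appearance parameters ``c`` are handled:

* ``POIC`` — project-out: residuals and steepest-descent images are
  projected onto the orthogonal complement of the appearance basis once;
  the Hessian is precomputed.
* ``SIC``  — simultaneous: shape and appearance increments are solved
  jointly each iteration; the Jacobian includes the basis-gradient terms.
* ``AIC``  — alternating: ``c`` is solved exactly, then a shape step is
  taken against the reconstruction residual.
* ``MAIC`` — modified alternating: the appearance update is applied before
  the residual used by the shape step is recomputed (running ``c``).
* ``WIC``  — Wiberg: ``c`` is eliminated analytically each iteration and
  the shape step uses the projected current-template Jacobian.

All fitters are deterministic given (model, image, init).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from spineseg.imgio import GrayImage, LandmarkSet, load_model_json, save_model_json
from spineseg.preprocess import sample_bilinear

logger = logging.getLogger(__name__)

ALGORITHMS = ("POIC", "SIC", "AIC", "MAIC", "WIC")


class AlignmentError(RuntimeError):
    """A shape could not be brought into the common frame."""


# ---------------------------------------------------------------------------
# shape model
# ---------------------------------------------------------------------------

@dataclass
class ShapeModel:
    """PCA shape model over Procrustes-aligned 16-point shapes.

    ``mean_shape`` is a 32-vector (x0, y0, ..., x15, y15) with zero
    centroid and unit Frobenius norm; ``eigenvectors`` (32 x k) are
    orthonormal and eigenvalues are sorted descending.
    """

    mean_shape: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        # contiguity is normalized so fits are bitwise reproducible across
        # serialization round trips (BLAS results depend on memory layout)
        self.mean_shape = np.ascontiguousarray(np.asarray(self.mean_shape, float).ravel())
        self.eigenvectors = np.ascontiguousarray(
            np.asarray(self.eigenvectors, float).reshape(self.mean_shape.size, -1)
        )
        self.eigenvalues = np.ascontiguousarray(np.asarray(self.eigenvalues, float).ravel())
        k = self.eigenvalues.size
        if self.eigenvectors.shape[1] != k:
            raise ValueError("eigenvector/eigenvalue count mismatch")
        if k:
            g = self.eigenvectors.T @ self.eigenvectors
            if not np.allclose(g, np.eye(k), atol=1e-8):
                raise ValueError("shape eigenvectors must be orthonormal")
            if np.any(np.diff(self.eigenvalues) > 1e-12):
                raise ValueError("eigenvalues must be nonincreasing")

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def _as_matrix(shape) -> np.ndarray:
    pts = shape.points if isinstance(shape, LandmarkSet) else np.asarray(shape, float)
    return pts.reshape(-1, 2)


def _align_to(shape: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal similarity alignment (rotation only; inputs pre-normalized)."""
    u, _, vt = np.linalg.svd(shape.T @ ref)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return shape @ r


def _normalize(shape: np.ndarray) -> np.ndarray:
    centered = shape - shape.mean(axis=0)
    norm = np.linalg.norm(centered)
    if norm < 1e-12:
        raise AlignmentError("degenerate shape: all points coincide")
    return centered / norm


def generalized_procrustes(
    shapes: list, tol: float = 1e-7, max_iter: int = 100
) -> tuple[list[np.ndarray], np.ndarray]:
    """Iterative similarity alignment of a set of shapes.

    Each shape is translated to zero centroid, scaled to unit norm, and
    rotated to the running mean by least squares; the mean is renormalized
    each round.  Returns the aligned shapes and the mean shape (zero
    centroid, unit norm).
    """
    if len(shapes) < 2:
        raise ValueError("need at least 2 shapes")
    mats = [_normalize(_as_matrix(s)) for s in shapes]
    mean = mats[0]
    for _ in range(max_iter):
        aligned = [_align_to(m, mean) for m in mats]
        new_mean = _normalize(np.mean(aligned, axis=0))
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    aligned = [_align_to(m, mean) for m in mats]
    return aligned, mean


def build_shape_model(aligned: list, var_retained: float = 0.95) -> ShapeModel:
    """PCA of aligned shapes keeping the smallest k with cumulative
    variance >= ``var_retained`` (components below 1e-12 are dropped)."""
    if len(aligned) < 2:
        raise ValueError("need at least 2 shapes for a shape model")
    X = np.stack([_as_matrix(s).ravel() for s in aligned])
    mean = X.mean(axis=0)
    cov = np.cov(X - mean, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    keep = evals > 1e-12
    evals, evecs = evals[keep], evecs[:, keep]
    if evals.size:
        cum = np.cumsum(evals) / evals.sum()
        k = int(np.searchsorted(cum, var_retained) + 1)
        k = min(k, evals.size)
    else:
        k = 0
    return ShapeModel(mean_shape=mean, eigenvectors=evecs[:, :k], eigenvalues=evals[:k])


# ---------------------------------------------------------------------------
# appearance model
# ---------------------------------------------------------------------------

@dataclass
class PatchAppearanceModel:
    """Per-scale PCA over concatenated per-landmark patches."""

    patch_shape: tuple[int, int]
    mean: np.ndarray  # (16 * ph * pw,)
    basis: np.ndarray  # (16 * ph * pw, k), orthonormal columns
    eigenvalues: np.ndarray
    retained_variance: float

    def __post_init__(self) -> None:
        ph, pw = self.patch_shape
        if ph % 2 == 0 or pw % 2 == 0:
            raise ValueError("patch dimensions must be odd (centered on landmark)")
        self.mean = np.ascontiguousarray(self.mean, dtype=float)
        self.basis = np.ascontiguousarray(self.basis, dtype=float)
        self.eigenvalues = np.ascontiguousarray(self.eigenvalues, dtype=float)
        if self.basis.size:
            g = self.basis.T @ self.basis
            if not np.allclose(g, np.eye(self.basis.shape[1]), atol=1e-8):
                raise ValueError("appearance basis must be orthonormal")


@dataclass
class AAMModel:
    """Shape model + per-scale patch appearance models + fitter defaults."""

    shape: ShapeModel
    appearance: dict  # scale -> PatchAppearanceModel
    scales: tuple
    patch_shape: tuple[int, int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.scales) < 1:
            raise ValueError("need at least one pyramid scale")
        for s in self.scales:
            if s not in self.appearance:
                raise ValueError(f"missing appearance model for scale {s}")

    def to_dict(self) -> dict:
        return {
            "patch_shape": list(self.patch_shape),
            "scales": list(self.scales),
            "metadata": self.metadata,
            "shape": {
                "mean_shape": self.shape.mean_shape,
                "eigenvectors": self.shape.eigenvectors,
                "eigenvalues": self.shape.eigenvalues,
            },
            "appearance": {
                str(s): {
                    "patch_shape": list(m.patch_shape),
                    "mean": m.mean,
                    "basis": m.basis,
                    "eigenvalues": m.eigenvalues,
                    "retained_variance": m.retained_variance,
                }
                for s, m in self.appearance.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AAMModel":
        shape = ShapeModel(
            d["shape"]["mean_shape"], d["shape"]["eigenvectors"], d["shape"]["eigenvalues"]
        )
        scales = tuple(float(s) for s in d["scales"])
        app = {}
        for key, m in d["appearance"].items():
            app[float(key)] = PatchAppearanceModel(
                tuple(int(v) for v in m["patch_shape"]),
                np.asarray(m["mean"], float),
                np.asarray(m["basis"], float).reshape(len(m["mean"]), -1),
                np.asarray(m["eigenvalues"], float),
                float(m["retained_variance"]),
            )
        return cls(
            shape=shape,
            appearance=app,
            scales=scales,
            patch_shape=tuple(int(v) for v in d["patch_shape"]),
            metadata=dict(d.get("metadata", {})),
        )

    def save(self, path) -> None:
        save_model_json(self.to_dict(), path)

    @classmethod
    def load(cls, path) -> "AAMModel":
        return cls.from_dict(load_model_json(path))


def extract_patches(
    pixels: np.ndarray,
    points: np.ndarray,
    patch_shape: tuple[int, int],
    warn_border: bool = True,
) -> np.ndarray:
    """Concatenated z-scored patches around each landmark (bilinear sampling).

    Landmarks closer to the border than half a patch are padded by edge
    replication (the sampler clamps coordinates); a warning is logged when
    ``warn_border`` is set (model building warns; the fitter, where border
    excursions are routine transients, does not).
    """
    ph, pw = patch_shape
    hy, hx = (ph - 1) / 2.0, (pw - 1) / 2.0
    h, w = pixels.shape
    if warn_border and (
        (points[:, 0] < hx).any()
        or (points[:, 1] < hy).any()
        or (points[:, 0] > w - 1 - hx).any()
        or (points[:, 1] > h - 1 - hy).any()
    ):
        logger.warning("landmark patch reaches outside the image; edge-replicated")
    dy, dx = np.meshgrid(
        np.arange(ph, dtype=float) - hy, np.arange(pw, dtype=float) - hx, indexing="ij"
    )
    out = np.empty((len(points), ph * pw))
    for i, (x, y) in enumerate(points):
        patch = sample_bilinear(pixels, y + dy, x + dx).ravel()
        std = patch.std()
        out[i] = (patch - patch.mean()) / (std if std > 1e-8 else 1.0)
    return out.ravel()


def _pca(X: np.ndarray, var_retained: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, orthonormal basis, eigenvalues keeping ``var_retained`` variance."""
    mean = X.mean(axis=0)
    Xc = X - mean
    # thin SVD route (n_samples << n_features)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    evals = s**2 / max(len(X) - 1, 1)
    keep = evals > 1e-12
    evals, vt = evals[keep], vt[keep]
    if evals.size:
        cum = np.cumsum(evals) / evals.sum()
        k = int(np.searchsorted(cum, var_retained) + 1)
        k = min(k, evals.size)
    else:
        k = 0
    return mean, vt[:k].T, evals[:k]


def _rescale_image(pixels: np.ndarray, scale: float) -> np.ndarray:
    if scale == 1.0:
        return pixels
    sh = max(2, int(round(pixels.shape[0] * scale)))
    sw = max(2, int(round(pixels.shape[1] * scale)))
    return resize(pixels, (sh, sw), anti_aliasing=scale < 1.0, preserve_range=True)


def build_appearance_model(
    dataset: list,
    patch_shape: tuple[int, int] = (17, 17),
    var_retained: float = 0.90,
    scales: tuple = (0.5, 1.0),
    shape_var_retained: float = 0.95,
) -> AAMModel:
    """Train the full AAM from (image, landmarks) pairs.

    Per pyramid scale, patches are extracted at the (scaled) ground-truth
    landmarks and PCA is applied to the concatenated patch vectors; the
    shape model is built once from the Procrustes-aligned landmark sets.
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 annotated examples")
    aligned, _mean = generalized_procrustes([lms for _, lms in dataset])
    shape_model = build_shape_model(aligned, var_retained=shape_var_retained)

    appearance: dict[float, PatchAppearanceModel] = {}
    for s in scales:
        vecs = []
        for image, lms in dataset:
            px = _rescale_image(image.pixels, s)
            pts = lms.points * s
            vecs.append(extract_patches(px, pts, patch_shape))
        X = np.stack(vecs)
        mean, basis, evals = _pca(X, var_retained)
        appearance[float(s)] = PatchAppearanceModel(
            patch_shape=tuple(patch_shape),
            mean=mean,
            basis=basis,
            eigenvalues=evals,
            retained_variance=float(var_retained),
        )
    return AAMModel(
        shape=shape_model,
        appearance=appearance,
        scales=tuple(float(s) for s in scales),
        patch_shape=tuple(patch_shape),
        metadata={
            "n_training": len(dataset),
            "shape_var_retained": shape_var_retained,
            "appearance_var_retained": var_retained,
        },
    )


# ---------------------------------------------------------------------------
# initialization helpers
# ---------------------------------------------------------------------------

def perturb_shape(
    gt: LandmarkSet, noise: dict | None = None, seed: int = 0
) -> LandmarkSet:
    """Seeded random similarity perturbation of a ground-truth shape.

    Translation is Gaussian with sigma ``trans_frac`` times the bounding-box
    diagonal (per axis), scale is Gaussian around 1 with sigma
    ``scale_sigma``, rotation Gaussian with sigma ``rot_deg`` degrees, both
    about the shape centroid.
    """
    n = {"trans_frac": 0.05, "scale_sigma": 0.02, "rot_deg": 3.0}
    if noise:
        n.update(noise)
    rng = np.random.default_rng(seed)
    pts = gt.points
    bbox = pts.max(axis=0) - pts.min(axis=0)
    diag = float(np.hypot(*bbox))
    t = rng.normal(0.0, n["trans_frac"] * diag, size=2) if n["trans_frac"] > 0 else np.zeros(2)
    s = 1.0 + (rng.normal(0.0, n["scale_sigma"]) if n["scale_sigma"] > 0 else 0.0)
    theta = np.deg2rad(rng.normal(0.0, n["rot_deg"])) if n["rot_deg"] > 0 else 0.0
    c = pts.mean(axis=0)
    ca, sa = np.cos(theta), np.sin(theta)
    rot = s * np.array([[ca, -sa], [sa, ca]])
    out = (pts - c) @ rot.T + c + t
    return LandmarkSet(points=out, frame=gt.frame)


def mean_shape_in_box(model: AAMModel, box) -> LandmarkSet:
    """Place the model mean shape into a detection box (deployment init)."""
    mean = model.shape.mean_shape.reshape(-1, 2)
    span = mean.max(axis=0) - mean.min(axis=0)
    scale = min(box.width / span[0], box.height / span[1]) * 0.92
    center = np.array([box.x + box.width / 2.0, box.y + box.height / 2.0])
    pts = (mean - mean.mean(axis=0)) * scale + center
    return LandmarkSet(points=pts, frame="detector-init")


def _similarity_from_mean(mean: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares similarity (a, b, tx, ty) mapping ``mean`` onto ``target``."""
    mx, my = mean[:, 0], mean[:, 1]
    n = len(mean)
    # normal equations of sum |A m + t - target|^2 over (a, b, tx, ty)
    J = np.zeros((2 * n, 4))
    J[0::2, 0] = mx
    J[0::2, 1] = -my
    J[0::2, 2] = 1.0
    J[1::2, 0] = my
    J[1::2, 1] = mx
    J[1::2, 3] = 1.0
    rhs = target.reshape(-1)
    q, *_ = np.linalg.lstsq(J, rhs, rcond=None)
    return q


def _apply_similarity(q: np.ndarray, pts: np.ndarray) -> np.ndarray:
    a, b, tx, ty = q
    return pts @ np.array([[a, b], [-b, a]]) + np.array([tx, ty])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Trace of one AAM fit: shapes and costs per iteration (0 = init)."""

    shapes: list  # LandmarkSet per iteration, full-image coordinates
    costs: list
    final: LandmarkSet
    converged: bool

    @property
    def n_iterations(self) -> int:
        return len(self.shapes) - 1


def fit(
    image: GrayImage,
    model: AAMModel,
    init: LandmarkSet,
    config: dict | None = None,
) -> FitResult:
    """Fit the AAM to an image from an initial 16-point shape.

    Coarse-to-fine over the model's pyramid scales; the iteration budget is
    split evenly across scales with the remainder to the finest.  Records
    the shape at full-image scale after every iteration.  Landmarks pushed
    outside the image are clamped to the border and the fit is marked
    unconverged.
    """
    cfg = {
        "algorithm": "WIC",
        "n_iterations": 25,
        "n_shape": None,
        "n_appearance": None,
        "max_halvings": 4,
    }
    if config:
        cfg.update(config)
    algorithm = cfg["algorithm"].upper()
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {cfg['algorithm']!r}; use one of {ALGORITHMS}")
    n_iter_total = int(cfg["n_iterations"])
    h, w = image.shape

    pts = init.points.copy()
    if (pts[:, 0] < 0).any() or (pts[:, 1] < 0).any() or (
        pts[:, 0] > w - 1
    ).any() or (pts[:, 1] > h - 1).any():
        raise ValueError("initial landmarks must lie inside the image")

    if n_iter_total == 0:
        init_copy = LandmarkSet(pts.copy(), frame=init.frame)
        return FitResult(shapes=[init_copy], costs=[], final=init_copy, converged=True)

    scales = sorted(model.scales)
    n_scales = len(scales)
    base = n_iter_total // n_scales
    budgets = [base] * n_scales
    budgets[-1] += n_iter_total - base * n_scales

    shapes = [LandmarkSet(pts.copy(), frame=init.frame)]
    costs: list[float] = []
    converged = True
    clamped = False

    ns = cfg["n_shape"]
    phi = model.shape.eigenvectors[:, :ns] if ns else model.shape.eigenvectors
    lam = model.shape.eigenvalues[: phi.shape[1]]
    mean_m = model.shape.mean_shape.reshape(-1, 2)

    first_cost_recorded = False
    for scale, budget in zip(scales, budgets):
        app = model.appearance[scale]
        na = cfg["n_appearance"]
        A = app.basis[:, :na] if na else app.basis
        a0 = app.mean
        px = _rescale_image(image.pixels, scale)
        sh, sw = px.shape

        # parameters at this scale
        cur = pts * scale
        q = _similarity_from_mean(mean_m, cur)
        y = _invert_similarity(q, cur)
        b = phi.T @ (y - mean_m).reshape(-1) if phi.shape[1] else np.zeros(0)

        fitter = _Fitter(algorithm, a0, A, phi, q, mean_m, model.patch_shape)

        def current_points(q, b):
            m = mean_m + (phi @ b).reshape(-1, 2) if b.size else mean_m.copy()
            return _apply_similarity(q, m)

        cur = current_points(q, b)
        g = extract_patches(px, cur, model.patch_shape, warn_border=False)
        cost = fitter.cost(g)
        if not first_cost_recorded:
            costs.append(cost)
            first_cost_recorded = True

        for _ in range(budget):
            dq, db = fitter.step(g)
            step = 1.0
            best = None
            for _half in range(int(cfg["max_halvings"]) + 1):
                q_new = q - step * dq
                b_new = b - step * db if b.size else b
                if b_new.size:
                    b_new = np.clip(b_new, -3.0 * np.sqrt(lam), 3.0 * np.sqrt(lam))
                pts_new = current_points(q_new, b_new)
                oob = (
                    (pts_new[:, 0] < 0).any()
                    or (pts_new[:, 1] < 0).any()
                    or (pts_new[:, 0] > sw - 1).any()
                    or (pts_new[:, 1] > sh - 1).any()
                )
                if oob:
                    pts_new = np.column_stack(
                        [np.clip(pts_new[:, 0], 0, sw - 1), np.clip(pts_new[:, 1], 0, sh - 1)]
                    )
                g_new = extract_patches(px, pts_new, model.patch_shape, warn_border=False)
                cost_new = fitter.cost(g_new)
                if cost_new <= cost or _half == int(cfg["max_halvings"]):
                    best = (q_new, b_new, pts_new, g_new, cost_new, oob)
                    break
                step *= 0.5
            q, b, cur, g, cost, oob = best
            if oob:
                clamped = True
            costs.append(cost)
            shapes.append(LandmarkSet(cur / scale, frame=init.frame))
        pts = cur / scale

    if clamped:
        converged = False
    final = LandmarkSet(pts, frame=init.frame)
    return FitResult(shapes=shapes, costs=costs, final=final, converged=converged)


def _invert_similarity(q: np.ndarray, pts: np.ndarray) -> np.ndarray:
    a, b, tx, ty = q
    det = a * a + b * b
    shifted = pts - np.array([tx, ty])
    inv = np.array([[a, -b], [b, a]]) / det
    return shifted @ inv


class _Fitter:
    """Shared Gauss-Newton machinery for the five LK variants."""

    def __init__(self, algorithm, a0, A, phi, q0, mean_m, patch_shape):
        self.algorithm = algorithm
        self.a0 = a0
        self.A = A
        self.phi = phi
        self.n_b = phi.shape[1]
        ph, pw = patch_shape
        self.ppl = ph * pw  # pixels per landmark
        n_lms = mean_m.shape[0]

        # landmark-position Jacobian at the mean configuration (q0 pose)
        a, b, *_ = q0
        rot = np.array([[a, b], [-b, a]])
        # columns: da, db, dtx, dty, then shape coefficients
        Jpos = np.zeros((n_lms, 2, 4 + self.n_b))
        mx, my = mean_m[:, 0], mean_m[:, 1]
        Jpos[:, 0, 0] = mx
        Jpos[:, 1, 0] = my
        Jpos[:, 0, 1] = -my
        Jpos[:, 1, 1] = mx
        Jpos[:, 0, 2] = 1.0
        Jpos[:, 1, 3] = 1.0
        if self.n_b:
            basis_pts = self.phi.reshape(n_lms, 2, self.n_b)
            Jpos[:, 0, 4:] = (
                basis_pts[:, 0, :] * rot[0, 0] + basis_pts[:, 1, :] * rot[1, 0]
            )
            Jpos[:, 1, 4:] = (
                basis_pts[:, 0, :] * rot[0, 1] + basis_pts[:, 1, :] * rot[1, 1]
            )

        self.SD0 = self._steepest_descent(a0, Jpos, patch_shape)
        if A.size:
            self.SD_basis = np.stack(
                [self._steepest_descent(A[:, k], Jpos, patch_shape) for k in range(A.shape[1])]
            )
        else:
            self.SD_basis = np.zeros((0,) + self.SD0.shape)
        self.Jpos = Jpos
        self.patch_shape = patch_shape
        self.c = np.zeros(A.shape[1]) if A.size else np.zeros(0)

        if algorithm == "POIC":
            SDp = self._project_out(self.SD0)
            self.SD_po = SDp
            self.H_po = SDp.T @ SDp
            self.H_po_inv = np.linalg.pinv(self.H_po, rcond=1e-10)

    def _steepest_descent(self, template, Jpos, patch_shape):
        """SD matrix (n_pixels, n_params) from template patch gradients."""
        ph, pw = patch_shape
        n_lms = Jpos.shape[0]
        tpl = template.reshape(n_lms, ph, pw)
        SD = np.zeros((n_lms * ph * pw, Jpos.shape[2]))
        for i in range(n_lms):
            gy, gx = np.gradient(tpl[i])
            gx = gx.ravel()
            gy = gy.ravel()
            block = gx[:, None] * Jpos[i, 0][None, :] + gy[:, None] * Jpos[i, 1][None, :]
            SD[i * ph * pw : (i + 1) * ph * pw] = block
        return SD

    def _project_out(self, M):
        if self.A.size:
            return M - self.A @ (self.A.T @ M)
        return M

    def cost(self, g: np.ndarray) -> float:
        r = g - self.a0
        if self.algorithm == "POIC":
            r = r - self.A @ (self.A.T @ r) if self.A.size else r
            return float(r @ r)
        if self.A.size:
            c = self.A.T @ r
            r = r - self.A @ c
        return float(r @ r)

    def _solve(self, J, r):
        H = J.T @ J
        return np.linalg.pinv(H, rcond=1e-10) @ (J.T @ r)

    def step(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One Gauss-Newton increment (dq, db) for the current sample ``g``."""
        r0 = g - self.a0
        if self.algorithm == "POIC":
            rp = self._project_out(r0)
            d = self.H_po_inv @ (self.SD_po.T @ rp)
        elif self.algorithm == "SIC":
            SD = self._current_SD(self.c)
            J = np.hstack([SD, self.A]) if self.A.size else SD
            r = r0 - self.A @ self.c if self.A.size else r0
            sol = self._solve(J, r)
            d = sol[: SD.shape[1]]
            if self.A.size:
                self.c = self.c + sol[SD.shape[1]:]
        elif self.algorithm == "AIC":
            c = self.A.T @ r0 if self.A.size else self.c
            self.c = c
            r = r0 - self.A @ c if self.A.size else r0
            SD = self._current_SD(c)
            d = self._solve(SD, r)
        elif self.algorithm == "MAIC":
            # appearance update applied before the residual is recomputed
            if self.A.size:
                r_prev = r0 - self.A @ self.c
                self.c = self.c + self.A.T @ r_prev
                r = r0 - self.A @ self.c
            else:
                r = r0
            SD = self._current_SD(self.c)
            d = self._solve(SD, r)
        elif self.algorithm == "WIC":
            c = self.A.T @ r0 if self.A.size else self.c
            self.c = c
            SD = self._project_out(self._current_SD(c))
            rp = self._project_out(r0)
            d = self._solve(SD, rp)
        else:  # pragma: no cover
            raise ValueError(self.algorithm)
        return d[:4], d[4:]

    def _current_SD(self, c: np.ndarray) -> np.ndarray:
        if self.SD_basis.shape[0] and c.size:
            return self.SD0 + np.tensordot(c, self.SD_basis, axes=(0, 0))
        return self.SD0


def point_to_point_error(a: LandmarkSet, b: LandmarkSet) -> float:
    """Mean Euclidean distance between corresponding landmarks."""
    return float(np.linalg.norm(a.points - b.points, axis=1).mean())


# ---------------------------------------------------------------------------
# algorithm comparison protocol
# ---------------------------------------------------------------------------

def compare_algorithms(
    test_set: list,
    model: AAMModel,
    algorithms: tuple = ALGORITHMS,
    n_passes: int = 100,
    n_iterations: int = 25,
    noise: dict | None = None,
    seed: int = 0,
):
    """Per-algorithm, per-iteration overlap-fraction table.

    ``test_set`` holds (image, gt_landmarks, reference_masks) triples; each
    pass draws fresh perturbed initializations, every algorithm is fitted
    from the same inits, the shape at every iteration is interpolated into
    a closed contour, rasterized, and compared with each reference mask.
    Returns a tidy DataFrame with mean, half-width and sigma per measure.
    """
    import pandas as pd

    from spineseg import contour as contour_mod
    from spineseg.metrics import fractions, summarize

    rng = np.random.default_rng(seed)
    records = {alg: {} for alg in algorithms}
    for _pass in range(n_passes):
        for idx, (image, gt, refs) in enumerate(test_set):
            init_seed = int(rng.integers(2**31))
            init = perturb_shape(gt, noise=noise, seed=init_seed)
            for alg in algorithms:
                res = fit(image, model, init, {"algorithm": alg, "n_iterations": n_iterations})
                for it, shp in enumerate(res.shapes):
                    cont = contour_mod.catmull_rom_closed(shp.points)
                    mask = contour_mod.rasterize(cont, image.shape, image.spacing)
                    for ref in refs:
                        rep = fractions(mask, ref)
                        records[alg].setdefault(it, []).append(
                            (rep.TPF, rep.FNF, rep.FF)
                        )
    rows = []
    for alg in algorithms:
        for it in sorted(records[alg]):
            arr = np.array(records[alg][it])
            row = {"algorithm": alg, "iteration": it}
            for j, name in enumerate(("TPF", "FNF", "FF")):
                stat = summarize(arr[:, j])
                row[f"{name}_mean"] = stat.mean
                row[f"{name}_halfwidth"] = stat.halfwidth
                row[f"sigma_{name}"] = stat.sigma
            rows.append(row)
    return pd.DataFrame(rows)
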