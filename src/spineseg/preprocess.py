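"""Initial filtration of sagittal spine slices.

Three steps precede detection and landmark fitting:

1. **Upsampling** by separable cubic convolution (Catmull-Rom kernel,
   ``a = -0.5`` by default) to increase working resolution.
2. **Intensity-inhomogeneity (IIH) correction.**  Surface-coil sensitivity
   falls off with distance from the coil, which for sagittal lumbar
   acquisitions means intensity decays roughly exponentially with depth
   from the skin.  The skin line is located from the bright subcutaneous
   fat band, a per-pixel depth map is computed, the expected bias
   ``b(d) = exp(-lam * d)`` is fitted by log-linear least squares over
   foreground pixels, and the image is divided by the fitted bias.
3. **Selective Gaussian denoising** to remove the noise amplified by the
   correction: each pixel is replaced by the Gaussian-weighted mean of the
   neighbors whose intensity lies within a tolerance window, and the window
   widens with depth by the same exponential factor (deep noise was
   amplified by ``exp(lam * d)``, so the tolerance is scaled accordingly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from spineseg.imgio import GrayImage


class EstimationError(RuntimeError):
    """A preprocessing quantity could not be estimated from the image."""


@dataclass
class ExponentialGain:
    """Multiplicative exponential bias model ``b(d) = exp(-lam * d)``.

    Attributes
    ----------
    I0 : float
        Reference (skin-level) foreground intensity, > 0.
    lam : float
        Decay rate per mm of depth.
    depth_map : 2D array
        Per-pixel distance (mm) from the detected skin boundary, >= 0.
    """

    I0: float
    lam: float
    depth_map: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.lam):
            raise ValueError("decay rate must be finite")
        if self.I0 <= 0:
            raise ValueError("reference intensity must be positive")
        self.depth_map = np.asarray(self.depth_map, dtype=float)
        if (self.depth_map < 0).any():
            raise ValueError("depth map must be non-negative")


# ---------------------------------------------------------------------------
# cubic convolution resampling
# ---------------------------------------------------------------------------

def _cubic_kernel(s: np.ndarray, a: float) -> np.ndarray:
    """Keys cubic convolution kernel with free parameter ``a``."""
    s = np.abs(s)
    out = np.zeros_like(s)
    near = s <= 1.0
    far = (s > 1.0) & (s < 2.0)
    out[near] = (a + 2.0) * s[near] ** 3 - (a + 3.0) * s[near] ** 2 + 1.0
    out[far] = a * s[far] ** 3 - 5.0 * a * s[far] ** 2 + 8.0 * a * s[far] - 4.0 * a
    return out


def sample_cubic(pixels: np.ndarray, ys: np.ndarray, xs: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Sample an image at float coordinates by 2D cubic convolution.

    Coordinates follow the package convention (pixel centers at integers);
    out-of-range taps use edge replication.  Sampling at exactly integer
    coordinates reproduces the pixel values exactly.
    """
    h, w = pixels.shape
    ys = np.asarray(ys, dtype=float)
    xs = np.asarray(xs, dtype=float)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    fy = ys - y0
    fx = xs - x0
    out = np.zeros(ys.shape, dtype=float)
    wy = [_cubic_kernel(fy - m, a) for m in (-1, 0, 1, 2)]
    wx = [_cubic_kernel(fx - m, a) for m in (-1, 0, 1, 2)]
    for i, m in enumerate((-1, 0, 1, 2)):
        ry = np.clip(y0 + m, 0, h - 1)
        for j, n in enumerate((-1, 0, 1, 2)):
            rx = np.clip(x0 + n, 0, w - 1)
            out += wy[i] * wx[j] * pixels[ry, rx]
    return out


def sample_bilinear(pixels: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Bilinear sub-pixel sampling with edge replication."""
    h, w = pixels.shape
    ys = np.clip(np.asarray(ys, dtype=float), 0, h - 1)
    xs = np.clip(np.asarray(xs, dtype=float), 0, w - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    fy = ys - y0
    fx = xs - x0
    return (
        pixels[y0, x0] * (1 - fy) * (1 - fx)
        + pixels[y0, x1] * (1 - fy) * fx
        + pixels[y1, x0] * fy * (1 - fx)
        + pixels[y1, x1] * fy * fx
    )


def upsample(image: GrayImage, factor: int, kernel_a: float = -0.5) -> GrayImage:
    """Upsample by an integer factor with separable cubic convolution.

    Output shape is the input shape times ``factor`` and spacing is divided
    by ``factor``.  Intensities are clipped to the input min/max (the cubic
    kernel can overshoot near edges).
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("upsample factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return GrayImage(image.pixels.copy(), image.spacing, image.source_id)
    h, w = image.shape
    ys = np.arange(h * factor, dtype=float) / factor
    xs = np.arange(w * factor, dtype=float) / factor
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    out = sample_cubic(image.pixels, yy, xx, a=kernel_a)
    out = np.clip(out, image.pixels.min(), image.pixels.max())
    spacing = (image.spacing[0] / factor, image.spacing[1] / factor)
    return GrayImage(out, spacing, image.source_id)


# ---------------------------------------------------------------------------
# skin boundary and exponential gain
# ---------------------------------------------------------------------------

def detect_skin_boundary(
    image: GrayImage,
    side: str = "left",
    quantile: float = 0.90,
    median_window: int = 11,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate the skin line from the bright fat band and build a depth map.

    For each row, the boundary is the first column (scanning inward from
    ``side``) whose intensity exceeds that row's ``quantile``.  Rows without
    a crossing inherit the median boundary of the rows that have one.  The
    boundary is then smoothed with a running median over ``median_window``
    rows.  Returns ``(boundary_cols, depth_map)`` with depths in mm.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    px = image.pixels
    h, w = px.shape
    thresh = np.quantile(px, quantile, axis=1)
    above = px > thresh[:, None]
    if not above.any():
        raise EstimationError(
            "no pixel exceeds the row quantile; supply a manual depth origin"
        )
    cols = np.arange(w) if side == "left" else np.arange(w)[::-1]
    boundary = np.full(h, -1, dtype=float)
    for r in range(h):
        hits = np.nonzero(above[r, cols])[0]
        if hits.size:
            boundary[r] = cols[hits[0]]
    missing = boundary < 0
    if missing.all():
        raise EstimationError(
            "no row exceeds the quantile; supply a manual depth origin"
        )
    boundary[missing] = np.median(boundary[~missing])
    boundary = median_filter(boundary, size=median_window, mode="nearest")

    col_idx = np.arange(w, dtype=float)[None, :]
    if side == "left":
        depth_px = col_idx - boundary[:, None]
    else:
        depth_px = boundary[:, None] - col_idx
    depth_map = np.maximum(depth_px, 0.0) * image.spacing[1]
    return boundary, depth_map


def fit_exponential_gain(
    image: GrayImage, depth_map: np.ndarray, min_foreground: int = 100
) -> ExponentialGain:
    """Fit ``b(d) = exp(-lam * d)`` over foreground pixels.

    Foreground is everything above the global Otsu threshold.  A straight
    line is fitted to ``log(intensity)`` versus depth by least squares; the
    slope is ``-lam`` and the intercept ``log(I0)``.
    """
    px = image.pixels
    thresh = _otsu_threshold(px)
    fg = (px > thresh) & (px > 0)
    if fg.sum() < min_foreground:
        raise EstimationError(
            f"only {int(fg.sum())} foreground pixels (need >= {min_foreground})"
        )
    d = np.asarray(depth_map, dtype=float)[fg]
    logi = np.log(px[fg])
    slope, intercept = np.polyfit(d, logi, 1)
    return ExponentialGain(I0=float(np.exp(intercept)), lam=float(-slope), depth_map=depth_map)


def _otsu_threshold(pixels: np.ndarray, nbins: int = 256) -> float:
    """Otsu's between-class variance maximizing threshold."""
    counts, edges = np.histogram(pixels.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = counts.astype(float)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m = np.cumsum(counts * centers)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m / w0
        mu1 = (m[-1] - m) / w1
    var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between)
    return float(centers[np.argmax(var_between)])


def correct_iih(image: GrayImage, gain: ExponentialGain) -> GrayImage:
    """Divide out the fitted exponential bias and restore the input mean.

    ``corrected = pixels * exp(lam * d)``, then rescaled multiplicatively so
    the output mean equals the input mean exactly.
    """
    if gain.depth_map.shape != image.shape:
        raise ValueError("gain was fitted on a different image geometry")
    out = image.pixels * np.exp(gain.lam * gain.depth_map)
    mean_out = out.mean()
    if mean_out > 0:
        out = out * (image.pixels.mean() / mean_out)
    return GrayImage(out, image.spacing, image.source_id)


def selective_gaussian(
    image: GrayImage,
    gain: ExponentialGain | None,
    sigma_px: float = 2.0,
    edge_threshold: float = 20.0,
) -> GrayImage:
    """Edge-preserving Gaussian smoothing with a depth-scaled tolerance.

    Each pixel becomes the Gaussian-weighted mean of the neighbors whose
    absolute difference from the center is below
    ``edge_threshold * exp(lam * d)``; pixels with no qualifying neighbor
    keep their value.  With ``gain=None`` the tolerance is constant.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    px = image.pixels
    h, w = px.shape
    radius = max(1, int(np.ceil(3.0 * sigma_px)))
    if gain is not None:
        tol = edge_threshold * np.exp(gain.lam * gain.depth_map)
    else:
        tol = np.full((h, w), edge_threshold, dtype=float)

    num = np.zeros_like(px)
    den = np.zeros_like(px)
    pad = np.pad(px, radius, mode="edge")
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            g = np.exp(-(dy * dy + dx * dx) / (2.0 * sigma_px**2))
            shifted = pad[radius + dy : radius + dy + h, radius + dx : radius + dx + w]
            ok = np.abs(shifted - px) < tol
            num += g * ok * shifted
            den += g * ok
    out = np.where(den > 0, num / np.maximum(den, 1e-300), px)
    return GrayImage(out, image.spacing, image.source_id)
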