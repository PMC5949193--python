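"""Vertebra detection with a cascade of boosted Haar-feature classifiers.

A Viola-Jones style attentional cascade: window-normalized Haar-like
features (an extended set with edge, line, center-surround, and optional
diagonal kinds) are evaluated in constant time from integral images;
decision stumps over these features are combined by discrete AdaBoost into
stages; each stage rejects most remaining negatives cheaply and a window is
accepted only if every stage passes.  Negative windows for stage ``k`` are
mined from the negative pool among windows the first ``k-1`` stages still
accept (bootstrapping), so successive stages concentrate on the hard
negatives.  Detection slides the window over an image pyramid and groups
overlapping raw hits; a final median-area band filter removes outlier-sized
boxes, mirroring the size constraints a spine column imposes on plausible
vertebra detections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.transform import resize

from spineseg.imgio import BoundingBox, GrayImage, load_model_json, save_model_json

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("edge_h", "edge_v", "line_h", "line_v", "center_surround", "tilted_edge")


class TrainingError(RuntimeError):
    """AdaBoost could not make progress (no stump beats chance)."""


@dataclass
class IntegralImage:
    """Cumulative-sum tables of an image (plain and squared), zero-padded.

    ``ii[r + 1, c + 1]`` is the sum of pixels in ``[0..r] x [0..c]``; the
    squared table supports window variance normalization.
    """

    ii: np.ndarray
    ii2: np.ndarray
    pixels: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def integral(image: GrayImage | np.ndarray) -> IntegralImage:
    """Build integral images (sum and squared-sum) with a zero border."""
    px = image.pixels if isinstance(image, GrayImage) else np.asarray(image, dtype=float)
    ii = np.zeros((px.shape[0] + 1, px.shape[1] + 1))
    ii2 = np.zeros_like(ii)
    np.cumsum(np.cumsum(px, axis=0), axis=1, out=ii[1:, 1:])
    np.cumsum(np.cumsum(px * px, axis=0), axis=1, out=ii2[1:, 1:])
    return IntegralImage(ii=ii, ii2=ii2, pixels=px)


def _rect_sum(ii: np.ndarray, x, y, w, h):
    """Sum of pixels in [y, y+h) x [x, x+w) via 4 lookups (vectorizable)."""
    return ii[y + h, x + w] - ii[y, x + w] - ii[y + h, x] + ii[y, x]


@dataclass
class HaarFeature:
    """A weighted-rectangle feature relative to the detection window.

    ``rects`` holds ``((x, y, w, h), weight)`` entries whose weighted areas
    sum to zero, so the response on a constant window vanishes.  The
    ``tilted_edge`` kind is a diagonal edge detector evaluated through a
    dense pixel mask rather than rectangle sums.
    """

    kind: str
    rects: list

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        total = sum(w * h * wt for (x, y, w, h), wt in self.rects)
        if abs(total) > 1e-9:
            raise ValueError("weighted rectangle areas must sum to zero")

    @property
    def tilted(self) -> bool:
        return self.kind == "tilted_edge"

    def mask(self, window: tuple[int, int]) -> np.ndarray:
        """Dense per-pixel weight image of this feature on a (w, h) window."""
        ww, wh = window
        m = np.zeros((wh, ww))
        if self.tilted:
            (x, y, w, h), _ = self.rects[0]
            jj, ii_ = np.meshgrid(np.arange(w), np.arange(h))
            block = np.where(ii_ > jj, -1.0, np.where(ii_ < jj, 1.0, 0.0))
            m[y : y + h, x : x + w] = block
        else:
            for (x, y, w, h), wt in self.rects:
                m[y : y + h, x : x + w] += wt
        return m


def generate_feature_pool(
    window: tuple[int, int] = (24, 24),
    feature_stride: int = 3,
    include_tilted: bool = False,
) -> list[HaarFeature]:
    """Enumerate Haar features on a stride grid of positions and sizes.

    The stride bounds the pool (and hence training cost); it is recorded in
    trained models.  Diagonal (``tilted_edge``) features are off by default.
    """
    ww, wh = window
    s = feature_stride
    feats: list[HaarFeature] = []
    sizes = [(w, h) for w in range(s, ww + 1, s) for h in range(s, wh + 1, s)]
    for w, h in sizes:
        for x in range(0, ww - 2 * w + 1, s):
            for y in range(0, wh - h + 1, s):
                feats.append(
                    HaarFeature("edge_v", [((x, y, w, h), 1.0), ((x + w, y, w, h), -1.0)])
                )
        for x in range(0, ww - w + 1, s):
            for y in range(0, wh - 2 * h + 1, s):
                feats.append(
                    HaarFeature("edge_h", [((x, y, w, h), 1.0), ((x, y + h, w, h), -1.0)])
                )
        for x in range(0, ww - 3 * w + 1, s):
            for y in range(0, wh - h + 1, s):
                feats.append(
                    HaarFeature(
                        "line_v", [((x, y, 3 * w, h), 1.0), ((x + w, y, w, h), -3.0)]
                    )
                )
        for x in range(0, ww - w + 1, s):
            for y in range(0, wh - 3 * h + 1, s):
                feats.append(
                    HaarFeature(
                        "line_h", [((x, y, w, 3 * h), 1.0), ((x, y + h, w, h), -3.0)]
                    )
                )
        for x in range(0, ww - 3 * w + 1, s):
            for y in range(0, wh - 3 * h + 1, s):
                feats.append(
                    HaarFeature(
                        "center_surround",
                        [((x, y, 3 * w, 3 * h), 1.0), ((x + w, y + h, w, h), -9.0)],
                    )
                )
    if include_tilted:
        for sz in range(2 * s, min(ww, wh) + 1, s):
            for x in range(0, ww - sz + 1, s):
                for y in range(0, wh - sz + 1, s):
                    feats.append(
                        HaarFeature(
                            "tilted_edge",
                            [((x, y, sz, sz), 1.0), ((x, y, sz, sz), -1.0)],
                        )
                    )
    return feats


def eval_feature(feature: HaarFeature, integ: IntegralImage, window: BoundingBox) -> float:
    """Variance-normalized response of one feature on one window.

    The weighted rectangle sum is divided by the window's intensity standard
    deviation; zero-variance windows return 0.
    """
    x0, y0 = int(round(window.x)), int(round(window.y))
    ww, wh = int(round(window.width)), int(round(window.height))
    h, w = integ.shape
    if x0 < 0 or y0 < 0 or x0 + ww > w or y0 + wh > h:
        raise ValueError("window out of image bounds")
    n = ww * wh
    s1 = _rect_sum(integ.ii, x0, y0, ww, wh)
    s2 = _rect_sum(integ.ii2, x0, y0, ww, wh)
    var = s2 / n - (s1 / n) ** 2
    if var <= 1e-12:
        return 0.0
    std = float(np.sqrt(var))
    if feature.tilted:
        win = integ.pixels[y0 : y0 + wh, x0 : x0 + ww]
        return float((feature.mask((ww, wh)) * win).sum() / std)
    raw = 0.0
    for (rx, ry, rw, rh), wt in feature.rects:
        raw += wt * _rect_sum(integ.ii, x0 + rx, y0 + ry, rw, rh)
    return float(raw / std)


# ---------------------------------------------------------------------------
# stumps and stages
# ---------------------------------------------------------------------------

@dataclass
class DecisionStump:
    """Threshold classifier on one feature with real-valued votes.

    The vote is ``left`` when the feature value is below ``threshold`` and
    ``right`` otherwise; ``polarity`` (+1/-1) records which side predicts
    the positive class.
    """

    feature_index: int
    threshold: float
    polarity: int
    left: float
    right: float

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be -1 or +1")

    def vote(self, values: np.ndarray) -> np.ndarray:
        return np.where(values < self.threshold, self.left, self.right)


@dataclass
class BoostedStage:
    """One AdaBoost stage: passes a sample iff the stump votes reach the threshold."""

    stumps: list
    stage_threshold: float
    hit_rate: float = float("nan")
    false_alarm: float = float("nan")

    def scores(self, feature_values: np.ndarray) -> np.ndarray:
        """Stage score per sample given the (n, n_features) value matrix."""
        total = np.zeros(feature_values.shape[0])
        for st in self.stumps:
            total += st.vote(feature_values[:, st.feature_index])
        return total

    def passes(self, feature_values: np.ndarray) -> np.ndarray:
        return self.scores(feature_values) >= self.stage_threshold


def _best_stump(F: np.ndarray, labels: np.ndarray, weights: np.ndarray) -> tuple:
    """Exhaustive weighted stump search over all features and thresholds.

    Returns ``(feature_index, threshold, polarity, error)`` minimizing the
    weighted 0-1 error; ties break toward the lowest feature index (stable).
    """
    n, m = F.shape
    order = np.argsort(F, axis=0, kind="stable")
    w_pos = np.where(labels > 0, weights, 0.0)
    w_neg = np.where(labels < 0, weights, 0.0)
    total_pos = w_pos.sum()
    total_neg = w_neg.sum()
    cols = np.arange(m)[None, :]
    Fs = F[order, cols]
    cum_pos = np.cumsum(w_pos[order], axis=0)
    cum_neg = np.cumsum(w_neg[order], axis=0)
    # split after position k (0..n-1): below = first k+1 sorted samples
    # polarity +1: predict + when f >= thr  -> err = pos_below + neg_above
    err_plus = np.vstack(
        [np.full((1, m), total_neg), cum_pos + (total_neg - cum_neg)]
    )
    err_minus = (total_pos + total_neg) - err_plus
    # invalid where threshold would fall between equal values
    tie = np.zeros_like(err_plus, dtype=bool)
    tie[1:-1] = Fs[:-1] == Fs[1:]
    err_plus = np.where(tie, np.inf, err_plus)
    err_minus = np.where(tie, np.inf, err_minus)

    best = np.inf
    best_tuple = None
    tol = 1e-12
    for errs, pol in ((err_plus, 1), (err_minus, -1)):
        # tolerance-aware tie-breaking: the smallest split index, then the
        # smallest feature index, with +1 polarity preferred
        col_min = errs.min(axis=0)
        k_idx = np.argmax(errs <= col_min[None, :] + tol, axis=0)
        feat_err = errs[k_idx, np.arange(m)]
        j = int(np.argmax(feat_err <= feat_err.min() + tol))
        if feat_err[j] < best - tol:
            k = int(k_idx[j])
            if k == 0:
                thr = Fs[0, j] - 1.0
            elif k == F.shape[0]:
                thr = Fs[-1, j] + 1.0
            else:
                thr = 0.5 * (Fs[k - 1, j] + Fs[k, j])
            best = float(feat_err[j])
            best_tuple = (j, float(thr), pol, best)
    return best_tuple


def train_stage(
    features: list,
    samples: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    params: dict | None = None,
    feature_values: np.ndarray | None = None,
) -> BoostedStage:
    """Train one boosted stage by discrete AdaBoost.

    ``samples`` are window-sized images (n, wh, ww); ``labels`` are +/-1 and
    ``weights`` sum to 1.  Stumps are added (each minimizing the weighted
    error over the whole pool, weights updated as
    ``w <- w * exp(alpha * 1[misclassified])`` with
    ``alpha = ln((1 - err) / err)`` and renormalized) until the stage
    reaches ``min_hit_rate`` with false alarm <= ``max_false_alarm`` on its
    training data — the stage threshold is lowered to meet the hit rate —
    or ``max_stumps`` is reached.
    """
    p = {"max_stumps": 25, "min_hit_rate": 0.995, "max_false_alarm": 0.5}
    if params:
        p.update(params)
    labels = np.asarray(labels, dtype=float)
    weights = np.asarray(weights, dtype=float).copy()
    if not ((labels > 0).any() and (labels < 0).any()):
        raise ValueError("need at least one positive and one negative sample")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("sample weights must sum to 1")
    if feature_values is None:
        feature_values = compute_feature_values(features, samples)
    F = feature_values

    stumps: list[DecisionStump] = []
    scores = np.zeros(F.shape[0])
    pos = labels > 0
    stage_threshold = 0.0
    hit = fa = float("nan")
    for _ in range(int(p["max_stumps"])):
        j, thr, pol, err = _best_stump(F, labels, weights)
        if err >= 0.5 - 1e-9:
            if not stumps:
                raise TrainingError("unlearnable stage: no stump beats chance")
            break
        err = max(err, 1e-10)
        alpha = float(np.log((1.0 - err) / err))
        left = -pol * alpha
        right = pol * alpha
        stump = DecisionStump(j, thr, pol, left, right)
        stumps.append(stump)
        vote = stump.vote(F[:, j])
        scores += vote
        miss = np.sign(vote) != labels
        weights = weights * np.exp(alpha * miss)
        weights = weights / weights.sum()

        # lower the stage threshold until the hit-rate target is met
        pos_scores = np.sort(scores[pos])
        k = int(np.floor((1.0 - p["min_hit_rate"]) * pos_scores.size))
        stage_threshold = float(pos_scores[k] - 1e-9)
        hit = float((scores[pos] >= stage_threshold).mean())
        fa = float((scores[~pos] >= stage_threshold).mean())
        if hit >= p["min_hit_rate"] and fa <= p["max_false_alarm"]:
            break
    return BoostedStage(stumps, stage_threshold, hit_rate=hit, false_alarm=fa)


def compute_feature_values(features: list, samples: np.ndarray) -> np.ndarray:
    """Variance-normalized feature responses, (n_samples, n_features).

    Evaluated as dense mask dot products; equal to the integral-image route
    (the unit tests assert this equivalence).
    """
    samples = np.asarray(samples, dtype=float)
    n, wh, ww = samples.shape
    flat = samples.reshape(n, wh * ww)
    std = flat.std(axis=1)
    std = np.where(std <= 1e-12, np.inf, std)
    masks = np.stack([f.mask((ww, wh)).ravel() for f in features])
    return (flat @ masks.T) / std[:, None]


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeModel:
    """Ordered attentional cascade; a window is accepted iff all stages pass."""

    window: tuple[int, int]
    stages: list
    features: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("a cascade needs at least one stage")

    def accept(self, feature_values: np.ndarray) -> np.ndarray:
        """Cascade decision per sample (conjunction of the stage decisions)."""
        ok = np.ones(feature_values.shape[0], dtype=bool)
        for stage in self.stages:
            idx = np.nonzero(ok)[0]
            if idx.size == 0:
                break
            ok[idx] = stage.passes(feature_values[idx])
        return ok

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "metadata": self.metadata,
            "features": [{"kind": f.kind, "rects": f.rects} for f in self.features],
            "stages": [
                {
                    "stage_threshold": s.stage_threshold,
                    "hit_rate": s.hit_rate,
                    "false_alarm": s.false_alarm,
                    "stumps": [
                        {
                            "feature_index": st.feature_index,
                            "threshold": st.threshold,
                            "polarity": st.polarity,
                            "left": st.left,
                            "right": st.right,
                        }
                        for st in s.stumps
                    ],
                }
                for s in self.stages
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeModel":
        features = [
            HaarFeature(f["kind"], [(tuple(int(v) for v in r), wt) for r, wt in f["rects"]])
            for f in d["features"]
        ]
        stages = [
            BoostedStage(
                [
                    DecisionStump(
                        int(st["feature_index"]),
                        float(st["threshold"]),
                        int(st["polarity"]),
                        float(st["left"]),
                        float(st["right"]),
                    )
                    for st in s["stumps"]
                ],
                float(s["stage_threshold"]),
                hit_rate=float(s["hit_rate"]),
                false_alarm=float(s["false_alarm"]),
            )
            for s in d["stages"]
        ]
        return cls(tuple(d["window"]), stages, features, dict(d.get("metadata", {})))

    def save(self, path) -> None:
        save_model_json(self.to_dict(), path)

    @classmethod
    def load(cls, path) -> "CascadeModel":
        return cls.from_dict(load_model_json(path))


def _resize_window(crop: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Resample a crop to the detection window by bilinear interpolation."""
    ww, wh = window
    h, w = crop.shape
    ys = np.linspace(0, h - 1, wh)
    xs = np.linspace(0, w - 1, ww)
    from spineseg.preprocess import sample_bilinear

    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return sample_bilinear(crop, yy, xx)


def _accept_windows(windows: np.ndarray, stages: list, features: list) -> np.ndarray:
    """Cascade decision for window images, evaluating only the used features."""
    used = sorted({st.feature_index for s in stages for st in s.stumps})
    if not used:
        return np.ones(len(windows), dtype=bool)
    remap = {j: i for i, j in enumerate(used)}
    F = compute_feature_values([features[j] for j in used], windows)
    ok = np.ones(len(windows), dtype=bool)
    for stage in stages:
        idx = np.nonzero(ok)[0]
        if idx.size == 0:
            break
        scores = np.zeros(idx.size)
        for st in stage.stumps:
            vals = F[idx, remap[st.feature_index]]
            scores += np.where(vals < st.threshold, st.left, st.right)
        ok[idx] = scores >= stage.stage_threshold
    return ok


def train_cascade(
    positives: list,
    negatives: list,
    params: dict | None = None,
) -> CascadeModel:
    """Train an attentional cascade on positive crops and negative images.

    ``positives`` are vertebra crops (arrays or :class:`GrayImage`), resized
    to the detection window; ``negatives`` are vertebra-free images from
    which negative windows are mined by seeded random sampling.  Stage ``k``
    trains on all positives plus negatives accepted by stages ``1..k-1``.
    Training stops early (with a warning, yielding a valid model) when no
    false positives can be mined.
    """
    p = {
        "n_stages": 12,
        "min_hit_rate": 0.995,
        "max_false_alarm": 0.5,
        "window": (24, 24),
        "feature_stride": 3,
        "max_stumps": 25,
        "n_neg_per_stage": None,
        "min_neg_per_stage": 50,
        "include_tilted": False,
        "seed": 0,
    }
    if params:
        p.update(params)
    window = tuple(p["window"])
    ww, wh = window
    rng = np.random.default_rng(p["seed"])

    pos_windows = np.stack(
        [
            _resize_window(img.pixels if isinstance(img, GrayImage) else np.asarray(img, float), window)
            for img in positives
        ]
    )
    neg_images = [
        img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
        for img in negatives
    ]
    n_pos = len(pos_windows)
    n_neg = int(p["n_neg_per_stage"] or n_pos)

    features = generate_feature_pool(window, p["feature_stride"], p["include_tilted"])
    pos_F = compute_feature_values(features, pos_windows)

    stages: list[BoostedStage] = []
    log: list[dict] = []
    for k in range(int(p["n_stages"])):
        neg_windows = _mine_negatives(
            neg_images, stages, features, window, n_neg, rng
        )
        if len(neg_windows) < max(1, int(p["min_neg_per_stage"])) and stages:
            logger.warning(
                "stage %d: false positives exhausted (%d mined), stopping early",
                k + 1,
                len(neg_windows),
            )
            break
        if len(neg_windows) == 0:
            logger.warning("stage %d: no false positives mined, stopping early", k + 1)
            break
        neg_F = compute_feature_values(features, neg_windows)
        F = np.vstack([pos_F, neg_F])
        labels = np.concatenate([np.ones(n_pos), -np.ones(len(neg_windows))])
        weights = np.full(labels.size, 1.0 / labels.size)
        try:
            stage = train_stage(
                features,
                None,
                labels,
                weights,
                {
                    "max_stumps": p["max_stumps"],
                    "min_hit_rate": p["min_hit_rate"],
                    "max_false_alarm": p["max_false_alarm"],
                },
                feature_values=F,
            )
        except TrainingError:
            logger.warning("stage %d unlearnable, stopping early", k + 1)
            break
        stages.append(stage)
        log.append(
            {
                "stage": k + 1,
                "n_neg": len(neg_windows),
                "n_stumps": len(stage.stumps),
                "hit_rate": stage.hit_rate,
                "false_alarm": stage.false_alarm,
            }
        )
        logger.info(
            "stage %d: %d stumps, hit %.4f, fa %.4f",
            k + 1,
            len(stage.stumps),
            stage.hit_rate,
            stage.false_alarm,
        )

    if not stages:
        raise TrainingError("could not train any cascade stage")
    metadata = {
        "n_positives": n_pos,
        "n_negative_images": len(neg_images),
        "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in p.items()},
        "training_log": log,
    }
    return CascadeModel(window=window, stages=stages, features=features, metadata=metadata)


def _mine_negatives(
    neg_images: list,
    stages: list,
    features: list,
    window: tuple[int, int],
    n_needed: int,
    rng: np.random.Generator,
    max_attempts_factor: int = 300,
) -> np.ndarray:
    """Sample random windows from negative images that the cascade so far accepts."""
    ww, wh = window
    mined: list[np.ndarray] = []
    attempts = 0
    max_attempts = max_attempts_factor * n_needed
    batch = max(64, n_needed)
    while len(mined) < n_needed and attempts < max_attempts:
        crops = []
        for _ in range(batch):
            img = neg_images[rng.integers(len(neg_images))]
            h, w = img.shape
            max_scale = min(h / wh, w / ww)
            if max_scale < 1.0:
                continue
            scale = float(rng.uniform(1.0, min(max_scale, 3.0)))
            cw, ch = int(round(ww * scale)), int(round(wh * scale))
            x = int(rng.integers(0, w - cw + 1))
            y = int(rng.integers(0, h - ch + 1))
            crops.append(_resize_window(img[y : y + ch, x : x + cw], window))
        attempts += batch
        if not crops:
            break
        crops_arr = np.stack(crops)
        if stages:
            crops_arr = crops_arr[_accept_windows(crops_arr, stages, features)]
        mined.extend(crops_arr[: n_needed - len(mined)])
    if not mined:
        return np.zeros((0, wh, ww))
    return np.stack(mined)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _stage_features_used(model: CascadeModel) -> list:
    return sorted({st.feature_index for s in model.stages for st in s.stumps})


def detect(
    image: GrayImage,
    model: CascadeModel,
    scale_factor: float = 1.1,
    step_px: int = 2,
    min_neighbors: int = 3,
) -> list[BoundingBox]:
    """Multi-scale sliding-window detection.

    The image pyramid holds downscales at powers of ``scale_factor``; at
    each level the window slides with ``step_px``, accepted windows are
    mapped back to original coordinates, raw hits are grouped by connected
    components of the IoU >= 0.3 overlap graph, groups with fewer than
    ``min_neighbors`` raw hits are discarded, and each surviving group
    returns its mean box with the raw-hit count as score.
    """
    ww, wh = model.window
    px = image.pixels
    if px.shape[0] < wh or px.shape[1] < ww:
        raise ValueError("image smaller than the detection window")

    any_tilted = any(model.features[j].tilted for j in _stage_features_used(model))
    raw: list[BoundingBox] = []
    scale = 1.0
    while px.shape[0] / scale >= wh and px.shape[1] / scale >= ww:
        sh = int(round(px.shape[0] / scale))
        sw = int(round(px.shape[1] / scale))
        scaled = (
            px
            if scale == 1.0
            else resize(px, (sh, sw), anti_aliasing=True, preserve_range=True)
        )
        hits = _detect_single_scale(scaled, model, step_px, any_tilted)
        for x, y in hits:
            raw.append(
                BoundingBox(x=x * scale, y=y * scale, width=ww * scale, height=wh * scale)
            )
        scale *= scale_factor

    return group_detections(raw, min_neighbors=min_neighbors)


def _detect_single_scale(
    px: np.ndarray, model: CascadeModel, step_px: int, any_tilted: bool
) -> list[tuple[int, int]]:
    ww, wh = model.window
    h, w = px.shape
    xs = np.arange(0, w - ww + 1, step_px)
    ys = np.arange(0, h - wh + 1, step_px)
    gx, gy = np.meshgrid(xs, ys)
    gx = gx.ravel()
    gy = gy.ravel()
    if gx.size == 0:
        return []

    integ = integral(px)
    n = ww * wh
    s1 = _rect_sum(integ.ii, gx, gy, ww, wh)
    s2 = _rect_sum(integ.ii2, gx, gy, ww, wh)
    var = np.maximum(s2 / n - (s1 / n) ** 2, 0.0)
    std = np.sqrt(var)
    inv_std = np.where(std <= 1e-6, 0.0, 1.0 / np.maximum(std, 1e-300))

    alive = np.arange(gx.size)
    masks_cache: dict[int, np.ndarray] = {}
    for stage in model.stages:
        if alive.size == 0:
            break
        scores = np.zeros(alive.size)
        ax, ay = gx[alive], gy[alive]
        for st in stage.stumps:
            feat = model.features[st.feature_index]
            if feat.tilted:
                if st.feature_index not in masks_cache:
                    masks_cache[st.feature_index] = feat.mask((ww, wh)).ravel()
                m = masks_cache[st.feature_index]
                vals = np.empty(alive.size)
                for i in range(alive.size):
                    win = px[ay[i] : ay[i] + wh, ax[i] : ax[i] + ww]
                    vals[i] = win.ravel() @ m
                vals = vals * inv_std[alive]
            else:
                raw = np.zeros(alive.size)
                for (rx, ry, rw, rh), wt in feat.rects:
                    raw += wt * _rect_sum(integ.ii, ax + rx, ay + ry, rw, rh)
                vals = raw * inv_std[alive]
            scores += np.where(vals < st.threshold, st.left, st.right)
        alive = alive[scores >= stage.stage_threshold]
    return [(int(gx[i]), int(gy[i])) for i in alive]


def group_detections(raw: list[BoundingBox], min_neighbors: int = 3) -> list[BoundingBox]:
    """Group raw hits by IoU >= 0.3 connected components; mean box per group."""
    if not raw:
        return []
    arr = np.array([[b.x, b.y, b.width, b.height] for b in raw])
    x0 = arr[:, 0]
    y0 = arr[:, 1]
    x1 = arr[:, 0] + arr[:, 2]
    y1 = arr[:, 1] + arr[:, 3]
    area = arr[:, 2] * arr[:, 3]
    ix = np.maximum(0.0, np.minimum(x1[:, None], x1[None, :]) - np.maximum(x0[:, None], x0[None, :]))
    iy = np.maximum(0.0, np.minimum(y1[:, None], y1[None, :]) - np.maximum(y0[:, None], y0[None, :]))
    inter = ix * iy
    iou_mat = inter / (area[:, None] + area[None, :] - inter)
    adj = iou_mat >= 0.3
    n_comp, comp = connected_components(coo_matrix(adj), directed=False)
    out = []
    for c in range(n_comp):
        members = arr[comp == c]
        if len(members) < min_neighbors:
            continue
        mean = members.mean(axis=0)
        out.append(
            BoundingBox(
                x=float(mean[0]),
                y=float(mean[1]),
                width=float(mean[2]),
                height=float(mean[3]),
                score=float(len(members)),
            )
        )
    out.sort(key=lambda b: (-b.score, b.x, b.y))
    return out


def filter_by_size(detections: list[BoundingBox]) -> list[BoundingBox]:
    """Keep boxes whose area lies within [0.5, 2.0] times the median area.

    With fewer than 3 boxes the input is returned unchanged (no meaningful
    median).
    """
    if len(detections) < 3:
        return list(detections)
    areas = np.array([b.area for b in detections])
    m = float(np.median(areas))
    return [b for b, a in zip(detections, areas) if 0.5 * m <= a <= 2.0 * m]
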