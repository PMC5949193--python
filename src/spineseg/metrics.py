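"""Segmentation agreement statistics and evaluation protocols.

Overlap between an automatic segmentation ``A_S`` and a reference
segmentation ``A_T`` is measured by three area fractions:

* ``TPF = |A_S ∩ A_T| / |A_T|`` — true positive fraction,
* ``FNF = |A_T − A_S| / |A_T|`` — false negative fraction,
* ``FF  = 1 − (|A_FP| + |A_FN|) / |A_T|`` with ``A_FP = A_S − A_T`` —
  the combined-error ("false") fraction.

All three are reported as percentages; ``TPF + FNF = 100`` is an exact
pixel-count identity and ``FF <= TPF`` always (``FF`` may go negative for
gross over-segmentation; it is reported unclamped).

Summaries follow the mean ± half-width convention with the 95%
normal-approximation half-width ``1.96 * sigma / sqrt(n)`` (sample sigma,
n−1 denominator).  Inter-rater consistency of measured areas uses the
two-way intraclass correlation coefficient (consistency by default,
absolute agreement selectable), for single and for average measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from spineseg.imgio import BinaryMask, LandmarkSet


class UndefinedMetricError(ValueError):
    """The metric is undefined for the given input (e.g. empty reference)."""


# ---------------------------------------------------------------------------
# overlap fractions
# ---------------------------------------------------------------------------

@dataclass
class FractionReport:
    """Pixel counts and percentage fractions of one mask pair."""

    a_T: int
    a_S: int
    a_TP: int
    a_FN: int
    a_FP: int
    TPF: float
    FNF: float
    FF: float


def fractions(a_S: BinaryMask, a_T: BinaryMask) -> FractionReport:
    """Overlap fractions of an automatic mask against a reference mask."""
    if a_S.shape != a_T.shape:
        raise ValueError("masks must share a shape")
    t = a_T.pixels
    s = a_S.pixels
    n_t = int(t.sum())
    if n_t == 0:
        raise UndefinedMetricError("reference mask is empty; fractions undefined")
    n_tp = int((s & t).sum())
    n_fn = int((t & ~s).sum())
    n_fp = int((s & ~t).sum())
    tpf = 100.0 * n_tp / n_t
    fnf = 100.0 * n_fn / n_t
    ff = 100.0 * (1.0 - (n_fp + n_fn) / n_t)
    return FractionReport(
        a_T=n_t, a_S=int(s.sum()), a_TP=n_tp, a_FN=n_fn, a_FP=n_fp, TPF=tpf, FNF=fnf, FF=ff
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class SummaryStat:
    """Mean with 95% normal-approximation half-width and sample sigma."""

    mean: float
    halfwidth: float
    sigma: float
    n: int


def summarize(values, alpha: float = 0.05) -> SummaryStat:
    """Mean ± half-width summary of a sample.

    The half-width is ``z * sigma / sqrt(n)`` with the conventional
    two-decimal z-score 1.96 at ``alpha = 0.05`` (the exact normal quantile
    is used for other levels) and sigma the n−1 standard deviation.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    z = 1.96 if alpha == 0.05 else float(stats.norm.ppf(1.0 - alpha / 2.0))
    sigma = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SummaryStat(
        mean=float(arr.mean()),
        halfwidth=z * sigma / np.sqrt(arr.size),
        sigma=sigma,
        n=int(arr.size),
    )


# ---------------------------------------------------------------------------
# convergence protocol
# ---------------------------------------------------------------------------

def convergence_table(
    shapes_per_iteration: list,
    expert_masks: list,
    spacing: tuple[float, float] = (1.0, 1.0),
    image_shape: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-iteration overlap fractions of a fit trace against reference masks.

    Each iteration's shape is interpolated into a closed centripetal
    Catmull-Rom contour, rasterized, and compared with every reference
    mask; the final columns hold the arithmetic mean across references.
    Row ``iteration`` 0 is the initialization.
    """
    from spineseg import contour as contour_mod

    if not expert_masks:
        raise ValueError("need at least one reference mask")
    shape = image_shape if image_shape is not None else expert_masks[0].shape
    rows = []
    for it, shp in enumerate(shapes_per_iteration):
        pts = shp.points if isinstance(shp, LandmarkSet) else np.asarray(shp, float)
        cont = contour_mod.catmull_rom_closed(pts)
        mask = contour_mod.rasterize(cont, shape, spacing)
        row = {"iteration": it}
        acc = np.zeros(3)
        for e, ref in enumerate(expert_masks, start=1):
            rep = fractions(mask, ref)
            row[f"TPF_{e}"] = rep.TPF
            row[f"FNF_{e}"] = rep.FNF
            row[f"FF_{e}"] = rep.FF
            acc += (rep.TPF, rep.FNF, rep.FF)
        acc /= len(expert_masks)
        row["TPF_mean"], row["FNF_mean"], row["FF_mean"] = acc
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

@dataclass
class IccResult:
    """Two-way ICC of one rater pair, single and average measures."""

    single: float
    average: float
    ci_low: float
    ci_high: float
    model: str


def icc_pair(x, y, model: str = "two-way consistency", alpha: float = 0.05) -> IccResult:
    """Two-way intraclass correlation between two raters.

    Subjects are rows, the two raters columns of a two-way ANOVA without
    replication.  ``two-way consistency`` rates relative agreement
    (ICC(C,1)); ``two-way agreement`` penalizes systematic offsets
    (ICC(A,1)).  Average-measures values follow Spearman-Brown; the
    confidence interval (single measures, consistency definition) comes
    from the F distribution at level ``alpha``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("raters must give equal-length 1D samples")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    if np.allclose(subj_means, subj_means[0]):
        raise UndefinedMetricError("zero between-subject variance; ICC undefined")

    ss_rows = k * ((subj_means - grand) ** 2).sum()
    ss_cols = n * ((rater_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    if model == "two-way consistency":
        single = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
        average = (ms_r - ms_e) / ms_r if ms_r > 0 else float("nan")
    elif model == "two-way agreement":
        denom = ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e)
        single = (ms_r - ms_e) / denom
        average = (ms_r - ms_e) / (ms_r + (ms_c - ms_e) / n)
    else:
        raise ValueError("model must be 'two-way consistency' or 'two-way agreement'")

    # F-based CI for the consistency single-measures coefficient
    if ms_e > 0:
        f_obs = ms_r / ms_e
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, df1, df2)
        f_l = stats.f.ppf(1.0 - alpha / 2.0, df2, df1)
        fl = f_obs / f_u
        fu = f_obs * f_l
        ci_low = (fl - 1.0) / (fl + k - 1.0)
        ci_high = (fu - 1.0) / (fu + k - 1.0)
    else:  # perfect agreement: the F ratio degenerates
        ci_low = ci_high = 1.0
    return IccResult(
        single=float(single),
        average=float(average),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        model=model,
    )


def icc_matrix(areas: np.ndarray, model: str = "two-way consistency"):
    """Pairwise ICC matrices over raters (rows) x subjects (columns).

    Returns ``(single, average, rbar)``: symmetric matrices with NaN
    diagonals and the per-rater mean of the off-diagonal entries (the
    r̄ summary of each rater against all others).
    """
    areas = np.asarray(areas, dtype=float)
    if areas.ndim != 2 or areas.shape[0] < 2:
        raise ValueError("need a raters x subjects matrix with >= 2 raters")
    r = areas.shape[0]
    single = np.full((r, r), np.nan)
    average = np.full((r, r), np.nan)
    for i in range(r):
        for j in range(i + 1, r):
            res = icc_pair(areas[i], areas[j], model=model)
            single[i, j] = single[j, i] = res.single
            average[i, j] = average[j, i] = res.average
    rbar = np.nanmean(single, axis=1)
    return single, average, rbar


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def kfold_split(n_items: int, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Seeded shuffle split into k folds with sizes differing by <= 1."""
    if not 2 <= k <= n_items:
        raise ValueError("need 2 <= k <= n_items")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    return [np.sort(f) for f in np.array_split(order, k)]


def crossval(
    dataset: list,
    k: int = 10,
    seed: int = 0,
    fit_config: dict | None = None,
    noise: dict | None = None,
    aam_params: dict | None = None,
) -> pd.DataFrame:
    """k-fold cross-validation of the landmark fitter against ground truth.

    ``dataset`` holds (image, gt_landmarks) pairs grouped per image (a list
    of lists, so folds never split an image's vertebrae).  Per fold the AAM
    is trained on the complement, every held-out vertebra is fitted from a
    perturbed ground-truth initialization, the fitted and ground-truth
    shapes are both interpolated with closed Catmull-Rom contours and
    rasterized, and TPF/FNF/FF are summarized per fold.  The final row is
    the arithmetic mean of the per-fold statistics.
    """
    from spineseg import aam as aam_mod
    from spineseg import contour as contour_mod

    if k < 2:
        raise ValueError("k must be >= 2 (training folds would be empty)")
    folds = kfold_split(len(dataset), k=k, seed=seed)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for fold_no, fold in enumerate(folds, start=1):
        held = set(int(i) for i in fold)
        train = [pair for i, group in enumerate(dataset) if i not in held for pair in group]
        model = aam_mod.build_appearance_model(train, **(aam_params or {}))
        vals = {m: [] for m in ("TPF", "FNF", "FF")}
        for i in sorted(held):
            for image, gt in dataset[i]:
                init = aam_mod.perturb_shape(gt, noise=noise, seed=int(rng.integers(2**31)))
                res = aam_mod.fit(image, model, init, fit_config)
                auto = contour_mod.rasterize(
                    contour_mod.catmull_rom_closed(res.final.points), image.shape, image.spacing
                )
                ref = contour_mod.rasterize(
                    contour_mod.catmull_rom_closed(gt.points), image.shape, image.spacing
                )
                rep = fractions(auto, ref)
                vals["TPF"].append(rep.TPF)
                vals["FNF"].append(rep.FNF)
                vals["FF"].append(rep.FF)
        row = {"fold": fold_no, "n": len(vals["TPF"])}
        for m in ("TPF", "FNF", "FF"):
            stat = summarize(vals[m])
            row[f"{m}_mean"] = stat.mean
            row[f"{m}_halfwidth"] = stat.halfwidth
            row[f"sigma_{m}"] = stat.sigma
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = {"fold": "mean", "n": int(df["n"].sum())}
    for col in df.columns:
        if col not in ("fold", "n"):
            mean_row[col] = float(df[col].mean())
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
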