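"""Model-quality metrics and the MOP extrapolation screen.

AUC (rank-based, ties at 1/2), the 10% omission rate, partial ROC with a
bootstrap significance test, the Continuous Boyce Index on moving suitability
windows, and Mobility-Oriented Parity (strict-extrapolation mask plus a scaled
environmental-distance surface).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata, spearmanr

from .containers import EnvStack, OccurrenceSet, SuitabilityMap
from .errors import DataError

__all__ = [
    "EvalReport",
    "MOPResult",
    "auc",
    "omission_rate_10",
    "partial_roc",
    "continuous_boyce",
    "mop",
]


@dataclass
class EvalReport:
    """The evaluation metrics computed for one species x procedure run."""

    AUC_TRAIN: float = np.nan
    AUC_TEST: float = np.nan
    AUC_DIFF: float = np.nan
    OR10: float = np.nan
    pROC_ratio_mean: float = np.nan
    pROC_p: float = np.nan
    CBI_modern: float = np.nan
    CBI_projected: float = np.nan


def auc(pos_scores, neg_scores) -> float:
    """Rank-based AUC = U / (n_pos * n_neg), ties counted 1/2."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DataError("AUC needs non-empty positive and negative score lists")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def omission_rate_10(train_presence_scores, test_presence_scores) -> float:
    """Fraction of test presences scoring strictly below the 10th percentile
    (linear interpolation) of the training presence scores."""
    train = np.asarray(train_presence_scores, dtype=float)
    test = np.asarray(test_presence_scores, dtype=float)
    if train.size < 10 or test.size < 1:
        raise DataError("OR10 needs >= 10 training scores and >= 1 test score")
    thr = np.percentile(train, 10.0, method="linear")
    return float(np.mean(test < thr))


def _scores_at_points(map_: SuitabilityMap, points: OccurrenceSet) -> np.ndarray:
    r = points.ys - map_.origin[0]
    c = points.xs - map_.origin[1]
    H, W = map_.values.shape
    ok = (r >= 0) & (r < H) & (c >= 0) & (c < W)
    r, c = r[ok], c[ok]
    on = map_.mask[r, c]
    return map_.values[r[on], c[on]]


def partial_roc(
    map_: SuitabilityMap,
    test_points: OccurrenceSet,
    E: float = 0.05,
    iterations: int = 500,
    resample_frac: float = 0.5,
    seed: int = 0,
) -> tuple[float, float]:
    """Partial-ROC AUC ratio with omission threshold E and bootstrap p-value.

    Per iteration, a bootstrap sample of ``resample_frac`` of the test points
    is drawn; the model's partial area over the region with sensitivity
    >= 1 - E is divided by the analytic partial area of the uniform-score null
    (the diagonal) over the same proportion-of-area range.  p is the fraction
    of iterations with ratio <= 1.
    """
    scores = _scores_at_points(map_, test_points)
    if scores.size < 10:
        raise DataError("partial ROC needs at least 10 test points on valid cells")
    bg = np.sort(map_.valid_values)
    thresholds = np.quantile(bg, np.linspace(0.0, 1.0, 201))
    # x: fraction of area predicted present at each threshold (decreasing)
    x = 1.0 - np.searchsorted(bg, thresholds, side="left") / bg.size

    rng = np.random.default_rng(seed)
    n_boot = max(2, int(round(resample_frac * scores.size)))
    ratios = np.empty(iterations)
    sorted_iters = 0
    for it in range(iterations):
        samp = np.sort(rng.choice(scores, size=n_boot, replace=True))
        y = 1.0 - np.searchsorted(samp, thresholds, side="left") / n_boot
        keep = y >= 1.0 - E
        xs, ys = x[keep], y[keep]
        order = np.argsort(xs)
        xs, ys = xs[order], ys[order]
        if xs.size < 2 or xs[-1] == xs[0]:
            ratios[it] = np.nan
            continue
        area_model = np.trapezoid(ys, xs)
        area_null = 0.5 * (xs[-1] ** 2 - xs[0] ** 2)
        ratios[it] = area_model / area_null if area_null > 0 else np.nan
        sorted_iters += 1
    valid = ratios[np.isfinite(ratios)]
    if valid.size == 0:
        raise DataError("partial ROC: no iteration produced a usable curve")
    return float(valid.mean()), float(np.mean(valid <= 1.0))


def continuous_boyce(
    map_: SuitabilityMap,
    eval_points: OccurrenceSet,
    n_windows: int = 101,
    window_width_frac: float = 0.1,
    value_scale: str = "rank",
) -> float:
    """Continuous Boyce Index: Spearman correlation between the
    predicted-to-expected ratio P/E of moving suitability windows and the
    window midpoint.  Windows with zero expected fraction are skipped; a
    constant P/E profile (no trend) returns 0.

    With ``value_scale="rank"`` (default) both the map and the evaluation
    scores are first mapped to the map's empirical quantile scale, which makes
    the index exactly invariant under any strictly increasing transform of the
    suitability values; ``"raw"`` windows the observed value range directly,
    as in the classic formulation.
    """
    obs = _scores_at_points(map_, eval_points)
    if obs.size < 10:
        raise DataError("CBI needs at least 10 evaluation points on valid cells")
    bg = map_.valid_values
    if bg.max() <= bg.min():
        raise DataError("CBI is undefined on a constant map")
    if value_scale == "rank":
        order = np.sort(bg)
        lt = np.searchsorted(order, bg, side="left")
        le = np.searchsorted(order, bg, side="right")
        bg = (lt + le) / (2.0 * order.size)
        lt = np.searchsorted(order, obs, side="left")
        le = np.searchsorted(order, obs, side="right")
        obs = (lt + le) / (2.0 * order.size)
    elif value_scale != "raw":
        raise DataError(f"unknown value_scale {value_scale!r}")
    lo, hi = float(bg.min()), float(bg.max())
    width = window_width_frac * (hi - lo)
    mids = np.linspace(lo + width / 2.0, hi - width / 2.0, n_windows)

    ratios, centers = [], []
    for m in mids:
        a, b = m - width / 2.0, m + width / 2.0
        e = np.mean((bg >= a) & (bg <= b))
        if e == 0:
            continue
        p = np.mean((obs >= a) & (obs <= b))
        ratios.append(p / e)
        centers.append(m)
    if len(ratios) < 3:
        raise DataError("CBI needs at least 3 usable windows")
    rho = spearmanr(ratios, centers).statistic
    return 0.0 if np.isnan(rho) else float(rho)


@dataclass
class MOPResult:
    """Strict-extrapolation mask and scaled environmental distance surface."""

    distance_surface: np.ndarray  # (H, W), [0, 1], NaN off-mask
    strict_mask: np.ndarray  # (H, W) bool
    strict_pct: float


def mop(
    calib: EnvStack,
    proj: EnvStack,
    ref_pct: float = 0.10,
    chunk_rows: int = 2000,
) -> MOPResult:
    """Mobility-Oriented Parity of a projection stack against its calibration.

    A projection cell is a *strict* extrapolation when any variable falls
    outside the calibration min-max.  The distance surface is the mean
    Euclidean distance (on variables standardized by the calibration mean/sd)
    from each projection cell to its nearest ``ref_pct`` fraction of
    calibration cells, min-max scaled to [0, 1]; cells whose environment
    coincides exactly with a calibration cell are at distance 0.  Chunking is
    an implementation detail and does not affect the result.
    """
    if calib.names != proj.names:
        raise DataError("calibration and projection stacks must share layer names")
    cal_vals, _ = calib.table()
    if cal_vals.shape[0] < 10:
        raise DataError("MOP needs at least 10 valid calibration cells")
    proj_vals, proj_cells = proj.table()

    cal_min = cal_vals.min(axis=0)
    cal_max = cal_vals.max(axis=0)
    strict = np.any((proj_vals < cal_min) | (proj_vals > cal_max), axis=1)

    mean = cal_vals.mean(axis=0)
    sd = cal_vals.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Zc = (cal_vals - mean) / sd
    Zp = (proj_vals - mean) / sd

    k = max(1, int(np.ceil(ref_pct * Zc.shape[0])))
    dist = np.empty(Zp.shape[0])
    for start in range(0, Zp.shape[0], chunk_rows):
        chunk = Zp[start : start + chunk_rows]
        d = cdist(chunk, Zc)
        exact = d.min(axis=1) == 0.0
        part = np.partition(d, k - 1, axis=1)[:, :k]
        md = part.mean(axis=1)
        md[exact] = 0.0
        dist[start : start + chunk_rows] = md

    dmin, dmax = dist.min(), dist.max()
    scaled = np.zeros_like(dist) if dmax == dmin else (dist - dmin) / (dmax - dmin)
    if dmax > dmin:
        scaled[dist == 0.0] = 0.0

    surface = np.full(proj.shape, np.nan)
    surface[proj_cells[:, 0], proj_cells[:, 1]] = scaled
    strict_grid = np.zeros(proj.shape, dtype=bool)
    strict_grid[proj_cells[:, 0], proj_cells[:, 1]] = strict
    return MOPResult(
        distance_surface=surface,
        strict_mask=strict_grid,
        strict_pct=float(100.0 * strict.sum() / proj_vals.shape[0]),
    )
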