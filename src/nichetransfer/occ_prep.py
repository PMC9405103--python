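"""Occurrence cleaning cascade.

Four stages, applied per species: (1) thinning to one record per grid cell and
period, (2) removal of environmental outliers outside the level-0.975
Mahalanobis ellipsoid of each period's records, (3) balancing the historical
and modern datasets to equal size by greedily deleting the record whose
removal maximizes the Monte Carlo Jaccard overlap of the two niche ellipsoids,
and (4) setting aside the modern records discarded by balancing as the
independent modern test set.

Outlier removal runs per period (not pooled), in a single pass.  Because the
filtering acts in environmental space, the a-priori and PCA variable sets may
legitimately retain different record subsets for the same species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

from ._seeds import derive_seed
from .containers import EnvStack, OccurrenceSet
from .errors import DataError

__all__ = [
    "CleaningReport",
    "thin_to_cells",
    "remove_env_outliers",
    "ellipsoid_overlap",
    "balance_by_overlap",
    "clean_cascade",
]

DEFAULT_LEVEL = 0.975
DEFAULT_MC_POINTS = 20_000


@dataclass
class CleaningReport:
    """Per-period record counts along the cascade, plus the held-out test set."""

    n_input: dict[str, int] = field(default_factory=dict)
    n_after_thinning: dict[str, int] = field(default_factory=dict)
    n_after_outliers: dict[str, int] = field(default_factory=dict)
    n_after_balancing: dict[str, int] = field(default_factory=dict)
    discarded_modern_test: OccurrenceSet = field(default_factory=OccurrenceSet.empty)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_thinning": self.n_after_thinning,
            "n_after_outliers": self.n_after_outliers,
            "n_after_balancing": self.n_after_balancing,
            "n_modern_test": len(self.discarded_modern_test),
        }


def thin_to_cells(occ: OccurrenceSet, env: EnvStack) -> OccurrenceSet:
    """Keep at most one record per (species, period, cell); drop records on
    masked-out or off-grid cells.  First record in input order wins."""
    df = occ.records
    if df.empty:
        return OccurrenceSet.empty()
    on_grid = env.contains(occ.ys, occ.xs)
    df = df[on_grid]
    df = df.drop_duplicates(subset=["species", "period", "y", "x"], keep="first")
    return OccurrenceSet(df.copy(), dict(occ.crs_meta))


def _fit_ellipsoid(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and covariance; raises on singular covariance."""
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or not np.isfinite(logdet):
        raise DataError(
            "singular record covariance; use fewer variables or more records"
        )
    return mu, cov


def _mahalanobis2(X: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = X - mu
    try:
        cho = linalg.cho_factor(cov)
    except linalg.LinAlgError as exc:
        raise DataError(
            "singular record covariance; use fewer variables or more records"
        ) from exc
    return np.einsum("ij,ij->i", diff, linalg.cho_solve(cho, diff.T).T)


def remove_env_outliers(
    occ: OccurrenceSet, env: EnvStack, level: float = DEFAULT_LEVEL
) -> OccurrenceSet:
    """Drop records whose environment lies outside the level-quantile
    Mahalanobis ellipsoid of their period's records (single pass)."""
    L = len(env.names)
    kept = []
    for period, df in occ.records.groupby("period", sort=False):
        if len(df) < L + 2:
            raise DataError(
                f"period {period!r} has {len(df)} records; need at least L+2={L + 2} "
                "for covariance estimation"
            )
        X = env.values_at(df["y"].to_numpy(), df["x"].to_numpy())
        mu, cov = _fit_ellipsoid(X)
        md2 = _mahalanobis2(X, mu, cov)
        keep = md2 <= chi2.ppf(level, df=L)
        kept.append(df[keep])
    merged = pd.concat(kept).sort_index() if kept else occ.records.iloc[0:0]
    return OccurrenceSet(merged.copy(), dict(occ.crs_meta))


# ---------------------------------------------------------------------------
# ellipsoid overlap


def _ellipsoid_bbox(mu: np.ndarray, cov: np.ndarray, c: float) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounding box of {x : (x-mu)' cov^-1 (x-mu) <= c}."""
    half = np.sqrt(c * np.diag(cov))
    return mu - half, mu + half


def _membership(points: np.ndarray, mu: np.ndarray, cov_inv: np.ndarray, c: float) -> np.ndarray:
    diff = points - mu
    return np.einsum("ij,jk,ik->i", diff, cov_inv, diff) <= c


def ellipsoid_overlap(
    envA: np.ndarray,
    envB: np.ndarray,
    level: float = DEFAULT_LEVEL,
    n_points: int = DEFAULT_MC_POINTS,
    seed: int = 0,
) -> float:
    """Monte Carlo Jaccard overlap of the two level-quantile Mahalanobis
    ellipsoids fitted to the record-by-variable matrices.

    Points are sampled uniformly in the union's bounding box; membership is
    tested analytically.  Seeded and deterministic.
    """
    L = envA.shape[1]
    if envB.shape[1] != L:
        raise DataError("record matrices must share the variable dimension")
    c = chi2.ppf(level, df=L)
    muA, covA = _fit_ellipsoid(envA)
    muB, covB = _fit_ellipsoid(envB)
    loA, hiA = _ellipsoid_bbox(muA, covA, c)
    loB, hiB = _ellipsoid_bbox(muB, covB, c)
    lo = np.minimum(loA, loB)
    hi = np.maximum(hiA, hiB)

    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_points, L))
    inA = _membership(pts, muA, np.linalg.inv(covA), c)
    inB = _membership(pts, muB, np.linalg.inv(covB), c)
    union = int(np.sum(inA | inB))
    if union == 0:
        return 0.0
    return float(np.sum(inA & inB) / union)


def _greedy_overlap_deletion(
    pool_X: np.ndarray,
    target: int,
    c: float,
    pts: np.ndarray,
    in_fixed: np.ndarray,
    chunk: int = 32,
) -> list[int]:
    """Greedy deletion core: at each step drop the pool record whose removal
    maximizes the MC Jaccard with the fixed ellipsoid (ties -> input order).

    Leave-one-out means and covariances are computed by downdating the pooled
    sums, and candidate memberships are evaluated in chunks against the shared
    point cloud, so each step is a handful of dense einsums.
    """
    n_fixed_in = int(in_fixed.sum())
    fixed_idx = np.nonzero(in_fixed)[0]
    alive = list(range(pool_X.shape[0]))
    while len(alive) > target:
        X = pool_X[alive]
        n = X.shape[0]
        S1 = X.sum(axis=0)
        S2 = X.T @ X
        means = (S1[None, :] - X) / (n - 1)
        scat = (
            S2[None, :, :]
            - X[:, :, None] * X[:, None, :]
            - (n - 1) * means[:, :, None] * means[:, None, :]
        )
        covs = scat / (n - 2)
        overlaps = np.full(n, -1.0)
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            try:
                invs = np.linalg.inv(covs[sl])
            except np.linalg.LinAlgError:
                continue  # singular leave-one-out covariance: never the best drop
            diff = pts[None, :, :] - means[sl, None, :]
            quad = np.matmul(diff, invs)
            quad = np.einsum("cpi,cpi->cp", quad, diff)
            in_c = quad <= c
            inter = in_c[:, fixed_idx].sum(axis=1)
            union = in_c.sum(axis=1) + n_fixed_in - inter
            with np.errstate(invalid="ignore"):
                overlaps[sl] = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        del alive[int(np.argmax(overlaps))]
    return alive


def balance_by_overlap(
    hist: OccurrenceSet,
    mod: OccurrenceSet,
    envH: EnvStack,
    envM: EnvStack,
    seed: int = 0,
    level: float = DEFAULT_LEVEL,
    n_points: int = DEFAULT_MC_POINTS,
) -> tuple[OccurrenceSet, OccurrenceSet, OccurrenceSet, CleaningReport]:
    """Reduce the larger dataset to the smaller one's size by greedy deletion.

    At each step the record whose removal maximizes the ellipsoid overlap
    between the historical and modern niches is deleted (ties break to input
    order).  Modern records discarded here become the independent test set.
    A single seeded Monte Carlo point cloud (drawn in the union bounding box of
    the initial ellipsoids, which contains every later candidate ellipsoid) is
    reused across steps so the greedy path is deterministic.
    """
    L = len(envH.names)
    nH, nM = len(hist), len(mod)
    if min(nH, nM) < L + 2:
        raise DataError(f"both datasets need at least L+2={L + 2} records to balance")

    report = CleaningReport(
        n_after_balancing={"historical": min(nH, nM), "modern": min(nH, nM)}
    )
    if nH == nM:
        report.discarded_modern_test = OccurrenceSet.empty()
        return hist, mod, OccurrenceSet.empty(), report

    XH = envH.values_at(hist.ys, hist.xs)
    XM = envM.values_at(mod.ys, mod.xs)
    shrink_modern = nM > nH
    fixed_X, pool_X = (XH, XM) if shrink_modern else (XM, XH)
    pool_occ = mod if shrink_modern else hist
    target = min(nH, nM)

    c = chi2.ppf(level, df=L)
    mu_f, cov_f = _fit_ellipsoid(fixed_X)
    mu_p, cov_p = _fit_ellipsoid(pool_X)
    lo_f, hi_f = _ellipsoid_bbox(mu_f, cov_f, c)
    lo_p, hi_p = _ellipsoid_bbox(mu_p, cov_p, c)
    lo = np.minimum(lo_f, lo_p)
    hi = np.maximum(hi_f, hi_p)
    # pad: leave-one-out ellipsoids can poke slightly beyond the full-set box
    pad = 0.15 * (hi - lo)
    rng = np.random.default_rng(derive_seed(seed, "balance-overlap"))
    pts = rng.uniform(lo - pad, hi + pad, size=(n_points, L))
    in_fixed = _membership(pts, mu_f, np.linalg.inv(cov_f), c)

    alive = _greedy_overlap_deletion(pool_X, target, c, pts, in_fixed)

    kept_occ = OccurrenceSet(pool_occ.records.iloc[alive].copy(), dict(pool_occ.crs_meta))
    dropped_idx = sorted(set(range(pool_X.shape[0])) - set(alive))
    dropped = OccurrenceSet(pool_occ.records.iloc[dropped_idx].copy(), dict(pool_occ.crs_meta))

    if shrink_modern:
        hist_out, mod_out, test_mod = hist, kept_occ, dropped
    else:
        hist_out, mod_out, test_mod = kept_occ, mod, OccurrenceSet.empty()
    report.discarded_modern_test = test_mod
    return hist_out, mod_out, test_mod, report


def clean_cascade(
    occ: OccurrenceSet,
    envH: EnvStack,
    envM: EnvStack,
    seed: int = 0,
    level: float = DEFAULT_LEVEL,
    n_points: int = DEFAULT_MC_POINTS,
) -> tuple[OccurrenceSet, OccurrenceSet, OccurrenceSet, CleaningReport]:
    """Run the full cascade for one species on its period stacks.

    Returns (historical, modern, modern_test, report) with equal historical and
    modern sizes and monotone non-increasing counts along the cascade.
    """
    counts_in = {p: int((occ.records["period"] == p).sum()) for p in ("historical", "modern")}
    thin_h = thin_to_cells(occ.for_period("historical"), envH)
    thin_m = thin_to_cells(occ.for_period("modern"), envM)
    out_h = remove_env_outliers(thin_h, envH, level=level)
    out_m = remove_env_outliers(thin_m, envM, level=level)
    hist, mod, test_mod, report = balance_by_overlap(
        out_h, out_m, envH, envM, seed=seed, level=level, n_points=n_points
    )
    report.n_input = counts_in
    report.n_after_thinning = {"historical": len(thin_h), "modern": len(thin_m)}
    report.n_after_outliers = {"historical": len(out_h), "modern": len(out_m)}
    return hist, mod, test_mod, report
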