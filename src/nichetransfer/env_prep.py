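"""Derivation of environmental variables and the two alternative variable sets.

From monthly climate we derive the 19 standard bioclimatic variables plus
monthly and annual Thornthwaite potential evapotranspiration (PET).  Two model
spaces are then built: the three a-priori variables (annual mean temperature,
annual precipitation, annual PET) and the first three axes of a PCA over the
full derived stack, each period transformed independently.

Conventions (documented because they differ between implementations):

* monthly mean temperature = (tmin + tmax) / 2;
* "quarters" are all 12 runs of 3 consecutive months, wrapping across the year
  boundary (Dec-Jan-Feb counts); ties for wettest/warmest quarter break to the
  first run scanning Jan -> Dec;
* bio4 is the sample standard deviation (ddof=1) of monthly means x 100; bio15
  is 100 x sd(prec) / (1 + bio12/12);
* Thornthwaite PET uses the classic heat-index equations with the day-length
  correction disabled (12 h days, 30-day months), so PET depends on temperature
  only.  Units: °C for temperature layers, mm for precipitation and PET.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA

from .containers import EnvStack, MonthlyClimate, OccurrenceSet
from .errors import DataError

__all__ = [
    "derive_bioclim",
    "tailor_study_area",
    "select_apriori",
    "pca_reduce",
    "align_pca_axes",
    "APRIORI_LAYERS",
    "thornthwaite_pet",
]

APRIORI_LAYERS = ["bio1", "bio12", "pet_annual"]


def thornthwaite_pet(tavg: np.ndarray) -> np.ndarray:
    """Monthly Thornthwaite PET (mm) from monthly mean temperature (12, ...).

    I = sum_m (T_m/5)^1.514 over months with T_m > 0;
    a = 6.75e-7 I^3 - 7.71e-5 I^2 + 1.792e-2 I + 0.49239;
    PET_m = 16 (10 T_m / I)^a for T_m > 0, else 0.
    """
    t = np.maximum(tavg, 0.0)
    heat = ((t / 5.0) ** 1.514).sum(axis=0)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    with np.errstate(divide="ignore", invalid="ignore"):
        pet = 16.0 * (10.0 * t / heat) ** a
    pet = np.where((t > 0) & (heat > 0), pet, 0.0)
    return pet


def _quarter_stats(monthly: np.ndarray, reduce: str) -> np.ndarray:
    """Stack of the 12 wrap-around 3-month runs, reduced per run."""
    ext = np.concatenate([monthly, monthly[:2]], axis=0)
    runs = np.stack([ext[i : i + 3] for i in range(12)])  # (12 runs, 3, H, W)
    if reduce == "mean":
        return runs.mean(axis=1)
    return runs.sum(axis=1)


def derive_bioclim(mc: MonthlyClimate) -> EnvStack:
    """Derive bio1..bio19 + monthly/annual Thornthwaite PET from monthly climate."""
    for name in ("tmin", "tmax", "prec"):
        arr = getattr(mc, name)
        if np.all(~np.isfinite(arr[:, mc.mask])):
            raise DataError(f"input layer {name} is entirely NA on the mask")

    tavg = (mc.tmin + mc.tmax) / 2.0
    prec = mc.prec

    qt = _quarter_stats(tavg, "mean")  # quarter mean temperature
    qp = _quarter_stats(prec, "sum")  # quarter precipitation sum

    # first-encountered argmax/argmin scanning Jan->Dec (numpy default)
    wettest_q = qp.argmax(axis=0)
    driest_q = qp.argmin(axis=0)
    warmest_q = qt.argmax(axis=0)
    coldest_q = qt.argmin(axis=0)
    ii, jj = np.meshgrid(
        np.arange(mc.shape[0]), np.arange(mc.shape[1]), indexing="ij"
    )

    bio = {}
    bio["bio1"] = tavg.mean(axis=0)
    bio["bio2"] = (mc.tmax - mc.tmin).mean(axis=0)
    bio["bio4"] = tavg.std(axis=0, ddof=1) * 100.0
    bio["bio5"] = mc.tmax.max(axis=0)
    bio["bio6"] = mc.tmin.min(axis=0)
    bio["bio7"] = bio["bio5"] - bio["bio6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        bio["bio3"] = np.where(bio["bio7"] != 0, 100.0 * bio["bio2"] / bio["bio7"], 0.0)
    bio["bio8"] = qt[wettest_q, ii, jj]
    bio["bio9"] = qt[driest_q, ii, jj]
    bio["bio10"] = qt[warmest_q, ii, jj]
    bio["bio11"] = qt[coldest_q, ii, jj]
    bio["bio12"] = prec.sum(axis=0)
    bio["bio13"] = prec.max(axis=0)
    bio["bio14"] = prec.min(axis=0)
    bio["bio15"] = 100.0 * prec.std(axis=0, ddof=1) / (1.0 + bio["bio12"] / 12.0)
    bio["bio16"] = qp[wettest_q, ii, jj]
    bio["bio17"] = qp[driest_q, ii, jj]
    bio["bio18"] = qp[warmest_q, ii, jj]
    bio["bio19"] = qp[coldest_q, ii, jj]

    pet = thornthwaite_pet(tavg)
    names = [f"bio{i}" for i in range(1, 20)]
    layers = [bio[n] for n in names]
    for m in range(12):
        names.append(f"pet{m + 1:02d}")
        layers.append(pet[m])
    names.append("pet_annual")
    layers.append(pet.sum(axis=0))

    stack = np.stack(layers).astype(float)
    stack[:, ~mc.mask] = np.nan
    return EnvStack(layers=stack, names=names, mask=mc.mask.copy(), period=mc.period)


def crop_window(env: EnvStack, row0: int, row1: int, col0: int, col1: int) -> EnvStack:
    """Crop a stack to the inclusive window [row0, row1] x [col0, col1]
    (window coordinates); the result remembers its world origin."""
    return EnvStack(
        layers=env.layers[:, row0 : row1 + 1, col0 : col1 + 1].copy(),
        names=list(env.names),
        mask=env.mask[row0 : row1 + 1, col0 : col1 + 1].copy(),
        period=env.period,
        provenance=env.provenance,
        pca_loadings=None if env.pca_loadings is None else env.pca_loadings.copy(),
        pca_center_scale=env.pca_center_scale,
        pca_variable_names=env.pca_variable_names,
        explained_variance_ratio=env.explained_variance_ratio,
        origin=(env.origin[0] + row0, env.origin[1] + col0),
        aligned_to=env.aligned_to,
        crs_meta=dict(env.crs_meta),
    )


def tailor_study_area(
    env: EnvStack, occ: OccurrenceSet, buffer_cells: int = 10
) -> EnvStack:
    """Crop a stack to the bounding box of the records (both periods pooled)
    expanded by ``buffer_cells``, clipped at the grid edge.

    The result remembers its world ``origin`` so occurrence coordinates remain
    valid without re-indexing; tailoring an already tailored stack with the
    same inputs is a no-op.
    """
    if len(occ) == 0:
        raise DataError("cannot tailor a study area from an empty occurrence set")
    r, c = env.to_window(occ.ys, occ.xs)
    H, W = env.shape
    inside = (r >= 0) & (r < H) & (c >= 0) & (c < W)
    if not inside.any():
        raise DataError("no occurrence record falls on the stack's grid")
    r, c = r[inside], c[inside]
    r0 = max(int(r.min()) - buffer_cells, 0)
    r1 = min(int(r.max()) + buffer_cells, H - 1)
    c0 = max(int(c.min()) - buffer_cells, 0)
    c1 = min(int(c.max()) + buffer_cells, W - 1)
    return crop_window(env, r0, r1, c0, c1)


def select_apriori(env: EnvStack) -> EnvStack:
    """The three a-priori variables, fixed order: bio1, bio12, annual PET."""
    missing = [n for n in APRIORI_LAYERS if n not in env.names]
    if missing:
        raise DataError(f"a-priori selection requires layers {missing} absent from stack")
    idx = [env.names.index(n) for n in APRIORI_LAYERS]
    return EnvStack(
        layers=env.layers[idx].copy(),
        names=list(APRIORI_LAYERS),
        mask=env.mask.copy(),
        period=env.period,
        provenance="apriori3",
        origin=env.origin,
        crs_meta=dict(env.crs_meta),
    )


def pca_reduce(env: EnvStack, k: int = 3) -> EnvStack:
    """Standardize every layer over valid cells and return the first ``k`` PCA
    axis scores as layers, with loadings and centring/scaling attached."""
    L = len(env.names)
    if L < k:
        raise DataError(f"need at least {k} layers for a {k}-axis PCA, have {L}")
    vals, cells = env.table()
    if vals.shape[0] < k + 1:
        raise DataError("too few valid cells for PCA")
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0)
    constant = [env.names[j] for j in np.nonzero(sd == 0)[0]]
    if constant:
        raise DataError(f"constant layers have zero variance under standardization: {constant}")
    z = (vals - mean) / sd

    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(z)

    grids = np.full((k, *env.shape), np.nan)
    grids[:, cells[:, 0], cells[:, 1]] = scores.T
    return EnvStack(
        layers=grids,
        names=[f"pc{i + 1}" for i in range(k)],
        mask=env.mask.copy(),
        period=env.period,
        provenance="pca3" if k == 3 else "pca",
        pca_loadings=pca.components_.T.copy(),  # (variables, axes)
        pca_center_scale=(mean, sd),
        pca_variable_names=list(env.names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        origin=env.origin,
        crs_meta=dict(env.crs_meta),
    )


def align_pca_axes(target: EnvStack, reference: EnvStack) -> EnvStack:
    """Flip each axis of ``target`` whose loadings anticorrelate with the same
    axis of ``reference`` (periods are PCA-transformed independently, so signs
    are arbitrary; alignment makes cross-period projection well defined)."""
    if target.pca_loadings is None or reference.pca_loadings is None:
        raise DataError("both stacks must carry PCA loadings to align axes")
    if target.pca_variable_names != reference.pca_variable_names:
        raise DataError("PCA stacks were built over different variable lists")
    signs = np.sign(
        np.einsum("va,va->a", target.pca_loadings, reference.pca_loadings)
    )
    signs[signs == 0] = 1.0
    return EnvStack(
        layers=target.layers * signs[:, None, None],
        names=list(target.names),
        mask=target.mask.copy(),
        period=target.period,
        provenance=target.provenance,
        pca_loadings=target.pca_loadings * signs[None, :],
        pca_center_scale=target.pca_center_scale,
        pca_variable_names=target.pca_variable_names,
        explained_variance_ratio=target.explained_variance_ratio,
        origin=target.origin,
        aligned_to=reference.period,
        crs_meta=dict(target.crs_meta),
    )
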