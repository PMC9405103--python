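"""Replicated fitting, cross-period projection, and probabilistic binarization.

A model run splits the presences into training and testing subsets, draws a
fresh contrast sample (background or pseudoabsences, per the procedure's
rule), fits, and predicts over the study area; repeating this 10 times and
averaging the maps yields the run's suitability surface.  Projection to the
other period re-predicts every replicate's fitted adapter on the other
period's stack and averages again — it is never a resampling of the fitted
map.  Averaged maps are converted to binary maps through a logistic
suitability-to-probability curve whose midpoint is calibrated so the mean
occurrence probability over the study area equals the species' prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from ._seeds import derive_seed
from .algorithms import (
    AlgorithmAdapter,
    EnsembleAdapter,
    PROCEDURES,
    ProcedureSpec,
    fit_bioclim,
    fit_classifier,
    fit_domain,
    fit_kde,
    sample_background,
)
from .containers import BinaryMap, EnvStack, SuitabilityMap
from .errors import ConfigurationError, DataError
from .evaluation_metrics import auc

__all__ = [
    "ReplicateRun",
    "FittedModel",
    "run_replicates",
    "project",
    "prevalence_logistic_binarize",
    "compute_prevalence",
]

_MIN_PRESENCES = {"bioclim": 5, "domain": 2, "kde": None}  # kde: L+2 at runtime


@dataclass
class ReplicateRun:
    """One subsampling replicate: partition, fitted adapter, and its AUCs."""

    index: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    adapter: AlgorithmAdapter
    auc_train: float
    auc_test: float


@dataclass
class FittedModel:
    """An averaged suitability map plus the replicate adapters behind it."""

    map: SuitabilityMap
    replicates: list[ReplicateRun]
    procedure: str
    env_names: list[str]
    env_provenance: str
    require_alignment: bool = True

    @property
    def auc_train(self) -> float:
        return float(np.nanmean([r.auc_train for r in self.replicates]))

    @property
    def auc_test(self) -> float:
        return float(np.nanmean([r.auc_test for r in self.replicates]))


def _contrast_n(
    spec: ProcedureSpec, env: EnvStack, n_excluded: int = 0
) -> tuple[str, Optional[int]]:
    rule, n = spec.contrast_rule, spec.contrast_n
    if rule == "fixed_n":
        # large requests are capped at the study area size (minus presence
        # cells when the rule excludes them)
        n = min(n, env.n_valid - (n_excluded if spec.exclude_presences else 0))
    return rule, n


def _fit_single(
    spec: ProcedureSpec,
    train_X: np.ndarray,
    contrast_X: np.ndarray,
    seed: int,
) -> AlgorithmAdapter:
    if spec.learner is not None:
        return fit_classifier(
            train_X, contrast_X, learner=spec.learner, seed=seed,
            permute_labels=spec.permute_labels,
        )
    if spec.name == "bioclim":
        return fit_bioclim(train_X)
    if spec.name == "domain":
        return fit_domain(train_X)
    if spec.name == "kde":
        return fit_kde(train_X)
    raise ConfigurationError(f"no fitter for procedure {spec.name!r}")


def run_replicates(
    presence_env: np.ndarray,
    adapter_spec: "str | ProcedureSpec",
    env_fit: EnvStack,
    reps: int = 10,
    train_frac: float = 0.7,
    seed: int = 0,
    presence_cells: Optional[np.ndarray] = None,
    fresh_contrast: bool = True,
) -> FittedModel:
    """Fit ``reps`` seeded subsampling replicates and average their maps.

    Per replicate: a fresh train/test split of the presences, a fresh contrast
    sample per the procedure's rule (one shared draw across replicates when
    ``fresh_contrast`` is off), a fit, and a prediction over ``env_fit``.
    AUC_TRAIN / AUC_TEST contrast the train / test presence scores with the
    replicate's own contrast sample.
    """
    spec = PROCEDURES[adapter_spec] if isinstance(adapter_spec, str) else adapter_spec
    X = np.atleast_2d(np.asarray(presence_env, dtype=float))
    n = X.shape[0]
    n_train = int(round(train_frac * n))
    if n_train < 1 or (train_frac < 1.0 and n_train >= n):
        n_train = max(1, min(n - 1, n_train))
    minimum = _MIN_PRESENCES.get(spec.name)
    if minimum is None:
        minimum = X.shape[1] + 2
    if n_train < minimum:
        raise DataError(
            f"procedure {spec.name!r} needs at least {minimum} training presences; "
            f"a {train_frac} split of {n} gives {n_train}"
        )

    vals, cells = env_fit.table()
    grid_sum = np.zeros(env_fit.shape)
    replicates: list[ReplicateRun] = []
    for rep in range(reps):
        rng = np.random.default_rng(derive_seed(seed, "split", rep))
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        n_excl = 0 if presence_cells is None else len(presence_cells)
        rule, n_c = _contrast_n(spec, env_fit, n_excl)
        contrast_X = sample_background(
            env_fit,
            n=n_c,
            seed=derive_seed(seed, "contrast", rep if fresh_contrast else 0),
            rule=rule,
            presence_cells=presence_cells,
            exclude_presences=spec.exclude_presences,
        )
        fit_seed = derive_seed(seed, "fit", rep)
        if spec.name == "ensemble":
            members = [
                _fit_single(PROCEDURES[m], X[train_idx], contrast_X, fit_seed)
                for m in spec.members
            ]
            adapter = EnsembleAdapter(members)
            if test_idx.size:
                member_aucs = np.array(
                    [
                        auc(m.predict(X[test_idx]), m.predict(contrast_X))
                        for m in members
                    ]
                )
                keep = member_aucs >= 0.7
                if not keep.any():
                    keep = np.ones(len(members), dtype=bool)
                adapter.set_weights(np.where(keep, member_aucs, 0.0))
        else:
            adapter = _fit_single(spec, X[train_idx], contrast_X, fit_seed)

        pred_contrast = adapter.predict(contrast_X)
        auc_train = auc(adapter.predict(X[train_idx]), pred_contrast)
        auc_test = (
            auc(adapter.predict(X[test_idx]), pred_contrast) if test_idx.size else np.nan
        )
        pred = adapter.predict(vals)
        grid_sum[cells[:, 0], cells[:, 1]] += pred
        replicates.append(
            ReplicateRun(rep, train_idx, test_idx, adapter, auc_train, auc_test)
        )

    grid = np.full(env_fit.shape, np.nan)
    grid[cells[:, 0], cells[:, 1]] = grid_sum[cells[:, 0], cells[:, 1]] / reps
    avg = SuitabilityMap(
        values=grid,
        mask=env_fit.mask.copy(),
        source={
            "procedure": spec.name,
            "period_trained": env_fit.period,
            "period_projected": env_fit.period,
        },
        origin=env_fit.origin,
    )
    return FittedModel(
        map=avg,
        replicates=replicates,
        procedure=spec.name,
        env_names=list(env_fit.names),
        env_provenance=env_fit.provenance,
        require_alignment=env_fit.provenance == "pca3",
    )


def project(fitted: FittedModel, env_other: EnvStack) -> SuitabilityMap:
    """Re-predict every replicate adapter on another period's stack, averaged."""
    if env_other.provenance != fitted.env_provenance:
        raise DataError(
            f"cannot project a {fitted.env_provenance} model onto a "
            f"{env_other.provenance} stack"
        )
    if list(env_other.names) != fitted.env_names:
        raise DataError(
            f"layer mismatch: model fitted on {fitted.env_names}, "
            f"stack provides {list(env_other.names)}"
        )
    if (
        fitted.env_provenance == "pca3"
        and fitted.require_alignment
        and env_other.aligned_to is None
    ):
        raise DataError(
            "pca3 projection stack carries no axis-alignment metadata; align the "
            "modern axes to the historical ones (or fit with alignment disabled)"
        )
    vals, cells = env_other.table()
    acc = np.zeros(vals.shape[0])
    for rep in fitted.replicates:
        acc += rep.adapter.predict(vals)
    grid = np.full(env_other.shape, np.nan)
    grid[cells[:, 0], cells[:, 1]] = acc / len(fitted.replicates)
    return SuitabilityMap(
        values=grid,
        mask=env_other.mask.copy(),
        source={
            "procedure": fitted.procedure,
            "period_trained": fitted.map.source.get("period_trained"),
            "period_projected": env_other.period,
        },
        origin=env_other.origin,
    )


def compute_prevalence(n_presence_cells: int, env: EnvStack) -> float:
    """Species prevalence = presence cells / valid cells of the study area."""
    if env.n_valid == 0:
        raise DataError("study area has no valid cells")
    return n_presence_cells / env.n_valid


def prevalence_logistic_binarize(
    map_: SuitabilityMap,
    prevalence: float,
    alpha: float = 0.05,
    mode: str = "bernoulli",
    seed: int = 0,
) -> BinaryMap:
    """Convert suitability to presence/absence through a calibrated logistic.

    P(cell) = 1 / (1 + exp(-(s - beta)/alpha)) with beta solved so the mean of
    P over valid cells equals ``prevalence`` (tolerance 1e-6).  ``bernoulli``
    draws each cell independently with probability P; ``expected_threshold``
    marks cells with P >= 0.5; ``expected_count`` marks the round(prevalence
    x N) cells with the highest P (ties broken by a seeded random jitter), the
    deterministic variant that stays defined when the map plateaus and no cell
    reaches P = 0.5.
    """
    if not (0.0 < prevalence < 1.0):
        raise ConfigurationError("prevalence must be in (0, 1)")
    s = map_.valid_values
    if s.max() == s.min():
        raise DataError("cannot calibrate a conversion curve on a constant map")

    def mean_p(beta: float) -> float:
        return float(np.mean(expit((s - beta) / alpha))) - prevalence

    lo = float(s.min() - 60.0 * alpha)
    hi = float(s.max() + 60.0 * alpha)
    beta = brentq(mean_p, lo, hi, xtol=1e-12)
    if abs(mean_p(beta)) > 1e-6:
        raise DataError("prevalence calibration did not converge to tolerance 1e-6")

    P = expit((map_.values - beta) / alpha)
    if mode == "bernoulli":
        rng = np.random.default_rng(seed)
        draw = rng.random(map_.values.shape)
        vals = (draw < P).astype(float)
    elif mode == "expected_threshold":
        vals = (P >= 0.5).astype(float)
    elif mode == "expected_count":
        rows, cols = np.nonzero(map_.mask)
        p_valid = P[rows, cols]
        k = int(round(prevalence * p_valid.size))
        rng = np.random.default_rng(seed)
        jitter = rng.random(p_valid.size) * 1e-12
        top = np.argsort(-(p_valid + jitter), kind="stable")[:k]
        vals = np.zeros(map_.values.shape)
        vals[rows[top], cols[top]] = 1.0
    else:
        raise ConfigurationError(f"unknown binarization mode {mode!r}")
    vals[~map_.mask] = np.nan
    return BinaryMap(
        values=vals,
        mask=map_.mask.copy(),
        threshold_meta={
            "prevalence": prevalence,
            "alpha": alpha,
            "beta": float(beta),
            "mode": mode,
            "seed": seed,
        },
        origin=map_.origin,
    )
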