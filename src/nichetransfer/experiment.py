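"""Full experiment grid: species x procedures x variable sets.

For every cell of the grid the runner produces the paired distributions —
Distribution 1, trained on historical occurrences and projected to the modern
climate, and Distribution 2, trained on modern occurrences and climate — then
their comparison statistics (Schoener's D, stability, range-size variation,
distance to the ideal point) and, optionally, the evaluation metrics (AUC
family, OR10, partial ROC, CBI) against the held-out modern test records.
Kruskal-Wallis and Bonferroni-corrected pairwise Mann-Whitney tests compare
procedures at alpha = 0.01.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import derive_seed
from .algorithms import DEFAULT_PROCEDURES, PROCEDURES
from .comparison_metrics import (
    distance_to_ideal,
    range_size_variation,
    schoener_d,
    stability,
)
from .containers import EnvStack, OccurrenceSet
from .env_prep import align_pca_axes, derive_bioclim, pca_reduce, select_apriori, tailor_study_area
from .errors import DataError
from .evaluation_metrics import (
    EvalReport,
    continuous_boyce,
    mop,
    omission_rate_10,
    partial_roc,
)
from .occ_prep import clean_cascade
from .synthetic_world import Scenario, ScenarioConfig, generate_scenario
from .workflow import (
    compute_prevalence,
    prevalence_logistic_binarize,
    project,
    run_replicates,
)

__all__ = [
    "ExperimentGrid",
    "ExperimentConfig",
    "ExperimentResult",
    "SignificanceMatrix",
    "run_experiment",
    "kruskal_wallis",
    "pairwise_mann_whitney",
    "summarize",
    "default_benchmark_config",
    "BENCHMARK_PROCEDURES",
]

VARIABLE_SETS = ("apriori3", "pca3")

# cheap, well-behaved procedures used by the behavioural-recovery benchmark,
# plus the deliberately crippled permuted-label control
BENCHMARK_PROCEDURES = [
    "bioclim", "glm", "maxent_surrogate", "fda", "cta", "svm", "control_permuted",
]


@dataclass
class ExperimentGrid:
    """The design grid; its size bookkeeping is exact before anything runs."""

    species: list[str]
    procedures: list[str] = field(default_factory=lambda: list(DEFAULT_PROCEDURES))
    variable_sets: list[str] = field(default_factory=lambda: ["apriori3"])
    master_seed: int = 0

    def __post_init__(self) -> None:
        unknown = [p for p in self.procedures if p not in PROCEDURES]
        if unknown:
            raise DataError(f"unknown procedures: {unknown}")
        bad = [v for v in self.variable_sets if v not in VARIABLE_SETS]
        if bad:
            raise DataError(f"unknown variable sets: {bad}")

    @property
    def expected_rows(self) -> int:
        return len(self.species) * len(self.procedures) * len(self.variable_sets)

    def plan(self) -> pd.DataFrame:
        """One row per grid cell, with its derived sub-seed."""
        rows = [
            {
                "species": sp,
                "procedure": proc,
                "variable_set": vs,
                "seed": derive_seed(self.master_seed, sp, vs, proc),
            }
            for sp, vs, proc in itertools.product(
                self.species, self.variable_sets, self.procedures
            )
        ]
        return pd.DataFrame(rows)

    def raster_manifest(self) -> pd.DataFrame:
        """The tailored raster sets implied by the grid: one per species x
        variable set x period."""
        rows = [
            {"species": sp, "variable_set": vs, "period": period}
            for sp, vs, period in itertools.product(
                self.species, self.variable_sets, ("historical", "modern")
            )
        ]
        return pd.DataFrame(rows)


@dataclass
class ExperimentConfig:
    """Runtime knobs of the workflow (all defaults per the standard protocol)."""

    reps: int = 10
    train_frac: float = 0.7
    buffer_cells: int = 10
    binarize_mode: str = "bernoulli"
    binarize_alpha: float = 0.05
    outlier_level: float = 0.975
    overlap_mc_points: int = 20_000
    align_axes: bool = True
    evaluate: bool = True
    run_mop: bool = True


@dataclass
class ExperimentResult:
    """Results table plus per species x variable-set extras."""

    results: pd.DataFrame
    mop_summary: pd.DataFrame
    cleaning: dict[tuple[str, str], dict]
    failures: pd.DataFrame

    @property
    def ok(self) -> bool:
        return self.failures.empty


def _variable_set_stacks(
    scenario: Scenario, variable_set: str, align_axes: bool
) -> dict[str, EnvStack]:
    """Full-grid stacks for one variable set, each period transformed
    independently (modern PCA axes sign-aligned to historical when enabled)."""
    raw = {p: derive_bioclim(mc) for p, mc in scenario.climates.items()}
    if variable_set == "apriori3":
        return {p: select_apriori(s) for p, s in raw.items()}
    hist = pca_reduce(raw["historical"], k=3)
    mod = pca_reduce(raw["modern"], k=3)
    if align_axes:
        mod = align_pca_axes(mod, hist)
    return {"historical": hist, "modern": mod}


def run_experiment(
    scenario: Scenario,
    grid: ExperimentGrid,
    config: Optional[ExperimentConfig] = None,
    completed: Optional[pd.DataFrame] = None,
) -> ExperimentResult:
    """Run every cell of the grid on a realized scenario.

    Stage errors are recorded per cell and the run continues; rows for failed
    cells carry the error message in the ``error`` column.  Passing a previous
    results table as ``completed`` makes the run resumable: cells already
    present there (by species, procedure, variable_set) are skipped and their
    rows carried over unchanged.
    """
    config = config or ExperimentConfig()
    done: set[tuple[str, str, str]] = set()
    carried: list[dict] = []
    if completed is not None and not completed.empty:
        done = set(
            zip(completed["species"], completed["procedure"], completed["variable_set"])
        )
        carried = completed.to_dict(orient="records")
    rows: list[dict] = []
    mop_rows: list[dict] = []
    cleaning: dict[tuple[str, str], dict] = {}
    failures: list[dict] = []

    for vs in grid.variable_sets:
        full = _variable_set_stacks(scenario, vs, config.align_axes)
        for sp in grid.species:
            if all((sp, proc, vs) in done for proc in grid.procedures):
                continue
            occ_sp = scenario.occurrences.for_species(sp)
            try:
                envH = tailor_study_area(full["historical"], occ_sp, config.buffer_cells)
                envM = tailor_study_area(full["modern"], occ_sp, config.buffer_cells)
                hist, mod, test_mod, report = clean_cascade(
                    occ_sp, envH, envM,
                    seed=derive_seed(grid.master_seed, sp, vs, "clean"),
                    level=config.outlier_level,
                    n_points=config.overlap_mc_points,
                )
                cleaning[(sp, vs)] = report.to_dict()
                prev_h = compute_prevalence(len(hist), envH)
                prev_m = compute_prevalence(len(mod), envM)
                XH = envH.values_at(hist.ys, hist.xs)
                XM = envM.values_at(mod.ys, mod.xs)
                cellsH = np.column_stack([hist.ys, hist.xs])
                cellsM = np.column_stack([mod.ys, mod.xs])
                if config.run_mop:
                    res = mop(envH, envM)
                    mop_rows.append(
                        {"species": sp, "variable_set": vs, "strict_pct": res.strict_pct}
                    )
            except Exception as exc:  # noqa: BLE001 - per-cell failure capture
                for proc in grid.procedures:
                    failures.append(
                        {"species": sp, "procedure": proc, "variable_set": vs,
                         "error": f"{type(exc).__name__}: {exc}"}
                    )
                continue

            for proc in grid.procedures:
                if (sp, proc, vs) in done:
                    continue
                seed_cell = derive_seed(grid.master_seed, sp, vs, proc)
                try:
                    row = _run_cell(
                        sp, proc, vs, seed_cell, config,
                        envH, envM, XH, XM, cellsH, cellsM,
                        prev_h, prev_m, test_mod,
                    )
                except Exception as exc:  # noqa: BLE001
                    failures.append(
                        {"species": sp, "procedure": proc, "variable_set": vs,
                         "error": f"{type(exc).__name__}: {exc}"}
                    )
                    continue
                rows.append(row)

    return ExperimentResult(
        results=pd.DataFrame(carried + rows),
        mop_summary=pd.DataFrame(mop_rows),
        cleaning=cleaning,
        failures=pd.DataFrame(failures, columns=["species", "procedure", "variable_set", "error"]),
    )


def _run_cell(
    sp: str, proc: str, vs: str, seed: int, config: ExperimentConfig,
    envH: EnvStack, envM: EnvStack,
    XH: np.ndarray, XM: np.ndarray,
    cellsH: np.ndarray, cellsM: np.ndarray,
    prev_h: float, prev_m: float,
    test_mod: OccurrenceSet,
) -> dict:
    fitted_h = run_replicates(
        XH, proc, envH, reps=config.reps, train_frac=config.train_frac,
        seed=derive_seed(seed, "hist"), presence_cells=cellsH,
    )
    projected = project(fitted_h, envM)
    fitted_m = run_replicates(
        XM, proc, envM, reps=config.reps, train_frac=config.train_frac,
        seed=derive_seed(seed, "mod"), presence_cells=cellsM,
    )
    modern_map = fitted_m.map

    bin1 = prevalence_logistic_binarize(
        projected, prev_h, alpha=config.binarize_alpha,
        mode=config.binarize_mode, seed=derive_seed(seed, "bin1"),
    )
    bin2 = prevalence_logistic_binarize(
        modern_map, prev_m, alpha=config.binarize_alpha,
        mode=config.binarize_mode, seed=derive_seed(seed, "bin2"),
    )

    D = schoener_d(projected, modern_map)
    S = stability(bin1, bin2)
    RSV = range_size_variation(bin1, bin2)
    d = distance_to_ideal(D, S, RSV)

    report = EvalReport()
    if config.evaluate:
        report.AUC_TRAIN = fitted_m.auc_train
        report.AUC_TEST = fitted_m.auc_test
        report.AUC_DIFF = report.AUC_TRAIN - report.AUC_TEST
        if len(test_mod) >= 10:
            train_scores = modern_map.values_at(cellsM[:, 0], cellsM[:, 1])
            test_scores = modern_map.values_at(test_mod.ys, test_mod.xs)
            report.OR10 = omission_rate_10(train_scores, test_scores)
            # a metric can be legitimately undefined for one cell (e.g. a
            # strict envelope omitting > E of the test points at every
            # positive threshold): report NaN, keep the comparison row
            try:
                report.pROC_ratio_mean, report.pROC_p = partial_roc(
                    projected, test_mod, seed=derive_seed(seed, "proc")
                )
            except DataError:
                pass
            try:
                report.CBI_modern = continuous_boyce(modern_map, test_mod)
                report.CBI_projected = continuous_boyce(projected, test_mod)
            except DataError:
                pass

    return {
        "species": sp, "procedure": proc, "variable_set": vs,
        "D": D, "S": S, "RSV": RSV, "d": d,
        "AUC_TRAIN": report.AUC_TRAIN, "AUC_TEST": report.AUC_TEST,
        "AUC_DIFF": report.AUC_DIFF, "OR10": report.OR10,
        "pROC_ratio_mean": report.pROC_ratio_mean, "pROC_p": report.pROC_p,
        "CBI_modern": report.CBI_modern, "CBI_projected": report.CBI_projected,
        "auc_train_hist": fitted_h.auc_train, "auc_test_hist": fitted_h.auc_test,
    }


# ---------------------------------------------------------------------------
# statistics layer


def kruskal_wallis(groups: "list[np.ndarray] | dict[str, np.ndarray]") -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value.

    All values identical across all groups is degenerate, not an error:
    returns (0, 1).
    """
    vals = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(vals) < 2 or any(len(g) == 0 for g in vals):
        raise DataError("Kruskal-Wallis needs >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in vals])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*vals)
    return float(H), float(p)


@dataclass
class SignificanceMatrix:
    """Pairwise Mann-Whitney p-values and corrected significance flags."""

    pvalues: pd.DataFrame
    significant: pd.DataFrame
    alpha: float
    correction: str
    threshold: float

    @property
    def n_significant(self) -> int:
        names = list(self.significant.index)
        return int(
            sum(
                bool(self.significant.loc[a, b])
                for i, a in enumerate(names)
                for b in names[i + 1 :]
            )
        )


def pairwise_mann_whitney(
    groups: dict[str, np.ndarray],
    alpha: float = 0.01,
    correction: str = "bonferroni",
) -> SignificanceMatrix:
    """Two-sided, tie-corrected normal-approximation Mann-Whitney tests on all
    group pairs; Bonferroni significance iff p < alpha / m, m = g(g-1)/2."""
    names = list(groups.keys())
    if len(names) < 2:
        raise DataError("need at least 2 groups")
    for k, v in groups.items():
        if len(v) < 2:
            raise DataError(f"group {k!r} has fewer than 2 values")
    m = len(names) * (len(names) - 1) // 2
    if correction == "bonferroni":
        threshold = alpha / m
    elif correction == "none":
        threshold = alpha
    else:
        raise DataError(f"unknown correction {correction!r}")

    p = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ga = np.asarray(groups[a], dtype=float)
            gb = np.asarray(groups[b], dtype=float)
            if np.all(np.concatenate([ga, gb]) == ga[0]):
                pv = 1.0  # identical constant groups: no evidence of difference
            else:
                pv = stats.mannwhitneyu(
                    ga, gb, alternative="two-sided", method="asymptotic",
                    use_continuity=True,
                ).pvalue
            p.loc[a, b] = p.loc[b, a] = float(pv)
    sig = p < threshold
    return SignificanceMatrix(
        pvalues=p, significant=sig, alpha=alpha, correction=correction,
        threshold=threshold,
    )


def _distance_class(d: float) -> str:
    if d < 60:
        return "low"
    if d <= 70:
        return "intermediate"
    return "high"


def summarize(results: pd.DataFrame) -> dict:
    """Per procedure x variable set summary, distance classes, RSV magnitude
    bins, and the scatter data (one point per species x procedure)."""
    if results.empty:
        raise DataError("no result rows to summarize")
    metric_cols = [
        c for c in ("D", "S", "RSV", "d", "CBI_modern", "CBI_projected")
        if c in results.columns
    ]
    means = (
        results.groupby(["variable_set", "procedure"])[metric_cols]
        .mean()
        .reset_index()
    )
    means["distance_class"] = means["d"].map(_distance_class)

    rsv_abs = results["RSV"].abs()
    rsv_bins = {
        "lt2": int((rsv_abs < 2).sum()),
        "2to5": int(((rsv_abs >= 2) & (rsv_abs <= 5)).sum()),
        "gt5": int((rsv_abs > 5).sum()),
    }
    scatter = results[["species", "procedure", "variable_set", "D", "S", "RSV", "d"]].copy()
    return {"means": means, "rsv_bins": rsv_bins, "scatter": scatter}


def default_benchmark_config() -> tuple[ScenarioConfig, ExperimentConfig]:
    """The default synthetic benchmark: 10 niche-conserved virtual species,
    moderate warming drift, 150 modern records per species (historical half),
    the cheap procedure panel plus the permuted-label control.  Binarization
    uses the deterministic expected_count mode so the comparison reflects map
    agreement rather than Bernoulli draw noise."""
    return ScenarioConfig(), ExperimentConfig(
        evaluate=False, run_mop=False, binarize_mode="expected_count"
    )


def run_benchmark(
    master_seed: int,
    procedures: Optional[list[str]] = None,
    variable_sets: Optional[list[str]] = None,
    scenario_cfg: Optional[ScenarioConfig] = None,
    config: Optional[ExperimentConfig] = None,
) -> ExperimentResult:
    """Realize the default benchmark scenario under ``master_seed`` and run it."""
    base_cfg, base_exp = default_benchmark_config()
    scenario_cfg = scenario_cfg or base_cfg
    scenario_cfg.seed = master_seed
    scenario = generate_scenario(scenario_cfg)
    grid = ExperimentGrid(
        species=scenario.species_ids,
        procedures=procedures or list(BENCHMARK_PROCEDURES),
        variable_sets=variable_sets or ["apriori3"],
        master_seed=master_seed,
    )
    return run_experiment(scenario, grid, config or base_exp)
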