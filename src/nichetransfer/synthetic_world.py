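"""Seeded synthetic climates and virtual species.

The generator produces two 30-year-style monthly climatologies ("historical"
and "modern") separated by a configurable drift, plus virtual species with
known Gaussian niches and occurrence samples drawn from their true suitability.
Climate fields are smoothed seeded white noise (spatial autocorrelation from a
Gaussian blur) on top of deterministic latitudinal and seasonal structure, so
every downstream stage is testable without any external download.

tmin/tmax are built as a mean field plus/minus a strictly positive diurnal
half-range, which guarantees tmax >= tmin by construction; drift noise is
applied to the mean field (one shared field for both temperature extremes) so
the ordering survives arbitrary drift settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import linalg
from scipy.ndimage import gaussian_filter

from ._seeds import derive_seed
from .containers import (
    EnvStack,
    MonthlyClimate,
    OccurrenceSet,
    SuitabilityMap,
    VirtualSpeciesSpec,
    OCC_COLUMNS,
)
from .errors import ConfigurationError, DataError

__all__ = [
    "DriftSpec",
    "BaseClimateConfig",
    "ScenarioConfig",
    "Scenario",
    "make_climate_pair",
    "true_suitability",
    "sample_occurrences",
    "make_virtual_species",
    "generate_scenario",
    "scenario_from_yaml",
]

MONTHS = np.arange(12)


@dataclass
class DriftSpec:
    """Additive climate change between the historical and modern period.

    Offsets are constants; ``*_gradient`` adds a north->south linear ramp whose
    total amplitude (top row to bottom row) equals the given value.
    ``noise_scale`` is the standard deviation of additional smoothed noise
    applied to the modern fields only (zero gives a purely deterministic
    drift).
    """

    temp_offset: float = 0.0  # °C, applied to both tmin and tmax
    prec_offset: float = 0.0  # mm / month
    temp_gradient: float = 0.0
    prec_gradient: float = 0.0
    noise_scale: float = 0.0

    def is_zero(self) -> bool:
        return all(
            v == 0.0
            for v in (
                self.temp_offset,
                self.prec_offset,
                self.temp_gradient,
                self.prec_gradient,
                self.noise_scale,
            )
        )


@dataclass
class BaseClimateConfig:
    """Deterministic backbone of the synthetic climate (temperate mid-latitude)."""

    mean_temp: float = 12.0  # °C annual mean at mid-grid
    lat_range: float = 8.0  # °C difference top (cold) to bottom (warm) row
    seasonal_amp: float = 9.0  # °C half-amplitude of the annual cycle
    diurnal_half_range: float = 4.0  # °C base half diurnal range
    spatial_temp_sd: float = 2.0  # °C sd of the smoothed temperature field
    base_prec: float = 70.0  # mm / month at mid-grid
    prec_seasonal_frac: float = 0.4  # winter-wet seasonal modulation
    prec_spatial_sd: float = 0.35  # sd of the log-scale precip field


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance smoothed white noise (spatially autocorrelated)."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def _lat_ramp(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """North (row 0) -> south linear ramp from -amplitude/2 to +amplitude/2."""
    H, W = shape
    ramp = np.linspace(-0.5, 0.5, H)[:, None] * amplitude
    return np.broadcast_to(ramp, (H, W)).copy()


def _make_base_climate(
    shape: tuple[int, int],
    base: BaseClimateConfig,
    roughness: float,
    rng: np.random.Generator,
    period: str,
) -> MonthlyClimate:
    H, W = shape
    mask = np.ones(shape, dtype=bool)

    tmean_field = (
        base.mean_temp
        + _lat_ramp(shape, base.lat_range)
        + base.spatial_temp_sd * _smooth_noise(rng, shape, roughness)
    )
    half_range = base.diurnal_half_range * (
        1.0 + 0.25 * np.abs(_smooth_noise(rng, shape, roughness))
    )
    prec_field = base.base_prec * np.exp(
        base.prec_spatial_sd * _smooth_noise(rng, shape, roughness)
        - 0.5 * base.prec_spatial_sd**2
    )

    season_t = np.cos(2 * np.pi * (MONTHS - 6) / 12.0)  # peak in July (month index 6)
    season_p = 1.0 + base.prec_seasonal_frac * np.cos(2 * np.pi * MONTHS / 12.0)

    tmin = np.empty((12, H, W))
    tmax = np.empty((12, H, W))
    prec = np.empty((12, H, W))
    for m in range(12):
        month_noise = 0.5 * _smooth_noise(rng, shape, roughness)
        tmean_m = tmean_field + base.seasonal_amp * season_t[m] + month_noise
        tmin[m] = tmean_m - half_range
        tmax[m] = tmean_m + half_range
        prec[m] = np.maximum(
            prec_field * season_p[m] * np.exp(0.2 * _smooth_noise(rng, shape, roughness)),
            0.0,
        )
    return MonthlyClimate(tmin=tmin, tmax=tmax, prec=prec, mask=mask, period=period)


def make_climate_pair(
    shape: tuple[int, int],
    drift_spec: DriftSpec,
    roughness: float = 4.0,
    seed: int = 0,
    base: Optional[BaseClimateConfig] = None,
) -> tuple[MonthlyClimate, MonthlyClimate]:
    """Generate a (historical, modern) climate pair with an additive drift.

    modern = historical + offsets + gradients + seeded smoothed noise; identical
    seed gives bitwise-identical output.
    """
    if len(shape) != 2 or shape[0] < 10 or shape[1] < 10:
        raise ConfigurationError(f"grid shape must be at least 10x10, got {shape}")
    if drift_spec.noise_scale < 0:
        raise ConfigurationError("drift noise_scale must be non-negative")
    if roughness <= 0:
        raise ConfigurationError("roughness (blur kernel width) must be positive")
    base = base or BaseClimateConfig()

    rng = np.random.default_rng(derive_seed(seed, "base-climate"))
    hist = _make_base_climate(shape, base, roughness, rng, period="historical")

    drift_rng = np.random.default_rng(derive_seed(seed, "drift"))
    dt = drift_spec.temp_offset + _lat_ramp(shape, drift_spec.temp_gradient)
    dp = drift_spec.prec_offset + _lat_ramp(shape, drift_spec.prec_gradient)
    if drift_spec.noise_scale > 0:
        dt = dt + drift_spec.noise_scale * _smooth_noise(drift_rng, shape, roughness)
        dp = dp + drift_spec.noise_scale * _smooth_noise(drift_rng, shape, roughness)

    modern = MonthlyClimate(
        tmin=hist.tmin + dt,
        tmax=hist.tmax + dt,
        prec=np.maximum(hist.prec + dp, 0.0),
        mask=hist.mask.copy(),
        period="modern",
    )
    return hist, modern


# ---------------------------------------------------------------------------
# virtual species


def true_suitability(spec: VirtualSpeciesSpec, env: EnvStack) -> SuitabilityMap:
    """Gaussian-niche suitability: s = s_max * exp(-1/2 (e-mu)' Sigma^-1 (e-mu))."""
    if spec.layer_names is not None:
        try:
            order = [env.names.index(n) for n in spec.layer_names]
        except ValueError as exc:
            raise DataError(f"species {spec.id} is defined over layers absent "
                            f"from the stack: {exc}") from exc
    else:
        if len(env.names) != spec.niche_mean.size:
            raise DataError("niche dimension does not match the stack's layer count")
        order = list(range(len(env.names)))

    vals, cells = env.table()
    e = vals[:, order]
    try:
        cho = linalg.cho_factor(spec.niche_cov)
    except linalg.LinAlgError as exc:
        raise DataError(f"niche covariance of {spec.id} is singular") from exc
    diff = e - spec.niche_mean
    md2 = np.einsum("ij,ij->i", diff, linalg.cho_solve(cho, diff.T).T)
    s = spec.max_suitability * np.exp(-0.5 * md2)

    grid = np.full(env.shape, np.nan)
    grid[cells[:, 0], cells[:, 1]] = s
    return SuitabilityMap(
        values=grid,
        mask=env.mask.copy(),
        source={"species": spec.id, "kind": "true_suitability", "period": env.period},
        origin=env.origin,
    )


def sample_occurrences(
    truth: SuitabilityMap,
    n: int,
    period: str,
    seed: int = 0,
    mode: str = "weighted",
    species: str = "sp",
) -> OccurrenceSet:
    """Draw occurrence records from a true suitability surface.

    ``weighted`` draws ``n`` distinct cells with probability proportional to
    suitability; ``bernoulli_then_subsample`` first realizes an independent
    Bernoulli(s) presence per cell and then subsamples ``n`` of the successes.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rows, cols = np.nonzero(truth.mask)
    s = truth.values[rows, cols]
    pos = s > 0
    rng = np.random.default_rng(seed)

    if mode == "weighted":
        n_pos = int(pos.sum())
        if n_pos < n:
            raise DataError(
                f"requested {n} occurrences but only {n_pos} cells have positive "
                f"suitability (shortfall {n - n_pos})"
            )
        p = s[pos] / s[pos].sum()
        idx = rng.choice(np.nonzero(pos)[0], size=n, replace=False, p=p)
    elif mode == "bernoulli_then_subsample":
        hits = np.nonzero(rng.random(s.size) < s)[0]
        if hits.size < n:
            raise DataError(
                f"Bernoulli realization produced {hits.size} presences, fewer than "
                f"the requested {n} (shortfall {n - hits.size})"
            )
        idx = rng.choice(hits, size=n, replace=False)
    else:
        raise ConfigurationError(f"unknown sampling mode {mode!r}")

    df = pd.DataFrame(
        {
            "species": species,
            "x": cols[idx] + truth.origin[1],
            "y": rows[idx] + truth.origin[0],
            "period": period,
            "source": "simulated",
        },
        columns=OCC_COLUMNS,
    )
    return OccurrenceSet(df)


def make_virtual_species(
    env: EnvStack,
    n_species: int,
    seed: int = 0,
    target_prevalence: float = 0.03,
    id_offset: int = 0,
) -> list[VirtualSpeciesSpec]:
    """Create Gaussian-niche species calibrated to a stenochorous prevalence.

    Each niche optimum is the environment of a randomly chosen valid cell of
    ``env`` (pass a cropped stack to anchor the niche inside an accessible
    range); the covariance is a scaled diagonal of the per-layer variances,
    with the scale solved by bisection so the fraction of cells with
    suitability > 0.5 lands at ``target_prevalence`` (restricted-range
    endemics occupy 1-5 % of cells).
    """
    vals, _ = env.table()
    sds = vals.std(axis=0)
    if np.any(sds == 0):
        raise DataError("cannot calibrate niches: an environmental layer is constant")
    rng = np.random.default_rng(derive_seed(seed, "species"))
    specs: list[VirtualSpeciesSpec] = []
    for i in range(id_offset, id_offset + n_species):
        mu = vals[rng.integers(vals.shape[0])]
        z2 = (((vals - mu) / sds) ** 2).sum(axis=1)

        def prevalence(scale: float) -> float:
            return float(np.mean(np.exp(-0.5 * z2 / scale) > 0.5))

        lo, hi = 1e-4, 1e3
        for _ in range(80):
            mid = np.sqrt(lo * hi)
            if prevalence(mid) < target_prevalence:
                lo = mid
            else:
                hi = mid
        scale = np.sqrt(lo * hi)
        specs.append(
            VirtualSpeciesSpec(
                id=f"vsp{i:02d}",
                niche_mean=mu.copy(),
                niche_cov=np.diag((sds**2) * scale),
                max_suitability=1.0,
                layer_names=list(env.names),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# scenario assembly


@dataclass
class ScenarioConfig:
    """The study conditions of the synthetic benchmark.

    Defaults emulate the target study design: two climate periods separated by
    a moderate warming drift, restricted-range species (1-5 % prevalence), and
    historical samples half the size of modern ones.
    """

    shape: tuple[int, int] = (100, 120)
    n_species: int = 10
    n_modern: int = 150
    hist_frac: float = 0.5  # historical sample size as a fraction of modern
    range_size: tuple[int, int] = (45, 45)  # accessible-area window per species
    drift: DriftSpec = field(
        default_factory=lambda: DriftSpec(temp_offset=1.0, noise_scale=0.1)
    )
    roughness: float = 4.0
    base: BaseClimateConfig = field(default_factory=BaseClimateConfig)
    target_prevalence: float = 0.03
    seed: int = 0


@dataclass
class Scenario:
    """A fully realized synthetic world."""

    climates: dict[str, MonthlyClimate]
    species: list[VirtualSpeciesSpec]
    occurrences: OccurrenceSet
    config: ScenarioConfig
    # per-species accessible range, world coords (row0, row1, col0, col1)
    windows: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Realize climates, species, and occurrence samples for a scenario.

    Species niches are defined over the three a-priori variables (annual mean
    temperature, annual precipitation, annual PET) of the *historical* stack.
    Each species is confined to a seeded rectangular accessible range (the
    dispersal-limited area of the BAM framework): its niche optimum is drawn
    from cells inside the range, prevalence is calibrated within it, and
    occurrences are sampled only from its cells — which is what makes the
    species stenochorous and the per-species study areas distinct.  Within the
    range, occurrences are drawn per period from that period's own true
    suitability (perfect-equilibrium assumption).
    """
    from .env_prep import crop_window, derive_bioclim, select_apriori

    hist, modern = make_climate_pair(
        cfg.shape, cfg.drift, roughness=cfg.roughness, seed=cfg.seed, base=cfg.base
    )
    env = {
        "historical": select_apriori(derive_bioclim(hist)),
        "modern": select_apriori(derive_bioclim(modern)),
    }
    H, W = cfg.shape
    wh = min(cfg.range_size[0], H)
    ww = min(cfg.range_size[1], W)
    rng = np.random.default_rng(derive_seed(cfg.seed, "ranges"))

    n_per_period = {
        "modern": cfg.n_modern,
        "historical": max(1, int(round(cfg.n_modern * cfg.hist_frac))),
    }
    specs: list[VirtualSpeciesSpec] = []
    windows: dict[str, tuple[int, int, int, int]] = {}
    parts = []
    for i in range(cfg.n_species):
        r0 = int(rng.integers(0, H - wh + 1))
        c0 = int(rng.integers(0, W - ww + 1))
        window = (r0, r0 + wh - 1, c0, c0 + ww - 1)
        sub_hist = crop_window(env["historical"], *window)
        (spec,) = make_virtual_species(
            sub_hist, 1, seed=derive_seed(cfg.seed, "niche", i),
            target_prevalence=cfg.target_prevalence, id_offset=i,
        )
        specs.append(spec)
        windows[spec.id] = window
        for period in ("historical", "modern"):
            sub = crop_window(env[period], *window)
            truth = true_suitability(spec, sub)
            parts.append(
                sample_occurrences(
                    truth,
                    n=n_per_period[period],
                    period=period,
                    seed=derive_seed(cfg.seed, "occ", spec.id, period),
                    species=spec.id,
                )
            )
    return Scenario(
        climates={"historical": hist, "modern": modern},
        species=specs,
        occurrences=OccurrenceSet.concat(parts),
        config=cfg,
        windows=windows,
    )



def scenario_from_yaml(path: str) -> ScenarioConfig:
    """Load a scenario configuration from YAML (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    drift = DriftSpec(**raw.pop("drift", {}))
    base = BaseClimateConfig(**raw.pop("base", {}))
    if "shape" in raw:
        raw["shape"] = tuple(raw["shape"])
    return ScenarioConfig(drift=drift, base=base, **raw)
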