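"""In-memory containers shared by every pipeline stage.

All grids are 2-D numpy arrays indexed ``[row, col]``; stacks are ``(L, H, W)``.
Grids are treated as planar: row/column indices are the only coordinates, and
any affine/CRS metadata supplied by a user raster is carried through untouched
in ``crs_meta``.

Occurrence records always live in *world* coordinates (the full simulated or
input grid). An :class:`EnvStack` cropped to a study area remembers its
``origin`` so records never need re-indexing as the mask is tailored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError

OCC_COLUMNS = ["species", "x", "y", "period", "source"]

PERIODS = ("historical", "modern")


# ---------------------------------------------------------------------------
# climate


@dataclass
class MonthlyClimate:
    """Twelve monthly grids each of tmin/tmax (°C) and precipitation sum (mm)."""

    tmin: np.ndarray  # (12, H, W)
    tmax: np.ndarray  # (12, H, W)
    prec: np.ndarray  # (12, H, W)
    mask: np.ndarray  # (H, W) bool
    period: str

    def __post_init__(self) -> None:
        for name in ("tmin", "tmax", "prec"):
            arr = getattr(self, name)
            if arr.shape != (12, *self.mask.shape):
                raise DataError(
                    f"{name} has shape {arr.shape}, expected (12, {self.mask.shape[0]}, "
                    f"{self.mask.shape[1]})"
                )
        m = self.mask
        if np.any(self.tmax[:, m] < self.tmin[:, m]):
            raise DataError("tmax < tmin on some masked cell")
        if np.any(self.prec[:, m] < 0):
            raise DataError("negative precipitation on some masked cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


# ---------------------------------------------------------------------------
# environmental stacks


@dataclass
class EnvStack:
    """Aligned multi-layer environmental grid with a validity mask.

    ``provenance`` is one of ``raw`` (derived variables), ``apriori3`` (the three
    a-priori variables) or ``pca3`` (first three PCA axis scores).  PCA stacks
    carry their loadings and per-variable centring/scaling so projections and
    axis alignment stay auditable.
    """

    layers: np.ndarray  # (L, H, W) float, NaN off-mask
    names: list[str]
    mask: np.ndarray  # (H, W) bool
    period: str
    provenance: str = "raw"
    pca_loadings: Optional[np.ndarray] = None  # (variables, axes)
    pca_center_scale: Optional[tuple[np.ndarray, np.ndarray]] = None
    pca_variable_names: Optional[list[str]] = None
    explained_variance_ratio: Optional[np.ndarray] = None
    origin: tuple[int, int] = (0, 0)  # world (row, col) of layers[:, 0, 0]
    aligned_to: Optional[str] = None  # pca3: period whose axis signs were matched
    crs_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layers.ndim != 3 or self.layers.shape[0] != len(self.names):
            raise DataError("layers must be (L, H, W) matching the names list")
        if self.layers.shape[1:] != self.mask.shape:
            raise DataError("layers and mask disagree on grid shape")
        if self.provenance == "apriori3" and len(self.names) != 3:
            raise DataError("apriori3 stacks carry exactly 3 layers")
        if self.provenance == "pca3":
            if len(self.names) != 3 or self.pca_loadings is None:
                raise DataError("pca3 stacks carry exactly 3 layers and loadings")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def table(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, cells): env vectors of valid cells and their
        window (row, col) indices."""
        rows, cols = np.nonzero(self.mask)
        vals = self.layers[:, rows, cols].T
        return vals, np.column_stack([rows, cols])

    def to_window(self, ys: np.ndarray, xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Translate world coordinates to window (row, col) indices."""
        return np.asarray(ys) - self.origin[0], np.asarray(xs) - self.origin[1]

    def contains(self, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
        """True where the world coordinates fall on a valid (masked-in) cell."""
        r, c = self.to_window(ys, xs)
        H, W = self.shape
        ok = (r >= 0) & (r < H) & (c >= 0) & (c < W)
        out = np.zeros(len(ok), dtype=bool)
        out[ok] = self.mask[r[ok], c[ok]]
        return out

    def values_at(self, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
        """Env vectors (n, L) at world coordinates; caller guarantees validity."""
        if not np.all(self.contains(ys, xs)):
            raise DataError("some coordinates fall off the grid or mask")
        r, c = self.to_window(ys, xs)
        return self.layers[:, r, c].T


# ---------------------------------------------------------------------------
# species & occurrences


@dataclass
class VirtualSpeciesSpec:
    """A Gaussian niche in environmental space with a known optimum."""

    id: str
    niche_mean: np.ndarray
    niche_cov: np.ndarray
    max_suitability: float = 1.0
    layer_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        mu = np.asarray(self.niche_mean, dtype=float)
        cov = np.asarray(self.niche_cov, dtype=float)
        if cov.shape != (mu.size, mu.size):
            raise DataError("niche_cov shape must match niche_mean length")
        if not np.allclose(cov, cov.T):
            raise DataError("niche_cov must be symmetric")
        if not (0 < self.max_suitability <= 1):
            raise DataError("max_suitability must be in (0, 1]")
        self.niche_mean = mu
        self.niche_cov = cov


@dataclass
class OccurrenceSet:
    """Species records with period labels and provenance, in world coordinates."""

    records: pd.DataFrame
    crs_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in OCC_COLUMNS if c not in self.records.columns]
        if missing:
            raise DataError(f"occurrence table is missing columns: {missing}")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def for_period(self, period: str) -> "OccurrenceSet":
        return OccurrenceSet(
            self.records[self.records["period"] == period].copy(), dict(self.crs_meta)
        )

    def for_species(self, species: str) -> "OccurrenceSet":
        return OccurrenceSet(
            self.records[self.records["species"] == species].copy(), dict(self.crs_meta)
        )

    @property
    def ys(self) -> np.ndarray:
        return self.records["y"].to_numpy(dtype=int)

    @property
    def xs(self) -> np.ndarray:
        return self.records["x"].to_numpy(dtype=int)

    @staticmethod
    def empty() -> "OccurrenceSet":
        return OccurrenceSet(pd.DataFrame(columns=OCC_COLUMNS))

    @staticmethod
    def concat(parts: list["OccurrenceSet"]) -> "OccurrenceSet":
        frames = [p.records for p in parts if len(p)]
        if not frames:
            return OccurrenceSet.empty()
        return OccurrenceSet(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# predictions


@dataclass
class SuitabilityMap:
    """Continuous [0, 1] prediction grid; NaN exactly off-mask."""

    values: np.ndarray  # (H, W)
    mask: np.ndarray
    source: dict = field(default_factory=dict)
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise DataError("values and mask disagree on grid shape")
        v = self.values[self.mask]
        if v.size and (np.any(~np.isfinite(v)) or v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise DataError("suitability values must be finite and within [0, 1] on mask")

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def values_at(self, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
        r = np.asarray(ys) - self.origin[0]
        c = np.asarray(xs) - self.origin[1]
        return self.values[r, c]


@dataclass
class BinaryMap:
    """Presence/absence grid produced by prevalence-calibrated binarization."""

    values: np.ndarray  # (H, W) float with {0, 1, NaN}
    mask: np.ndarray
    threshold_meta: dict = field(default_factory=dict)
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise DataError("values and mask disagree on grid shape")

    @property
    def presence_cells(self) -> set[tuple[int, int]]:
        rows, cols = np.nonzero(self.mask & (self.values == 1))
        return set(zip((rows + self.origin[0]).tolist(), (cols + self.origin[1]).tolist()))

    @property
    def n_presence(self) -> int:
        return int(np.nansum(self.values[self.mask]))
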