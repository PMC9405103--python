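"""Headline comparison statistics on a projected/modern distribution pair.

Schoener's D on normalized suitability surfaces, the percentage of stable
presence cells S, the signed range-size variation RSV, and the Euclidean
distance d of the triple (D, S, RSV) from the theoretical best performance
(D=1, S=100, RSV=0).  d mixes the three axes on their raw scales (D in [0,1],
S and RSV in percent), which is why its empirical ceiling sits near 100 for
|RSV| of a few percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import BinaryMap, SuitabilityMap
from .errors import ConfigurationError, DataError

__all__ = [
    "PairComparison",
    "schoener_d",
    "stability",
    "range_size_variation",
    "distance_to_ideal",
]


@dataclass
class PairComparison:
    """Per species x procedure x variable-set comparison record."""

    species: str
    procedure: str
    variable_set: str
    D: float
    S: float
    RSV: float
    d: float


def _check_pair(a, b) -> None:
    if a.values.shape != b.values.shape or not np.array_equal(a.mask, b.mask):
        raise DataError("maps must share grid and mask")


def schoener_d(map1: SuitabilityMap, map2: SuitabilityMap) -> float:
    """D = 1 - 1/2 sum |p_i - q_i| over maps normalized to sum 1 on the mask."""
    _check_pair(map1, map2)
    p = map1.valid_values.astype(float)
    q = map2.valid_values.astype(float)
    sp, sq = p.sum(), q.sum()
    if sp <= 0 or sq <= 0:
        raise DataError("Schoener's D is undefined for an all-zero map")
    return float(1.0 - 0.5 * np.abs(p / sp - q / sq).sum())


def stability(bin1: BinaryMap, bin2: BinaryMap, denominator: str = "union") -> float:
    """Percentage of presence cells shared by the two binary predictions.

    ``union`` (default) is Jaccard x 100: |A ∩ B| / |A ∪ B|; ``total_cells``
    divides by the number of valid cells instead.
    """
    _check_pair(bin1, bin2)
    A, B = bin1.presence_cells, bin2.presence_cells
    if denominator == "union":
        den = len(A | B)
        if den == 0:
            raise DataError("stability is undefined when both presence sets are empty")
    elif denominator == "total_cells":
        den = int(bin1.mask.sum())
        if den == 0:
            raise DataError("no valid cells")
    else:
        raise ConfigurationError(f"unknown denominator {denominator!r}")
    return float(100.0 * len(A & B) / den)


def range_size_variation(projected: BinaryMap, modern: BinaryMap) -> float:
    """Signed percent change of predicted range size,
    100 (|A_projected| - |A_modern|) / |A_modern|; positive = overestimation."""
    _check_pair(projected, modern)
    n_mod = modern.n_presence
    if n_mod == 0:
        raise DataError("RSV is undefined when the modern prediction has no presence cells")
    return float(100.0 * (projected.n_presence - n_mod) / n_mod)


def distance_to_ideal(D: float, S: float, RSV: float) -> float:
    """d = sqrt((1-D)^2 + (100-S)^2 + RSV^2) on raw scales."""
    if not (0.0 <= D <= 1.0):
        raise DataError(f"D must be in [0, 1], got {D}")
    if not (0.0 <= S <= 100.0):
        raise DataError(f"S must be in [0, 100], got {S}")
    return float(np.sqrt((1.0 - D) ** 2 + (100.0 - S) ** 2 + RSV**2))
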