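"""Entropy-method indicator weighting and the composite resource density index.

Weighting follows the classical information-entropy scheme: min-max
standardize each indicator, convert columns to share distributions, score each
indicator by one minus its normalized Shannon entropy, and normalize the
scores to weights.  The composite index u is the weighted sum of standardized
indicators; the density index divides u by population and land area through a
geometric mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import IndicatorPanel, Orientation

__all__ = [
    "DegenerateColumnError",
    "WeightVector",
    "minmax_standardize",
    "standardize_matrix",
    "entropy_weights",
    "composite_index",
    "chrdi",
    "chrdi_panel",
]

RESOURCE_INDICATORS = ("institutions", "health_technicians", "beds", "financial_subsidies")
POPULATION = "population_thousands"
AREA = "area_km2"


class DegenerateColumnError(ValueError):
    """Raised when an indicator column carries no usable variation."""


@dataclass(frozen=True)
class WeightVector:
    """Entropy weights with their intermediate quantities.

    ``entropy`` is the normalized Shannon entropy e_j of each column's share
    distribution, ``difference`` is g_j = 1 - e_j, and ``weights`` is
    g_j / sum(g), which sums to one.
    """

    indicators: tuple[str, ...]
    entropy: np.ndarray
    difference: np.ndarray
    weights: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "indicator": self.indicators,
                "entropy": self.entropy,
                "difference": self.difference,
                "weight": self.weights,
            }
        )


def minmax_standardize(values: np.ndarray, orientation: Orientation | str = Orientation.POSITIVE) -> np.ndarray:
    """Map values into [0, 1]; negative orientation reflects the scale."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateColumnError("need at least 2 values to standardize")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateColumnError("constant column cannot be min-max standardized")
    if Orientation(orientation) is Orientation.POSITIVE:
        return (x - lo) / (hi - lo)
    return (hi - x) / (hi - lo)


def standardize_matrix(wide: pd.DataFrame, panel: IndicatorPanel | None = None) -> pd.DataFrame:
    """Min-max standardize every column of a units x indicators frame."""
    out = {}
    for col in wide.columns:
        ori = panel.orientation(col) if panel is not None else Orientation.POSITIVE
        out[col] = minmax_standardize(wide[col].to_numpy(), ori)
    return pd.DataFrame(out, index=wide.index)


def entropy_weights(standardized: pd.DataFrame | np.ndarray, zero_offset: float = 0.0) -> WeightVector:
    """Entropy weights from a standardized units x indicators matrix.

    The share of unit i in column j is P_ij = x_ij / sum_i x_ij; the column
    entropy is e_j = -(1/ln m) * sum_i P_ij ln P_ij with 0*ln(0) taken as 0.
    ``zero_offset`` optionally shifts all entries before forming shares (some
    applied work adds e.g. 1e-4 instead of using the limit convention).
    """
    if isinstance(standardized, pd.DataFrame):
        names = tuple(str(c) for c in standardized.columns)
        x = standardized.to_numpy(dtype=float)
    else:
        x = np.asarray(standardized, dtype=float)
        names = tuple(f"x{j}" for j in range(x.shape[1]))
    m = x.shape[0]
    if m < 2:
        raise DegenerateColumnError("need at least 2 units")
    if (x < 0).any():
        raise ValueError("standardized values must be nonnegative")
    if zero_offset:
        x = x + zero_offset
    colsum = x.sum(axis=0)
    if (colsum <= 0).any():
        bad = [names[j] for j in np.flatnonzero(colsum <= 0)]
        raise DegenerateColumnError(f"all-zero column(s): {bad}")
    p = x / colsum
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e = -plogp.sum(axis=0) / np.log(m)
    g = 1.0 - e
    gsum = g.sum()
    if gsum <= 1e-15:
        raise DegenerateColumnError(
            "all columns are maximally even (g_j = 0 for every indicator); "
            "entropy weighting is undefined — supply manual weights"
        )
    return WeightVector(names, e, g, g / gsum)


def composite_index(standardized: pd.DataFrame | np.ndarray, weights: WeightVector) -> np.ndarray:
    """u_i = sum_j W_j * x'_ij for each unit row."""
    if isinstance(standardized, pd.DataFrame):
        if tuple(str(c) for c in standardized.columns) != weights.indicators:
            raise ValueError(
                f"indicator mismatch: matrix has {tuple(standardized.columns)}, "
                f"weights cover {weights.indicators}"
            )
        x = standardized.to_numpy(dtype=float)
    else:
        x = np.asarray(standardized, dtype=float)
        if x.shape[1] != len(weights.indicators):
            raise ValueError("column count does not match weight vector")
    return x @ weights.weights


def chrdi(u: float | np.ndarray, population_thousands: float | np.ndarray, area_km2: float | np.ndarray) -> float | np.ndarray:
    """Geometric mean of per-population and per-area density of the index."""
    pop = np.asarray(population_thousands, dtype=float)
    area = np.asarray(area_km2, dtype=float)
    if (pop <= 0).any() or (area <= 0).any():
        raise ValueError("population and area must be strictly positive")
    out = np.sqrt((np.asarray(u, dtype=float) / pop) * (np.asarray(u, dtype=float) / area))
    return float(out) if out.ndim == 0 else out


def chrdi_panel(
    panel: IndicatorPanel,
    indicators: tuple[str, ...] = RESOURCE_INDICATORS,
    mode: str = "per_year",
    zero_offset: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full entropy -> composite -> density pipeline over a panel.

    mode ``per_year`` standardizes and weights each year's cross-section
    independently; ``pooled`` standardizes and weights across the stacked
    unit-year observations, applying one weight vector to all years.

    Returns ``(index_table, weight_table)`` where the index table has columns
    (unit_id, year, u, chrdi) and the weight table (year, indicator, entropy,
    difference, weight); pooled mode reports year = -1.
    """
    if mode not in ("per_year", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    need = list(indicators) + [POPULATION, AREA]
    panel.require_balanced(need)

    idx_rows, w_rows = [], []

    def emit(year_label: int, wide: pd.DataFrame, meta: pd.DataFrame, wv: WeightVector) -> None:
        std = standardize_matrix(wide, panel)
        u = composite_index(std, wv)
        dens = chrdi(u, meta[POPULATION].to_numpy(), meta[AREA].to_numpy())
        for k, unit_year in enumerate(wide.index):
            unit, yr = unit_year if isinstance(unit_year, tuple) else (unit_year, year_label)
            idx_rows.append({"unit_id": unit, "year": yr, "u": u[k], "chrdi": dens[k]})
        wf = wv.as_frame()
        wf.insert(0, "year", year_label)
        w_rows.append(wf)

    if mode == "per_year":
        for year in panel.years:
            wide = panel.wide(year=year, indicators=list(indicators))
            meta = panel.wide(year=year, indicators=[POPULATION, AREA])
            wv = entropy_weights(standardize_matrix(wide, panel), zero_offset=zero_offset)
            emit(year, wide, meta, wv)
    else:
        wide = panel.wide(indicators=list(indicators))
        meta = panel.wide(indicators=[POPULATION, AREA])
        wv = entropy_weights(standardize_matrix(wide, panel), zero_offset=zero_offset)
        emit(-1, wide, meta, wv)

    index_table = pd.DataFrame(idx_rows).sort_values(["year", "unit_id"]).reset_index(drop=True)
    weight_table = pd.concat(w_rows, ignore_index=True)
    return index_table, weight_table
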