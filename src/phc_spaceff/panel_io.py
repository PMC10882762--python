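"""Panel data model, coordinate tables, spatial weights, and packaged fixtures.

The long-format :class:`IndicatorPanel` is the interchange type for every
downstream stage: entropy weighting, DEA, and the spatial Durbin model all
consume named indicator columns from it.  Spatial weights are built once and
shared by the Moran and SDM stages.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Orientation",
    "IndicatorPanel",
    "CoordinateTable",
    "SpatialWeights",
    "PanelSchemaError",
    "PanelValueError",
    "read_indicator_panel",
    "read_coordinates",
    "inverse_distance_weights",
    "load_fixture",
    "FIXTURE_NAMES",
]

EARTH_RADIUS_KM = 6371.0

FIXTURE_NAMES = ("table2_chrdi", "table4_efficiency", "table5_moran")


class PanelSchemaError(ValueError):
    """A required column is missing or mis-typed."""


class PanelValueError(ValueError):
    """A cell value violates a panel invariant (non-numeric, duplicate, ...)."""


class Orientation(str, enum.Enum):
    """Whether larger indicator values are better (positive) or worse."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


class Standardization(str, enum.Enum):
    NONE = "none"
    ROW = "row"


@dataclass(frozen=True)
class IndicatorPanel:
    """Long-format unit x year x indicator panel.

    Parameters
    ----------
    data
        Tidy frame with columns ``unit_id, year, indicator, value``.
    orientations
        Per-indicator orientation; indicators absent from the mapping default
        to :attr:`Orientation.POSITIVE`.
    """

    data: pd.DataFrame
    orientations: Mapping[str, Orientation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"unit_id", "year", "indicator", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise PanelSchemaError(f"panel is missing columns: {sorted(missing)}")
        dup = self.data.duplicated(["unit_id", "year", "indicator"])
        if dup.any():
            rows = self.data.loc[dup, ["unit_id", "year", "indicator"]]
            raise PanelValueError(
                "duplicate (unit, year, indicator) records: "
                + "; ".join(f"({r.unit_id}, {r.year}, {r.indicator})" for r in rows.itertuples())
            )
        vals = pd.to_numeric(self.data["value"], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            idx = self.data.index[bad][0]
            raise PanelValueError(f"non-finite value at row {idx}")
        for name in ("population_thousands", "area_km2"):
            sel = self.data["indicator"] == name
            if sel.any() and (self.data.loc[sel, "value"] <= 0).any():
                raise PanelValueError(f"{name} must be strictly positive")

    # -- accessors ---------------------------------------------------------

    @property
    def units(self) -> list[str]:
        return sorted(self.data["unit_id"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    @property
    def indicators(self) -> list[str]:
        return sorted(self.data["indicator"].unique())

    def orientation(self, indicator: str) -> Orientation:
        return Orientation(self.orientations.get(indicator, Orientation.POSITIVE))

    def wide(self, year: int | None = None, indicators: Sequence[str] | None = None) -> pd.DataFrame:
        """Pivot to units x indicators (one year) or (unit, year) x indicators."""
        df = self.data if year is None else self.data[self.data["year"] == year]
        if indicators is not None:
            missing = set(indicators) - set(df["indicator"].unique())
            if missing:
                raise PanelValueError(
                    f"indicators absent from panel{'' if year is None else f' in {year}'}: {sorted(missing)}"
                )
            df = df[df["indicator"].isin(indicators)]
        index = "unit_id" if year is not None else ["unit_id", "year"]
        out = df.pivot_table(index=index, columns="indicator", values="value", aggfunc="first")
        if out.isna().any().any():
            gaps = out.isna().stack()
            gaps = gaps[gaps].index.tolist()[:10]
            raise PanelValueError(f"panel is unbalanced; missing cells include {gaps}")
        if indicators is not None:
            out = out[list(indicators)]
        return out.sort_index()

    def require_balanced(self, indicators: Sequence[str]) -> None:
        """Raise unless every (unit, year) has every named indicator."""
        for year in self.years:
            self.wide(year=year, indicators=indicators)


@dataclass(frozen=True)
class CoordinateTable:
    """One representative point per unit, geographic or planar."""

    ids: tuple[str, ...]
    xy: np.ndarray  # (n, 2): (lon, lat) degrees, or planar (x, y)
    planar: bool = False

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise PanelValueError("duplicate unit ids in coordinate table")
        if self.xy.shape != (len(self.ids), 2):
            raise PanelSchemaError("coordinate array must be (n_units, 2)")

    def __len__(self) -> int:
        return len(self.ids)

    def distances(self) -> np.ndarray:
        """Pairwise distance matrix: great-circle km, or Euclidean if planar."""
        if self.planar:
            diff = self.xy[:, None, :] - self.xy[None, :, :]
            return np.hypot(diff[..., 0], diff[..., 1])
        lon = np.radians(self.xy[:, 0])
        lat = np.radians(self.xy[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
        return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class SpatialWeights:
    """n x n nonnegative weight matrix with zero diagonal."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    standardization: str = "none"
    kind: str = "custom"

    def __post_init__(self) -> None:
        w = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if w.shape != (n, n):
            raise PanelSchemaError(f"weight matrix must be {n}x{n}")
        if (w < 0).any():
            raise PanelValueError("spatial weights must be nonnegative")
        if np.abs(np.diag(w)).max(initial=0.0) > 0:
            raise PanelValueError("spatial weight diagonal must be zero")
        object.__setattr__(self, "matrix", w)

    @property
    def n(self) -> int:
        return len(self.ids)

    def row_standardized(self) -> "SpatialWeights":
        w = self.matrix.copy()
        sums = w.sum(axis=1, keepdims=True)
        nz = sums[:, 0] > 0
        w[nz] = w[nz] / sums[nz]
        return SpatialWeights(self.ids, w, standardization="row", kind=self.kind)

    def total(self) -> float:
        """Sum of all weights (the Moran normalizer)."""
        return float(self.matrix.sum())


# ---------------------------------------------------------------------------
# readers


def read_indicator_panel(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    orientations: Mapping[str, Orientation | str] | None = None,
) -> IndicatorPanel:
    """Read a tidy CSV into a validated :class:`IndicatorPanel`.

    ``schema`` maps canonical names (``unit_id, year, indicator, value``) to the
    column names actually present in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    schema = dict(schema or {})
    rename = {schema.get(k, k): k for k in ("unit_id", "year", "indicator", "value")}
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"{path.name}: missing columns {missing}")
    df = df.rename(columns=rename)[["unit_id", "year", "indicator", "value"]]
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = vals.isna() & df["value"].notna()
    if bad.any():
        raise PanelValueError(f"{path.name}: non-numeric value at row {int(df.index[bad][0])}")
    df["value"] = vals
    df["year"] = df["year"].astype(int)
    df["unit_id"] = df["unit_id"].astype(str)
    oris = {k: Orientation(v) for k, v in (orientations or {}).items()}
    return IndicatorPanel(df, oris)


def read_coordinates(path: str | Path, planar: bool = False) -> CoordinateTable:
    """Read a ``unit_id, lat, lon`` (or ``unit_id, x, y`` with planar=True) CSV."""
    df = pd.read_csv(path)
    if planar:
        cols = ("unit_id", "x", "y")
    else:
        cols = ("unit_id", "lat", "lon")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"coordinate file missing columns {missing}")
    ids = tuple(df["unit_id"].astype(str))
    if planar:
        xy = df[["x", "y"]].to_numpy(dtype=float)
    else:
        xy = df[["lon", "lat"]].to_numpy(dtype=float)
    return CoordinateTable(ids, xy, planar=planar)


def inverse_distance_weights(
    coords: CoordinateTable, standardization: str | Standardization = Standardization.NONE
) -> SpatialWeights:
    """Build w_ij = 1/d_ij weights; greater distance means smaller weight."""
    if len(coords) < 2:
        raise PanelValueError("need at least 2 units for spatial weights")
    std = Standardization(standardization)
    d = coords.distances()
    off = ~np.eye(len(coords), dtype=bool)
    if (d[off] <= 0).any():
        i, j = np.argwhere((d <= 0) & off)[0]
        raise PanelValueError(
            f"coincident coordinates for units {coords.ids[i]!r} and {coords.ids[j]!r}"
        )
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    out = SpatialWeights(coords.ids, w, standardization="none", kind="inverse_distance")
    if std is Standardization.ROW:
        out = out.row_standardized()
    return out


# ---------------------------------------------------------------------------
# packaged fixtures (values transcribed to 3 decimals exactly as printed)


def load_fixture(name: str) -> pd.DataFrame:
    """Return one of the packaged reference tables as a DataFrame.

    ``table2_chrdi``: province, year, chrdi (31 x 5).
    ``table4_efficiency``: province, year, traditional, corrected (31 x 5).
    ``table5_moran``: year, moran_i, expected, sd, z, p, p_censored (5 rows);
    ``p_censored`` marks p-values printed only as an upper bound.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    ref = resources.files("phc_spaceff.fixtures").joinpath(f"{name}.csv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p)
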