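"""Seeded generators emulating the statistical structure of every stage.

Three families: (1) production panels with a known Cobb–Douglas frontier and
half-normal inefficiency for DEA recovery tests, (2) spatial panels drawn
from the reduced form of the spatial Durbin model with known rho/beta/theta,
and (3) resource-indicator panels with unit size factors and a common upward
trend feeding the entropy/density stage.  Everything is deterministic given
(scenario, seed) and each generator returns a truth record sufficient to
reconstruct the draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dea_bootstrap import DeaInstance
from .panel_io import CoordinateTable, IndicatorPanel, SpatialWeights

__all__ = [
    "SyntheticScenario",
    "make_coordinates",
    "lattice_weights",
    "simulate_dea_panel",
    "simulate_sdm_panel",
    "simulate_indicator_panel",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Generator parameters shared across the simulation entry points."""

    N: int = 31
    T: int = 5
    start_year: int = 2016
    # frontier: output = A_t * prod(x_j^a_j) * exp(-u), u ~ |N(0, sigma_u^2)|
    frontier_exponents: tuple[float, ...] = (0.3, 0.3, 0.2)
    sigma_u: float = 0.3
    sigma_v: float = 0.0  # two-sided noise; off-model for DEA, keep 0
    productivity_trend: float = 0.0  # multiplicative drift of A_t per year
    n_outputs: int = 2
    # indicator panel
    indicator_trend: float = 0.06
    indicator_noise: float = 0.10
    # SDM process
    rho: float = 0.4
    beta: tuple[float, ...] = (1.0, -0.5)
    theta: tuple[float, ...] = (0.8, 0.0)
    sigma_eps: float = 0.5
    sigma_mu: float = 1.0
    fe_x_corr: float = 0.0  # correlation of unit effects with first regressor
    x_corr: float = 0.3  # cross-correlation between regressor columns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 4 or self.T < 1:
            raise ValueError("need N >= 4 and T >= 1")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        for v in (self.sigma_u, self.sigma_v, self.sigma_eps, self.sigma_mu,
                  self.indicator_noise):
            if v < 0:
                raise ValueError("variance parameters must be nonnegative")
        if len(self.beta) != len(self.theta):
            raise ValueError("beta and theta must have equal length")

    @property
    def years(self) -> list[int]:
        return [self.start_year + t for t in range(self.T)]


def make_coordinates(N: int, layout: str = "grid", seed: int | None = None) -> CoordinateTable:
    """Distinct planar points: smallest square lattice covering N, or uniform."""
    if N < 4:
        raise ValueError("need N >= 4")
    ids = tuple(f"u{i:03d}" for i in range(N))
    if layout == "grid":
        side = math.ceil(math.sqrt(N))
        pts = [(float(i % side), float(i // side)) for i in range(N)]
        xy = np.array(pts[:N])
    elif layout == "random":
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0.0, 100.0, size=(N, 2))
        # nudge any coincident pair apart (measure-zero, but be safe)
        while True:
            d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() > 1e-9:
                break
            i = int(np.argwhere(d <= 1e-9)[0][0])
            xy[i] += rng.uniform(-1, 1, 2)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return CoordinateTable(ids, xy, planar=True)


def lattice_weights(N: int, standardization: str = "row") -> SpatialWeights:
    """Rook-contiguity weights on the grid layout of :func:`make_coordinates`.

    Sparse neighbour structure gives much sharper identification of the
    spatial parameters than dense inverse-distance weights, so the recovery
    experiments use it.
    """
    coords = make_coordinates(N, "grid")
    xy = coords.xy
    w = (np.abs(xy[:, None, :] - xy[None, :, :]).sum(axis=-1) == 1.0).astype(float)
    np.fill_diagonal(w, 0.0)
    out = SpatialWeights(coords.ids, w, kind="binary_contiguity")
    return out.row_standardized() if standardization == "row" else out


def simulate_dea_panel(
    scenario: SyntheticScenario, rts: str = "vrs", seed: int | None = None
) -> tuple[dict[int, DeaInstance], dict]:
    """Production panels with known radial input efficiency per DMU.

    Inputs are log-normal; the frontier is A_t * prod(x_j^a_j) with exponents
    summing to at most 1 (VRS) or exactly 1 (CRS); observed outputs are the
    frontier level scaled by exp(-u) and split over ``n_outputs`` fixed
    shares, so the true input-oriented efficiency is exp(-u / sum(a)).
    """
    a = np.asarray(scenario.frontier_exponents, dtype=float)
    ra = a.sum()
    rts = rts.lower()
    if rts == "crs" and not np.isclose(ra, 1.0):
        a = a / ra
        ra = 1.0
    elif rts == "vrs" and ra > 1.0 + 1e-12:
        raise ValueError("VRS frontier needs sum of exponents <= 1")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    shares = np.linspace(1.0, 2.0, scenario.n_outputs)
    shares /= shares.sum()
    instances: dict[int, DeaInstance] = {}
    truth = {"rts": rts, "exponents": a.tolist(), "true_theta": {}, "u": {}}
    for t, year in enumerate(scenario.years):
        x = rng.lognormal(mean=1.0, sigma=0.4, size=(scenario.N, a.size))
        u = np.abs(rng.normal(0.0, scenario.sigma_u, size=scenario.N))
        A_t = math.exp(-scenario.productivity_trend * t)
        frontier = A_t * np.prod(x ** a, axis=1)
        out_level = frontier * np.exp(-u)
        if scenario.sigma_v > 0:
            out_level = out_level * np.exp(rng.normal(0.0, scenario.sigma_v, scenario.N))
        y = out_level[:, None] * shares[None, :]
        labels = tuple(f"u{i:03d}" for i in range(scenario.N))
        instances[year] = DeaInstance(x, y, labels)
        truth["true_theta"][year] = np.exp(-u / ra).tolist()
        truth["u"][year] = u.tolist()
    return instances, truth


def simulate_sdm_panel(
    W: SpatialWeights, scenario: SyntheticScenario, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Panel drawn from Y_t = (I - rho W)^{-1} (X_t beta + W X_t theta + mu + eps_t).

    Regressor columns share cross-correlation ``x_corr``; unit effects mu can
    be correlated with the first regressor (``fe_x_corr``) to exercise the
    fixed-vs-random screen.  The truth record carries every draw.
    """
    if W.standardization != "row":
        raise ValueError("simulate_sdm_panel expects a row-standardized W")
    N, T, K = W.n, scenario.T, len(scenario.beta)
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    w = W.matrix
    eigs = np.linalg.eigvals(w).real
    lo = 1.0 / eigs.min() if eigs.min() < 0 else -np.inf
    if not (lo < scenario.rho < 1.0):
        raise ValueError(f"rho={scenario.rho} outside invertibility interval ({lo:.3f}, 1)")
    A_inv = np.linalg.inv(np.eye(N) - scenario.rho * w)

    cov = np.full((K, K), scenario.x_corr) + (1.0 - scenario.x_corr) * np.eye(K)
    L = np.linalg.cholesky(cov)
    X = rng.standard_normal((T, N, K)) @ L.T
    mu = rng.normal(0.0, scenario.sigma_mu, size=N)
    if scenario.fe_x_corr != 0.0:
        xbar0 = X[:, :, 0].mean(axis=0)
        xs = (xbar0 - xbar0.mean()) / (xbar0.std() + 1e-12)
        r = scenario.fe_x_corr
        mu = scenario.sigma_mu * (r * xs + np.sqrt(max(1 - r * r, 0.0)) * (mu / max(scenario.sigma_mu, 1e-12)))
    eps = rng.normal(0.0, scenario.sigma_eps, size=(T, N))

    beta = np.asarray(scenario.beta)
    theta = np.asarray(scenario.theta)
    rows = []
    Y = np.empty((T, N))
    for t, year in enumerate(scenario.years):
        rhs = X[t] @ beta + w @ X[t] @ theta + mu + eps[t]
        Y[t] = A_inv @ rhs
        for i, unit in enumerate(W.ids):
            row = {"unit_id": unit, "year": year, "y": Y[t, i]}
            row.update({f"x{k + 1}": X[t, i, k] for k in range(K)})
            rows.append(row)
    truth = {
        "rho": scenario.rho, "beta": beta.tolist(), "theta": theta.tolist(),
        "sigma_eps": scenario.sigma_eps, "mu": mu.tolist(),
        "eps": eps.tolist(), "X": X.tolist(), "Y": Y.tolist(),
        "regressors": [f"x{k + 1}" for k in range(K)],
    }
    return pd.DataFrame(rows), truth


def simulate_indicator_panel(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[IndicatorPanel, dict]:
    """Resource-indicator panel with everything the full pipeline consumes.

    Emits the four weighted resource indicators, population (thousands) and
    area (km^2), the DEA input/output service indicators, and covariate
    columns.  Indicator levels are log-normal around unit-specific size
    factors with a common multiplicative year trend; population and area are
    fixed over time, so rising indicators push the density index upward in
    expectation.  DEA outputs follow a Cobb–Douglas frontier of the inputs
    with half-normal inefficiency (sigma_u of the scenario).
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    N, T = scenario.N, scenario.T
    units = [f"u{i:03d}" for i in range(N)]
    size = rng.lognormal(mean=0.0, sigma=0.6, size=N)  # unit scale factors
    pop = rng.lognormal(mean=8.0, sigma=0.5, size=N)  # thousands
    area = rng.lognormal(mean=11.0, sigma=0.8, size=N)  # km^2
    ind_scale = {"institutions": 30.0, "health_technicians": 100.0, "beds": 45.0,
                 "financial_subsidies": 12.0, "health_workers": 110.0,
                 "non_health_workers": 11.0}
    exponents = {"institutions": 0.25, "beds": 0.25, "health_workers": 0.3,
                 "non_health_workers": 0.1}
    out_share = {"consultations": 0.5, "admissions": 0.2, "family_visits": 0.3}
    rows = []

    def put(unit: str, year: int, name: str, value: float) -> None:
        rows.append({"unit_id": unit, "year": year, "indicator": name, "value": value})

    for t, year in enumerate(scenario.years):
        growth = (1.0 + scenario.indicator_trend) ** t
        for i, unit in enumerate(units):
            level = {}
            for name, scale in ind_scale.items():
                noise = rng.lognormal(0.0, scenario.indicator_noise)
                level[name] = scale * size[i] * growth * noise
                put(unit, year, name, level[name])
            u = abs(rng.normal(0.0, scenario.sigma_u))
            frontier = 50.0 * np.prod([level[k] ** a for k, a in exponents.items()])
            for name, share in out_share.items():
                put(unit, year, name, share * frontier * np.exp(-u))
            put(unit, year, "population_thousands", pop[i])
            put(unit, year, "area_km2", area[i])
            put(unit, year, "gdp_per_capita", rng.lognormal(3.0, 0.3))
            put(unit, year, "urbanization", rng.uniform(0.3, 0.9))
    panel = IndicatorPanel(pd.DataFrame(rows))
    truth = {"size": size.tolist(), "population": pop.tolist(), "area": area.tolist(),
             "trend": scenario.indicator_trend}
    return panel, truth
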