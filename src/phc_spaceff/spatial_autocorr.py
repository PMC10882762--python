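"""Global and local Moran statistics, inference, cluster labels, and quadrants.

The global statistic is

    I = [ sum_ij w_ij (x_i - xbar)(x_j - xbar) ]
        / [ (1/N) sum_i (x_i - xbar)^2 * sum_ij w_ij ]

with null expectation E(I) = -1/(N-1).  Closed-form variances are available
under the normality and randomization assumptions; a permutation null is the
robust alternative.  The local statistic decomposes I per unit and the sign
pattern of (own deviation, spatial lag of deviations) assigns HH/HL/LL/LH
cluster labels, reported only where the conditional-permutation p-value beats
alpha.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import SpatialWeights

__all__ = [
    "MoranGlobalResult",
    "MoranLocalResult",
    "Cluster",
    "global_moran",
    "moran_inference",
    "local_moran",
    "quadrant_classify",
]


class Cluster(str, enum.Enum):
    HH = "HH"
    HL = "HL"
    LL = "LL"
    LH = "LH"
    NS = "NS"


@dataclass(frozen=True)
class MoranGlobalResult:
    I: float
    expected: float
    sd: float
    z: float
    p: float
    method: str
    n_permutations: int = 0

    def as_row(self) -> dict:
        return {
            "moran_i": self.I, "expected": self.expected, "sd": self.sd,
            "z": self.z, "p": self.p, "method": self.method,
        }


@dataclass(frozen=True)
class MoranLocalResult:
    ids: tuple[str, ...]
    I_local: np.ndarray
    p: np.ndarray
    cluster: tuple[str, ...]
    alpha: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit_id": self.ids, "I_local": self.I_local, "p": self.p, "cluster": self.cluster}
        )


def _validate(x: np.ndarray, W: SpatialWeights) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != W.n:
        raise ValueError(f"x must be a length-{W.n} vector")
    if x.size < 3:
        raise ValueError("need at least 3 units")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; Moran's I is undefined (zero variance)")
    if W.total() <= 0:
        raise ValueError("weight matrix is all zero")
    return x


def _moran_stat(x: np.ndarray, w: np.ndarray) -> float:
    z = x - x.mean()
    s0 = w.sum()
    return float((z @ w @ z) / ((z @ z) / x.size * s0))


def global_moran(x: np.ndarray, W: SpatialWeights) -> MoranGlobalResult:
    """Point estimate only; see :func:`moran_inference` for sd/z/p."""
    x = _validate(x, W)
    n = x.size
    return MoranGlobalResult(
        I=_moran_stat(x, W.matrix), expected=-1.0 / (n - 1),
        sd=float("nan"), z=float("nan"), p=float("nan"), method="none",
    )


def moran_inference(
    x: np.ndarray,
    W: SpatialWeights,
    method: str = "randomization",
    n_permutations: int = 999,
    seed: int | None = None,
) -> MoranGlobalResult:
    """Global Moran's I with sd, z, and a one-sided (greater) p-value.

    ``normality`` and ``randomization`` use the classical closed-form moments;
    ``permutation`` builds an empirical null by relabeling x.
    """
    x = _validate(x, W)
    n = x.size
    w = W.matrix
    I = _moran_stat(x, w)
    EI = -1.0 / (n - 1)

    if method == "permutation":
        if n_permutations < 99:
            raise ValueError("need at least 99 permutations")
        rng = np.random.default_rng(seed)
        sims = np.empty(n_permutations)
        for k in range(n_permutations):
            sims[k] = _moran_stat(rng.permutation(x), w)
        sd = float(sims.std(ddof=1))
        z = (I - EI) / sd
        p = (np.count_nonzero(sims >= I) + 1) / (n_permutations + 1)
        return MoranGlobalResult(I, EI, sd, z, float(p), "permutation", n_permutations)

    s0 = w.sum()
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    if method == "normality":
        var = (n * n * s1 - n * s2 + 3.0 * s0 * s0) / (s0 * s0 * (n * n - 1)) - EI * EI
    elif method == "randomization":
        z_dev = x - x.mean()
        b2 = n * (z_dev ** 4).sum() / ((z_dev ** 2).sum() ** 2)
        num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3.0 * s0 * s0) - b2 * (
            (n * n - n) * s1 - 2.0 * n * s2 + 6.0 * s0 * s0
        )
        var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - EI * EI
    else:
        raise ValueError(f"unknown method {method!r}")
    sd = float(np.sqrt(var))
    z = (I - EI) / sd
    p = float(stats.norm.sf(z))
    return MoranGlobalResult(I, EI, sd, z, p, method)


def local_moran(
    x: np.ndarray,
    W: SpatialWeights,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int | None = None,
) -> MoranLocalResult:
    """Per-unit Moran decomposition with conditional-permutation p-values.

    I_i = N (x_i - xbar) * lag_i / sum_k (x_k - xbar)^2, where lag_i is the
    weighted sum of the other units' deviations.  For each unit the null holds
    x_i fixed and permutes the remaining values over the other locations; the
    p-value is one-sided toward the observed side of the null mean.
    """
    x = _validate(x, W)
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    n = x.size
    w = W.matrix
    z = x - x.mean()
    denom = (z ** 2).sum()
    lag = w @ z
    I_loc = n * z * lag / denom

    rng = np.random.default_rng(seed)
    p = np.empty(n)
    for i in range(n):
        others = np.delete(z, i)
        wi = np.delete(w[i], i)
        sims = np.empty(n_permutations)
        for k in range(n_permutations):
            sims[k] = n * z[i] * (wi @ rng.permutation(others)) / denom
        if I_loc[i] >= sims.mean():
            p[i] = (np.count_nonzero(sims >= I_loc[i]) + 1) / (n_permutations + 1)
        else:
            p[i] = (np.count_nonzero(sims <= I_loc[i]) + 1) / (n_permutations + 1)

    labels = []
    for zi, li, pi in zip(z, lag, p):
        if pi >= alpha:
            labels.append(Cluster.NS.value)
        elif zi > 0:
            labels.append(Cluster.HH.value if li > 0 else Cluster.HL.value)
        else:
            labels.append(Cluster.LL.value if li <= 0 else Cluster.LH.value)
    return MoranLocalResult(tuple(W.ids), I_loc, p, tuple(labels), alpha)


def quadrant_classify(chrdi: pd.Series | dict, efficiency: pd.Series | dict) -> pd.Series:
    """Quadrant of each unit relative to the cross-unit means of both axes.

    I: allocation and efficiency both above their means; II: low allocation,
    high efficiency; III: both low; IV: high allocation, low efficiency.
    Values exactly at a mean count as low.
    """
    c = pd.Series(chrdi, dtype=float)
    e = pd.Series(efficiency, dtype=float)
    if set(c.index) != set(e.index):
        raise ValueError("chrdi and efficiency must cover the same units")
    if len(c) < 2:
        raise ValueError("need at least 2 units")
    e = e.reindex(c.index)
    hi_c = c > c.mean()
    hi_e = e > e.mean()
    out = pd.Series("III", index=c.index, name="quadrant")
    out[hi_c & hi_e] = "I"
    out[~hi_c & hi_e] = "II"
    out[hi_c & ~hi_e] = "IV"
    return out
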