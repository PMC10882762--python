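"""Input-oriented DEA technical efficiency with smoothed-bootstrap bias correction.

The radial efficiency of each decision-making unit (DMU) is the optimum of

    min theta   s.t.   X lam <= theta * x_i,   Y lam >= y_i,   lam >= 0,

with sum(lam) = 1 added under variable returns to scale.  Bias correction
uses the homogeneous smoothed bootstrap: efficiency estimates are reflected
about 1, resampled with replacement, perturbed by Gaussian kernel noise with a
Silverman bandwidth (with the usual variance-correction factor), folded back
into (0, 1], and the DEA problem is re-solved against the pseudo frontier
obtained by inflating every DMU's inputs by theta_hat / theta_star.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel_io import IndicatorPanel

__all__ = [
    "DeaInstance",
    "EfficiencyResult",
    "DeaError",
    "dea_te",
    "simar_wilson",
    "efficiency_panel",
    "DEFAULT_INPUTS",
    "DEFAULT_OUTPUTS",
]

DEFAULT_INPUTS = ("institutions", "beds", "health_workers", "non_health_workers")
DEFAULT_OUTPUTS = ("consultations", "admissions", "family_visits")

_THETA_FLOOR = 1e-9


class DeaError(RuntimeError):
    pass


@dataclass(frozen=True)
class DeaInstance:
    """n DMUs with p positive inputs and q nonnegative outputs."""

    inputs: np.ndarray  # (n, p)
    outputs: np.ndarray  # (n, q)
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        y = np.atleast_2d(np.asarray(self.outputs, dtype=float))
        if x.shape[0] != y.shape[0]:
            raise ValueError("inputs and outputs must cover the same DMUs")
        if (x <= 0).any():
            raise ValueError("all inputs must be strictly positive")
        if (y < 0).any() or (y.max(axis=1) <= 0).any():
            raise ValueError("outputs must be nonnegative with at least one positive per DMU")
        object.__setattr__(self, "inputs", x)
        object.__setattr__(self, "outputs", y)
        if not self.labels:
            object.__setattr__(self, "labels", tuple(f"dmu{i}" for i in range(x.shape[0])))
        elif len(self.labels) != x.shape[0]:
            raise ValueError("label count does not match DMU count")

    @property
    def n(self) -> int:
        return self.inputs.shape[0]


@dataclass(frozen=True)
class EfficiencyResult:
    labels: tuple[str, ...]
    theta_traditional: np.ndarray
    theta_corrected: np.ndarray
    bias: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    rts: str
    B: int
    bandwidth: float
    level: float
    seed: int | None = None
    replicates: np.ndarray | None = field(default=None, repr=False)  # (B, n)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": self.labels,
                "traditional": self.theta_traditional,
                "corrected": self.theta_corrected,
                "bias": self.bias,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _solve_one(x_i: np.ndarray, y_i: np.ndarray, X: np.ndarray, Y: np.ndarray, vrs: bool) -> float:
    """One input-oriented envelopment LP; reference set (X, Y) may differ from the DMU."""
    n, p = X.shape
    q = Y.shape[1]
    c = np.zeros(1 + n)
    c[0] = 1.0
    A_ub = np.zeros((p + q, 1 + n))
    A_ub[:p, 0] = -x_i
    A_ub[:p, 1:] = X.T
    A_ub[p:, 1:] = -Y.T
    b_ub = np.concatenate([np.zeros(p), -y_i])
    if vrs:
        A_eq = np.zeros((1, 1 + n))
        A_eq[0, 1:] = 1.0
        b_eq = np.ones(1)
    else:
        A_eq = b_eq = None
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(None, None)] + [(0.0, None)] * n,
        method="highs",
    )
    if res.status != 0:
        raise DeaError(f"LP failed (status {res.status}): {res.message}")
    return float(res.fun)


def dea_te(
    instance: DeaInstance,
    rts: str = "vrs",
    reference: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Radial input efficiency of every DMU; 1 marks the empirical frontier.

    ``reference`` substitutes an alternative (inputs, outputs) envelopment set,
    which the bootstrap uses to score original DMUs against a pseudo frontier.
    """
    rts = rts.lower()
    if rts not in ("crs", "vrs"):
        raise ValueError(f"rts must be 'crs' or 'vrs', got {rts!r}")
    X, Y = reference if reference is not None else (instance.inputs, instance.outputs)
    theta = np.empty(instance.n)
    for i in range(instance.n):
        try:
            theta[i] = _solve_one(instance.inputs[i], instance.outputs[i], X, Y, rts == "vrs")
        except DeaError as exc:
            raise DeaError(f"DMU {instance.labels[i]!r}: {exc}") from exc
    # own-envelopment scores land in (0, 1] up to solver tolerance
    if reference is None:
        theta = np.minimum(theta, 1.0)
    return np.clip(theta, _THETA_FLOOR, None)


def _silverman_bandwidth(reflected: np.ndarray) -> float:
    m = reflected.size
    sd = reflected.std(ddof=1)
    iqr = np.subtract(*np.percentile(reflected, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * spread * m ** (-0.2)


def simar_wilson(
    instance: DeaInstance,
    rts: str = "vrs",
    B: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
    keep_replicates: bool = False,
) -> EfficiencyResult:
    """Homogeneous smoothed-bootstrap bias correction of DEA scores.

    Returns per-DMU traditional and bias-corrected efficiencies, the bias
    estimate, and percentile confidence bounds from {2*theta_hat - theta*_b}.
    """
    p, q = instance.inputs.shape[1], instance.outputs.shape[1]
    if instance.n < p + q + 1:
        raise ValueError(f"need at least p+q+1 = {p + q + 1} DMUs, got {instance.n}")
    if B < 100:
        raise ValueError("B must be at least 100")
    alpha = 1.0 - level
    if B * alpha / 2.0 < 1.0:
        raise ValueError(f"B={B} too small for a {level:.0%} percentile interval")

    theta_hat = dea_te(instance, rts=rts)
    if np.allclose(theta_hat, 1.0):
        raise DeaError("all DMUs sit on the frontier; no variation to smooth")

    reflected = np.concatenate([theta_hat, 2.0 - theta_hat])
    h = _silverman_bandwidth(reflected)
    mu, var = reflected.mean(), reflected.var(ddof=1)
    scale = 1.0 / np.sqrt(1.0 + h * h / var)

    rng = np.random.default_rng(seed)
    n = instance.n
    boot = np.empty((B, n))
    for b in range(B):
        draw = rng.choice(reflected, size=n, replace=True)
        smoothed = draw + h * rng.standard_normal(n)
        smoothed = mu + scale * (smoothed - mu)
        theta_star = np.where(smoothed <= 1.0, smoothed, 2.0 - smoothed)
        theta_star = np.clip(theta_star, _THETA_FLOOR, 1.0)
        pseudo_inputs = (theta_hat / theta_star)[:, None] * instance.inputs
        boot[b] = dea_te(instance, rts=rts, reference=(pseudo_inputs, instance.outputs))

    bias = boot.mean(axis=0) - theta_hat
    corrected = theta_hat - bias
    ci = 2.0 * theta_hat[None, :] - boot
    ci_low = np.percentile(ci, 100 * alpha / 2.0, axis=0)
    ci_high = np.percentile(ci, 100 * (1.0 - alpha / 2.0), axis=0)
    return EfficiencyResult(
        labels=instance.labels,
        theta_traditional=theta_hat,
        theta_corrected=corrected,
        bias=bias,
        ci_low=ci_low,
        ci_high=ci_high,
        rts=rts.lower(),
        B=B,
        bandwidth=h,
        level=level,
        seed=seed,
        replicates=boot if keep_replicates else None,
    )


def efficiency_panel(
    panel: IndicatorPanel,
    inputs: Sequence[str] = DEFAULT_INPUTS,
    outputs: Sequence[str] = DEFAULT_OUTPUTS,
    rts: str = "vrs",
    B: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """Year-by-year DEA with bootstrap correction over a long panel.

    Each year's cross-section is treated as an independent frontier.  Seeds
    for the per-year bootstraps are derived from ``seed`` so years are
    individually reproducible.
    """
    panel.require_balanced(list(inputs) + list(outputs))
    frames = []
    for k, year in enumerate(panel.years):
        xin = panel.wide(year=year, indicators=list(inputs))
        yout = panel.wide(year=year, indicators=list(outputs))
        inst = DeaInstance(xin.to_numpy(), yout.to_numpy(), tuple(xin.index))
        res = simar_wilson(
            inst, rts=rts, B=B, level=level,
            seed=None if seed is None else seed + 1000 * k,
        )
        frame = res.as_frame()
        frame.insert(1, "year", year)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
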