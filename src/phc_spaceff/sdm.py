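"""Fixed-effects spatial Durbin panel model by maximum likelihood.

The model is Y = rho*W*Y + X*beta + W*X*theta + (fixed effects) + eps on a
balanced N x T panel with one cross-sectional weight matrix W applied within
each period.  Estimation concentrates the log-likelihood in rho using the
eigenvalues of W for the Jacobian term log|I - rho*W|, then recovers the
slope coefficients by least squares on the demeaned data.  The spatial lag
model (theta = 0) and spatial error model share the same machinery, which the
likelihood-ratio tests exploit.  Marginal effects are decomposed with
S_k(W) = (I - rho W)^{-1} (beta_k I + theta_k W): the average diagonal is the
direct effect, the average row sum the total effect, and their difference the
spillover (indirect) effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel_io import SpatialWeights

__all__ = [
    "SdmSpec",
    "SdmFit",
    "EffectsTable",
    "fit_sdm",
    "impacts",
    "lr_tests",
    "hausman_screen",
    "vif",
    "sig_marks",
]


@dataclass(frozen=True)
class SdmSpec:
    dependent: str
    regressors: tuple[str, ...]
    W: SpatialWeights
    fixed_effects: str = "unit"  # unit | time | two_way | none

    def __post_init__(self) -> None:
        if self.dependent in self.regressors:
            raise ValueError("dependent variable cannot appear among regressors")
        if self.fixed_effects not in ("unit", "time", "two_way", "none"):
            raise ValueError(f"unknown fixed_effects mode {self.fixed_effects!r}")
        if self.W.standardization != "row":
            raise ValueError("SDM estimation requires a row-standardized W")


@dataclass(frozen=True)
class SdmFit:
    model: str  # sdm | slm | sem
    rho: float  # spatial coefficient (lambda for SEM)
    beta: np.ndarray
    theta_lag: np.ndarray  # empty for slm/sem
    sigma2: float
    loglik: float
    regressors: tuple[str, ...]
    fixed_effects: str
    N: int
    T: int
    vcov: np.ndarray = field(repr=False)  # over (beta, theta, rho)
    r2_within: float = float("nan")
    r2_corr: float = float("nan")
    fe_estimates: pd.Series | None = None
    rho_bounds: tuple[float, float] = (np.nan, np.nan)
    boundary: bool = False

    @property
    def k(self) -> int:
        return len(self.regressors)

    @property
    def delta(self) -> np.ndarray:
        return np.concatenate([self.beta, self.theta_lag])

    def params_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def summary(self) -> pd.DataFrame:
        names = list(self.regressors) + [f"W:{r}" for r in self.regressors][: len(self.theta_lag)]
        est = np.concatenate([self.delta, [self.rho]])
        se = self.params_se()
        z = est / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"term": names + ["rho"], "estimate": est, "se": se, "z": z, "p": p,
             "sig": [sig_marks(v) for v in p]}
        )


def sig_marks(p: float) -> str:
    """Three-level significance marks (99 / 95 / 90 percent)."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# estimation helpers


def _stack(panel: pd.DataFrame, spec: SdmSpec, columns: Sequence[str]) -> np.ndarray:
    """Arrange panel columns year-major (T blocks of N, unit order = W.ids)."""
    units = list(spec.W.ids)
    years = sorted(panel["year"].unique())
    wide = panel.set_index(["year", "unit_id"])
    blocks = []
    for t in years:
        try:
            block = wide.loc[t].loc[units, list(columns)]
        except KeyError as exc:
            raise ValueError(f"panel is missing unit/year cells: {exc}") from exc
        if block[list(columns)].isna().any().any():
            raise ValueError(f"missing values in year {t}")
        blocks.append(block.to_numpy(dtype=float))
    return np.vstack(blocks)


def _demean(M: np.ndarray, N: int, T: int, mode: str) -> np.ndarray:
    M = M.reshape(T, N, -1)
    if mode == "none":
        out = M
    elif mode == "unit":
        out = M - M.mean(axis=0, keepdims=True)
    elif mode == "time":
        out = M - M.mean(axis=1, keepdims=True)
    else:  # two_way
        out = M - M.mean(axis=0, keepdims=True) - M.mean(axis=1, keepdims=True) + M.mean(axis=(0, 1), keepdims=True)
    return out.reshape(T * N, -1)


def _apply_W(M: np.ndarray, W: np.ndarray, N: int, T: int) -> np.ndarray:
    return (W @ M.reshape(T, N, -1)).reshape(T * N, -1)


def _rho_interval(eigs: np.ndarray) -> tuple[float, float]:
    re = eigs.real
    lo = 1.0 / re.min() if re.min() < 0 else -0.999
    hi = 1.0 / re.max() if re.max() > 0 else 0.999
    return lo, hi


def fit_sdm(
    panel: pd.DataFrame,
    spec: SdmSpec,
    model: str = "sdm",
    lee_yu: bool = False,
    rho_fixed: float | None = None,
) -> SdmFit:
    """Fit an SDM / SLM / SEM on a balanced panel by concentrated ML.

    ``panel`` is tidy-wide: one row per (unit_id, year) with the dependent and
    regressor columns.  ``lee_yu`` switches to the transformed likelihood for
    demeaned fixed-effects panels: sums of squares of the demeaned data equal
    those of an orthonormal (T-1)-dimensional transformation per unit, so the
    likelihood uses N(T-1) effective observations and a T-1 multiplier on
    log|I - rho W| (time demeaning analogously removes the unit eigenvalue of
    a row-standardized W).  This removes the incidental-parameter bias of
    sigma^2 and keeps likelihood-ratio tests calibrated.
    """
    if model not in ("sdm", "slm", "sem"):
        raise ValueError(f"unknown model {model!r}")
    W = spec.W.matrix
    N = spec.W.n
    years = sorted(panel["year"].unique())
    T = len(years)
    K = len(spec.regressors)
    n_obs = N * T
    n_params = K * (2 if model == "sdm" else 1) + 2
    if n_obs < n_params + 10:
        raise ValueError(f"panel too small: {n_obs} observations for {n_params} parameters")

    y = _stack(panel, spec, [spec.dependent])
    X = _stack(panel, spec, spec.regressors)
    if model == "sdm":
        Z = np.hstack([X, _apply_W(X, W, N, T)])
    else:
        Z = X
    fe = spec.fixed_effects
    if fe == "none":
        Z = np.hstack([np.ones((n_obs, 1)), Z])
    yd = _demean(y, N, T, fe)
    Zd = _demean(Z, N, T, fe)

    # collinearity screen
    if np.linalg.matrix_rank(Zd) < Zd.shape[1]:
        raise np.linalg.LinAlgError("regressor matrix (X, WX) is rank deficient")

    eigs = np.linalg.eigvals(W)
    lo, hi = _rho_interval(eigs)
    eps = 1e-6

    # effective dimensions under the transformed (Lee–Yu) likelihood
    drop_time = fe in ("time", "two_way")
    if lee_yu:
        T_ll = T - 1 if fe in ("unit", "two_way") and T > 1 else T
        N_ll = N - 1 if drop_time else N
    else:
        T_ll, N_ll = T, N
    n_eff = N_ll * T_ll

    def logdet(r: float) -> float:
        ld = float(np.log(1.0 - r * eigs).sum().real)
        if lee_yu and drop_time:
            ld -= float(np.log(1.0 - r))  # remove the constant-vector eigenvalue
        return ld

    ZtZinv = np.linalg.inv(Zd.T @ Zd)
    proj = ZtZinv @ Zd.T

    if model in ("sdm", "slm"):
        Wy = _demean(_apply_W(y, W, N, T), N, T, fe)
        b0 = proj @ yd
        bd = proj @ Wy
        e0 = (yd - Zd @ b0).ravel()
        ed = (Wy - Zd @ bd).ravel()

        def negll(r: float) -> float:
            s = e0 - r * ed
            return 0.5 * n_eff * np.log(s @ s / n_eff) - T_ll * logdet(r)

        if rho_fixed is None:
            res = optimize.minimize_scalar(negll, bounds=(lo + eps, hi - eps), method="bounded",
                                           options={"xatol": 1e-10})
            rho = float(res.x)
        else:
            rho = float(rho_fixed)
        delta = (b0 - rho * bd).ravel()
        resid = e0 - rho * ed
        fitted_sp = yd.ravel() - resid
    else:  # SEM: y = X beta + u, u = lam W u + e
        Wyd = _demean(_apply_W(y, W, N, T), N, T, fe)
        WZd = _demean(_apply_W(Z, W, N, T), N, T, fe)

        def sem_parts(lam: float):
            yt = yd - lam * Wyd
            Zt = Zd - lam * WZd
            b = np.linalg.lstsq(Zt, yt, rcond=None)[0]
            e = (yt - Zt @ b).ravel()
            return b, e

        def negll(lam: float) -> float:
            _, e = sem_parts(lam)
            return 0.5 * n_eff * np.log(e @ e / n_eff) - T_ll * logdet(lam)

        if rho_fixed is None:
            res = optimize.minimize_scalar(negll, bounds=(lo + eps, hi - eps), method="bounded",
                                           options={"xatol": 1e-10})
            rho = float(res.x)
        else:
            rho = float(rho_fixed)
        b, resid = sem_parts(rho)
        delta = b.ravel()
        fitted_sp = yd.ravel() - resid

    boundary = min(rho - lo, hi - rho) < 1e-4
    sigma2 = float(resid @ resid) / n_eff
    loglik = -0.5 * n_eff * (np.log(2 * np.pi * sigma2) + 1.0) + T_ll * logdet(rho)

    if fe == "none":
        const, delta = delta[0], delta[1:]
        Zd_eff = Zd[:, 1:]
    else:
        Zd_eff = Zd

    beta = delta[:K]
    theta = delta[K:] if model == "sdm" else np.zeros(0)

    # information matrix over (delta, rho, sigma2) — SAR-type models
    if model in ("sdm", "slm"):
        A_inv_eigs = 1.0 / (1.0 - rho * eigs)
        C_eigs = eigs * A_inv_eigs  # eigenvalues of W (I - rho W)^{-1}
        trC = float(C_eigs.sum().real)
        trC2 = float((C_eigs ** 2).sum().real)
        C = W @ np.linalg.inv(np.eye(N) - rho * W)
        trCtC = float(np.sum(C * C))  # tr(C' C)
        coef_full = np.concatenate([[const], delta]) if fe == "none" else delta
        Zdelta = Zd @ coef_full
        CZd = _apply_W(Zdelta[:, None], C, N, T).ravel()
        kz = Zd.shape[1]
        info = np.zeros((kz + 2, kz + 2))
        info[:kz, :kz] = Zd.T @ Zd / sigma2
        info[:kz, kz] = Zd.T @ CZd / sigma2
        info[kz, :kz] = info[:kz, kz]
        info[kz, kz] = T_ll * (trC2 + trCtC) + (CZd @ CZd) / sigma2
        info[kz, kz + 1] = T_ll * trC / sigma2
        info[kz + 1, kz] = info[kz, kz + 1]
        info[kz + 1, kz + 1] = n_eff / (2.0 * sigma2 ** 2)
        vcov_full = np.linalg.inv(info)
        drop = [0] if fe == "none" else []
        keep = [i for i in range(kz + 1) if i not in drop]
        vcov = vcov_full[np.ix_(keep, keep)]
    else:
        kz = Zd_eff.shape[1]
        B = np.eye(N) - rho * W
        Zt = Zd_eff - rho * _apply_W(Zd_eff, W, N, T)
        CB = W @ np.linalg.inv(B)
        trC = float(np.trace(CB))
        trC2 = float(np.trace(CB @ CB))
        trCtC = float(np.sum(CB * CB))
        info = np.zeros((kz + 2, kz + 2))
        info[:kz, :kz] = Zt.T @ Zt / sigma2
        info[kz, kz] = T_ll * (trC2 + trCtC)
        info[kz, kz + 1] = T_ll * trC / sigma2
        info[kz + 1, kz] = info[kz, kz + 1]
        info[kz + 1, kz + 1] = n_eff / (2.0 * sigma2 ** 2)
        vcov = np.linalg.inv(info)[: kz + 1, : kz + 1]

    ybar = yd.ravel()
    sst = float(ybar @ ybar)
    r2_within = 1.0 - float(resid @ resid) / sst if sst > 0 else float("nan")
    corr = np.corrcoef(fitted_sp, ybar)[0, 1] if np.std(fitted_sp) > 0 else float("nan")

    fe_est = None
    if fe in ("unit", "two_way"):
        spatial_part = y.ravel() - (
            _apply_W(y, W, N, T).ravel() * rho if model in ("sdm", "slm") else 0.0
        )
        raw = (spatial_part - (Z @ np.concatenate([beta, theta]) if model == "sdm" else Z @ beta).ravel())
        fe_est = pd.Series(raw.reshape(T, N).mean(axis=0), index=list(spec.W.ids), name="fe")

    return SdmFit(
        model=model, rho=rho, beta=beta, theta_lag=theta, sigma2=sigma2,
        loglik=float(loglik), regressors=spec.regressors, fixed_effects=fe,
        N=N, T=T, vcov=vcov, r2_within=r2_within, r2_corr=float(corr ** 2),
        fe_estimates=fe_est, rho_bounds=(lo, hi), boundary=boundary,
    )


# ---------------------------------------------------------------------------
# impacts


@dataclass(frozen=True)
class EffectsTable:
    regressors: tuple[str, ...]
    direct: np.ndarray
    indirect: np.ndarray
    total: np.ndarray
    direct_se: np.ndarray
    indirect_se: np.ndarray
    total_se: np.ndarray
    n_sims: int

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for k, name in enumerate(self.regressors):
            for effect, est, se in (
                ("direct", self.direct[k], self.direct_se[k]),
                ("indirect", self.indirect[k], self.indirect_se[k]),
                ("total", self.total[k], self.total_se[k]),
            ):
                z = est / se if se > 0 else np.nan
                p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
                rows.append({"regressor": name, "effect": effect, "estimate": est,
                             "se": se, "z": z, "p": p, "sig": sig_marks(p)})
        return pd.DataFrame(rows)


def _impact_point(rho: float, beta: np.ndarray, theta: np.ndarray, W: np.ndarray):
    N = W.shape[0]
    A_inv = np.linalg.inv(np.eye(N) - rho * W)
    direct = np.empty(beta.size)
    total = np.empty(beta.size)
    for k in range(beta.size):
        Sk = A_inv @ (beta[k] * np.eye(N) + theta[k] * W)
        direct[k] = np.trace(Sk) / N
        total[k] = Sk.sum() / N
    return direct, total - direct, total


def impacts(
    fit: SdmFit,
    W: SpatialWeights,
    n_sims: int = 1000,
    seed: int | None = None,
) -> EffectsTable:
    """Direct / indirect / total effect decomposition with simulated SEs.

    Parameter draws come from a Gaussian approximation to the sampling
    distribution of (beta, theta, rho) using the fit's covariance matrix.
    """
    lo, hi = fit.rho_bounds
    if not (lo < fit.rho < hi):
        raise ValueError("rho outside the invertibility interval of W")
    K = fit.k
    theta = fit.theta_lag if fit.theta_lag.size else np.zeros(K)
    d, ind, tot = _impact_point(fit.rho, fit.beta, theta, W.matrix)

    rng = np.random.default_rng(seed)
    mean = np.concatenate([fit.delta, [fit.rho]])
    draws = rng.multivariate_normal(mean, fit.vcov, size=n_sims, method="svd")
    sims = np.empty((n_sims, 3, K))
    for s in range(n_sims):
        db = draws[s, :K]
        dt = draws[s, K:-1] if fit.theta_lag.size else np.zeros(K)
        dr = float(np.clip(draws[s, -1], lo + 1e-6, hi - 1e-6))
        sims[s, 0], sims[s, 1], sims[s, 2] = _impact_point(dr, db, dt, W.matrix)
    ses = sims.std(axis=0, ddof=1)
    return EffectsTable(
        regressors=fit.regressors, direct=d, indirect=ind, total=tot,
        direct_se=ses[0], indirect_se=ses[1], total_se=ses[2], n_sims=n_sims,
    )


# ---------------------------------------------------------------------------
# model-selection tests


def lr_tests(fit_full: SdmFit, fit_slm: SdmFit, fit_sem: SdmFit) -> pd.DataFrame:
    """LR tests of SDM against its SLM (theta = 0) and SEM restrictions."""
    if fit_full.model != "sdm" or fit_slm.model != "slm" or fit_sem.model != "sem":
        raise ValueError("expected fits for sdm, slm, sem in that order")
    same = (
        fit_full.regressors == fit_slm.regressors == fit_sem.regressors
        and fit_full.N == fit_slm.N == fit_sem.N
        and fit_full.T == fit_slm.T == fit_sem.T
    )
    if not same:
        raise ValueError("fits are not nested on identical data")
    df = fit_full.k
    rows = []
    for name, restricted in (("sdm_vs_slm", fit_slm), ("sdm_vs_sem", fit_sem)):
        lr = 2.0 * (fit_full.loglik - restricted.loglik)
        rows.append({
            "test": name, "lr": lr, "df": df,
            "p": float(stats.chi2.sf(max(lr, 0.0), df)),
        })
    return pd.DataFrame(rows)


def hausman_screen(panel: pd.DataFrame, spec: SdmSpec) -> dict:
    """Classic fixed- vs random-effects contrast on the non-spatial model.

    Screening step run before spatial estimation: within (FE) estimates are
    contrasted with Swamy–Arora random-effects GLS estimates of
    y = X b + u_i + e.  Returns statistic, df, p, and a flag when the
    contrast covariance needed a pseudo-inverse.
    """
    W = spec.W
    N, K = W.n, len(spec.regressors)
    years = sorted(panel["year"].unique())
    T = len(years)
    y = _stack(panel, spec, [spec.dependent])
    X = _stack(panel, spec, spec.regressors)

    yd = _demean(y, N, T, "unit").ravel()
    Xd = _demean(X, N, T, "unit")
    XtXinv = np.linalg.inv(Xd.T @ Xd)
    b_fe = XtXinv @ Xd.T @ yd
    resid_fe = yd - Xd @ b_fe
    df_fe = N * (T - 1) - K
    s2_e = float(resid_fe @ resid_fe) / df_fe

    # between regression on unit means (with constant)
    ym = y.reshape(T, N).mean(axis=0)
    Xm = X.reshape(T, N, K).mean(axis=0)
    Xb = np.hstack([np.ones((N, 1)), Xm])
    bb = np.linalg.lstsq(Xb, ym, rcond=None)[0]
    rb = ym - Xb @ bb
    s2_b = float(rb @ rb) / max(N - K - 1, 1)
    s2_u = max(s2_b - s2_e / T, 0.0)
    lam = 1.0 - np.sqrt(s2_e / (s2_e + T * s2_u)) if (s2_e + T * s2_u) > 0 else 0.0

    yq = (y.reshape(T, N) - lam * ym[None, :]).reshape(-1)
    Xq = (X.reshape(T, N, K) - lam * Xm[None, :, :]).reshape(-1, K)
    cq = np.full((N * T, 1), 1.0 - lam)
    Zq = np.hstack([cq, Xq])
    ZtZinv = np.linalg.inv(Zq.T @ Zq)
    b_re = (ZtZinv @ Zq.T @ yq)[1:]

    # common sigma^2 (from the consistent FE residuals) in both covariance
    # matrices: guarantees a PSD contrast and keeps the statistic calibrated
    # when RE is close to FE and the naive difference is noise-dominated
    diff = b_fe - b_re
    Vd = s2_e * (XtXinv - ZtZinv[1:, 1:])
    pinv_used = False
    try:
        sol = np.linalg.solve(Vd, diff)
        if not np.isfinite(sol).all() or diff @ sol < 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(Vd) @ diff
        pinv_used = True
    stat = float(abs(diff @ sol))
    return {
        "statistic": stat, "df": K, "p": float(stats.chi2.sf(stat, K)),
        "pinv_fallback": pinv_used,
    }


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1 - R^2_k) per regressor column."""
    if X.shape[1] < 2:
        raise ValueError("need at least 2 regressors")
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant column present; remove it before VIF")
    out = {}
    M = X.to_numpy(dtype=float)
    n = M.shape[0]
    for k, name in enumerate(X.columns):
        yk = M[:, k]
        others = np.hstack([np.ones((n, 1)), np.delete(M, k, axis=1)])
        bk = np.linalg.lstsq(others, yk, rcond=None)[0]
        resid = yk - others @ bk
        sst = float(((yk - yk.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
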