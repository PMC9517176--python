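"""Geographically weighted regression (GWR) with residual diagnostics.

GWR generalises the global linear model y_i = β₀ + Σ_k β_k x_ik + ε_i by
letting every coefficient vary with location:

    y_i = β₀(u_i, v_i) + Σ_k β_k(u_i, v_i) · x_ik + ε_i

At each observation the coefficients are estimated by weighted least squares
with Gaussian kernel weights w_ij = exp(−(d_ij / b)²), so nearby
observations dominate the local fit. The bandwidth ``b`` is chosen by
golden-section search on the corrected Akaike criterion (AICc); model fit
uses the GWR hat matrix S (effective parameters tr S). Spatial randomness of
the standardized residuals is checked with Moran's I under row-standardized
inverse-distance weights, with a seeded permutation p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GWRFit",
    "MoranResult",
    "select_gwr_predictors",
    "fit_gwr",
    "select_bandwidth",
    "morans_i",
]

_RIDGE = 1e-8


@dataclass
class GWRFit:
    """A fitted GWR: local coefficients, residuals and fit statistics."""

    coords: np.ndarray  # (n, 2)
    local_coefficients: np.ndarray  # (n, p+1), column 0 = intercept
    fitted: np.ndarray
    residuals: np.ndarray
    std_residuals: np.ndarray
    bandwidth: float
    kernel: str
    r2: float
    adj_r2: float
    aicc: float
    effective_params: float  # tr(S)
    variable_names: list[str] = field(default_factory=list)

    def coefficients_frame(self) -> pd.DataFrame:
        cols = ["intercept"] + (
            self.variable_names or [f"x{k}" for k in range(1, self.local_coefficients.shape[1])]
        )
        df = pd.DataFrame(self.local_coefficients, columns=cols)
        df.insert(0, "v", self.coords[:, 1])
        df.insert(0, "u", self.coords[:, 0])
        df["fitted"] = self.fitted
        df["residual"] = self.residuals
        df["std_residual"] = self.std_residuals
        return df


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    p_value: float
    permutations: int


def select_gwr_predictors(
    index_table: pd.DataFrame,
    pm25: pd.Series | np.ndarray,
    r_cut: float = 0.6,
) -> list[str]:
    """Pick the GWR covariates among the landscape indices.

    Returns the index most correlated (|Pearson r|) with zonal PM2.5, plus
    the strongest-ranked remaining index whose |r| with the first is below
    ``r_cut``; if none qualifies a single index is returned with a warning.
    """
    y = np.asarray(pm25, dtype=float)
    r = {
        col: float(np.corrcoef(index_table[col].to_numpy(dtype=float), y)[0, 1])
        for col in index_table.columns
        if np.std(index_table[col].to_numpy(dtype=float)) > 0
    }
    if not r:
        raise ValueError("no non-constant index columns")
    ranked = sorted(r, key=lambda c: abs(r[c]), reverse=True)
    first = ranked[0]
    x1 = index_table[first].to_numpy(dtype=float)
    for col in ranked[1:]:
        r12 = abs(np.corrcoef(x1, index_table[col].to_numpy(dtype=float))[0, 1])
        if r12 < r_cut:
            return [first, col]
    warnings.warn(f"no second index with |r| < {r_cut} against {first}; returning one index")
    return [first]


def _kernel_weights(d: np.ndarray, bandwidth: float, kernel: str) -> np.ndarray:
    if kernel == "gaussian":
        return np.exp(-((d / bandwidth) ** 2))
    if kernel == "bisquare":
        w = (1 - (d / bandwidth) ** 2) ** 2
        w[d >= bandwidth] = 0.0
        return w
    raise ValueError(f"unknown kernel {kernel!r}")


def fit_gwr(
    coords: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    bandwidth: float,
    kernel: str = "gaussian",
    variable_names: Optional[Sequence[str]] = None,
) -> GWRFit:
    """Fit GWR at every observation location.

    ``X`` excludes the intercept column (added internally). A numerically
    singular local design falls back to a tiny ridge with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n < p + 3:
        raise ValueError(f"need n >= p + 3 observations, got n={n}, p={p}")
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    Xd = np.column_stack([np.ones(n), X])
    betas = np.empty((n, p + 1))
    fitted = np.empty(n)
    trace_s = 0.0
    d2 = (
        (coords[:, 0][:, None] - coords[:, 0][None, :]) ** 2
        + (coords[:, 1][:, None] - coords[:, 1][None, :]) ** 2
    )
    d = np.sqrt(d2)
    for i in range(n):
        w = _kernel_weights(d[i], bandwidth, kernel)
        Xw = Xd * w[:, None]
        xtx = Xd.T @ Xw
        xty = Xw.T @ y
        try:
            beta = np.linalg.solve(xtx, xty)
            ok = np.all(np.isfinite(beta)) and np.linalg.cond(xtx) < 1e12
        except np.linalg.LinAlgError:
            ok = False
        if not ok:
            warnings.warn(f"singular local design at observation {i}; ridge fallback")
            beta = np.linalg.solve(xtx + _RIDGE * np.eye(p + 1), xty)
        betas[i] = beta
        fitted[i] = Xd[i] @ beta
        # hat-matrix row: e_i' S = x_i' (X'WX)^{-1} X'W ; only the diagonal
        si = Xd[i] @ np.linalg.solve(xtx + (0 if ok else _RIDGE * np.eye(p + 1)), Xw.T)
        trace_s += si[i]
    residuals = y - fitted
    rss = float(residuals @ residuals)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    v1 = trace_s
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - v1 - 1) if n - v1 - 1 > 0 else float("nan")
    sigma2 = rss / max(n - v1, 1e-9)
    # internally studentized residuals (leverage from the GWR hat diagonal)
    lev = np.empty(n)
    for i in range(n):
        w = _kernel_weights(d[i], bandwidth, kernel)
        Xw = Xd * w[:, None]
        xtx = Xd.T @ Xw
        try:
            sol = np.linalg.solve(xtx, Xw.T)
        except np.linalg.LinAlgError:
            sol = np.linalg.solve(xtx + _RIDGE * np.eye(p + 1), Xw.T)
        lev[i] = (Xd[i] @ sol)[i]
    denom = np.sqrt(np.maximum(sigma2 * (1.0 - np.clip(lev, None, 1 - 1e-9)), 1e-300))
    std_resid = residuals / denom
    if n - v1 - 2 > 0:
        # floor the error variance at machine-precision share of the response
        # variance so exact fits compare by effective parameters alone
        sigma2_floor = max(1e-14 * tss / n, 1e-300)
        aicc = (
            2 * n * math.log(math.sqrt(max(rss / n, sigma2_floor)))
            + n * math.log(2 * math.pi)
            + n * (n + v1) / (n - 2 - v1)
        )
    else:
        aicc = float("inf")
    return GWRFit(
        coords=coords,
        local_coefficients=betas,
        fitted=fitted,
        residuals=residuals,
        std_residuals=std_resid,
        bandwidth=float(bandwidth),
        kernel=kernel,
        r2=r2,
        adj_r2=adj_r2,
        aicc=aicc,
        effective_params=float(v1),
        variable_names=list(variable_names) if variable_names else [],
    )


def select_bandwidth(
    coords: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    kernel: str = "gaussian",
    bounds: Optional[tuple[float, float]] = None,
    tol: float = 1e-2,
) -> float:
    """Golden-section search for the AICc-minimising bandwidth.

    Deterministic given its inputs. If the AICc profile over the evaluated
    points is not unimodal the global minimum over all evaluated bandwidths
    is returned with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    d = np.sqrt(
        (coords[:, 0][:, None] - coords[:, 0][None, :]) ** 2
        + (coords[:, 1][:, None] - coords[:, 1][None, :]) ** 2
    )
    dmax = float(d.max())
    if bounds is None:
        bounds = (max(dmax / 50.0, 1e-6), 2.0 * dmax)
    lo, hi = bounds
    evaluated: dict[float, float] = {}

    def aicc(b: float) -> float:
        if b not in evaluated:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                evaluated[b] = fit_gwr(coords, y, X, b, kernel).aicc
        return evaluated[b]

    invphi = (math.sqrt(5) - 1) / 2
    a, bb = lo, hi
    c = bb - invphi * (bb - a)
    e = a + invphi * (bb - a)
    while bb - a > tol * (hi - lo):
        if aicc(c) < aicc(e):
            bb = e
        else:
            a = c
        c = bb - invphi * (bb - a)
        e = a + invphi * (bb - a)
    aicc(lo), aicc(hi)  # ensure endpoints are in the profile
    best_gs = (a + bb) / 2
    aicc(best_gs)
    best = min(evaluated, key=evaluated.get)
    if evaluated[best] < aicc(best_gs) - 1e-9:
        warnings.warn("AICc profile not unimodal; returning grid minimum")
        return float(best)
    return float(best_gs)


def morans_i(
    values: np.ndarray,
    coords: np.ndarray,
    permutations: int = 999,
    seed: int = 0,
) -> MoranResult:
    """Global Moran's I with row-standardized inverse-distance weights.

    The expected value under spatial randomness is −1/(n−1); the p-value is
    a two-sided seeded permutation test (``permutations`` random relabelings).
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError("Moran's I needs at least 4 observations")
    if np.std(values) <= 0:
        raise ValueError("zero variance: Moran's I undefined for constant values")
    d = np.sqrt(
        (coords[:, 0][:, None] - coords[:, 0][None, :]) ** 2
        + (coords[:, 1][:, None] - coords[:, 1][None, :]) ** 2
    )
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)  # row-standardize

    z = values - values.mean()
    denom = float(z @ z)

    def stat(zv: np.ndarray) -> float:
        return float(zv @ (w @ zv) / denom)  # Σw = n cancels n/Σw

    i_obs = stat(z)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(permutations)
    for k in range(permutations):
        perm_stats[k] = stat(rng.permutation(z))
    if i_obs >= expected:
        extreme = int(np.sum(perm_stats >= i_obs))
    else:
        extreme = int(np.sum(perm_stats <= i_obs))
    p_one = (extreme + 1) / (permutations + 1)
    p = min(1.0, 2.0 * p_one)
    return MoranResult(I=i_obs, expected=expected, p_value=p, permutations=permutations)
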