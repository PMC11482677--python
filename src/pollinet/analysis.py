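"""Post-simulation statistics.

Covers three stages: (i) indirect interaction effects from matrix powers
of the community interaction matrix, (ii) structure-recovery regressions
(quasibinomial GLM fitted by hand-written IRLS, plus normal-equation
OLS), and (iii) restoration-survey summaries relating plot-network
nestedness to pollinator visitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .dynamics import ModelParams, effective_pair_strength
from .networks import BipartiteNetwork, nodf

__all__ = [
    "IndirectEffects",
    "indirect_effects",
    "build_interaction_matrix",
    "RegressionResult",
    "ols_fit",
    "recovery_regression",
    "visitation_summary",
    "visitation_slope",
    "nestedness_density_relation",
]


class IndirectEffects(NamedTuple):
    beta3: float
    beta: float | None
    spectral_radius: float


def indirect_effects(M: np.ndarray) -> IndirectEffects:
    """Mean order-3 and net indirect effects of an interaction matrix.

    beta3 is the mean entry of M^3.  beta is the mean entry of the summed
    higher-order series sum_{k>=2} M^k = (I - M)^-1 - I - M, which
    converges only when the spectral radius of M is below 1; otherwise
    beta is returned as None while beta3 and the radius are still
    reported.
    """
    M = np.asarray(M, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be square")
    radius = float(np.max(np.abs(np.linalg.eigvals(M))))
    beta3 = float(np.mean(np.linalg.matrix_power(M, 3)))
    if radius < 1.0:
        I = np.eye(M.shape[0])
        series = np.linalg.inv(I - M) - I - M
        beta = float(np.mean(series))
    else:
        beta = None
    return IndirectEffects(beta3, beta, radius)


def build_interaction_matrix(
    net: BipartiteNetwork,
    N: np.ndarray,
    u: np.ndarray,
    p: ModelParams,
    include_type2: bool = True,
) -> np.ndarray:
    """Signed per-capita interaction matrix M at the current state.

    Mutualistic entries M[i, k] for linked pairs are the closed-form
    trait-averaged kernel strength, optionally damped by the type-II
    saturation factor 1/(1 + H g N_k) at the partner's current density;
    competitive entries are -alpha_ij within guilds (diagonal zero).
    """
    S = net.n_species
    sp = net.n_plants
    sigma = p.sigma_vector(S)
    deg = net.degrees
    M = np.zeros((S, S))
    if p.alpha is not None:
        M -= np.asarray(p.alpha) - np.eye(S)
    rows, cols = np.nonzero(net.binary)
    for i, kk in zip(rows, cols):
        k = kk + sp
        for a, bnd in ((i, k), (k, i)):
            g = effective_pair_strength(
                u[a], u[bnd], sigma[a], sigma[bnd], p.gamma0, p.omega, int(deg[a])
            )
            if include_type2:
                g = g / (1.0 + p.H * g * N[bnd])
            M[a, bnd] = g
    return M


@dataclass
class RegressionResult:
    params: np.ndarray        # [intercept, slope, ...]
    se: np.ndarray
    dispersion: float
    family: str
    converged: bool
    n: int

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slope(self) -> float:
        return float(self.params[1])

    @property
    def slope_se(self) -> float:
        return float(self.se[1])

    @property
    def t_values(self) -> np.ndarray:
        return self.params / self.se

    def predict(self, x: np.ndarray) -> np.ndarray:
        X = _design(np.asarray(x, float))
        eta = X @ self.params
        if self.family == "gaussian":
            return eta
        return 1.0 / (1.0 + np.exp(-eta))


def _design(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    return np.column_stack([np.ones(len(x)), x])


def ols_fit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares via the normal equations, with classic SEs."""
    X = _design(x)
    y = np.asarray(y, float)
    n, k = X.shape
    if n <= k:
        raise ValueError("need more observations than parameters")
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = n - k
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(XtX)
    return RegressionResult(
        params=beta,
        se=np.sqrt(np.diag(cov)),
        dispersion=s2,
        family="gaussian",
        converged=True,
        n=n,
    )


def _irls_logit(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
):
    beta = np.zeros(X.shape[1])
    mu = np.clip(y * 0.5 + 0.25, 1e-6, 1 - 1e-6)
    eta = np.log(mu / (1 - mu))
    converged = False
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        var = mu * (1 - mu)
        w = weights * var
        z = eta + (y - mu) / var
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
        eta = X @ beta
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
    return beta, mu, converged


def recovery_regression(
    table: pd.DataFrame,
    predictor: str,
    response: str = "recovery_richness",
    weights: Optional[np.ndarray] = None,
) -> RegressionResult:
    """Quasibinomial (logit link) GLM of a [0, 1] response on one metric.

    Fitted by iteratively reweighted least squares; the dispersion is the
    Pearson chi-square divided by the residual degrees of freedom, and
    standard errors are the binomial ones scaled by sqrt(dispersion).
    Degenerate responses (all 0 or all 1, i.e., complete separation of
    the fit) fall back to reporting the unscaled binomial fit with a
    warning.
    """
    df = table.dropna(subset=[predictor, response])
    if len(df) < 10:
        raise ValueError("need at least 10 networks for the recovery regression")
    y = df[response].to_numpy(float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("response values must lie in [0, 1]")
    X = _design(df[predictor].to_numpy(float))
    w = np.ones(len(y)) if weights is None else np.asarray(weights, float)
    n, k = X.shape
    beta, mu, converged = _irls_logit(X, y, w)
    pearson = float(np.sum(w * (y - mu) ** 2 / (mu * (1 - mu))))
    dof = n - k
    dispersion = pearson / dof
    family = "quasibinomial"
    if not converged or not np.isfinite(dispersion) or dispersion <= 0:
        warnings.warn(
            "quasibinomial fit degenerate; reporting binomial-deviance fit",
            stacklevel=2,
        )
        dispersion = 1.0
        family = "binomial"
    var = mu * (1 - mu)
    WX = X * (w * var)[:, None]
    cov = dispersion * np.linalg.inv(X.T @ WX)
    return RegressionResult(
        params=beta,
        se=np.sqrt(np.diag(cov)),
        dispersion=dispersion,
        family=family,
        converged=converged,
        n=n,
    )


def visitation_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per plot-month network summaries from a long visitation table.

    Expects columns treatment, month, plot, plant, pollinator, visits and
    (optionally) rate.  For each sampled network returns its binarized
    NODF, the mean number of visits per pollinator and the mean
    visitation rate.  Empty plot-month networks are dropped with a
    warning.
    """
    required = {"treatment", "month", "plot", "plant", "pollinator", "visits"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"visitation table missing columns: {sorted(missing)}")
    rows = []
    for (treatment, month, plot), grp in table.groupby(
        ["treatment", "month", "plot"], sort=True
    ):
        grp = grp[grp["visits"] > 0]
        if grp.empty:
            warnings.warn(
                f"empty plot-month network dropped: {treatment}/{month}/{plot}",
                stacklevel=2,
            )
            continue
        mat = grp.pivot_table(
            index="plant", columns="pollinator", values="visits",
            aggfunc="sum", fill_value=0,
        )
        net = BipartiteNetwork(
            list(mat.index), list(mat.columns), mat.to_numpy(float)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nodf_val = nodf(net)
        per_pollinator = grp.groupby("pollinator")["visits"].sum()
        row = {
            "treatment": treatment,
            "month": month,
            "plot": plot,
            "nodf": nodf_val,
            "mean_visits": float(per_pollinator.mean()),
        }
        if "rate" in grp.columns:
            row["mean_rate"] = float(grp.groupby("pollinator")["rate"].sum().mean())
        rows.append(row)
    return pd.DataFrame(rows)


def visitation_slope(
    summary: pd.DataFrame, response: str = "mean_visits"
) -> dict:
    """OLS slope of a visitation response on NODF, pooled over treatments.

    Also fits per-treatment intercepts (common slope) to compare restored
    vs unrestored baselines.
    """
    pooled = ols_fit(summary["nodf"].to_numpy(), summary[response].to_numpy())
    out = {
        "slope": pooled.slope,
        "slope_se": pooled.slope_se,
        "t_value": float(pooled.slope / pooled.slope_se),
        "intercept": pooled.intercept,
    }
    treatments = sorted(summary["treatment"].unique())
    if len(treatments) == 2:
        dummy = (summary["treatment"] == treatments[0]).to_numpy(float)
        X = np.column_stack([summary["nodf"].to_numpy(float), dummy])
        fit = ols_fit(X, summary[response].to_numpy(float))
        out["intercept_" + treatments[1]] = fit.intercept
        out["intercept_" + treatments[0]] = fit.intercept + float(fit.params[2])
    return out


def nestedness_density_relation(
    records: pd.DataFrame,
    gamma0_values: Optional[list] = None,
) -> pd.DataFrame:
    """Per-gamma0 OLS of mean pollinator density on network NODF.

    ``records`` needs columns network_id, gamma0, nodf and
    mean_pollinator_density (one row per network per gamma0 level, e.g.
    from the backward/hysteresis branch above the collapse regime).
    """
    if gamma0_values is None:
        gamma0_values = sorted(records["gamma0"].unique())
    rows = []
    for g0 in gamma0_values:
        sub = records[np.isclose(records["gamma0"], g0)]
        if len(sub) < 3:
            raise ValueError(f"need at least 3 networks at gamma0={g0}")
        fit = ols_fit(
            sub["nodf"].to_numpy(), sub["mean_pollinator_density"].to_numpy()
        )
        rows.append(
            {
                "gamma0": g0,
                "slope": fit.slope,
                "slope_se": fit.slope_se,
                "intercept": fit.intercept,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows)
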