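"""Longitudinal statistics for tracked organoid time series.

Workflow mirroring the analysis of pretreatment-normalized trajectories:

* ``normalize`` -- divide each organoid's post-treatment values by its own
  pretreatment value (organoid-level, requires tracking) or by the well
  pretreatment mean (well-level, mimics pooled analysis without tracking).
* ``fit_lmm`` -- random-intercept linear mixed model
  ``Y ~ time + treatment + treatment:time + (1 | organoid)`` with an AR(1)
  correlation structure on the within-organoid residuals (time as a
  categorical factor; AR(1) on the ordered time index), estimated by REML.
* ``fit_pooled`` -- the same fixed-effect structure without the random
  intercept (generalized least squares with AR(1) errors).
* ``lsmeans_contrasts`` -- estimated marginal means per treatment x time
  cell and all pairwise treatment differences at each time point with
  Tukey HSD adjustment.
* ``bivariate_fit`` and ``correlation_matrix`` -- pretreatment bivariate
  regression and the 24x24 Pearson correlation matrix.

The REML estimator is implemented directly (block-diagonal marginal
covariance sigma_b^2 J + sigma^2 R(rho) per organoid) because the random
intercept + AR(1) combination is the model of interest end to end; it is
cross-validated against an independent reference implementation in the
test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.linalg import solve_triangular

from redoxtrack.features import FEATURE_COLUMNS

log = logging.getLogger(__name__)

ORGANOID_LEVEL = "organoid_level"
WELL_LEVEL = "well_level"


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(
    table: pd.DataFrame,
    variable: str = "mean_orr",
    mode: str = ORGANOID_LEVEL,
    *,
    pretreatment_time: float | None = None,
) -> pd.DataFrame:
    """Pretreatment-normalize one variable of a long feature table.

    Returns rows (organoid_id, well, treatment, time_h, Y, pretreatment)
    where Y = X_post / X_pre(organoid) in organoid-level mode or
    X_post / mean_well(X_pre) in well-level mode.  Pretreatment rows are
    kept but flagged; organoids (or wells) with a zero/undefined
    denominator are dropped with a logged reason.
    """
    if mode not in (ORGANOID_LEVEL, WELL_LEVEL):
        raise ValueError(f"mode must be {ORGANOID_LEVEL!r} or {WELL_LEVEL!r}")
    if variable not in table.columns:
        raise KeyError(f"variable {variable!r} not in table")
    df = table.copy()
    t0 = pretreatment_time if pretreatment_time is not None else df["time_h"].min()
    pre = df[df["time_h"] == t0]

    if mode == ORGANOID_LEVEL:
        denom = pre.set_index("organoid_id")[variable]
        bad = denom.index[(~np.isfinite(denom)) | (denom <= 0)].tolist()
        missing = sorted(set(df["organoid_id"]) - set(denom.index))
        for oid in bad:
            log.info("organoid %s dropped: non-positive pretreatment %s", oid, variable)
        for oid in missing:
            log.info("organoid %s dropped: no pretreatment row", oid)
        keep = set(denom.index) - set(bad)
        df = df[df["organoid_id"].isin(keep)]
        df["Y"] = df[variable].to_numpy() / denom.reindex(df["organoid_id"]).to_numpy()
    else:
        denom = pre.groupby("well")[variable].mean()
        bad = denom.index[(~np.isfinite(denom)) | (denom <= 0)].tolist()
        for wid in bad:
            log.info("well %s dropped: non-positive pretreatment mean %s", wid, variable)
        df = df[~df["well"].isin(bad)]
        df["Y"] = df[variable].to_numpy() / denom.reindex(df["well"]).to_numpy()

    out = df[["organoid_id", "well", "treatment", "time_h"]].copy()
    out["Y"] = df["Y"].to_numpy()
    out["pretreatment"] = df["time_h"].to_numpy() == t0
    out.attrs["mode"] = mode
    out.attrs["variable"] = variable
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# random-intercept + AR(1) mixed model (REML)
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    """REML fit of Y ~ time*treatment + (1|organoid), AR(1) residuals.

    ``beta`` holds the fixed effects in the order produced by
    :func:`_design_matrix`; ``sigma_b2`` the random-intercept variance
    (zero for the pooled/GLS model), ``rho`` the AR(1) residual
    correlation on the time index, ``sigma2`` the residual variance.
    """

    beta: pd.Series
    cov_beta: pd.DataFrame
    sigma_b2: float
    sigma2: float
    rho: float
    loglik: float
    times: list[float]
    groups: list[str]
    df_contrast: float
    n_obs: int
    n_organoids: int
    converged: bool
    random_intercept: bool

    def cell_mean(self, group: str, time_h: float) -> float:
        return float(self._emm_row(group, time_h) @ self.beta.to_numpy())

    def _emm_row(self, group: str, time_h: float) -> np.ndarray:
        names = list(self.beta.index)
        x = np.zeros(len(names))
        x[names.index("intercept")] = 1.0
        tname = f"time[{time_h}]"
        gname = f"treat[{group}]"
        if tname in names:
            x[names.index(tname)] = 1.0
        if gname in names:
            x[names.index(gname)] = 1.0
        iname = f"{tname}:{gname}"
        if iname in names:
            x[names.index(iname)] = 1.0
        return x


class DesignError(ValueError):
    """Raised when the treatment x time design has an empty cell."""


def _design_matrix(df: pd.DataFrame) -> tuple[np.ndarray, list[str], list[float], list[str]]:
    times = sorted(df["time_h"].unique())
    groups = sorted(df["treatment"].unique(), key=lambda g: (g != "control", g))
    counts = df.groupby(["treatment", "time_h"]).size()
    for g in groups:
        for t in times:
            if (g, t) not in counts.index:
                raise DesignError(f"empty design cell: treatment={g}, time={t}")
    names = ["intercept"]
    cols = [np.ones(len(df))]
    tvals = df["time_h"].to_numpy()
    gvals = df["treatment"].to_numpy()
    for t in times[1:]:
        names.append(f"time[{t}]")
        cols.append((tvals == t).astype(float))
    for g in groups[1:]:
        names.append(f"treat[{g}]")
        cols.append((gvals == g).astype(float))
    for t in times[1:]:
        for g in groups[1:]:
            names.append(f"time[{t}]:treat[{g}]")
            cols.append(((tvals == t) & (gvals == g)).astype(float))
    return np.column_stack(cols), names, times, groups


def _block_cov(time_idx: np.ndarray, gamma: float, rho: float) -> np.ndarray:
    """V0 = gamma * J + R(rho) for one organoid's ordered time indices."""
    lag = np.abs(time_idx[:, None] - time_idx[None, :])
    return gamma + rho**lag


def _reml_neg_loglik(
    u: np.ndarray,
    blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    n_obs: int,
    p: int,
    random_intercept: bool,
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Negative REML log-likelihood profiled over sigma^2.

    u = (log gamma, atanh rho) with gamma = sigma_b^2 / sigma^2 (gamma
    omitted when there is no random intercept).  Returns (nll, beta,
    cov_beta_unscaled, sigma2_hat).
    """
    if random_intercept:
        gamma = np.exp(u[0])
        rho = np.tanh(u[1])
    else:
        gamma = 0.0
        rho = np.tanh(u[0])

    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    cache: dict[tuple, tuple[np.ndarray, float]] = {}
    parts = []
    for X_i, y_i, tidx in blocks:
        key = tuple(tidx)
        if key not in cache:
            V0 = _block_cov(tidx, gamma, rho)
            L = np.linalg.cholesky(V0)
            cache[key] = (L, 2.0 * np.sum(np.log(np.diag(L))))
        L, ld = cache[key]
        logdet += ld
        Xw = solve_triangular(L, X_i, lower=True)
        yw = solve_triangular(L, y_i, lower=True)
        xtvx += Xw.T @ Xw
        xtvy += Xw.T @ yw
        ytvy += yw @ yw
        parts.append((Xw, yw))

    xtvx_inv = np.linalg.pinv(xtvx)
    beta = xtvx_inv @ xtvy
    rss = ytvy - beta @ xtvy  # = r' V0^-1 r at the GLS solution
    sigma2 = rss / (n_obs - p)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    nll = 0.5 * (
        logdet
        + (n_obs - p) * np.log(sigma2)
        + logdet_xtvx
        + (n_obs - p) * (1.0 + np.log(2.0 * np.pi))
    )
    return nll, beta, xtvx_inv, sigma2


def _fit_gls_ar1(
    series: pd.DataFrame, *, random_intercept: bool
) -> LmmFit:
    df = series[~series["pretreatment"]].copy()
    if df["Y"].isna().any():
        n = int(df["Y"].isna().sum())
        log.info("dropping %d rows with undefined response", n)
        df = df.dropna(subset=["Y"])
    if df["treatment"].nunique() < 2:
        raise DesignError("need at least 2 treatment groups")
    if df["time_h"].nunique() < 2:
        raise DesignError("need at least 2 post-treatment time points")

    X, names, times, groups = _design_matrix(df)
    y = df["Y"].to_numpy(float)
    p = X.shape[1]
    n_obs = len(y)
    time_to_idx = {t: i for i, t in enumerate(times)}

    blocks = []
    for oid, grp in df.groupby("organoid_id", sort=True):
        order = np.argsort(grp["time_h"].to_numpy())
        idx = grp.index.to_numpy()[order]
        tidx = np.array([time_to_idx[t] for t in grp.loc[idx, "time_h"]], dtype=float)
        rowpos = df.index.get_indexer(idx)
        blocks.append((X[rowpos], y[rowpos], tidx))
    n_org = len(blocks)

    def objective(u):
        try:
            return _reml_neg_loglik(u, blocks, n_obs, p, random_intercept)[0]
        except np.linalg.LinAlgError:
            return 1e12

    x0 = np.array([np.log(0.5), np.arctanh(0.3)]) if random_intercept else np.array([np.arctanh(0.3)])
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    nll, beta, cov_unscaled, sigma2 = _reml_neg_loglik(
        res.x, blocks, n_obs, p, random_intercept
    )
    if random_intercept:
        gamma = float(np.exp(res.x[0]))
        rho = float(np.tanh(res.x[1]))
    else:
        gamma = 0.0
        rho = float(np.tanh(res.x[0]))

    cov_beta = cov_unscaled * sigma2
    # contrasts between treatments compare groups of organoids, so the
    # relevant replication unit is the organoid (containment-style df)
    df_contrast = max(n_org - len(groups), 1)
    return LmmFit(
        beta=pd.Series(beta, index=names),
        cov_beta=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma_b2=gamma * sigma2,
        sigma2=float(sigma2),
        rho=rho,
        loglik=-float(nll),
        times=times,
        groups=groups,
        df_contrast=float(df_contrast),
        n_obs=n_obs,
        n_organoids=n_org,
        converged=bool(res.success),
        random_intercept=random_intercept,
    )


def fit_lmm(series: pd.DataFrame) -> LmmFit:
    """Random-intercept + AR(1) mixed model on organoid-normalized series."""
    return _fit_gls_ar1(series, random_intercept=True)


def fit_pooled(series: pd.DataFrame) -> LmmFit:
    """Fixed-effects GLS with AR(1) errors (no organoid random intercept)."""
    return _fit_gls_ar1(series, random_intercept=False)


# ---------------------------------------------------------------------------
# least-squares means and Tukey contrasts
# ---------------------------------------------------------------------------

def lsmeans_contrasts(fit: LmmFit) -> pd.DataFrame:
    """All pairwise treatment differences at each time point, Tukey-adjusted.

    The Tukey family is the set of pairwise comparisons among the k
    treatment groups within one time point.  ``percent_difference`` is the
    difference of normalized means x 100.
    """
    rows = []
    k = len(fit.groups)
    cov = fit.cov_beta.to_numpy()
    for t in fit.times:
        for a, b in combinations(fit.groups, 2):
            L = fit._emm_row(a, t) - fit._emm_row(b, t)
            est = float(L @ fit.beta.to_numpy())
            se = float(np.sqrt(L @ cov @ L))
            tstat = est / se if se > 0 else np.inf
            p_unadj = 2.0 * sps.t.sf(abs(tstat), fit.df_contrast)
            p_adj = float(
                sps.studentized_range.sf(abs(tstat) * np.sqrt(2.0), k, fit.df_contrast)
            )
            p_adj = min(max(p_adj, p_unadj), 1.0)
            rows.append(
                {
                    "time_h": t,
                    "group_a": a,
                    "group_b": b,
                    "estimate": est,
                    "percent_difference": est * 100.0,
                    "se": se,
                    "t": tstat,
                    "p_unadjusted": p_unadj,
                    "p_adjusted": p_adj,
                    "significant": p_adj < 0.05,
                }
            )
    return pd.DataFrame(rows)


def estimated_marginal_means(fit: LmmFit) -> pd.DataFrame:
    rows = []
    cov = fit.cov_beta.to_numpy()
    for t in fit.times:
        for g in fit.groups:
            x = fit._emm_row(g, t)
            rows.append(
                {
                    "time_h": t,
                    "treatment": g,
                    "emmean": float(x @ fit.beta.to_numpy()),
                    "se": float(np.sqrt(x @ cov @ x)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bivariate regression and correlation matrix
# ---------------------------------------------------------------------------

def bivariate_fit(table: pd.DataFrame, x: str, y: str) -> tuple[float, float, float]:
    """OLS of y on x: returns (slope, Pearson r, two-sided p for the slope)."""
    data = table[[x, y]].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 paired observations")
    xv, yv = data[x].to_numpy(float), data[y].to_numpy(float)
    if np.std(xv) == 0:
        raise ValueError(f"predictor {x!r} has zero variance")
    res = sps.linregress(xv, yv)
    return float(res.slope), float(res.rvalue), float(res.pvalue)


def correlation_matrix(
    table: pd.DataFrame, columns: list[str] | None = None, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of the 24 variables (pretreatment).

    Returns (r, significant) DataFrames; ``significant`` masks p < alpha
    (unadjusted).  Constant columns are set to NaN / False and logged;
    the diagonal is 1 / True.
    """
    if columns is None:
        columns = [c for c in FEATURE_COLUMNS if c in table.columns]
    data = table[columns]
    if len(data) < 4:
        raise ValueError("need at least 4 organoids")
    k = len(columns)
    r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    sig = pd.DataFrame(np.eye(k, dtype=bool), index=columns, columns=columns)
    constant = [c for c in columns if np.nanstd(data[c].to_numpy(float)) == 0]
    for c in constant:
        log.info("constant column %r masked in correlation matrix", c)
    for i, a in enumerate(columns):
        for j in range(i + 1, k):
            b = columns[j]
            if a in constant or b in constant:
                rv, pv = np.nan, 1.0
            else:
                pair = data[[a, b]].dropna()
                rv, pv = sps.pearsonr(pair[a], pair[b])
            r.iloc[i, j] = r.iloc[j, i] = rv
            sig.iloc[i, j] = sig.iloc[j, i] = bool(pv < alpha)
    for c in constant:
        r.loc[c, c] = np.nan
        sig.loc[c, c] = False
    return r, sig


# ---------------------------------------------------------------------------
# simulation helpers (known-truth data for validation)
# ---------------------------------------------------------------------------

def simulate_normalized_series(
    rng: np.random.Generator,
    *,
    n_per_group: int = 15,
    groups: tuple[str, ...] = ("control", "treated"),
    times: tuple[float, ...] = (0.33, 12.0, 24.0, 36.0, 48.0),
    effects: dict[tuple[str, float], float] | None = None,
    intercept_sd: float = 0.1,
    rho: float = 0.5,
    sigma: float = 0.05,
) -> pd.DataFrame:
    """Simulate an organoid-normalized series from the model's own assumptions.

    Y_it = 1 + effect(group, t) + b_i + e_it with b_i ~ N(0, intercept_sd^2)
    and AR(1) errors of marginal sd ``sigma`` and lag-1 correlation ``rho``
    on the time index.  ``effects`` maps (group, time) to the mean shift.
    """
    effects = effects or {}
    rows = []
    oid = 0
    T = len(times)
    chol = np.linalg.cholesky(rho ** np.abs(np.subtract.outer(range(T), range(T))))
    for g in groups:
        for _ in range(n_per_group):
            oid += 1
            b = rng.normal(0, intercept_sd)
            e = sigma * (chol @ rng.normal(size=T))
            for k, t in enumerate(times):
                rows.append(
                    {
                        "organoid_id": oid,
                        "well": g,
                        "treatment": g,
                        "time_h": t,
                        "Y": 1.0 + effects.get((g, t), 0.0) + b + e[k],
                        "pretreatment": False,
                    }
                )
    return pd.DataFrame(rows)


def simulate_raw_longitudinal(
    rng: np.random.Generator,
    *,
    n_per_group: int = 12,
    groups: tuple[str, ...] = ("control", "treated"),
    times: tuple[float, ...] = (0.0, 0.33, 12.0, 24.0, 36.0, 48.0),
    effects: dict[tuple[str, float], float] | None = None,
    baseline_mean: float = 0.65,
    intercept_sd: float = 0.1,
    rho: float = 0.5,
    sigma: float = 0.03,
    variable: str = "mean_orr",
) -> pd.DataFrame:
    """Simulate raw (unnormalized) organoid trajectories with heterogeneity.

    X_it = (baseline + b_i) * (1 + effect(group, t)) + e_it, including a
    pretreatment row at t=0, so that organoid-level and well-level
    normalization can both be applied and their downstream models compared.
    """
    effects = effects or {}
    rows = []
    oid = 0
    T = len(times)
    chol = np.linalg.cholesky(rho ** np.abs(np.subtract.outer(range(T), range(T))))
    for g in groups:
        for _ in range(n_per_group):
            oid += 1
            base = baseline_mean + rng.normal(0, intercept_sd)
            e = sigma * (chol @ rng.normal(size=T))
            for k, t in enumerate(times):
                rows.append(
                    {
                        "organoid_id": oid,
                        "well": g,
                        "treatment": g,
                        "time_h": t,
                        variable: base * (1.0 + effects.get((g, t), 0.0)) + e[k],
                    }
                )
    return pd.DataFrame(rows)
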