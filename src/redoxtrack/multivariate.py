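"""PCA of the 24 organoid variables with pretreatment loadings.

The protocol: standardize each variable to zero mean / unit variance
*within each time point* (the variables span very different scales),
compute principal-component loadings from the pretreatment data only, then
project the 24-h and 48-h data through those fixed loadings to visualize
treatment-induced drift of organoid subpopulations in the pretreatment
PC1-PC2 plane.  Groups are summarized by 95% bivariate-normal ellipses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from redoxtrack.features import FEATURE_COLUMNS, METABOLIC_COLUMNS

log = logging.getLogger(__name__)


@dataclass
class PcaModel:
    """Loadings learned on standardized pretreatment data.

    ``loadings`` has one column per component (orthonormal); sign fixed so
    each component's largest-magnitude entry is positive.
    """

    loadings: pd.DataFrame  # variables x components
    explained_variance_ratio: np.ndarray
    variables: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class EllipseSpec:
    group: str
    center: np.ndarray  # (PC1, PC2)
    covariance: np.ndarray  # 2x2
    level: float = 0.95

    @property
    def radii(self) -> np.ndarray:
        """Semi-axes of the coverage ellipse (chi-square radius)."""
        evals = np.linalg.eigvalsh(self.covariance)
        return np.sqrt(np.maximum(evals, 0.0) * sps.chi2.ppf(self.level, df=2))


def standardize_within_time(
    table: pd.DataFrame, variables: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each variable within each time point.

    Returns (standardized table, retained variables).  Variables constant
    at any time point are dropped (with a log line) because they carry no
    scale-free information for that fit.
    """
    if variables is None:
        variables = [c for c in FEATURE_COLUMNS if c in table.columns]
    counts = table.groupby("time_h").size()
    if (counts < 2).any():
        raise ValueError("need at least 2 organoids per time point")
    dropped = set()
    for t, grp in table.groupby("time_h"):
        sd = grp[variables].std(ddof=0)
        for v in sd.index[(sd == 0) | sd.isna()]:
            dropped.add(v)
            log.info("variable %r constant at t=%s h; dropped from PCA", v, t)
    keep = [v for v in variables if v not in dropped]
    out = table.copy()
    for t, grp in table.groupby("time_h"):
        mu = grp[keep].mean()
        sd = grp[keep].std(ddof=0)
        out.loc[grp.index, keep] = (grp[keep] - mu) / sd
    return out, keep


def fit_pca(standardized: pd.DataFrame, variables: list[str]) -> PcaModel:
    """PCA via SVD of the standardized pretreatment matrix.

    Loadings are the right singular vectors (eigenvectors of the sample
    correlation structure); the number of components is
    min(n_rows - 1, n_variables).
    """
    Z = standardized[variables].to_numpy(float)
    if Z.shape[0] < 3:
        raise ValueError("need at least 3 organoids to fit PCA")
    Zc = Z - Z.mean(axis=0)
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    k = min(Z.shape[0] - 1, len(variables))
    Vt = Vt[:k]
    s = s[:k]
    # deterministic sign: largest-|loading| entry positive per component
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    var = s**2
    evr = var / np.sum(Zc**2)
    loadings = pd.DataFrame(
        Vt.T, index=variables, columns=[f"PC{i+1}" for i in range(k)]
    )
    return PcaModel(loadings=loadings, explained_variance_ratio=evr, variables=list(variables))


def project(model: PcaModel, standardized: pd.DataFrame) -> pd.DataFrame:
    """Project standardized data through the (pretreatment) loadings."""
    missing = [v for v in model.variables if v not in standardized.columns]
    if missing:
        raise KeyError(f"missing variables for projection: {missing}")
    Z = standardized[model.variables].to_numpy(float)
    scores = Z @ model.loadings.to_numpy()
    out = pd.DataFrame(scores, columns=model.loadings.columns, index=standardized.index)
    for key in ("organoid_id", "time_h", "treatment", "phenotype", "group"):
        if key in standardized.columns:
            out[key] = standardized[key].to_numpy()
    return out


def biplot_scale(model: PcaModel, scores: pd.DataFrame) -> float:
    """Scale factor mapping scores into the loadings interval for a biplot."""
    max_load = float(np.abs(model.loadings[["PC1", "PC2"]].to_numpy()).max())
    max_score = float(np.abs(scores[["PC1", "PC2"]].to_numpy()).max())
    return max_load / max_score if max_score > 0 else 1.0


def ellipse_95(scores: pd.DataFrame, group: str, *, level: float = 0.95) -> EllipseSpec | None:
    """95% bivariate-normal ellipse of one group's (PC1, PC2) scores.

    Center = mean, shape = sample covariance, radius = chi-square(2)
    quantile.  Groups with fewer than 3 points are skipped (returns None).
    """
    pts = scores.loc[scores["group"] == group, ["PC1", "PC2"]].to_numpy(float)
    if pts.shape[0] < 3:
        log.info("group %r has %d < 3 points; ellipse skipped", group, pts.shape[0])
        return None
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    return EllipseSpec(group=group, center=center, covariance=cov, level=level)


def point_in_ellipse(spec: EllipseSpec, points: np.ndarray) -> np.ndarray:
    """Boolean mask of points inside the coverage ellipse (Mahalanobis test)."""
    d = points - spec.center
    inv = np.linalg.inv(spec.covariance)
    md2 = np.einsum("ij,jk,ik->i", d, inv, d)
    return md2 <= sps.chi2.ppf(spec.level, df=2)


def top_loadings(model: PcaModel, k: int = 12) -> pd.DataFrame:
    """Variables ranked by L2 norm of their (PC1, PC2) loadings, top k.

    Ties are broken by variable name for reproducibility.  Each entry is
    tagged metabolic or morphological.
    """
    if k > len(model.variables):
        log.warning("k=%d exceeds %d variables; clipping", k, len(model.variables))
        k = len(model.variables)
    L = model.loadings[["PC1", "PC2"]]
    norm = np.hypot(L["PC1"], L["PC2"])
    df = pd.DataFrame(
        {
            "variable": model.variables,
            "pc1_loading": L["PC1"].to_numpy(),
            "pc2_loading": L["PC2"].to_numpy(),
            "norm": norm.to_numpy(),
            "kind": [
                "metabolic" if v in METABOLIC_COLUMNS else "morphological"
                for v in model.variables
            ],
        }
    )
    df = df.sort_values(["norm", "variable"], ascending=[False, True], kind="stable")
    return df.head(k).reset_index(drop=True)
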