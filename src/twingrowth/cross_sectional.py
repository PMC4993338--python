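"""Cross-sectional regression of telomere length with twin-pair-clustered SEs.

Point estimates are ordinary least squares; the covariance of the estimates is
the cluster sandwich

    V = c * (X'X)^-1 [ sum_g X_g' e_g e_g' X_g ] (X'X)^-1

clustered on twin pair, with the CR1-style small-sample factor
c = G/(G-1) * (N-1)/(N-p) and t(G-1) reference inference by default.  Both
the factor and the reference distribution are configurable; exact numerical
agreement with any particular survey-regression software is not claimed.

Sex is coded female = 1 in this module (a positive coefficient means women
have longer telomeres), the convention of the cross-sectional estimates the
defaults are calibrated to.  The growth-curve module codes male = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ClusterOLSFit:
    """OLS fit with cluster-robust (sandwich) inference."""

    coefficients: pd.Series
    robust_vcov: pd.DataFrame
    se: pd.Series
    ci_95: pd.DataFrame  # columns: lower, upper
    p_values: pd.Series
    n_obs: int
    n_clusters: int
    df_inference: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "robust_se": self.se,
                "ci_lower": self.ci_95["lower"],
                "ci_upper": self.ci_95["upper"],
                "p_value": self.p_values,
            }
        )


def _collinear_terms(X: np.ndarray, names: list[str]) -> list[str]:
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return []
    # flag columns whose removal does not reduce the rank
    bad = []
    for j in range(X.shape[1]):
        keep = [k for k in range(X.shape[1]) if k != j]
        if np.linalg.matrix_rank(X[:, keep]) == r:
            bad.append(names[j])
    return bad


def fit_cluster_ols(
    y,
    X: pd.DataFrame,
    clusters,
    small_sample: str = "CR1",
    use_t: bool = True,
) -> ClusterOLSFit:
    """OLS with cluster sandwich covariance.

    Parameters
    ----------
    y : outcome vector.
    X : design matrix (include an intercept column explicitly).
    clusters : cluster label per row (twin-pair IDs).
    small_sample : "CR1" applies G/(G-1)*(N-1)/(N-p); "none" applies no factor.
    use_t : if True, CIs and p-values use t(G-1); otherwise standard normal.
    """
    y = np.asarray(y, dtype=float)
    Xm = X.to_numpy(dtype=float)
    names = list(X.columns)
    clusters = np.asarray(clusters)
    n, p = Xm.shape
    if y.shape[0] != n or clusters.shape[0] != n:
        raise ValueError("y, X and clusters must have the same length")
    labels = pd.unique(clusters)
    G = len(labels)
    if G < 2:
        raise ValueError("need at least 2 clusters for a cluster sandwich")
    if np.linalg.matrix_rank(Xm) < p:
        raise ValueError(f"design is singular; collinear terms: {_collinear_terms(Xm, names)}")

    XtX_inv = np.linalg.inv(Xm.T @ Xm)
    beta = XtX_inv @ (Xm.T @ y)
    resid = y - Xm @ beta

    meat = np.zeros((p, p))
    for g in labels:
        idx = clusters == g
        s = Xm[idx].T @ resid[idx]
        meat += np.outer(s, s)
    vcov = XtX_inv @ meat @ XtX_inv
    if small_sample == "CR1":
        vcov *= G / (G - 1) * (n - 1) / (n - p)
    elif small_sample != "none":
        raise ValueError("small_sample must be 'CR1' or 'none'")

    se = np.sqrt(np.diag(vcov))
    df = float(G - 1)
    if use_t:
        q = stats.t.ppf(0.975, df)
        pvals = 2 * stats.t.sf(np.abs(beta / se), df)
    else:
        q = stats.norm.ppf(0.975)
        pvals = 2 * stats.norm.sf(np.abs(beta / se))

    idx = pd.Index(names)
    return ClusterOLSFit(
        coefficients=pd.Series(beta, index=idx),
        robust_vcov=pd.DataFrame(vcov, index=idx, columns=idx),
        se=pd.Series(se, index=idx),
        ci_95=pd.DataFrame(
            {"lower": beta - q * se, "upper": beta + q * se}, index=idx
        ),
        p_values=pd.Series(pvals, index=idx),
        n_obs=n,
        n_clusters=G,
        df_inference=df,
    )


def cross_sectional_analysis(
    individuals: pd.DataFrame,
    first_measures: pd.DataFrame,
    include_grs: bool = False,
    grs_scale: str = "ts",
) -> ClusterOLSFit:
    """First-occasion LTL on age and sex (female = 1), clustered on twin pair.

    ``include_grs`` adds the mean-centered GRS; individuals without a score
    are dropped (complete-case).  ``grs_scale='sd'`` standardises the outcome
    to unit SD first, so the GRS coefficient reads as SD change per allele.
    """
    data = first_measures.merge(
        individuals[["individual_id", "pair_id", "sex"] + (["grs"] if include_grs else [])],
        on="individual_id",
    )
    if data["ts_adjusted"].isna().any():
        raise ValueError("run batch adjustment before the cross-sectional fit")
    y = data["ts_adjusted"].to_numpy(dtype=float)
    if grs_scale == "sd":
        y = y / y.std(ddof=1)
    elif grs_scale != "ts":
        raise ValueError("grs_scale must be 'ts' or 'sd'")
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "age": data["age_at_draw"].astype(float),
            "sex_female": (data["sex"] == "female").astype(float),
        }
    )
    if include_grs:
        keep = data["grs"].notna()
        data, X, y = data[keep], X[keep], y[keep.to_numpy()]
        X = X.assign(grs_centered=(data["grs"] - data["grs"].mean()).to_numpy())
    return fit_cluster_ols(y, X, data["pair_id"].to_numpy())
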