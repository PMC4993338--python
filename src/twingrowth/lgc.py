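"""Latent growth curve (LGC) models for longitudinal twin telomere data.

The model is a linear mixed model on the T/S-ratio with a piecewise-linear
age trend.  Ages are centered at a knot c (default 69.3 years) and enter
through the spline basis

    B1(t) = min(t - c, 0),   B2(t) = max(t - c, 0),

so the intercept is the expected T/S at the knot, slope 1 the annual rate of
change before it and slope 2 the rate after it.  Twin relatedness is handled
by two nested random-effect levels over the active growth terms: a between-
pair (familial) deviation a_j shared by both twins and a within-pair
(individual, non-familial) deviation b_ij, each with an unstructured
covariance, plus an occasion-independent Gaussian residual.  For pair j with
stacked measurements y_j of its two twins,

    y_j ~ N( X_j beta,  Z_Bj S_B Z_Bj' + blockdiag_i(Z_Wij S_W Z_Wij') + s2 I ).

Estimation is maximum likelihood (not REML), so differences in -2 log
likelihood between nested models are valid chi-square difference tests even
when the fixed effects differ.  Covariances are parameterised by log-Cholesky
factors for unconstrained optimisation; fixed effects are profiled out by
generalised least squares at each variance evaluation.  Boundary (near-zero
variance) solutions are reported as fitted; the chi-square reference for the
difference test is the naive one, anticonservative when the truth is on the
boundary.

Sex is coded male = 1 in this module (a negative sex coefficient means men
have shorter telomeres); the GRS covariate is centered on its mean over the
individuals entering the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_GROWTH = ("intercept", "slope1", "slope2")
_COVARIATES = ("sex", "grs")
_INTERACTIONS = ("slope2:sex", "slope2:grs", "sex:grs")

_LOG2PI = float(np.log(2.0 * np.pi))


def age_basis(age, centering_age: float = 69.3):
    """Piecewise-linear spline basis (B1, B2) around the centering age.

    B1 + B2 = age - centering_age; B1 is the pre-knot limb (non-positive),
    B2 the post-knot limb (non-negative).
    """
    d = np.asarray(age, dtype=float) - centering_age
    return np.minimum(d, 0.0), np.maximum(d, 0.0)


@dataclass(frozen=True)
class LGCSpec:
    """Definition of one growth-curve model.

    growth_terms also index the random-effect structure: both random levels
    carry an unstructured covariance over the active growth terms.  The
    residual variance is a single parameter shared across occasions.
    """

    centering_age: float = 69.3
    growth_terms: tuple = _GROWTH
    covariates: tuple = ("sex",)
    interactions: tuple = ()
    bic_n: str = "pairs"  # or "individuals" / "observations"

    def __post_init__(self) -> None:
        if "intercept" not in self.growth_terms:
            raise ValueError("growth_terms must include the intercept")
        for t in self.growth_terms:
            if t not in _GROWTH:
                raise ValueError(f"unknown growth term {t!r}")
        for c in self.covariates:
            if c not in _COVARIATES:
                raise ValueError(f"unknown covariate {c!r}")
        for i in self.interactions:
            if i not in _INTERACTIONS:
                raise ValueError(f"unknown interaction {i!r}")
            needed = i.split(":")
            for part in needed:
                if part in _GROWTH and part not in self.growth_terms:
                    raise ValueError(f"interaction {i!r} needs growth term {part!r}")
                if part in _COVARIATES and part not in self.covariates:
                    raise ValueError(f"interaction {i!r} needs covariate {part!r}")
        if self.bic_n not in ("pairs", "individuals", "observations"):
            raise ValueError("bic_n must be pairs/individuals/observations")

    @property
    def fixed_names(self) -> list[str]:
        return (
            [g for g in _GROWTH if g in self.growth_terms]
            + [c for c in _COVARIATES if c in self.covariates]
            + [i for i in _INTERACTIONS if i in self.interactions]
        )

    @property
    def n_growth(self) -> int:
        return len(self.growth_terms)

    def is_nested_in(self, other: "LGCSpec") -> bool:
        return (
            self.centering_age == other.centering_age
            and set(self.growth_terms) <= set(other.growth_terms)
            and set(self.covariates) <= set(other.covariates)
            and set(self.interactions) <= set(other.interactions)
        )


def intercept_only_spec(**kw) -> LGCSpec:
    return LGCSpec(growth_terms=("intercept",), **kw)


def one_slope_spec(**kw) -> LGCSpec:
    return LGCSpec(growth_terms=("intercept", "slope1"), **kw)


def two_slope_spec(**kw) -> LGCSpec:
    return LGCSpec(growth_terms=("intercept", "slope1", "slope2"), **kw)


def count_parameters(spec: LGCSpec) -> int:
    """Free parameters: fixed effects + two unstructured random covariances
    (d(d+1)/2 each, d = active growth terms) + 1 residual variance."""
    d = spec.n_growth
    return len(spec.fixed_names) + d * (d + 1) + 1


@dataclass
class LGCParams:
    """Parameter values of a growth-curve model (generating or fitted)."""

    fixed: dict[str, float]
    between_pair_cov: np.ndarray
    within_pair_cov: np.ndarray
    residual_var: float

    def __post_init__(self) -> None:
        self.between_pair_cov = np.atleast_2d(np.asarray(self.between_pair_cov, float))
        self.within_pair_cov = np.atleast_2d(np.asarray(self.within_pair_cov, float))
        if self.residual_var < 0:
            raise ValueError("residual_var must be non-negative")


@dataclass
class LGCFit:
    spec: LGCSpec
    params: LGCParams
    minus2ll: float
    aic: float
    bic: float
    parameter_count: int
    fixed_vcov: pd.DataFrame
    converged: bool
    n_pairs: int
    n_individuals: int
    n_samples: int
    optimizer_message: str = ""

    def fixed_summary(self) -> pd.DataFrame:
        """Fixed effects with Wald standard errors, 95% CIs and p-values."""
        names = self.spec.fixed_names
        est = np.array([self.params.fixed[n] for n in names])
        se = np.sqrt(np.diag(self.fixed_vcov.to_numpy()))
        z = est / se
        return pd.DataFrame(
            {
                "estimate": est,
                "se": se,
                "ci_lower": est - 1.96 * se,
                "ci_upper": est + 1.96 * se,
                "p_value": 2 * stats.norm.sf(np.abs(z)),
            },
            index=pd.Index(names, name="term"),
        )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class _Design:
    """Pair-grouped design, batched by missingness pattern for speed."""

    groups: list  # (y (g,m), X (g,m,p), Zb (g,m,d), Zw (g,m,2d))
    fixed_names: list[str]
    n_pairs: int
    n_individuals: int
    n_samples: int


def _build_design(spec: LGCSpec, data: pd.DataFrame) -> _Design:
    req = ["pair_id", "individual_id", "age_at_draw", "ts_adjusted"]
    missing_cols = [c for c in req if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data missing columns: {missing_cols}")
    df = data.copy()
    need = list(req)
    if "sex" in spec.covariates:
        need.append("sex")
    if "grs" in spec.covariates:
        need.append("grs")
    n0 = len(df)
    df = df.dropna(subset=[c for c in need if c in df.columns])
    if len(df) < n0:
        logger.info("fit: dropped %d rows with missing values", n0 - len(df))
    if df.empty:
        raise ValueError("no complete rows to fit")

    b1, b2 = age_basis(df["age_at_draw"].to_numpy(), spec.centering_age)
    growth_cols = {"intercept": np.ones(len(df)), "slope1": b1, "slope2": b2}
    cols = {g: growth_cols[g] for g in _GROWTH if g in spec.growth_terms}
    if "sex" in spec.covariates:
        cols["sex"] = (df["sex"].to_numpy() == "male").astype(float)
    if "grs" in spec.covariates:
        per_ind = df.groupby("individual_id")["grs"].first()
        centered = df["grs"].to_numpy(float) - per_ind.mean()
        cols["grs"] = centered
    for inter in spec.interactions:
        a, b = inter.split(":")
        left = growth_cols[a] if a in _GROWTH else cols[a]
        cols[inter] = left * cols[b]

    fixed_names = spec.fixed_names
    X = np.column_stack([cols[n] for n in fixed_names])
    Z = np.column_stack([growth_cols[g] for g in _GROWTH if g in spec.growth_terms])
    y = df["ts_adjusted"].to_numpy(float)
    d = Z.shape[1]

    df = df.reset_index(drop=True)
    pattern_members: dict[tuple[int, int], list] = {}
    n_ind = df["individual_id"].nunique()
    for pair_id, pdf in df.groupby("pair_id", sort=True):
        twins = sorted(pdf["individual_id"].unique())
        idx_by_twin = [
            pdf.index[pdf["individual_id"] == t].to_numpy() for t in twins[:2]
        ]
        if len(twins) > 2:
            raise ValueError(f"pair {pair_id!r} has more than two individuals")
        m1 = len(idx_by_twin[0])
        m2 = len(idx_by_twin[1]) if len(idx_by_twin) > 1 else 0
        pattern_members.setdefault((m1, m2), []).append(idx_by_twin)

    groups = []
    for (m1, m2), members in pattern_members.items():
        m = m1 + m2
        g = len(members)
        yg = np.empty((g, m))
        Xg = np.empty((g, m, X.shape[1]))
        Zb = np.empty((g, m, d))
        Zw = np.zeros((g, m, 2 * d))
        for k, idx_by_twin in enumerate(members):
            rows = np.concatenate(idx_by_twin) if m2 else idx_by_twin[0]
            yg[k] = y[rows]
            Xg[k] = X[rows]
            Zb[k] = Z[rows]
            Zw[k, :m1, :d] = Z[idx_by_twin[0]]
            if m2:
                Zw[k, m1:, d:] = Z[idx_by_twin[1]]
        groups.append((yg, Xg, Zb, Zw))

    return _Design(
        groups=groups,
        fixed_names=fixed_names,
        n_pairs=len(df["pair_id"].unique()),
        n_individuals=n_ind,
        n_samples=len(df),
    )


def _marginal_covs(design: _Design, cov_b, cov_w, resid_var):
    """Yield (y, X, V) per pattern group."""
    d = cov_b.shape[0]
    cov_w2 = np.zeros((2 * d, 2 * d))
    cov_w2[:d, :d] = cov_w
    cov_w2[d:, d:] = cov_w
    for yg, Xg, Zb, Zw in design.groups:
        V = np.einsum("gmd,de,gne->gmn", Zb, cov_b, Zb)
        V += np.einsum("gmd,de,gne->gmn", Zw, cov_w2, Zw)
        m = V.shape[-1]
        V[:, np.arange(m), np.arange(m)] += resid_var
        yield yg, Xg, V


def _accumulate(design: _Design, cov_b, cov_w, resid_var):
    """Cholesky-based sufficient statistics of the marginal likelihood.

    Returns (XtViX, XtViy, ytViy, logdet, n_obs) summed over pairs, or None
    if any pair covariance fails to be positive definite.
    """
    p = len(design.fixed_names)
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    n_obs = 0
    for yg, Xg, V in _marginal_covs(design, cov_b, cov_w, resid_var):
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        m = V.shape[-1]
        rhs = np.concatenate([Xg, yg[..., None]], axis=2)
        W = np.linalg.solve(L, rhs)  # batched forward solve
        Wx, wy = W[..., :p], W[..., p]
        XtViX += np.einsum("gmi,gmj->ij", Wx, Wx)
        XtViy += np.einsum("gmi,gm->i", Wx, wy)
        ytViy += float(np.einsum("gm,gm->", wy, wy))
        logdet += 2.0 * float(np.log(np.diagonal(L, axis1=1, axis2=2)).sum())
        n_obs += yg.size
    return XtViX, XtViy, ytViy, logdet, n_obs


def neg2_loglik(params: LGCParams, spec: LGCSpec, data: pd.DataFrame) -> float:
    """-2 log marginal likelihood of the data at the given parameters.

    Pairs are independent; each contributes a multivariate-normal density
    over the stacked measurements of its two twins.  Non-positive-definite
    covariance parameters return +inf (optimizer-safe).
    """
    design = _build_design(spec, data)
    return _neg2_loglik_design(design, params, spec)


def _neg2_loglik_design(design: _Design, params: LGCParams, spec: LGCSpec) -> float:
    d = spec.n_growth
    cov_b = params.between_pair_cov
    cov_w = params.within_pair_cov
    if cov_b.shape != (d, d) or cov_w.shape != (d, d):
        raise ValueError(f"random covariances must be {d}x{d} for this spec")
    for m in (cov_b, cov_w):
        if not np.allclose(m, m.T):
            raise ValueError("random covariances must be symmetric")
        if np.linalg.eigvalsh(m).min() < -1e-12:
            logger.warning("non-PSD covariance supplied; returning +inf")
            return np.inf
    beta = np.array([params.fixed[n] for n in design.fixed_names])
    acc = _accumulate(design, cov_b, cov_w, params.residual_var)
    if acc is None:
        return np.inf
    XtViX, XtViy, ytViy, logdet, n_obs = acc
    quad = ytViy - 2.0 * beta @ XtViy + beta @ XtViX @ beta
    return float(logdet + quad + n_obs * _LOG2PI)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------


def _n_chol(d: int) -> int:
    return d * (d + 1) // 2


def _theta_to_cov(theta: np.ndarray, d: int) -> np.ndarray:
    """Log-Cholesky vector (diag entries on log scale) to covariance."""
    L = np.zeros((d, d))
    k = 0
    for i in range(d):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[k]) if i == j else theta[k]
            k += 1
    return L @ L.T


def _cov_to_theta(cov: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    d = cov.shape[0]
    cov = cov + floor * np.eye(d)
    L = np.linalg.cholesky(cov)
    out = []
    for i in range(d):
        for j in range(i + 1):
            out.append(np.log(L[i, i]) if i == j else L[i, j])
    return np.array(out)


def _unpack_theta(theta: np.ndarray, d: int):
    nc = _n_chol(d)
    cov_b = _theta_to_cov(theta[:nc], d)
    cov_w = _theta_to_cov(theta[nc : 2 * nc], d)
    resid_var = float(np.exp(2.0 * theta[-1]))
    return cov_b, cov_w, resid_var


def _profile_deviance(theta: np.ndarray, design: _Design, d: int):
    """Profile -2LL over theta, with fixed effects solved by GLS."""
    cov_b, cov_w, resid_var = _unpack_theta(theta, d)
    acc = _accumulate(design, cov_b, cov_w, resid_var)
    if acc is None:
        return np.inf, None, None
    XtViX, XtViy, ytViy, logdet, n_obs = acc
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    quad = ytViy - beta @ XtViy
    return float(logdet + quad + n_obs * _LOG2PI), beta, XtViX


def _chol_grad(G: np.ndarray, theta_block: np.ndarray, d: int) -> np.ndarray:
    """Map a symmetric gradient wrt a covariance to its log-Cholesky vector."""
    L = np.zeros((d, d))
    k = 0
    for i in range(d):
        for j in range(i + 1):
            L[i, j] = np.exp(theta_block[k]) if i == j else theta_block[k]
            k += 1
    GL = 2.0 * (G @ L)
    out = np.empty(_n_chol(d))
    k = 0
    for i in range(d):
        for j in range(i + 1):
            out[k] = GL[i, i] * L[i, i] if i == j else GL[i, j]
            k += 1
    return out


def _deviance_and_grad(theta: np.ndarray, design: _Design, d: int):
    """Profiled -2LL and its analytic gradient wrt the log-Cholesky vector.

    Because the fixed effects are at their GLS optimum given theta, the total
    derivative of the profiled deviance equals the partial derivative at the
    fitted residuals (envelope theorem).  Per pair, with u = V^-1 r,

        d(-2LL) = tr[(V^-1 - u u') dV],

    and dV/d(cov entries) factors through the random-effect designs.
    """
    cov_b, cov_w, resid_var = _unpack_theta(theta, d)
    p = len(design.fixed_names)
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    n_obs = 0
    cache = []
    for yg, Xg, V in _marginal_covs(design, cov_b, cov_w, resid_var):
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(theta.size)
        rhs = np.concatenate([Xg, yg[..., None]], axis=2)
        W = np.linalg.solve(L, rhs)
        Wx, wy = W[..., :p], W[..., p]
        XtViX += np.einsum("gmi,gmj->ij", Wx, Wx)
        XtViy += np.einsum("gmi,gm->i", Wx, wy)
        ytViy += float(np.einsum("gm,gm->", wy, wy))
        logdet += 2.0 * float(np.log(np.diagonal(L, axis1=1, axis2=2)).sum())
        n_obs += yg.size
        cache.append(L)
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(theta.size)
    f = float(logdet + ytViy - beta @ XtViy + n_obs * _LOG2PI)

    A_b = np.zeros((d, d))
    A_w = np.zeros((d, d))
    g_resid = 0.0
    eye_cache: dict[int, np.ndarray] = {}
    for (yg, Xg, Zb, Zw), L in zip(design.groups, cache):
        m = L.shape[-1]
        r = yg - np.einsum("gmp,p->gm", Xg, beta)
        Lt = np.swapaxes(L, 1, 2)
        u = np.linalg.solve(Lt, np.linalg.solve(L, r[..., None]))[..., 0]
        eye = eye_cache.setdefault(m, np.eye(m))
        Linv = np.linalg.solve(L, np.broadcast_to(eye, L.shape))
        Vinv = np.einsum("gkm,gkn->gmn", Linv, Linv)
        M = Vinv - np.einsum("gm,gn->gmn", u, u)
        A_b += np.einsum("gmd,gmn,gne->de", Zb, M, Zb)
        A_w2 = np.einsum("gmd,gmn,gne->de", Zw, M, Zw)
        A_w += A_w2[:d, :d] + A_w2[d:, d:]
        g_resid += float(np.einsum("gmm->", M))

    nc = _n_chol(d)
    grad = np.empty(theta.size)
    grad[:nc] = _chol_grad(A_b, theta[:nc], d)
    grad[nc : 2 * nc] = _chol_grad(A_w, theta[nc : 2 * nc], d)
    grad[-1] = g_resid * 2.0 * resid_var  # theta is log SD
    return f, grad


def _start_theta(design: _Design, d: int) -> np.ndarray:
    """Moment-based start: OLS residual variance split 50/25/25 between-pair /
    within-pair / residual; slope variances scaled by the basis magnitude."""
    X = np.concatenate([g[1].reshape(-1, g[1].shape[2]) for g in design.groups])
    y = np.concatenate([g[0].ravel() for g in design.groups])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = max(float(resid.var(ddof=X.shape[1])), 1e-8)
    Zb = np.concatenate([g[2].reshape(-1, d) for g in design.groups])
    scale = np.maximum(np.mean(Zb**2, axis=0), 1.0)  # intercept column -> 1
    theta = []
    for frac in (0.50, 0.25):
        cov = np.diag(frac * s2 / scale)
        theta.append(_cov_to_theta(cov))
    theta.append([0.5 * np.log(0.25 * s2)])
    return np.concatenate(theta)


def _bounds(d: int) -> list[tuple[float, float]]:
    bounds = []
    for _level in range(2):
        for i in range(d):
            for j in range(i + 1):
                bounds.append((-13.0, 3.0) if i == j else (-3.0, 3.0))
    bounds.append((-7.0, 2.0))  # log residual SD
    return bounds


def _minimize_restarted(theta0, design, d, bounds, gtol):
    """L-BFGS-B, rerun from its own solution until the deviance stops
    improving.  Restarting resets the Hessian memory and the line search,
    which escapes the premature stalls the flat log-Cholesky valley causes."""
    opts = {"maxiter": 1000, "maxfun": 5000, "gtol": gtol, "ftol": 1e-14,
            "maxcor": 25, "maxls": 50}
    best = None
    x, f_prev = theta0, np.inf
    for _ in range(12):
        res = optimize.minimize(
            _deviance_and_grad, x, args=(design, d), jac=True,
            method="L-BFGS-B", bounds=bounds, options=opts,
        )
        if best is None or res.fun < best.fun:
            best = res
        if not np.isfinite(res.fun) or f_prev - res.fun < 1e-9:
            break
        x, f_prev = res.x, res.fun
    return best


def fit_ml(
    spec: LGCSpec,
    data: pd.DataFrame,
    start: LGCParams | None = None,
    seed: int = 0,
    gtol: float = 1e-9,
) -> LGCFit:
    """Fit the growth-curve model by maximum likelihood.

    Covariances are optimised through their log-Cholesky factors with the
    fixed effects profiled out by GLS; a single seeded random restart is
    attempted on non-convergence.  Returns the fit even when not converged
    (flagged), so diagnostics remain inspectable.
    """
    design = _build_design(spec, data)
    if design.n_pairs < 2:
        raise ValueError("need at least 2 twin pairs")
    d = spec.n_growth

    if start is not None:
        theta0 = np.concatenate(
            [
                _cov_to_theta(start.between_pair_cov),
                _cov_to_theta(start.within_pair_cov),
                [0.5 * np.log(max(start.residual_var, 1e-12))],
            ]
        )
    else:
        theta0 = _start_theta(design, d)

    bounds = _bounds(d)
    theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])

    rng = np.random.default_rng(seed)
    best = None
    message = ""
    for attempt in range(2):
        t0 = theta0 if attempt == 0 else np.clip(
            theta0 + rng.normal(0.0, 0.5, theta0.size),
            [b[0] for b in bounds],
            [b[1] for b in bounds],
        )
        res = _minimize_restarted(t0, design, d, bounds, gtol)
        if best is None or res.fun < best.fun:
            best = res
            message = str(res.message)
        if res.success and np.isfinite(res.fun):
            break

    m2ll, beta, XtViX = _profile_deviance(best.x, design, d)
    cov_b, cov_w, resid_var = _unpack_theta(best.x, d)
    names = design.fixed_names
    fixed_vcov = pd.DataFrame(np.linalg.inv(XtViX), index=names, columns=names)
    params = LGCParams(
        fixed=dict(zip(names, beta)),
        between_pair_cov=cov_b,
        within_pair_cov=cov_w,
        residual_var=resid_var,
    )
    k = count_parameters(spec)
    n_bic = {
        "pairs": design.n_pairs,
        "individuals": design.n_individuals,
        "observations": design.n_samples,
    }[spec.bic_n]
    return LGCFit(
        spec=spec,
        params=params,
        minus2ll=m2ll,
        aic=m2ll + 2 * k,
        bic=m2ll + k * np.log(n_bic),
        parameter_count=k,
        fixed_vcov=fixed_vcov,
        converged=bool(best.success and np.isfinite(m2ll)),
        n_pairs=design.n_pairs,
        n_individuals=design.n_individuals,
        n_samples=design.n_samples,
        optimizer_message=message,
    )


# ---------------------------------------------------------------------------
# model comparison and prediction
# ---------------------------------------------------------------------------


@dataclass
class LRTResult:
    delta_minus2ll: float
    df: int
    p_value: float


def lrt_from_deviances(minus2ll_reduced: float, minus2ll_full: float, df: int) -> LRTResult:
    """Chi-square difference test from two -2 log-likelihood values."""
    delta = minus2ll_reduced - minus2ll_full
    if df < 0:
        raise ValueError("df must be non-negative")
    p = 1.0 if df == 0 else float(stats.chi2.sf(max(delta, 0.0), df))
    return LRTResult(delta_minus2ll=delta, df=df, p_value=p)


def likelihood_ratio_test(
    fit_reduced: LGCFit, fit_full: LGCFit, tol: float = 1e-3
) -> LRTResult:
    """Chi-square difference test between two nested fitted models."""
    if not fit_reduced.spec.is_nested_in(fit_full.spec):
        raise ValueError("fit_reduced is not nested in fit_full")
    if not (fit_reduced.converged and fit_full.converged):
        raise ValueError("both fits must have converged")
    delta = fit_reduced.minus2ll - fit_full.minus2ll
    if delta < -tol:
        raise ValueError(
            f"full model fits worse than reduced (delta={delta:.4g}); "
            "optimizer failure suspected"
        )
    df = fit_full.parameter_count - fit_reduced.parameter_count
    delta = max(delta, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(delta, df))
    return LRTResult(delta_minus2ll=delta, df=df, p_value=p)


def predict_trajectory(
    fit: LGCFit, ages, sex: str = "female", grs_centered: float = 0.0
) -> pd.DataFrame:
    """Fixed-effects-only predicted T/S over an age grid.

    Piecewise-linear with the knot at the spec's centering age; without
    slope-by-sex interaction the male and female curves are parallel.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    ages = np.asarray(ages, dtype=float)
    b1, b2 = age_basis(ages, fit.spec.centering_age)
    fx = fit.params.fixed
    male = 1.0 if sex == "male" else 0.0
    pred = np.full(ages.shape, fx["intercept"])
    if "slope1" in fx:
        pred = pred + fx["slope1"] * b1
    if "slope2" in fx:
        pred = pred + fx["slope2"] * b2
    if "sex" in fx:
        pred = pred + fx["sex"] * male
    if "grs" in fx:
        pred = pred + fx["grs"] * grs_centered
    if "slope2:sex" in fx:
        pred = pred + fx["slope2:sex"] * b2 * male
    if "slope2:grs" in fx:
        pred = pred + fx["slope2:grs"] * b2 * grs_centered
    if "sex:grs" in fx:
        pred = pred + fx["sex:grs"] * male * grs_centered
    return pd.DataFrame({"age": ages, "sex": sex, "predicted_ts": pred})
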