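"""Mixed-effects logistic regression of ovarian atrophy on TE dosage.

The phenotype is binary (F1 female has atrophied ovaries or not); the
covariates of interest are per-paternal-strain TE abundance estimators.
Models are binomial GLMMs with random intercepts for experimental block
(always) and optionally paternal strain; the marginal likelihood is
maximized with the Laplace approximation to the random-effect integrals
(the glmer convention: fixed effects and conditional modes from the
joint penalized fit, one parameter counted per variance component).

Nested models are compared by likelihood-ratio test and by AIC; each
association ledger row records the focal estimator's LRT chi-square, df,
p-value, AIC difference and association sign, with support for rerunning
under strain exclusion (outlier sensitivity). LRT p-values for variance
components use the naive chi-square reference without a boundary-mixture
correction, which is anti-conservative for that case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.linalg import qr as _qr
from scipy.stats import chi2 as _chi2

__all__ = [
    "GlmmSpec",
    "ModelFit",
    "LRTResult",
    "strain_filter",
    "fit_logistic_glmm",
    "lrt",
    "association_scan",
    "heritability_comparison",
]

_SIGMA_LO, _SIGMA_HI = 1e-4, 30.0
_SEPARATION_BOUND = 30.0


@dataclass(frozen=True)
class GlmmSpec:
    """Model specification: per-strain fixed covariates, random factors.

    ``strain_fixed`` enters paternal strain as a categorical fixed
    effect (reference level dropped); strain cannot simultaneously be a
    random factor.
    """

    covariates: tuple[str, ...] = ()
    random: tuple[str, ...] = ("block",)
    strain_fixed: bool = False

    def __post_init__(self):
        bad = set(self.random) - {"block", "strain"}
        if bad:
            raise ValueError(f"unknown random factors: {sorted(bad)}")
        if self.strain_fixed and "strain" in self.random:
            raise ValueError("strain cannot be both fixed categorical and random")


@dataclass
class ModelFit:
    log_likelihood: float
    aic: float
    n_params: int
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    variance_components: dict[str, float]  # factor -> sigma^2
    converged: bool
    n_obs: int
    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...]
    diagnostics: str = ""

    def __post_init__(self):
        assert abs(self.aic - (-2.0 * self.log_likelihood + 2.0 * self.n_params)) < 1e-9


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float
    delta_aic: float
    association_sign: str  # "+", "-" or "0"
    focal: str | None = None


# ----------------------------------------------------------------------
# strain filter
# ----------------------------------------------------------------------

def strain_filter(
    records: pd.DataFrame,
    min_females: int = 20,
    min_blocks: int = 2,
    per_block: bool = True,
) -> tuple[set[str], pd.DataFrame]:
    """Retain strains scored deeply enough for the association models.

    Default (``per_block=True``): a strain is kept iff it contributed at
    least ``min_females`` females in each of at least ``min_blocks``
    distinct blocks. With ``per_block=False`` the count is pooled: at
    least ``min_blocks`` blocks and ``min_females`` females in total.
    """
    counts = records.groupby(["strain", "block"], sort=False).size()
    retained: set[str] = set()
    for strain, per in counts.groupby(level="strain"):
        if per_block:
            if (per >= min_females).sum() >= min_blocks:
                retained.add(strain)
        else:
            if len(per) >= min_blocks and per.sum() >= min_females:
                retained.add(strain)
    return retained, records[records["strain"].isin(retained)].copy()


# ----------------------------------------------------------------------
# Laplace GLMM machinery
# ----------------------------------------------------------------------

def _bin_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # y*eta - log(1+exp(eta)), stable
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _penalized_mode(y, X, codes_list, sizes, sigma2, z0=None, max_iter=80):
    """Joint Newton maximization over (beta, u) of the penalized ll."""
    n, p = X.shape
    q = int(sum(sizes))
    d = p + q
    z = np.zeros(d) if z0 is None or len(z0) != d else z0.copy()
    offsets = np.cumsum([p] + list(sizes))[:-1]
    pen_diag = np.zeros(d)
    for off, sz, s2 in zip(offsets, sizes, sigma2):
        pen_diag[off : off + sz] = 1.0 / s2

    def components(zv):
        eta = X @ zv[:p]
        for off, sz, codes in zip(offsets, sizes, codes_list):
            eta = eta + zv[off : off + sz][codes]
        mu = special.expit(eta)
        pll = _bin_ll(y, eta) - 0.5 * float(pen_diag @ (zv * zv))
        return eta, mu, pll

    eta, mu, pll = components(z)
    converged = False
    H = None
    for _ in range(max_iter):
        r = y - mu
        grad = np.empty(d)
        grad[:p] = X.T @ r
        for off, sz, codes in zip(offsets, sizes, codes_list):
            grad[off : off + sz] = np.bincount(codes, weights=r, minlength=sz)
        grad -= pen_diag * z
        W = mu * (1.0 - mu) + 1e-12
        H = np.zeros((d, d))
        WX = W[:, None] * X
        H[:p, :p] = X.T @ WX
        for off, sz, codes in zip(offsets, sizes, codes_list):
            M = np.zeros((sz, p))
            np.add.at(M, codes, WX)
            H[:p, off : off + sz] = M.T
            H[off : off + sz, :p] = M
            H[off : off + sz, off : off + sz][np.diag_indices(sz)] = np.bincount(
                codes, weights=W, minlength=sz
            )
        for (off1, sz1, c1), (off2, sz2, c2) in _pairs(offsets, sizes, codes_list):
            C = np.zeros((sz1, sz2))
            np.add.at(C, (c1, c2), W)
            H[off1 : off1 + sz1, off2 : off2 + sz2] = C
            H[off2 : off2 + sz2, off1 : off1 + sz1] = C.T
        H[np.diag_indices(d)] += pen_diag
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        decrement = float(grad @ step)
        if decrement < 1e-10:
            converged = True
            break
        t = 1.0
        for _ in range(30):
            z_new = z + t * step
            eta, mu, pll_new = components(z_new)
            if pll_new >= pll - 1e-12:
                break
            t *= 0.5
        z, pll = z_new, pll_new
    return z, pll, H, converged


def _pairs(offsets, sizes, codes_list):
    items = list(zip(offsets, sizes, codes_list))
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            yield items[i], items[j]


def _laplace_loglik(y, X, codes_list, sizes, sigma, z0=None, nagq: int = 25):
    """Marginal log-likelihood at given random-effect SDs.

    The Laplace approximation is LL = binomial ll at the joint mode
    - quadratic penalty - sum_f q_f log sigma_f - 0.5 log|H_uu|, the
    2*pi factors of the Gaussian prior and the Laplace integral
    cancelling exactly. With a single random factor the likelihood
    factorizes over groups and is refined by adaptive Gauss-Hermite
    quadrature (``nagq`` nodes) centered on the conditional modes.
    """
    p = X.shape[1]
    sigma2 = np.asarray(sigma, dtype=float) ** 2
    z, pll, H, conv = _penalized_mode(y, X, codes_list, sizes, sigma2, z0)
    q = int(sum(sizes))
    eta = X @ z[:p]
    offsets = np.cumsum([p] + list(sizes))[:-1]
    for off, sz, codes in zip(offsets, sizes, codes_list):
        eta = eta + z[off : off + sz][codes]
    if q == sizes[0] and len(sizes) == 1 and nagq > 1:
        ll = _agq_loglik(y, X @ z[:p], codes_list[0], sizes[0], float(sigma[0]), z[p:], nagq)
        return ll, z, H, conv
    ll = _bin_ll(y, eta)
    for off, sz, s, s2 in zip(offsets, sizes, sigma, sigma2):
        u = z[off : off + sz]
        ll -= 0.5 * float(u @ u) / s2 + sz * np.log(s)
    if q:
        sign, logdet = np.linalg.slogdet(H[p:, p:])
        assert sign > 0
        ll -= 0.5 * logdet
    return ll, z, H, conv


def _agq_loglik(y, eta_fixed, codes, size, sigma, u_mode, nodes):
    """Adaptive Gauss-Hermite marginal ll for a single random factor.

    Each group's integral over its intercept is evaluated on ``nodes``
    Hermite abscissae rescaled by the conditional curvature at the mode,
    so the quadrature is exact in the Gaussian limit and converges fast
    for binomial clusters.
    """
    t, w = np.polynomial.hermite.hermgauss(nodes)
    logw = np.log(w)
    ll = 0.0
    s2 = sigma * sigma
    for g in range(size):
        m = codes == g
        e0 = eta_fixed[m]
        yg = y[m]
        mu = special.expit(e0 + u_mode[g])
        h = float((mu * (1.0 - mu)).sum()) + 1.0 / s2  # conditional curvature
        uj = u_mode[g] + np.sqrt(2.0 / h) * t
        e = e0[:, None] + uj[None, :]
        f = yg @ e - np.logaddexp(0.0, e).sum(axis=0)
        logg = f - 0.5 * uj * uj / s2 - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
        a = logw + t * t + logg
        amax = a.max()
        ll += amax + np.log(np.exp(a - amax).sum()) + 0.5 * np.log(2.0 / h)
    return float(ll)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        return
    _, R, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")


def _build_design(records: pd.DataFrame, spec: GlmmSpec, covariates: pd.DataFrame | None):
    y = records["atrophied"].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("atrophied must be binary 0/1")
    cols = [np.ones(len(records))]
    names = ["(Intercept)"]
    for name in spec.covariates:
        if covariates is None or name not in covariates.columns:
            raise ValueError(f"covariate {name!r} not provided")
        vals = records["strain"].map(covariates[name]).to_numpy(dtype=float)
        if np.isnan(vals).any():
            missing = sorted(records.loc[np.isnan(vals), "strain"].unique())
            raise ValueError(f"covariate {name!r} missing for strains {missing}")
        cols.append(vals)
        names.append(name)
    if spec.strain_fixed:
        levels = sorted(records["strain"].unique())
        for lev in levels[1:]:  # first level is the reference
            cols.append((records["strain"] == lev).to_numpy(dtype=float))
            names.append(f"strain[{lev}]")
    X = np.column_stack(cols)
    _check_rank(X, names)
    codes_list, sizes = [], []
    for factor in spec.random:
        values = records[factor].astype(str)
        levels = sorted(values.unique())
        if len(levels) < 2:
            raise ValueError(f"random factor {factor!r} needs >= 2 levels")
        lookup = {lev: i for i, lev in enumerate(levels)}
        codes_list.append(values.map(lookup).to_numpy(dtype=np.intp))
        sizes.append(len(levels))
    return y, X, names, codes_list, sizes


def fit_logistic_glmm(
    records: pd.DataFrame,
    spec: GlmmSpec = GlmmSpec(),
    covariates: pd.DataFrame | None = None,
) -> ModelFit:
    """Maximum-likelihood binomial GLMM fit (Laplace approximation).

    ``records`` has one row per female with columns strain, block,
    atrophied; ``covariates`` is a per-strain table indexed by strain.
    Deterministic given the data: fixed effects start at zero and each
    random-effect SD at 1. With no random factors the fit is an ordinary
    logistic regression and the likelihood is exact. Complete separation
    or non-convergence is reported through ``converged``/``diagnostics``,
    never silently.
    """
    y, X, names, codes_list, sizes = _build_design(records, spec, covariates)
    n, p = X.shape
    n_factors = len(sizes)
    state: dict = {"z": None}

    def negll(log_sigma: np.ndarray) -> float:
        sig = np.exp(np.atleast_1d(log_sigma))
        ll, z, _, _ = _laplace_loglik(y, X, codes_list, sizes, sig, state["z"])
        state["z"] = z
        return -ll

    diagnostics = ""
    outer_ok = True
    if n_factors == 0:
        sigma_hat = np.array([])
    elif n_factors == 1:
        res = optimize.minimize_scalar(
            lambda x: negll(np.array([x])),
            bounds=(np.log(_SIGMA_LO), np.log(_SIGMA_HI)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        sigma_hat = np.exp([res.x])
        outer_ok = bool(res.success)
    else:
        res = optimize.minimize(
            negll,
            x0=np.zeros(n_factors),
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 1000},
        )
        sigma_hat = np.clip(np.exp(res.x), _SIGMA_LO, _SIGMA_HI)
        outer_ok = bool(res.success)

    ll, z, H, inner_ok = _laplace_loglik(y, X, codes_list, sizes, sigma_hat, state["z"]) if n_factors else _plain_fit(y, X)
    beta = z[:p]
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)

    converged = bool(inner_ok and outer_ok)
    if np.max(np.abs(beta)) > _SEPARATION_BOUND:
        converged = False
        diagnostics = "possible complete separation: |coefficient| exceeds bound"
    elif not converged:
        diagnostics = "optimizer did not converge"

    n_params = p + n_factors
    return ModelFit(
        log_likelihood=float(ll),
        aic=-2.0 * float(ll) + 2.0 * n_params,
        n_params=n_params,
        coefficients=dict(zip(names, beta)),
        standard_errors=dict(zip(names, se)),
        variance_components={f: float(s**2) for f, s in zip(spec.random, sigma_hat)},
        converged=converged,
        n_obs=n,
        fixed_terms=tuple(names),
        random_terms=tuple(spec.random),
        diagnostics=diagnostics,
    )


def _plain_fit(y, X):
    """Ordinary logistic regression (no random factors): exact ML."""
    z, pll, H, conv = _penalized_mode(y, X, [], [], np.array([]), None)
    return pll, z, H, conv


# ----------------------------------------------------------------------
# model comparison
# ----------------------------------------------------------------------

def lrt(null: ModelFit, alt: ModelFit, focal: str | None = None) -> LRTResult:
    """Likelihood-ratio comparison of nested fits.

    chi2 = max(0, 2(LL_alt - LL_null)); the p-value is the upper
    chi-square tail at df = difference in parameter count; delta_aic =
    AIC_alt - AIC_null. The association sign is the sign of the focal
    fixed coefficient in the alternative model (inferred when exactly
    one fixed term was added).
    """
    if not (set(null.fixed_terms) <= set(alt.fixed_terms) and set(null.random_terms) <= set(alt.random_terms)):
        raise ValueError("models are not nested: null terms must be a subset of alternative terms")
    df = alt.n_params - null.n_params
    if df < 1:
        raise ValueError("alternative model must have more parameters than the null")
    chi2 = max(0.0, 2.0 * (alt.log_likelihood - null.log_likelihood))
    p = float(_chi2.sf(chi2, df))
    if focal is None:
        extra = [t for t in alt.fixed_terms if t not in null.fixed_terms]
        focal = extra[0] if len(extra) == 1 else None
    if focal is not None and focal in alt.coefficients:
        coef = alt.coefficients[focal]
        sign = "+" if coef > 0 else "-" if coef < 0 else "0"
    else:
        sign = "0"
    return LRTResult(
        chi2=chi2,
        df=df,
        p=p,
        delta_aic=alt.aic - null.aic,
        association_sign=sign,
        focal=focal,
    )


def association_scan(
    records: pd.DataFrame,
    covariate_table: pd.DataFrame,
    focal_estimators: list[str],
    baseline_covariates: tuple[str, ...] = (),
    exclude_strains: tuple[str, ...] = (),
    random_strain: bool = False,
) -> pd.DataFrame:
    """Ledger of nested LRTs, one row per focal dosage estimator.

    For each estimator the null model (block random intercept plus any
    baseline covariates, e.g. hobo coverage) is compared to the
    alternative that adds the estimator as a fixed effect. Fitting is
    complete-case per estimator: strains with a missing value are
    dropped (and counted in the ledger). ``exclude_strains`` reruns the
    scan without the named strains (outlier sensitivity); naming an
    absent strain warns but does not fail.
    """
    absent = [s for s in exclude_strains if s not in set(records["strain"])]
    if absent:
        warnings.warn(f"exclusion list names absent strains: {absent}", stacklevel=2)
    base_records = records[~records["strain"].isin(set(exclude_strains))]
    random = ("block", "strain") if random_strain else ("block",)

    rows = []
    for focal in focal_estimators:
        row = {
            "estimator": focal,
            "n_strains": 0,
            "chi2": np.nan,
            "df": np.nan,
            "p": np.nan,
            "sign": "",
            "delta_aic": np.nan,
            "converged": False,
            "note": "",
        }
        needed = [focal, *baseline_covariates]
        missing_cols = [c for c in needed if c not in covariate_table.columns]
        if missing_cols:
            row["note"] = f"estimator not in covariate table: {missing_cols}"
            rows.append(row)
            continue
        ok = covariate_table[needed].notna().all(axis=1)
        usable = set(covariate_table.index[ok])
        sub = base_records[base_records["strain"].isin(usable)]
        n_strains = sub["strain"].nunique()
        row["n_strains"] = int(n_strains)
        if n_strains < 3:
            row["note"] = "fewer than 3 strains with complete covariates"
            rows.append(row)
            continue
        vals = covariate_table.loc[sorted(set(sub["strain"])), focal]
        if float(vals.max() - vals.min()) == 0.0:
            row["note"] = "estimator constant across strains; skipped"
            rows.append(row)
            continue
        try:
            null_fit = fit_logistic_glmm(
                sub, GlmmSpec(tuple(baseline_covariates), random), covariate_table
            )
            alt_fit = fit_logistic_glmm(
                sub, GlmmSpec(tuple(baseline_covariates) + (focal,), random), covariate_table
            )
            res = lrt(null_fit, alt_fit, focal=focal)
        except (ValueError, np.linalg.LinAlgError) as exc:
            row["note"] = f"fit failed: {exc}"
            rows.append(row)
            continue
        row.update(
            chi2=res.chi2,
            df=res.df,
            p=res.p,
            sign=res.association_sign,
            delta_aic=res.delta_aic,
            converged=null_fit.converged and alt_fit.converged,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def heritability_comparison(records: pd.DataFrame) -> tuple[ModelFit, ModelFit, LRTResult]:
    """Block-only null vs paternal strain as a categorical fixed effect.

    Quantifies heritable variation in induction: the alternative model
    adds one coefficient per non-reference strain, so with S strains the
    LRT has S-1 degrees of freedom and delta_aic = -(chi2 - 2(S-1)).
    """
    null_fit = fit_logistic_glmm(records, GlmmSpec((), ("block",)))
    alt_fit = fit_logistic_glmm(records, GlmmSpec((), ("block",), strain_fixed=True))
    return null_fit, alt_fit, lrt(null_fit, alt_fit)
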