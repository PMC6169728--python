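"""Ordinal-indicator SEM: correlated-factors and general-factor models.

Models are fitted to a mixed polychoric/polyserial correlation matrix by
diagonally weighted least squares (DWLS): minimize

    F(theta) = sum_k (s_k - sigma_k(theta))^2 / w_k

over the free parameters, where s_k are the sample correlations among the
ordinal items and between items and covariates, sigma_k(theta) the
model-implied values and w_k the estimated sampling variances of s_k.
Covariate-covariate correlations are conditioned on (fixed at their sample
values), mirroring fixed-x regression.

Structure.  Each item loads on exactly one specific latent trait factor
and, in the general-factor (bifactor) variant, additionally on a general
psychopathology factor.  Every latent factor is regressed on every
covariate (PRS, sex, age, PCs).  All latent factors have total variance
fixed at 1, so loadings and regression coefficients are standardized;
disturbance correlations between specific factors are free while the
general factor's disturbance is orthogonal to them.

Inference.  Test statistics are mean-adjusted (Satorra-Bentler style):
T = n*F*df / tr(U Gamma) with U the DWLS residual weight operator and
Gamma the asymptotic covariance of the sample correlations estimated from
per-observation influence values (family-clustered when clusters are
given).  Standard errors use the corresponding sandwich
A^-1 B A^-1 with B aggregated over family clusters.  Nested models are
compared with the scaled chi-square difference test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .polycor import PolychoricMatrix

__all__ = [
    "ModelSpec",
    "FitResult",
    "NestedTestResult",
    "build_model",
    "count_free_parameters",
    "fit_dwls",
    "regress_latents",
    "sandwich_se",
    "fit_indices",
    "nested_difference_test",
]

GENERAL = "GP"


# ----------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Factor structure: item assignments, general factor, covariates."""

    factor_items: tuple[tuple[str, tuple[str, ...]], ...]
    general: bool
    covariates: tuple[str, ...]

    @property
    def specific_factors(self) -> list[str]:
        return [f for f, _ in self.factor_items]

    @property
    def factors(self) -> list[str]:
        return self.specific_factors + ([GENERAL] if self.general else [])

    @property
    def items(self) -> list[str]:
        return [it for _, its in self.factor_items for it in its]

    @property
    def factor_of(self) -> dict[str, str]:
        return {it: f for f, its in self.factor_items for it in its}

    def param_names(self) -> list[str]:
        names = [f"lambda_s[{it}]" for it in self.items]
        if self.general:
            names += [f"lambda_g[{it}]" for it in self.items]
        sf = self.specific_factors
        names += [f"psi[{a},{b}]" for i, a in enumerate(sf) for b in sf[i + 1:]]
        names += [f"beta[{f},{c}]" for f in self.factors for c in self.covariates]
        return names

    @property
    def n_free(self) -> int:
        p = len(self.items)
        m = len(self.specific_factors)
        q = len(self.covariates)
        n = p + m * (m - 1) // 2 + m * q
        if self.general:
            n += p + q
        return n

    @property
    def n_moments(self) -> int:
        p = len(self.items)
        return p * (p - 1) // 2 + p * len(self.covariates)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """True when this spec's free parameters are a strict subset."""
        mine, theirs = set(self.param_names()), set(other.param_names())
        return mine < theirs


def build_model(
    factor_items: Mapping[str, Sequence[str]],
    general: bool,
    covariates: Sequence[str] = (),
) -> ModelSpec:
    """Validate and freeze a factor structure.

    Every item must belong to exactly one specific factor; with ``general``
    every item additionally loads on the general factor.  Latent variances
    are fixed at 1; specific-specific disturbance correlations are free;
    the general factor is orthogonal to the specifics (disturbance level).
    """
    seen: dict[str, str] = {}
    for f, its in factor_items.items():
        if f == GENERAL:
            raise ValueError(f"{GENERAL!r} is reserved for the general factor")
        if len(its) < 2:
            raise ValueError(f"factor {f!r} needs >= 2 items")
        for it in its:
            if it in seen:
                raise ValueError(
                    f"item {it!r} assigned to both {seen[it]!r} and {f!r}"
                )
            seen[it] = f
    if len(factor_items) < 1:
        raise ValueError("need at least one specific factor")
    spec = ModelSpec(
        factor_items=tuple((f, tuple(its)) for f, its in factor_items.items()),
        general=general,
        covariates=tuple(covariates),
    )
    if spec.n_moments - spec.n_free < 0:
        raise ValueError(
            f"model under-identified: {spec.n_free} free parameters for "
            f"{spec.n_moments} sample moments"
        )
    return spec


def count_free_parameters(spec: ModelSpec) -> tuple[int, int]:
    """Free-parameter count and model degrees of freedom.

    Convention (fixed): fitted moments are the item-item and item-covariate
    correlations; thresholds and covariate-covariate correlations are
    margin-fixed and counted in neither moments nor parameters.
    df = moments - free parameters.
    """
    df = spec.n_moments - spec.n_free
    if df < 0:
        raise ValueError("negative df: model under-identified")
    return spec.n_free, df


# ----------------------------------------------------------------------
# parameter vector layout


class _ParamMap:
    def __init__(self, spec: ModelSpec):
        self.spec = spec
        items = spec.items
        self.p = len(items)
        self.m = len(spec.specific_factors)
        self.F = self.m + (1 if spec.general else 0)
        self.q = len(spec.covariates)
        fac_idx = {f: i for i, f in enumerate(spec.factors)}
        self.item_specific = np.array(
            [fac_idx[spec.factor_of[it]] for it in items], dtype=int
        )
        self.g_idx = fac_idx[GENERAL] if spec.general else -1

        self.n_lam_s = self.p
        self.n_lam_g = self.p if spec.general else 0
        self.psi_pairs = [
            (i, j) for i in range(self.m) for j in range(i + 1, self.m)
        ]
        self.n_psi = len(self.psi_pairs)
        self.n_gamma = self.F * self.q
        self.n_par = self.n_lam_s + self.n_lam_g + self.n_psi + self.n_gamma
        self.names = spec.param_names()

    def unpack(self, theta: np.ndarray):
        p, F, q = self.p, self.F, self.q
        lam = np.zeros((p, F))
        lam[np.arange(p), self.item_specific] = theta[:p]
        off = p
        if self.spec.general:
            lam[:, self.g_idx] = theta[off:off + p]
            off += p
        psi = np.zeros((F, F))
        for k, (i, j) in enumerate(self.psi_pairs):
            psi[i, j] = psi[j, i] = theta[off + k]
        off += self.n_psi
        gamma = theta[off:off + F * q].reshape(F, q) if q else np.zeros((F, 0))
        return lam, psi, gamma

    def start(self) -> np.ndarray:
        theta = np.zeros(self.n_par)
        theta[:self.n_lam_s] = 0.5
        off = self.n_lam_s
        if self.spec.general:
            theta[off:off + self.p] = 0.5
            off += self.p
        theta[off:off + self.n_psi] = 0.2
        return theta

    def bounds(self) -> list[tuple[float, float]]:
        b = [(-0.999, 0.999)] * (self.n_lam_s + self.n_lam_g)
        b += [(-0.99, 0.99)] * self.n_psi
        b += [(-0.999, 0.999)] * self.n_gamma
        return b


def _implied_psi(lam, psi_free, gamma, phi):
    base = gamma @ phi @ gamma.T if gamma.shape[1] else np.zeros((lam.shape[1],) * 2)
    Psi = base + psi_free
    np.fill_diagonal(Psi, 1.0)
    return Psi, base


class _Objective:
    """DWLS discrepancy with analytic Jacobian on the moment vector."""

    def __init__(self, pm: _ParamMap, s: np.ndarray, w: np.ndarray,
                 yy_ii: np.ndarray, yy_jj: np.ndarray,
                 yx_ai: np.ndarray, yx_li: np.ndarray, phi: np.ndarray):
        self.pm = pm
        self.s = s
        self.w = w
        self.yy_ii, self.yy_jj = yy_ii, yy_jj
        self.yx_ai, self.yx_li = yx_ai, yx_li
        self.phi = phi
        self.n_yy = len(yy_ii)

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        lam, psi_f, gamma = self.pm.unpack(theta)
        Psi, _ = _implied_psi(lam, psi_f, gamma, self.phi)
        syy = np.einsum("ij,jk,ik->i",
                        lam[self.yy_ii], Psi, lam[self.yy_jj], optimize=True) \
            if self.n_yy else np.empty(0)
        if len(self.yx_ai):
            gp = gamma @ self.phi  # F x q
            syx = np.einsum("ij,ij->i", lam[self.yx_ai], gp[:, self.yx_li].T)
        else:
            syx = np.empty(0)
        return np.concatenate([syy, syx])

    def sigma_jac(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pm = self.pm
        lam, psi_f, gamma = pm.unpack(theta)
        Psi, _ = _implied_psi(lam, psi_f, gamma, self.phi)
        gp = gamma @ self.phi if pm.q else np.zeros((pm.F, 0))
        K = self.n_yy + len(self.yx_ai)
        J = np.zeros((K, pm.n_par))
        ii, jj = self.yy_ii, self.yy_jj
        ai, li = self.yx_ai, self.yx_li
        PsiLam = Psi @ lam.T  # F x p

        col = 0
        # specific loadings, then general loadings
        loading_blocks = [(np.arange(pm.p), pm.item_specific)]
        if pm.spec.general:
            loading_blocks.append((np.arange(pm.p), np.full(pm.p, pm.g_idx)))
        for items_arr, facs_arr in loading_blocks:
            for i, f in zip(items_arr, facs_arr):
                d = np.zeros(K)
                d[:self.n_yy] = (ii == i) * PsiLam[f, jj] + (jj == i) * PsiLam[f, ii]
                if len(ai):
                    d[self.n_yy:] = (ai == i) * gp[f, li]
                J[:, col] = d
                col += 1
        for (f, g) in pm.psi_pairs:
            d = np.zeros(K)
            d[:self.n_yy] = lam[ii, f] * lam[jj, g] + lam[ii, g] * lam[jj, f]
            J[:, col] = d
            col += 1
        for f in range(pm.F):
            for l in range(pm.q):
                c = gp[:, l]  # (GammaPhi)[:, l]
                t = lam @ c  # p
                d = np.zeros(K)
                d[:self.n_yy] = (
                    lam[ii, f] * t[jj] + t[ii] * lam[jj, f]
                    - 2.0 * c[f] * lam[ii, f] * lam[jj, f]
                )
                if len(ai):
                    d[self.n_yy:] = lam[ai, f] * self.phi[l, li]
                J[:, col] = d
                col += 1
        return self.sigma(theta), J

    def value_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        sig, J = self.sigma_jac(theta)
        r = self.s - sig
        f = float(np.sum(r * r / self.w))
        g = -2.0 * (J.T @ (r / self.w))
        return f, g


# ----------------------------------------------------------------------
# results


@dataclass
class FitResult:
    spec: ModelSpec
    theta: np.ndarray
    param_names: list[str]
    loadings: pd.DataFrame  # item, factor, specific, general (NaN w/o general)
    psi: pd.DataFrame  # disturbance covariances between specific factors
    factor_corr: pd.DataFrame  # implied latent correlations
    betas: pd.DataFrame  # factor, covariate, beta, (se/p filled by sandwich)
    discrepancy: float
    n: int
    df: int
    chi2: float
    scaling: float
    cfi: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    converged: bool
    n_iter: int
    grad_norm: float
    heywood_items: list[str]
    baseline_chi2: float
    baseline_df: int
    # internals for inference
    _objective: _Objective = field(repr=False, default=None)
    _moments: PolychoricMatrix = field(repr=False, default=None)
    _gamma_mom: np.ndarray = field(repr=False, default=None)  # clustered Gamma
    _trUG: float = field(repr=False, default=0.0)

    def loading_table(self, domains: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Table-2-style layout usable by :mod:`genfactor.metrics`."""
        tab = self.loadings.rename(columns={"factor": "scale"}).copy()
        if not self.spec.general:
            tab["general"] = 0.0
        if domains is not None:
            tab["domain"] = tab["scale"].map(dict(domains))
        else:
            tab["domain"] = "unassigned"
        return tab[["item", "scale", "domain", "general", "specific"]]

    def beta_table(self) -> pd.DataFrame:
        return self.betas.copy()


@dataclass
class NestedTestResult:
    delta_chi2: float
    delta_df: int
    p_value: float
    restricted: str
    scaling: float
    method: str = "scaled"


# ----------------------------------------------------------------------
# fitting


def _moment_layout(spec: ModelSpec, moments: PolychoricMatrix):
    items, covs = spec.items, list(spec.covariates)
    expect = items + covs
    if moments.labels != expect:
        raise ValueError(
            "moment matrix must be built on the model's items + covariates "
            f"in order; got {moments.labels[:4]}..., expected {expect[:4]}..."
        )
    p = len(items)
    yy_ii, yy_jj, yx_ai, yx_li, order = [], [], [], [], []
    for k, (i, j) in enumerate(moments.moment_index):
        if j < p:
            yy_ii.append(i)
            yy_jj.append(j)
            order.append((0, k))
        else:
            yx_ai.append(i)
            yx_li.append(j - p)
            order.append((1, k))
    perm = [k for flag, k in sorted(order, key=lambda t: (t[0], t[1]))]
    return (np.array(yy_ii, dtype=int), np.array(yy_jj, dtype=int),
            np.array(yx_ai, dtype=int), np.array(yx_li, dtype=int),
            np.array(perm, dtype=int))


def _phi_block(spec: ModelSpec, moments: PolychoricMatrix) -> np.ndarray:
    p = len(spec.items)
    q = len(spec.covariates)
    phi = moments.matrix[p:p + q, p:p + q].copy()
    if q > 1:
        off = phi[~np.eye(q, dtype=bool)]
        if np.any(np.abs(off) > 0.999):
            raise ValueError("collinear covariates (|r| > 0.999) in moment matrix")
    return phi


def _cluster_gamma(influence: np.ndarray, clusters: np.ndarray | None) -> np.ndarray:
    """Asymptotic covariance of sqrt(n)*(s - sigma) from influence values."""
    n = influence.shape[0]
    if clusters is None:
        return influence.T @ influence / n
    df_ = pd.DataFrame(influence)
    df_["__c"] = np.asarray(clusters)
    sums = df_.groupby("__c", sort=False).sum().to_numpy()
    return sums.T @ sums / n


def _scaled_stat(F_val: float, n: int, df: int, U: np.ndarray,
                 gamma_mom: np.ndarray) -> tuple[float, float]:
    """Mean-adjusted test statistic and its scaling correction."""
    trUG = float(np.sum(U * gamma_mom.T))
    if df <= 0 or trUG <= 0:
        return 0.0, np.nan
    c = trUG / df
    return n * F_val / c, c


def fit_dwls(
    spec: ModelSpec,
    moments: PolychoricMatrix,
    clusters: Sequence | None = None,
    fixed: Mapping[str, float] | None = None,
    max_iter: int = 2000,
    gtol: float = 1e-6,
    ftol: float = 1e-12,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Fit a model by diagonally weighted least squares.

    ``clusters`` (one label per observation behind ``moments``) switches the
    robust statistic and the stored moment covariance to family-clustered
    form.  ``fixed`` pins named parameters (e.g. all general loadings to 0)
    for nesting experiments.
    """
    pm = _ParamMap(spec)
    yy_ii, yy_jj, yx_ai, yx_li, perm = _moment_layout(spec, moments)
    s = moments.moment_values[perm]
    w = np.maximum(moments.moment_var[perm], 1e-12)
    phi = _phi_block(spec, moments)
    obj = _Objective(pm, s, w, yy_ii, yy_jj, yx_ai, yx_li, phi)

    theta0 = pm.start() if theta0 is None else np.asarray(theta0, dtype=float).copy()
    bounds = pm.bounds()
    free_mask = np.ones(pm.n_par, dtype=bool)
    if fixed:
        name_idx = {nm: i for i, nm in enumerate(pm.names)}
        for nm, val in fixed.items():
            if nm not in name_idx:
                raise KeyError(f"unknown parameter {nm!r}")
            i = name_idx[nm]
            theta0[i] = val
            bounds[i] = (val, val)
            free_mask[i] = False

    res = optimize.minimize(
        obj.value_grad, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "gtol": gtol, "ftol": ftol},
    )
    theta = res.x.copy()
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm < 1e-4
    if not converged:
        warnings.warn(
            f"DWLS fit did not converge after {res.nit} iterations "
            f"(grad norm {grad_norm:.2e}); results are the best point found",
            RuntimeWarning,
        )

    theta = _fix_signs(pm, theta, fixed)
    lam, psi_f, gamma = pm.unpack(theta)
    Psi, _ = _implied_psi(lam, psi_f, gamma, phi)

    # Heywood screen: implied item uniqueness must be non-negative
    communal = np.einsum("if,fg,ig->i", lam, Psi, lam)
    heywood = [spec.items[i] for i in np.nonzero(communal > 1.0 + 1e-8)[0]]
    if heywood:
        warnings.warn(f"communality > 1 (Heywood-adjacent) for items: {heywood}",
                      RuntimeWarning)

    F_val = obj.value_grad(theta)[0]
    _, df = count_free_parameters(spec)
    n = moments.n

    # robust (mean-adjusted) chi-square; fixed parameters are not free
    # directions, so they are excluded from the residual operator
    sig, J_full = obj.sigma_jac(theta)
    J = J_full[:, free_mask]
    Wd = 1.0 / w
    if moments.influence.shape[1]:
        infl = moments.influence[:, perm]
        gamma_mom = _cluster_gamma(infl, None if clusters is None else clusters)
    else:
        gamma_mom = np.diag(w)  # synthetic moments: nominal weights
    A = J.T @ (J * Wd[:, None])
    A_inv = np.linalg.pinv(A)
    WJ = J * Wd[:, None]
    U = np.diag(Wd) - WJ @ A_inv @ WJ.T
    df_eff = df + int((~free_mask).sum())
    chi2, scaling = _scaled_stat(F_val, n, df_eff, U, gamma_mom)
    df = df_eff

    # baseline (independence) model: every fitted moment zero
    F_base = float(np.sum(s * s / w))
    df_base = len(s)
    chi2_base, _ = _scaled_stat(F_base, n, df_base, np.diag(Wd), gamma_mom)

    cfi = _cfi(chi2, df, chi2_base, df_base)
    rmsea, rmsea_ci = _rmsea(chi2, df, n)

    loadings = pd.DataFrame(
        {
            "item": spec.items,
            "factor": [spec.factor_of[it] for it in spec.items],
            "specific": lam[np.arange(pm.p), pm.item_specific],
            "general": lam[:, pm.g_idx] if spec.general else np.nan,
        }
    )
    sf = spec.specific_factors
    psi_df = pd.DataFrame(psi_f[:pm.m, :pm.m], index=sf, columns=sf)
    corr_df = pd.DataFrame(Psi, index=spec.factors, columns=spec.factors)
    beta_rows = []
    for fi, f in enumerate(spec.factors):
        for ci, c in enumerate(spec.covariates):
            beta_rows.append({"factor": f, "covariate": c,
                              "beta": float(gamma[fi, ci])})
    betas = pd.DataFrame(beta_rows, columns=["factor", "covariate", "beta"])

    fit = FitResult(
        spec=spec, theta=theta, param_names=pm.names,
        loadings=loadings, psi=psi_df, factor_corr=corr_df, betas=betas,
        discrepancy=F_val, n=n, df=df, chi2=chi2, scaling=scaling,
        cfi=cfi, rmsea=rmsea, rmsea_ci=rmsea_ci,
        converged=converged, n_iter=int(res.nit), grad_norm=grad_norm,
        heywood_items=heywood, baseline_chi2=chi2_base, baseline_df=df_base,
        _objective=obj, _moments=moments, _gamma_mom=gamma_mom, _trUG=scaling * df,
    )
    if moments.influence.shape[1]:
        ses = sandwich_se(fit, clusters)
        fit.betas = _attach_se(fit, ses)
    return fit


def _fix_signs(pm: _ParamMap, theta: np.ndarray,
               fixed: Mapping[str, float] | None) -> np.ndarray:
    """Resolve sign indeterminacy: first loading of each factor positive."""
    fixed_names = set(fixed or ())
    lam, psi_f, gamma = pm.unpack(theta)
    flips = np.ones(pm.F)
    for fi in range(pm.F):
        if fi == pm.g_idx:
            first = 0
            val = lam[first, fi]
            name = f"lambda_g[{pm.spec.items[first]}]"
        else:
            rows = np.nonzero(pm.item_specific == fi)[0]
            first = rows[0]
            val = lam[first, fi]
            name = f"lambda_s[{pm.spec.items[first]}]"
        if val < 0 and name not in fixed_names:
            flips[fi] = -1.0
    lam = lam * flips[None, :]
    psi_f = psi_f * np.outer(flips, flips)
    np.fill_diagonal(psi_f, 0.0)
    gamma = gamma * flips[:, None]
    out = np.empty_like(theta)
    out[:pm.p] = lam[np.arange(pm.p), pm.item_specific]
    off = pm.p
    if pm.spec.general:
        out[off:off + pm.p] = lam[:, pm.g_idx]
        off += pm.p
    for k, (i, j) in enumerate(pm.psi_pairs):
        out[off + k] = psi_f[i, j]
    off += pm.n_psi
    if pm.q:
        out[off:] = gamma.reshape(-1)
    return out


def _cfi(chi2: float, df: int, chi2_b: float, df_b: int) -> float:
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    if den == 0.0:
        return 1.0
    return float(np.clip(1.0 - num / den, 0.0, 1.0))


def _rmsea(chi2: float, df: int, n: int,
           level: float = 0.90) -> tuple[float, tuple[float, float]]:
    if df <= 0:
        return np.nan, (np.nan, np.nan)
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * n)))
    alpha = (1.0 - level) / 2.0

    def bound(prob: float) -> float:
        # noncentrality lambda with ncx2.cdf(chi2; df, lam) == prob
        f = lambda lam: stats.ncx2.cdf(chi2, df, lam) - prob
        if f(0.0) < 0.0:
            return 0.0
        hi = max(chi2, 1.0)
        while f(hi) > 0.0:
            hi *= 2.0
            if hi > 1e8:
                return np.nan
        return float(optimize.brentq(f, 0.0, hi, xtol=1e-10))

    lo_nc = bound(1.0 - alpha)
    hi_nc = bound(alpha)
    ci = (float(np.sqrt(max(lo_nc, 0.0) / (df * n))),
          float(np.sqrt(max(hi_nc, 0.0) / (df * n))))
    return rmsea, ci


def fit_indices(fit: FitResult) -> dict:
    """CFI, RMSEA with 90% CI and the scaled chi-square of a fit."""
    return {
        "chi2": fit.chi2,
        "df": fit.df,
        "scaling": fit.scaling,
        "cfi": fit.cfi,
        "rmsea": fit.rmsea,
        "rmsea_ci90": fit.rmsea_ci,
        "baseline_chi2": fit.baseline_chi2,
        "baseline_df": fit.baseline_df,
    }


def sandwich_se(fit: FitResult, clusters: Sequence | None = None) -> pd.Series:
    """Cluster-robust (sandwich) standard errors of all free parameters.

    SE = sqrt(diag(A^-1 B A^-1)) / n with A = J' W J (the bread) and B the
    outer product of per-cluster aggregated moment scores.  With
    ``clusters=None`` every observation is its own cluster, which
    reproduces the naive (independence) sandwich.
    """
    obj = fit._objective
    moments = fit._moments
    if moments is None or moments.influence.shape[1] == 0:
        raise ValueError("fit has no influence information (synthetic moments)")
    if clusters is not None:
        clusters = np.asarray(clusters)
        if len(clusters) != moments.influence.shape[0]:
            raise ValueError("cluster labels must align with the observations")
        if len(np.unique(clusters)) == moments.influence.shape[0]:
            clusters = None  # singleton clusters = naive
    _, J = obj.sigma_jac(fit.theta)
    Wd = 1.0 / obj.w
    A = J.T @ (J * Wd[:, None])
    A_inv = np.linalg.pinv(A)
    perm = _moment_layout(fit.spec, moments)[4]
    infl = moments.influence[:, perm]
    scores = infl @ (J * Wd[:, None])  # n x n_par
    if clusters is not None:
        df_ = pd.DataFrame(scores)
        df_["__c"] = clusters
        scores = df_.groupby("__c", sort=False).sum().to_numpy()
    B = scores.T @ scores
    cov = A_inv @ B @ A_inv / (moments.n ** 2)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return pd.Series(se, index=fit.param_names)


def _attach_se(fit: FitResult, ses: pd.Series) -> pd.DataFrame:
    betas = fit.betas.copy()
    se_vals, p_vals, r2 = [], [], []
    for _, row in betas.iterrows():
        se = float(ses[f"beta[{row['factor']},{row['covariate']}]"])
        z = row["beta"] / se if se > 0 else np.nan
        se_vals.append(se)
        p_vals.append(2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan)
        r2.append(row["beta"] ** 2)
    betas["se"] = se_vals
    betas["p"] = p_vals
    betas["r2"] = r2
    return betas


def regress_latents(
    spec: ModelSpec, moments: PolychoricMatrix, clusters: Sequence | None = None
) -> pd.DataFrame:
    """Standardized regressions of every latent factor on every covariate.

    The paths are free parameters of the same DWLS fit (not a two-stage
    factor-score regression); returns the beta table with sandwich SEs,
    p-values and R^2 = beta^2.
    """
    if not spec.covariates:
        raise ValueError("model has no covariates to regress on")
    return fit_dwls(spec, moments, clusters=clusters).betas


def nested_difference_test(
    restricted: FitResult,
    full: FitResult,
    method: str = "scaled",
    n_boot: int = 199,
    seed: int = 0,
) -> NestedTestResult:
    """Difference test for nested DWLS fits.

    ``method="scaled"`` is the Satorra-Bentler style scaled statistic:
    cd = (tr(U_r G) - tr(U_f G)) / (df_r - df_f) and
    T_d = (n F_r - n F_f) / cd, referred to chi-square with df_r - df_f
    degrees of freedom.  It is well calibrated when the restriction is an
    interior point of the larger model; when the restriction removes a
    whole factor (all its loadings zero), the chi-square reference is
    anti-conservative because the removed factor's parameters are not
    identified under the null.

    ``method="boundary_boot"`` replaces the chi-square reference with a
    parametric simulation at the moment level: sample correlation vectors
    are drawn from N(sigma_r(theta_hat), Gamma_hat/n) under the restricted
    model, both models are refitted and the observed fit gain is compared
    with the simulated null gains.  With (n_boot+1)*alpha an integer, the
    Monte-Carlo test has exact size alpha under its null.  Costlier, but
    calibrated at the zero-factor boundary.
    """
    if not restricted.spec.is_nested_in(full.spec):
        raise ValueError("models are not properly nested (or are identical)")
    ddf = restricted.df - full.df
    if ddf <= 0:
        raise ValueError("restricted model must have more degrees of freedom")
    if restricted.n != full.n:
        raise ValueError("fits are based on different sample sizes")
    n = restricted.n
    gain = n * restricted.discrepancy - n * full.discrepancy
    cd = (restricted._trUG - full._trUG) / ddf
    if cd <= 0:
        warnings.warn("non-positive scaled-difference correction; falling back "
                      "to unscaled difference", RuntimeWarning)
        cd = 1.0
    t_d = max(gain / cd, 0.0)
    label = "correlated_factors" if not restricted.spec.general else "restricted"
    if method == "scaled":
        p = float(stats.chi2.sf(t_d, ddf))
        return NestedTestResult(delta_chi2=float(t_d), delta_df=int(ddf),
                                p_value=p, restricted=label, scaling=float(cd))
    if method != "boundary_boot":
        raise ValueError(f"unknown method {method!r}")

    p = _boundary_boot_p(restricted, full, n_boot, seed)
    return NestedTestResult(delta_chi2=float(t_d), delta_df=int(ddf), p_value=p,
                            restricted=label, scaling=float(cd),
                            method="boundary_boot")


def _boundary_boot_p(restricted: FitResult, full: FitResult,
                     n_boot: int, seed: int) -> float:
    """Moment-level parametric bootstrap reference for the fit gain.

    The observed gain is recomputed with the same warm-started refit
    protocol used for the simulated draws, so observed and simulated gains
    are exchangeable under the null.
    """
    moments = restricted._moments
    obj_r = restricted._objective
    n = restricted.n
    sigma_hat = obj_r.sigma(restricted.theta)  # permuted order
    gamma_mom = restricted._gamma_mom
    # factor of Gamma/n (eigen clip for safety)
    vals, vecs = np.linalg.eigh(gamma_mom / n)
    L = vecs * np.sqrt(np.maximum(vals, 0.0))[None, :]
    perm = _moment_layout(restricted.spec, moments)[4]
    inv_perm = np.empty_like(perm)
    inv_perm[perm] = np.arange(len(perm))
    rng = np.random.default_rng(seed)
    theta_f0 = _embed_restricted(restricted, full)

    def refit_gain(mat: np.ndarray) -> float:
        boot_mom = PolychoricMatrix(
            labels=moments.labels, matrix=mat, cell_types={}, thresholds={},
            moment_index=moments.moment_index, moment_var=moments.moment_var,
            influence=np.empty((n, 0)), n=n,
        )
        # capped, warm-started refits: the gain statistic only has to be
        # computed by the same deterministic protocol for the observed and
        # simulated draws, so a fixed iteration budget is valid (and fast)
        fit_r = fit_dwls(restricted.spec, boot_mom, theta0=restricted.theta,
                         max_iter=60, gtol=1e-5, ftol=1e-10)
        fit_f = fit_dwls(full.spec, boot_mom, theta0=theta_f0,
                         max_iter=60, gtol=1e-5, ftol=1e-10)
        return n * fit_r.discrepancy - n * fit_f.discrepancy

    gain_obs = refit_gain(moments.matrix.copy())
    exceed = 0
    for _ in range(n_boot):
        s_star = sigma_hat + L @ rng.standard_normal(L.shape[1])
        mat = moments.matrix.copy()
        s_orig = s_star[inv_perm]
        for k, (i, j) in enumerate(moments.moment_index):
            mat[i, j] = mat[j, i] = s_orig[k]
        if refit_gain(mat) >= gain_obs:
            exceed += 1
    return (1.0 + exceed) / (n_boot + 1.0)


def _embed_restricted(restricted: FitResult, full: FitResult) -> np.ndarray:
    """Map the restricted solution into the full parameter vector."""
    pm_f = _ParamMap(full.spec)
    theta0 = pm_f.start()
    theta0[pm_f.n_lam_s:pm_f.n_lam_s + pm_f.n_lam_g] = 0.1  # small general start
    idx_f = {nm: i for i, nm in enumerate(full.param_names)}
    for nm, val in zip(restricted.param_names, restricted.theta):
        if nm in idx_f:
            theta0[idx_f[nm]] = val
    return theta0
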