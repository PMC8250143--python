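"""REML fitting of linear mixed models with user-defined covariance structure.

The model is

    y = X beta + sum_j Z_j u_j + e,   u_j ~ N(0, sigma_j^2 K_j),  e ~ N(0, sigma_e^2 I)

with the K_j supplied by the user (pedigree A, genomic G, kernels, Kronecker
products).  Each correlated effect is absorbed into the design through a
factor L_j with L_j L_j' = K_j, giving Z_j* = Z_j L_j and iid transformed
effects u_j* ~ N(0, sigma_j^2 I); Z_j* u_j* has the same distribution as
Z_j u_j.  Variance components are estimated by maximizing the profiled
restricted log-likelihood over the variance ratios lambda_j = sigma_j^2 /
sigma_e^2: with H = I + sum_j lambda_j Z_j* Z_j*',

    beta_hat    = (X' H^-1 X)^-1 X' H^-1 y
    sigma_e^2   = r' H^-1 r / (n - p),          r = y - X beta_hat
    l_R         = -1/2 [ (n-p)(1 + log(2 pi sigma_e^2)) + log|H| + log|X' H^-1 X| ]

BLUPs on the transformed scale are u_j*^ = lambda_j Z_j*' H^-1 r / 1, i.e.
sigma_j^2 Z_j*' V*^-1 (y - X beta_hat) with V* = sigma_e^2 H, and are mapped
back with u_j^ = L_j u_j*^.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .relmat import CovFactor, RelationshipMatrix, factorize

__all__ = [
    "FixedSpec",
    "RandomTermSpec",
    "DesignBundle",
    "FittedLMM",
    "build_design",
    "reml_criterion",
    "fit_lmm",
    "blups",
    "summarize",
    "heritability",
    "UserCovLMM",
]

LOG_LAMBDA_BOUND = np.log(1e10)  # lambda in [1e-10, 1e10]


@dataclass
class FixedSpec:
    """Fixed-effect specification: intercept plus named covariates.

    ``terms`` is a list of (column_name, role) with role "categorical" or
    "numeric".  Categorical covariates use reference-level dummy coding with
    the lexicographically first level as reference.
    """

    intercept: bool = True
    terms: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class RandomTermSpec:
    """A named grouping factor paired with its covariance matrix."""

    name: str
    factor: str
    covariance: RelationshipMatrix
    method: str = "auto"


@dataclass
class DesignBundle:
    """Assembled design: X, per-term incidence Z_j, transformed Z_j* = Z_j L_j."""

    X: np.ndarray
    x_labels: list[str]
    Z: list[np.ndarray]
    Z_star: list[np.ndarray]
    ZZt: list[np.ndarray]  # precomputed Z_j* Z_j*' (n x n), reused per criterion call
    factors: list[CovFactor]
    K_sub: list[RelationshipMatrix]
    term_names: list[str]
    term_factors: list[str]
    levels: list[list[str]]
    fixed_categories: dict[str, list[str]]
    n: int
    p: int
    q: int


@dataclass
class FittedLMM:
    """REML fit artifact."""

    beta: pd.Series
    sigma2: dict[str, float]  # per-term variances plus "residual"
    reml_loglik: float
    u_star: dict[str, pd.Series]
    u: dict[str, pd.Series]
    converged: bool
    trace: list[dict]
    design: DesignBundle | None
    fixed: FixedSpec
    random: list[RandomTermSpec] | None
    response: str
    n_dropped: int = 0
    lambdas: dict[str, float] = field(default_factory=dict)
    K_fitted: dict[str, RelationshipMatrix] = field(default_factory=dict)
    term_factors: dict[str, str] = field(default_factory=dict)
    fixed_categories: dict[str, list[str]] = field(default_factory=dict)

    @property
    def term_names(self) -> list[str]:
        return [k for k in self.sigma2 if k != "residual"]


def _build_X(
    data: pd.DataFrame, fixed: FixedSpec, categories: dict[str, list[str]] | None = None
) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Fixed design matrix with reference-level dummy coding.

    When ``categories`` is given (prediction on new data) the training level
    sets are reused; an unseen level is an error.
    """
    cols: list[np.ndarray] = []
    labels: list[str] = []
    cats_out: dict[str, list[str]] = {}
    n = len(data)
    if fixed.intercept:
        cols.append(np.ones(n))
        labels.append("(Intercept)")
    for name, role in fixed.terms:
        if name not in data.columns:
            raise ValueError(f"fixed covariate column {name!r} not found in data")
        if role == "numeric":
            v = pd.to_numeric(data[name], errors="raise").to_numpy(dtype=float)
            cols.append(v)
            labels.append(name)
        elif role == "categorical":
            vals = data[name].astype(str)
            if categories is not None and name in categories:
                levels = categories[name]
                unseen = sorted(set(vals) - set(levels))
                if unseen:
                    raise ValueError(
                        f"unseen level(s) {unseen} for fixed factor {name!r}"
                    )
            else:
                levels = sorted(vals.unique())
            cats_out[name] = list(levels)
            for lev in levels[1:]:  # first (lexicographic) level is the reference
                cols.append((vals == lev).to_numpy(dtype=float))
                labels.append(f"{name}[{lev}]")
        else:
            raise ValueError(f"unknown fixed-term role {role!r}")
    if not cols:
        raise ValueError("empty fixed-effect design (no intercept, no terms)")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify aliased columns by greedy QR-style scan
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(labels[j])
        raise ValueError(f"fixed design is rank-deficient; aliased columns: {aliased}")
    return X, labels, cats_out


def build_design(
    data: pd.DataFrame, fixed: FixedSpec, random: list[RandomTermSpec]
) -> DesignBundle:
    """Assemble X, Z_j, and transformed Z_j* for the rows of ``data``.

    Each covariance matrix is subset and reordered to the factor levels that
    actually occur (fitting uses only observed levels); repeated records of a
    genotype share a Z column, so replicated designs are supported.
    """
    if not random:
        raise ValueError("at least one random term is required")
    names = [t.name for t in random]
    if len(set(names)) != len(names):
        raise ValueError("random term names must be unique")
    X, x_labels, cats = _build_X(data, fixed)
    n = len(data)
    Zs, Zstars, ZZts, factors, K_subs, levels_all, term_factors = [], [], [], [], [], [], []
    for term in random:
        if term.factor not in data.columns:
            raise ValueError(f"factor column {term.factor!r} not found in data")
        obs = data[term.factor].astype(str).to_numpy()
        # order levels by their order in the covariance labels for determinism
        present = set(obs)
        levels = [lab for lab in term.covariance.labels if lab in present]
        missing = sorted(present - set(levels))
        if missing:
            raise KeyError(
                f"term {term.name!r}: {len(missing)} level(s) missing from "
                f"covariance labels: {missing[:10]}"
            )
        K_sub = term.covariance.subset(levels)
        fac = factorize(K_sub, term.method)
        pos = {lab: j for j, lab in enumerate(levels)}
        Z = np.zeros((n, len(levels)))
        Z[np.arange(n), [pos[g] for g in obs]] = 1.0
        Zstar = Z @ fac.factor
        Zs.append(Z)
        Zstars.append(Zstar)
        ZZts.append(Zstar @ Zstar.T)
        factors.append(fac)
        K_subs.append(K_sub)
        levels_all.append(levels)
        term_factors.append(term.factor)
    return DesignBundle(
        X=X,
        x_labels=x_labels,
        Z=Zs,
        Z_star=Zstars,
        ZZt=ZZts,
        factors=factors,
        K_sub=K_subs,
        term_names=names,
        term_factors=term_factors,
        levels=levels_all,
        fixed_categories=cats,
        n=n,
        p=X.shape[1],
        q=len(random),
    )


def reml_criterion(
    log_lambdas: np.ndarray,
    design: DesignBundle,
    y: np.ndarray,
    restricted: bool = True,
) -> tuple[float, np.ndarray, float]:
    """Profiled (restricted) log-likelihood at variance ratios exp(log_lambdas).

    Returns (loglik, profiled beta_hat, profiled sigma_e^2).  With
    ``restricted=False`` the ordinary profiled log-likelihood is returned
    (divisor n, no log|X'H^-1 X| term) — an internal testing toggle.
    """
    lam = np.exp(np.asarray(log_lambdas, dtype=float))
    if lam.shape != (design.q,):
        raise ValueError(f"expected {design.q} log-ratios, got {lam.shape}")
    n, p, X = design.n, design.p, design.X
    H = np.eye(n)
    for lj, M in zip(lam, design.ZZt):
        H += lj * M
    try:
        c, low = sla.cho_factor(H, lower=True, check_finite=False)
    except sla.LinAlgError as exc:  # pragma: no cover - H is PD by construction
        raise np.linalg.LinAlgError("H numerically singular") from exc
    Hi_y = sla.cho_solve((c, low), y, check_finite=False)
    Hi_X = sla.cho_solve((c, low), X, check_finite=False)
    XtHiX = X.T @ Hi_X
    beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
    r = y - X @ beta
    Hi_r = sla.cho_solve((c, low), r, check_finite=False)
    dof = n - p if restricted else n
    sigma_e2 = float(r @ Hi_r) / dof
    sigma_e2 = max(sigma_e2, 1e-300)
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(c))))
    ll = -0.5 * (dof * (1.0 + np.log(2.0 * np.pi * sigma_e2)) + logdet_H)
    if restricted:
        sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X' H^-1 X not positive definite")
        ll -= 0.5 * logdet_XtHiX
    return float(ll), beta, sigma_e2


def _compute_blups(
    design: DesignBundle, y: np.ndarray, lam: np.ndarray, beta: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Joint BLUPs: u_j*^ = lambda_j Z_j*' H^-1 (y - X beta^); u_j^ = L_j u_j*^."""
    n = design.n
    H = np.eye(n)
    for lj, M in zip(lam, design.ZZt):
        H += lj * M
    c, low = sla.cho_factor(H, lower=True, check_finite=False)
    r = y - design.X @ beta
    Hi_r = sla.cho_solve((c, low), r, check_finite=False)
    u_star = [lj * (Zs.T @ Hi_r) for lj, Zs in zip(lam, design.Z_star)]
    u = [fac.factor @ us for fac, us in zip(design.factors, u_star)]
    return u_star, u


class ConvergenceWarning(UserWarning):
    pass


def _optimize_reml(
    design: DesignBundle, y: np.ndarray, restricted: bool = True
) -> tuple[np.ndarray, float, bool, list[dict]]:
    """Nelder-Mead over log variance-ratio coordinates with restart policy.

    Starts at log lambda = 0; on non-convergence restarts from all -2 and
    all +2.  If restarts disagree by more than 1e-6 in the criterion the
    larger optimum wins; every start is recorded in the trace.
    """
    q = design.q

    def neg(ll_pars):
        x = np.clip(ll_pars, -LOG_LAMBDA_BOUND, LOG_LAMBDA_BOUND)
        return -reml_criterion(x, design, y, restricted)[0]

    starts = [np.zeros(q)]
    results = []
    trace: list[dict] = []
    for attempt, x0 in enumerate(starts):
        res = minimize(
            neg,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": 1e-8,
                "fatol": 1e-10,
                "maxiter": 2000 * q,
                "maxfev": 4000 * q,
            },
        )
        x = np.clip(res.x, -LOG_LAMBDA_BOUND, LOG_LAMBDA_BOUND)
        results.append((float(-res.fun), x, bool(res.success)))
        trace.append(
            {
                "start": x0.tolist(),
                "loglik": float(-res.fun),
                "log_lambda": x.tolist(),
                "converged": bool(res.success),
                "nfev": int(res.nfev),
            }
        )
        if not res.success and attempt == 0:
            starts.extend([np.full(q, -2.0), np.full(q, 2.0)])
    best_ll, best_x, best_ok = max(results, key=lambda t: t[0])
    at_bound = np.abs(best_x) >= LOG_LAMBDA_BOUND - 1e-9
    if at_bound.any():
        trace.append({"boundary_terms": np.where(at_bound)[0].tolist()})
    return best_x, best_ll, best_ok, trace


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed: FixedSpec | None = None,
    random: list[RandomTermSpec] | None = None,
    restricted: bool = True,
) -> FittedLMM:
    """Fit the multi-term mixed model by REML and extract BLUPs.

    Rows with a missing response are dropped (with a warning giving the
    count).  Variance components are recovered from the profiled ratios as
    sigma_j^2 = lambda_j^ sigma_e^2; BLUPs are mapped to the original scale
    through the covariance factor of each term.
    """
    if fixed is None:
        fixed = FixedSpec()
    if not random:
        raise ValueError("at least one random term is required")
    if response not in data.columns:
        raise ValueError(f"response column {response!r} not found in data")
    yv = pd.to_numeric(data[response], errors="coerce")
    keep = yv.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} record(s) with missing response", stacklevel=2)
    sub = data.loc[keep].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError("no fittable records (all responses missing)")
    y = yv[keep].to_numpy(dtype=float)
    design = build_design(sub, fixed, random)
    if design.n <= design.p:
        raise ValueError("need more observations than fixed-effect parameters")
    if len(np.unique(y)) < design.q + 2:
        raise ValueError("response has too few distinct values to estimate variances")
    best_x, best_ll, ok, trace = _optimize_reml(design, y, restricted)
    ll, beta, sigma_e2 = reml_criterion(best_x, design, y, restricted)
    if not ok:
        warnings.warn(
            "REML optimizer did not report convergence; returning best point",
            ConvergenceWarning,
            stacklevel=2,
        )
    lam = np.exp(best_x)
    u_star, u = _compute_blups(design, y, lam, beta)
    sigma2 = {name: float(lj * sigma_e2) for name, lj in zip(design.term_names, lam)}
    sigma2["residual"] = float(sigma_e2)
    u_star_s = {
        name: pd.Series(us, index=pd.Index(levels, name="level"))
        for name, us, levels in zip(design.term_names, u_star, design.levels)
    }
    u_s = {
        name: pd.Series(uu, index=pd.Index(levels, name="level"))
        for name, uu, levels in zip(design.term_names, u, design.levels)
    }
    return FittedLMM(
        beta=pd.Series(beta, index=design.x_labels),
        sigma2=sigma2,
        reml_loglik=float(ll),
        u_star=u_star_s,
        u=u_s,
        converged=ok,
        trace=trace,
        design=design,
        fixed=fixed,
        random=list(random),
        response=response,
        n_dropped=n_dropped,
        lambdas={name: float(lj) for name, lj in zip(design.term_names, lam)},
        K_fitted=dict(zip(design.term_names, design.K_sub)),
        term_factors=dict(zip(design.term_names, design.term_factors)),
        fixed_categories=design.fixed_categories,
    )


def blups(model: FittedLMM) -> dict[str, pd.Series]:
    """Original-scale conditional means of the random effects, keyed by term."""
    return {k: v.copy() for k, v in model.u.items()}


def fitted_values(model: FittedLMM) -> np.ndarray:
    """In-sample fitted values X beta^ + sum_j Z_j u_j^."""
    if model.design is None:
        raise ValueError("fit artifact has no design matrices (loaded from disk?)")
    d = model.design
    yhat = d.X @ model.beta.to_numpy()
    for Z, name in zip(d.Z, d.term_names):
        yhat = yhat + Z @ model.u[name].to_numpy()
    return yhat


def heritability(model: FittedLMM, terms: list[str] | None = None) -> float:
    """h^2 = sum(sigma_j^2 over chosen terms) / (same + sigma_e^2)."""
    if terms is None:
        terms = model.term_names
    num = sum(model.sigma2[t] for t in terms)
    denom = num + model.sigma2["residual"]
    return 1.0 if denom == 0 else num / denom


def summarize(model: FittedLMM) -> str:
    """Human-readable fit report."""
    lines = ["Linear mixed model fit by REML (user covariance)"]
    lines.append(f"  restricted log-likelihood: {model.reml_loglik:.4f}")
    lines.append(f"  converged: {model.converged}")
    if model.n_dropped:
        lines.append(f"  records dropped (missing response): {model.n_dropped}")
    lines.append("  variance components:")
    for name, val in model.sigma2.items():
        lines.append(f"    {name:>12s}  {val:.6f}")
    lines.append("  fixed effects:")
    for name, val in model.beta.items():
        lines.append(f"    {name:>12s}  {val:.6f}")
    h2 = heritability(model)
    lines.append(f"  heritability (all terms): {h2:.4f}")
    return "\n".join(lines)


class UserCovLMM(BaseEstimator):
    """Mixed-model estimator with user-defined random-effect covariances.

    scikit-learn-style interface: construct with the model specification,
    ``fit`` on a phenotype table (a DataFrame containing the response, the
    grouping-factor columns named by the random terms, and any fixed
    covariates), then read fitted attributes or ``predict`` new genotypes.

    Parameters
    ----------
    response : str
        Name of the response column.
    fixed : FixedSpec or None
        Fixed-effect specification; default intercept-only.
    random_terms : list of RandomTermSpec
        The random terms; each names a factor column and carries its
        covariance matrix.
    restricted : bool
        REML (True, default) or ML profiling.

    Attributes
    ----------
    beta_ : pandas.Series          fixed-effect estimates
    sigma2_ : dict                 variance components, including "residual"
    reml_loglik_ : float           restricted log-likelihood at the optimum
    u_ : dict of pandas.Series     original-scale BLUPs per term
    u_star_ : dict of pandas.Series  transformed-scale BLUPs per term
    converged_ : bool
    result_ : FittedLMM            the full fit artifact
    """

    def __init__(self, response="y", fixed=None, random_terms=None, restricted=True):
        self.response = response
        self.fixed = fixed
        self.random_terms = random_terms
        self.restricted = restricted

    def fit(self, data: pd.DataFrame, y=None):
        if self.random_terms is None:
            raise ValueError("random_terms must be provided")
        res = fit_lmm(
            data,
            response=self.response,
            fixed=self.fixed,
            random=self.random_terms,
            restricted=self.restricted,
        )
        self.result_ = res
        self.beta_ = res.beta
        self.sigma2_ = res.sigma2
        self.reml_loglik_ = res.reml_loglik
        self.u_ = res.u
        self.u_star_ = res.u_star
        self.converged_ = res.converged
        self.n_features_in_ = data.shape[1]
        return self

    def predict(self, data: pd.DataFrame | None = None, full_covariances=None):
        """In-sample fitted values, or predictions for new genotype levels.

        With no arguments returns the fitted values for the training rows.
        With ``data`` (a table of factor/covariate columns for the records to
        predict) and ``full_covariances`` (term name -> RelationshipMatrix
        covering fitted and new levels) returns predicted responses via the
        conditional-mean extension of the fitted BLUPs.
        """
        self._check_fitted()
        if data is None:
            return fitted_values(self.result_)
        from .predictnew import predict_phenotypes

        if full_covariances is None:
            full_covariances = {t.name: t.covariance for t in self.random_terms}
        return predict_phenotypes(self.result_, full_covariances, data)

    def predict_new_levels(self, full_covariances):
        """Per-term BLUPs for every level of the supplied covariances."""
        self._check_fitted()
        from .predictnew import predict_new_levels

        return predict_new_levels(self.result_, full_covariances)

    def score(self, data: pd.DataFrame, y=None):
        """Pearson correlation between observed responses and predictions."""
        self._check_fitted()
        from .evalcv import accuracy_metrics

        obs = pd.to_numeric(data[self.response], errors="coerce").to_numpy(float)
        pred = self.predict(data)
        if isinstance(pred, pd.Series):
            pred = pred.to_numpy()
        r, _ = accuracy_metrics(obs, pred)
        return r

    def summary(self) -> str:
        self._check_fitted()
        return summarize(self.result_)

    def heritability(self, terms=None) -> float:
        self._check_fitted()
        return heritability(self.result_, terms)

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("this UserCovLMM instance is not fitted yet")
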