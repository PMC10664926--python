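"""Binomial logit mixed models for per-decoy detection.

Detection of a decoy is modelled as Bernoulli on the logit scale with
fixed effects drawn from {season, viewshed_class, density_quartile} and
their two-way interactions, plus a random intercept for site.  With a
single scalar random effect the marginal likelihood factorises over sites
into one-dimensional integrals, which are evaluated by adaptive
Gauss–Hermite quadrature (the integrand is re-centred at its mode and
scaled by the curvature there; Laplace is the 1-node special case).

Candidate fixed-effect structures are compared by AICc.  Interactions are
coded as full cell products and each candidate's design matrix is reduced
to full column rank, so a model containing an interaction spans its main
effects — different parameterizations of the same column space collapse to
a single candidate, mirroring how selection tables are usually reported.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .trial_data import DENSITY_QUARTILES, SEASONS, VIEWSHED_CLASSES

__all__ = [
    "TERM_LEVELS",
    "GLMMSpec",
    "GLMMFit",
    "build_design",
    "records_to_frame",
    "fit_binomial_glmm",
    "enumerate_candidates",
    "select_models",
    "predict_bootstrap",
]

# domain-ordered levels; the first level of each factor is the reference
TERM_LEVELS = {
    "season": list(SEASONS),
    "viewshed_class": list(VIEWSHED_CLASSES),
    "density_quartile": list(DENSITY_QUARTILES),
}

MAIN_TERMS = tuple(TERM_LEVELS)


def _canonical_interaction(term: str) -> str:
    a, b = term.split(":")
    a, b = sorted((a, b), key=list(TERM_LEVELS).index)
    return f"{a}:{b}"


@dataclass(frozen=True)
class GLMMSpec:
    """A candidate model: fixed-effect terms plus a site random intercept."""

    fixed_terms: tuple[str, ...] = ()
    random_intercept_group: str = "site"

    def __post_init__(self):
        canon = []
        for t in self.fixed_terms:
            canon.append(_canonical_interaction(t) if ":" in t else t)
        for t in canon:
            for part in t.split(":"):
                if part not in TERM_LEVELS:
                    raise ValueError(f"unknown term component {part!r}")
        object.__setattr__(self, "fixed_terms", tuple(sorted(set(canon))))

    @property
    def label(self) -> str:
        return " + ".join(self.fixed_terms) if self.fixed_terms else "1"


def _dummies(df: pd.DataFrame, factor: str, drop_first: bool) -> tuple[list[str], np.ndarray]:
    levels = TERM_LEVELS[factor]
    use = levels[1:] if drop_first else levels
    cols = [f"{factor}[{lv}]" for lv in use]
    mat = np.column_stack([(df[factor] == lv).to_numpy(float) for lv in use])
    return cols, mat


def build_design(df: pd.DataFrame, spec: GLMMSpec) -> tuple[np.ndarray, list[str]]:
    """Full-rank design matrix (with intercept) for a candidate model.

    Main effects use treatment coding against the first domain-ordered
    level; interactions enter as full cell-indicator products.  Columns
    that are linearly dependent on earlier ones are dropped greedily, so
    the returned matrix has full column rank whatever the term mix.
    """
    names: list[str] = ["(Intercept)"]
    blocks: list[np.ndarray] = [np.ones((len(df), 1))]
    for term in spec.fixed_terms:
        if ":" in term:
            fa, fb = term.split(":")
            ca, ma = _dummies(df, fa, drop_first=False)
            cb, mb = _dummies(df, fb, drop_first=False)
            cols, mats = [], []
            for i, na in enumerate(ca):
                for j, nb in enumerate(cb):
                    cols.append(f"{na}:{nb}")
                    mats.append(ma[:, i] * mb[:, j])
            names.extend(cols)
            blocks.append(np.column_stack(mats))
        else:
            cols, mat = _dummies(df, term, drop_first=True)
            names.extend(cols)
            blocks.append(mat)
    X = np.column_stack(blocks)
    keep = _independent_columns(X)
    return X[:, keep], [names[i] for i in keep]


def _independent_columns(X: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Indices of a greedy maximal linearly independent column subset."""
    keep: list[int] = []
    basis = np.zeros((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        if basis.shape[1]:
            resid = col - basis @ (basis.T @ col)
        else:
            resid = col
        norm = np.linalg.norm(resid)
        if norm > tol * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            q = resid / norm
            basis = np.column_stack([basis, q])
    return keep


@dataclass
class GLMMFit:
    """A fitted binomial GLMM with one random intercept."""

    spec: GLMMSpec
    coefficients: pd.Series
    random_intercept_sd: float
    log_likelihood: float
    n_params: int
    n_obs: int
    aicc: float
    converged: bool
    n_quad: int
    _X: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _groups: np.ndarray = field(repr=False, default=None)
    _theta: np.ndarray = field(repr=False, default=None)
    _ridge: float = field(repr=False, default=0.0)

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.n_params


def _aicc(ll: float, k: int, n: int) -> float:
    if n <= k + 1:
        return float("inf")
    return -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _group_indices(groups: np.ndarray) -> list[np.ndarray]:
    order = {}
    for i, g in enumerate(groups):
        order.setdefault(g, []).append(i)
    return [np.asarray(ix) for ix in order.values()]


def _marginal_loglik(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    group_ix: Sequence[np.ndarray],
    z_nodes: np.ndarray,
    log_w: np.ndarray,
    ridge: float,
) -> float:
    """AGQ marginal log-likelihood at theta = (beta, log_sigma).

    Per group the conditional log-density h(b) (Bernoulli log-lik plus the
    N(0, sigma^2) prior on b) is maximised by Newton steps; quadrature
    nodes are placed at the mode with spacing set by the curvature.
    """
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    eta0 = X @ beta
    total = 0.0
    for ix in group_ix:
        e = eta0[ix]
        yy = y[ix]
        b = 0.0
        inv_var = 1.0 / sigma**2
        for _ in range(50):
            mu = _expit(e + b)
            grad = np.sum(yy - mu) - b * inv_var
            hess = -np.sum(mu * (1.0 - mu)) - inv_var
            step = grad / hess
            b -= step
            if abs(step) < 1e-10:
                break
        mu = _expit(e + b)
        neg_h2 = np.sum(mu * (1.0 - mu)) + inv_var
        tau = 1.0 / np.sqrt(neg_h2)
        bk = b + np.sqrt(2.0) * tau * z_nodes  # node positions
        etak = e[:, None] + bk[None, :]
        # Bernoulli log-lik at each node: sum_j y*eta - log(1+exp(eta))
        ll_nodes = np.sum(yy[:, None] * etak - np.logaddexp(0.0, etak), axis=0)
        ll_nodes += -0.5 * bk**2 * inv_var - log_sigma - 0.5 * np.log(2.0 * np.pi)
        terms = log_w + ll_nodes + z_nodes**2
        m = terms.max()
        total += 0.5 * np.log(2.0) + np.log(tau) + m + np.log(np.sum(np.exp(terms - m)))
    return total - 0.5 * ridge * float(beta @ beta)


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _irls_start(X: np.ndarray, y: np.ndarray, ridge: float = 1e-4) -> np.ndarray:
    """Ridge-stabilised IRLS for plain logistic regression (starting values)."""
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(25):
        eta = X @ beta
        mu = _expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        A = (X * w[:, None]).T @ X + ridge * np.eye(p)
        new = np.linalg.solve(A, (X * w[:, None]).T @ z)
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


def fit_binomial_glmm(
    df: pd.DataFrame,
    spec: GLMMSpec,
    n_quad: int = 15,
    ridge: float = 1e-4,
    force_zero_sd: bool = False,
    max_restarts: int = 3,
) -> GLMMFit:
    """Maximum-likelihood fit of a binomial logit GLMM with site intercept.

    ``df`` needs a binary ``found`` column, the grouping column named by
    the spec, and the factor columns used by the fixed terms.  A weak
    ridge (default 1e-4) keeps estimates finite under complete separation
    (strata where every decoy was found, or none was).  A boundary fit
    (sigma -> 0) is reported as random_intercept_sd = 0, not an error.
    """
    group_col = spec.random_intercept_group
    groups = df[group_col].to_numpy()
    if not force_zero_sd and len(np.unique(groups)) < 2:
        # no between-group information; fall back to the fixed-effect model
        force_zero_sd = True
    y = df["found"].to_numpy(dtype=float)
    X, names = build_design(df, spec)
    n, p = X.shape
    group_ix = _group_indices(groups)
    z_nodes, w_nodes = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(w_nodes)

    beta0 = _irls_start(X, y, ridge=max(ridge, 1e-6))

    if force_zero_sd:
        # pure fixed-effects logistic fit (sigma pinned at 0)
        beta = _irls_start(X, y, ridge=ridge)
        eta = X @ beta
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        k = p + 1  # variance still counted: it is estimated to be 0
        coef = pd.Series(beta, index=names)
        theta = np.concatenate([beta, [-np.inf]])
        return GLMMFit(spec=spec, coefficients=coef, random_intercept_sd=0.0,
                       log_likelihood=ll, n_params=k, n_obs=n,
                       aicc=_aicc(ll, k, n), converged=True, n_quad=n_quad,
                       _X=X, _y=y, _groups=groups, _theta=theta, _ridge=ridge)

    def negloglik(theta):
        return -_marginal_loglik(theta, X, y, group_ix, z_nodes, log_w, ridge)

    bounds = [(None, None)] * p + [(np.log(1e-4), np.log(50.0))]
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            x0 = np.concatenate([beta0, [np.log(0.5)]])
        else:
            x0 = np.concatenate([beta0 + rng.normal(0, 0.3, p),
                                 [np.log(rng.uniform(0.2, 2.0))]])
        res = optimize.minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-12,
                                         "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    theta = best.x
    sigma = float(np.exp(theta[-1]))
    boundary = sigma <= 1.1e-4
    ll = float(-negloglik(theta) + 0.5 * ridge * float(theta[:-1] @ theta[:-1]))
    if boundary:
        sigma = 0.0
    k = p + 1  # fixed effects (incl. intercept) + variance component
    converged = bool(best.success)
    if not converged:
        warnings.warn(f"GLMM fit did not converge for model {spec.label!r}",
                      stacklevel=2)
    coef = pd.Series(theta[:-1], index=names)
    return GLMMFit(spec=spec, coefficients=coef, random_intercept_sd=sigma,
                   log_likelihood=ll, n_params=k, n_obs=n, aicc=_aicc(ll, k, n),
                   converged=converged, n_quad=n_quad,
                   _X=X, _y=y, _groups=groups, _theta=theta, _ridge=ridge)


def marginal_loglik_at(fit: GLMMFit, n_quad: int) -> float:
    """Re-evaluate the fitted model's marginal log-likelihood with a
    different node count (diagnostic for quadrature accuracy)."""
    group_ix = _group_indices(fit._groups)
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    theta = fit._theta
    if np.isneginf(theta[-1]):
        return fit.log_likelihood
    raw = _marginal_loglik(theta, fit._X, fit._y, group_ix, z, np.log(w), 0.0)
    return float(raw)


def enumerate_candidates(
    all_terms: Sequence[str] = MAIN_TERMS,
    template: Optional[pd.DataFrame] = None,
) -> list[GLMMSpec]:
    """All candidate fixed-effect structures with distinct column spaces.

    Builds every subset of the main effects and their two-way interactions
    and collapses subsets whose design matrices span the same column space
    on a full-factorial template, keeping the subset with fewest terms.
    """
    if template is None:
        template = full_factorial_frame()
    inters = [f"{a}:{b}" for a, b in itertools.combinations(all_terms, 2)]
    pool = list(all_terms) + inters
    seen: dict[tuple, GLMMSpec] = {}
    for r in range(len(pool) + 1):
        for combo in itertools.combinations(pool, r):
            spec = GLMMSpec(fixed_terms=combo)
            X, _ = build_design(template, spec)
            key = _column_space_key(X)
            if key not in seen or len(spec.fixed_terms) < len(seen[key].fixed_terms):
                seen[key] = spec
    return sorted(seen.values(), key=lambda s: (len(s.fixed_terms), s.label))


def full_factorial_frame() -> pd.DataFrame:
    rows = [
        {"season": s, "viewshed_class": v, "density_quartile": d}
        for s in TERM_LEVELS["season"]
        for v in TERM_LEVELS["viewshed_class"]
        for d in TERM_LEVELS["density_quartile"]
    ]
    return pd.DataFrame(rows)


def _column_space_key(X: np.ndarray) -> tuple:
    """Hashable fingerprint of a column space: rank + rounded projector."""
    q, _ = np.linalg.qr(X)
    rank = np.linalg.matrix_rank(X)
    q = q[:, :rank]
    proj = q @ q.T
    return (rank, tuple(np.round(proj, 6).ravel().tolist()))


def select_models(fits: Sequence[GLMMFit]) -> pd.DataFrame:
    """Ranked AICc selection table with the best-supported set (ΔAICc ≤ 2).

    Ties are broken by fewer parameters, then label; duplicates of the same
    AICc and label appear once.
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    for f in fits:
        rows.append({
            "model": f.spec.label,
            "n_params": f.n_params,
            "log_likelihood": f.log_likelihood,
            "aicc": f.aicc,
            "converged": f.converged,
        })
    df = pd.DataFrame(rows).drop_duplicates(subset=["model"], keep="first")
    df = df.sort_values(["aicc", "n_params", "model"], ignore_index=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    df["best_supported"] = df["delta_aicc"] <= 2.0
    return df


def _numeric_hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x0)
    h = rel_step * (1.0 + np.abs(x0))
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def coefficient_covariance(fit: GLMMFit) -> np.ndarray:
    """Asymptotic covariance of the fixed effects from the observed
    information of the marginal (penalised) log-likelihood."""
    group_ix = _group_indices(fit._groups)
    z, w = np.polynomial.hermite.hermgauss(fit.n_quad)
    log_w = np.log(w)
    p = len(fit.coefficients)
    theta_full = fit._theta.copy()

    if np.isneginf(theta_full[-1]):
        # fixed-effects model: standard logistic information
        eta = fit._X @ theta_full[:-1]
        mu = _expit(eta)
        W = mu * (1.0 - mu)
        info = (fit._X * W[:, None]).T @ fit._X + fit._ridge * np.eye(p)
        return np.linalg.inv(info)

    def nll(theta):
        return -_marginal_loglik(theta, fit._X, fit._y, group_ix, z, log_w,
                                 fit._ridge)

    H = _numeric_hessian(nll, theta_full)
    # regularise: clip tiny/negative curvature before inverting
    evals, evecs = np.linalg.eigh(H)
    evals = np.clip(evals, 1e-8, None)
    cov_full = (evecs / evals) @ evecs.T
    return cov_full[:p, :p]


def predict_bootstrap(
    fit: GLMMFit,
    newdata: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.90,
    seed: int = 0,
    include_random: bool = True,
) -> pd.DataFrame:
    """Parametric-bootstrap predictions on the probability scale.

    Coefficients are drawn from their asymptotic normal; a fresh random
    intercept is drawn per replicate when ``include_random`` (predicting
    for an unseen site).  Percentile intervals; deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    Xn, names = build_design(newdata, fit.spec)
    if list(names) != list(fit.coefficients.index):
        # align on the fitted columns (newdata may not realise every cell)
        full = pd.DataFrame(Xn, columns=names)
        Xn = np.column_stack([
            full[c].to_numpy() if c in full.columns else np.zeros(len(full))
            for c in fit.coefficients.index
        ])
    beta_hat = fit.coefficients.to_numpy()
    cov = coefficient_covariance(fit)
    draws = rng.multivariate_normal(beta_hat, cov, size=n_boot, method="svd")
    eta = draws @ Xn.T
    if include_random and fit.random_intercept_sd > 0:
        eta += rng.normal(0.0, fit.random_intercept_sd, size=(n_boot, 1))
    probs = _expit(eta)
    lo = (1.0 - level) / 2.0
    out = newdata.copy().reset_index(drop=True)
    out["predicted"] = _expit(Xn @ beta_hat)
    out["lower"] = np.quantile(probs, lo, axis=0)
    out["upper"] = np.quantile(probs, 1.0 - lo, axis=0)
    return out


def records_to_frame(records, calendars) -> pd.DataFrame:
    """Model frame from available trial records: found flag plus factors."""
    from .trial_data import assign_density_quartile, assign_season

    rows = []
    for r in records:
        rows.append({
            "site": r.site_id,
            "found": int(r.found),
            "season": assign_season(r, calendars[r.site_id]),
            "viewshed_class": r.viewshed_class,
            "density_quartile": assign_density_quartile(r.distance_m),
        })
    return pd.DataFrame(rows)
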