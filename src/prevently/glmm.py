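"""Two-level mixed-effects (ordered) logistic trend models.

Fits daily PrEP-use and CAS outcomes on the changepoint-centred time axis:
fixed effects are a restricted cubic spline in time, the intra-pandemic
indicator, optional spline x pandemic interactions and an optional lagged
dosing term; random effects are a per-participant intercept and pandemic
indicator with an unstructured 2x2 covariance.  Estimation is maximum
likelihood with adaptive Gauss-Hermite quadrature (Laplace = 1 node);
standard errors are cluster-robust (sandwich) over participants by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from ._agq import (
    AGQProblem,
    BinaryFamily,
    OrdinalFamily,
    PlainProblem,
    sigma_from_theta,
    theta_from_sigma,
)
from .config import CAS_KNOTS_DEFAULT, PREP_KNOTS_DEFAULT
from .rcs import SplineSpec, rcs_basis

__all__ = [
    "ConvergenceError",
    "MixedModelSpec",
    "MixedModelFit",
    "fit_mixed_logit",
    "fit_mixed_ologit",
    "fit_lagged_association",
    "joint_interaction_test",
    "predict_marginal_prob",
    "marginal_loglik",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class MixedModelSpec:
    """Fixed- and random-part layout of a trend model.

    ``spline_by_pandemic`` adds the spline x pandemic interaction block
    (present only together with its main effects).  ``random`` is
    "intercept+pandemic" (unstructured 2x2) or "none" (plain ML).
    ``pandemic_continuous`` swaps the I(t>=0) indicator for max(t, 0)/100 in
    the fixed and random parts (an alternative "pandemic time" reading).
    """

    knots: tuple[float, ...] = PREP_KNOTS_DEFAULT
    include_spline: bool = True
    include_pandemic: bool = True
    spline_by_pandemic: bool = False
    lagged_dose: bool = False
    lag_days: int = 1
    lag_by_pandemic: bool = False
    random: str = "intercept+pandemic"
    n_quad: int = 7
    pandemic_continuous: bool = False

    def __post_init__(self) -> None:
        if self.spline_by_pandemic and not (self.include_spline and self.include_pandemic):
            raise ValueError("interaction terms require both main effects")
        if self.lag_by_pandemic and not (self.lagged_dose and self.include_pandemic):
            raise ValueError("lag x pandemic interaction requires both main effects")
        if self.random not in ("intercept+pandemic", "none"):
            raise ValueError(f"unknown random part {self.random!r}")
        if self.n_quad < 1:
            raise ValueError("n_quad must be >= 1")


@dataclass
class MixedModelFit:
    terms: list[str]
    beta: np.ndarray
    se_robust: np.ndarray
    vcov_robust: np.ndarray
    vcov_model: np.ndarray
    re_covariance: np.ndarray | None
    thresholds: np.ndarray | None
    loglik: float
    n_obs: int
    n_groups: int
    n_dropped: int
    converged: bool
    boundary: bool
    grad_norm: float
    n_iter: int
    spec: MixedModelSpec
    family: str
    t_range: tuple[float, float]
    theta_internal: np.ndarray = field(repr=False, default=None)
    score_by_cluster: np.ndarray = field(repr=False, default=None)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def summary_table(self) -> pd.DataFrame:
        z = self.beta / self.se_robust
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.beta,
                "se_robust": self.se_robust,
                "odds_ratio": np.exp(self.beta),
                "or_ci_low": np.exp(self.beta - 1.959964 * self.se_robust),
                "or_ci_high": np.exp(self.beta + 1.959964 * self.se_robust),
                "z": z,
                "p": p,
            }
        )

    def interaction_indices(self) -> list[int]:
        return [i for i, t in enumerate(self.terms) if t.endswith(":pandemic") and t != "pandemic"]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _pandemic_col(df: pd.DataFrame, spec: MixedModelSpec) -> np.ndarray:
    if spec.pandemic_continuous:
        return np.maximum(df["t"].to_numpy(dtype=float), 0.0) / 100.0
    return df["pandemic"].to_numpy(dtype=float)


def build_design(df: pd.DataFrame, spec: MixedModelSpec, intercept: bool = True):
    """Design matrix and term names for panel rows (requires columns t, pandemic)."""
    cols, names = [], []
    n = len(df)
    if intercept:
        cols.append(np.ones(n))
        names.append("intercept")
    sp = SplineSpec(spec.knots)
    if spec.include_spline:
        basis = rcs_basis(df["t"].to_numpy(dtype=float), sp)
        for j in range(basis.shape[1]):
            cols.append(basis[:, j])
            names.append(f"time_{j + 1}")
    z = _pandemic_col(df, spec)
    if spec.include_pandemic:
        cols.append(z)
        names.append("pandemic")
    if spec.spline_by_pandemic:
        for j in range(basis.shape[1]):
            cols.append(basis[:, j] * z)
            names.append(f"time_{j + 1}:pandemic")
    if spec.lagged_dose:
        lag = df["lagged_dose"].to_numpy(dtype=float)
        cols.append(lag)
        names.append(f"dose_lag{spec.lag_days}")
        if spec.lag_by_pandemic:
            cols.append(lag * z)
            names.append(f"dose_lag{spec.lag_days}:pandemic")
    return np.column_stack(cols), names, z


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _numeric_hessian(fun_grad, theta, rel_step=1e-5):
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        h = rel_step * (1.0 + abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        H[:, j] = (fun_grad(tp) - fun_grad(tm)) / (2 * h)
    return 0.5 * (H + H.T)


def _fit(problem, theta0, gtol_per_obs=1e-5, maxiter=300):
    N = problem.N

    def f(theta):
        res = problem.eval(theta, want_grad=True)
        return res.nll / N, res.grad / N

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = optimize.minimize(
            f, theta0, jac=True, method="BFGS",
            options={"gtol": gtol_per_obs, "maxiter": maxiter},
        )
    grad_norm = float(np.abs(opt.jac).max())
    converged = bool(opt.success) or grad_norm < 50 * gtol_per_obs
    return opt, converged, grad_norm


def _start_values(y, X, z, groups, family_cls):
    """Pooled Newton fit on beta (ignoring clustering) for fixed-part starts."""
    prob = PlainProblem(y, X, z, groups, family_cls)
    theta = np.zeros(prob.n_par)
    theta[prob.p :] = prob.family.start_aux(prob.y)
    aux = theta[prob.p :]
    for _ in range(25):
        eta = prob.X @ theta[: prob.p]
        d1 = prob.family.d_eta(aux, eta)
        g_beta = prob.X.T @ d1
        if np.abs(g_beta).max() < 1e-6 * max(len(y), 1):
            break
        w = -prob.family.d2_eta(aux, eta)
        XtWX = (prob.X * w[:, None]).T @ prob.X + 1e-8 * np.eye(prob.p)
        try:
            step_beta = np.linalg.solve(XtWX, g_beta)
        except np.linalg.LinAlgError:
            break
        theta[: prob.p] += np.clip(step_beta, -2, 2)
    return theta, prob


def _empirical_re_start(y, z, groups):
    """Moment starting covariance from per-cluster empirical logits.

    The spread of cluster-level logits of the outcome in the pre (z=0) and
    post (z=1) regimes gives rough intercept / indicator-slope variances; the
    result only seeds the optimiser.
    """
    yb = (np.asarray(y, dtype=float) > 0).astype(float)  # binarise ordinals
    df = pd.DataFrame({"y": yb, "z": np.asarray(z) > 0, "g": groups})

    def elogit(s):
        m = (s.sum() + 0.5) / (len(s) + 1.0)
        return np.log(m / (1 - m))

    pre = df[~df.z].groupby("g")["y"].apply(elogit)
    post = df[df.z].groupby("g")["y"].apply(elogit)
    both = pd.concat([pre.rename("a"), post.rename("b")], axis=1).dropna()
    v0 = float(pre.var()) if pre.size > 2 else 1.0
    if both.shape[0] > 2:
        slope = both["b"] - both["a"]
        v1 = float(slope.var())
        c01 = float(np.cov(both["a"], slope)[0, 1])
    else:
        v1, c01 = 1.0, 0.0
    v0 = np.clip(v0 if np.isfinite(v0) else 1.0, 0.1, 10.0)
    v1 = np.clip(v1 if np.isfinite(v1) else 1.0, 0.1, 10.0)
    lim = 0.9 * np.sqrt(v0 * v1)
    c01 = np.clip(c01 if np.isfinite(c01) else 0.0, -lim, lim)
    return np.array([[v0, c01], [c01, v1]])


def _fit_family(df, outcome, spec, family_cls, cluster="participant_id"):
    work = df.copy()
    n_total = len(work)
    work = work[work[outcome].notna()]
    if spec.lagged_dose:
        work = work[work["lagged_dose"].notna()]
    n_dropped = n_total - len(work)
    y = work[outcome].to_numpy(dtype=float)
    intercept = family_cls is BinaryFamily
    X, names, z = build_design(work, spec, intercept=intercept)
    groups = work[cluster].to_numpy()

    # column scaling for optimiser conditioning
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    Xs = X / scale

    theta0, _plain = _start_values(y, Xs, z, groups, family_cls)

    if spec.random == "none":
        problem = PlainProblem(y, Xs, z, groups, family_cls)
        theta_start = theta0
    else:
        problem = AGQProblem(y, Xs, z, groups, family_cls, n_quad=spec.n_quad)
        sigma0 = _empirical_re_start(y, z, groups)
        theta_start = np.concatenate([theta0, theta_from_sigma(sigma0)])

    opt, bfgs_ok, grad_norm = _fit(problem, theta_start)
    if not bfgs_ok and spec.random != "none":
        # one retry from a different covariance start
        alt = theta_start.copy()
        alt[-3:] = theta_from_sigma(np.diag([2.0, 2.0]))
        opt2, ok2, gn2 = _fit(problem, alt)
        if ok2 or opt2.fun < opt.fun:
            opt, bfgs_ok, grad_norm = opt2, ok2, gn2

    theta_hat = opt.x
    final = problem.eval(theta_hat, want_grad=True)

    def g_of(theta):
        return problem.eval(theta, want_grad=True).grad

    # Newton polish: BFGS stops on a loose per-observation gradient criterion
    # (or with a line-search precision loss); damped Newton steps on the exact
    # score with a finite-difference Hessian sharpen the optimum and rescue
    # near-converged runs.  The last Hessian doubles as the sandwich bread.
    H = _numeric_hessian(g_of, theta_hat)
    for rebuild in range(3):
        try:
            H_inv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            H_inv = np.linalg.pinv(H)
        for _ in range(6):
            step = -H_inv @ final.grad
            if np.abs(step).max() < 1e-10:
                break
            lam = 1.0
            improved = False
            for _half in range(8):
                cand = problem.eval(theta_hat + lam * step, want_grad=True)
                if cand.nll <= final.nll + 1e-10:
                    theta_hat = theta_hat + lam * step
                    final = cand
                    improved = True
                    break
                lam *= 0.5
            if not improved:
                break
        grad_norm = float(np.abs(final.grad).max()) / max(problem.N, 1)
        if grad_norm < 1e-6 or np.abs(step).max() < 1e-9:
            break
        H = _numeric_hessian(g_of, theta_hat)

    converged = bfgs_ok or grad_norm < 5e-4
    if not converged:
        raise ConvergenceError(
            f"mixed model did not converge: per-obs gradient max {grad_norm:.3e} "
            f"after {opt.nit} BFGS iterations ({opt.message}) plus Newton polish"
        )
    S = final.score_by_cluster
    G = problem.G
    meat = (S.T @ S) * (G / (G - 1.0)) if G > 1 else S.T @ S
    vcov_rob = H_inv @ meat @ H_inv
    vcov_mod = H_inv

    n_aux = problem.family.n_aux
    # unscale the fixed-effect block
    D = np.diag(1.0 / scale)
    beta = theta_hat[: problem.p] / scale
    full_D = np.eye(theta_hat.size)
    full_D[: problem.p, : problem.p] = D
    vcov_rob = full_D @ vcov_rob @ full_D
    vcov_mod = full_D @ vcov_mod @ full_D

    if spec.random == "none":
        re_cov = None
        boundary = False
    else:
        re_cov = sigma_from_theta(theta_hat[-3:])
        boundary = bool(min(re_cov[0, 0], re_cov[1, 1]) < 1e-4)

    thresholds = None
    if n_aux:
        aux = theta_hat[problem.p : problem.p + n_aux]
        thresholds = np.cumsum(np.concatenate([[aux[0]], np.exp(aux[1:])]))

    se = np.sqrt(np.clip(np.diag(vcov_rob)[: problem.p], 0, None))
    t_vals = work["t"].to_numpy(dtype=float)
    return MixedModelFit(
        terms=names,
        beta=beta,
        se_robust=se,
        vcov_robust=vcov_rob,
        vcov_model=vcov_mod,
        re_covariance=re_cov,
        thresholds=thresholds,
        loglik=-final.nll,
        n_obs=problem.N,
        n_groups=problem.G,
        n_dropped=n_dropped,
        converged=converged,
        boundary=boundary,
        grad_norm=grad_norm,
        n_iter=int(opt.nit),
        spec=spec,
        family="binary" if intercept else "ordinal",
        t_range=(float(t_vals.min()), float(t_vals.max())),
        theta_internal=theta_hat,
        score_by_cluster=S,
    )


def fit_mixed_logit(
    panel: pd.DataFrame,
    outcome: str = "dose_day",
    spec: MixedModelSpec | None = None,
    cluster: str = "participant_id",
) -> MixedModelFit:
    """Two-level mixed-effects logistic regression of a daily binary outcome.

    Rows with a missing outcome are dropped (and counted in ``n_dropped``);
    missingness is never imputed.
    """
    spec = spec or MixedModelSpec()
    df = panel.copy()
    df[outcome] = pd.to_numeric(df[outcome], errors="coerce")
    return _fit_family(df, outcome, spec, BinaryFamily, cluster)


def fit_mixed_ologit(
    panel: pd.DataFrame,
    outcome: str = "episode_count",
    spec: MixedModelSpec | None = None,
    cluster: str = "participant_id",
) -> MixedModelFit:
    """Proportional-odds mixed model of a capped ordinal daily outcome."""
    spec = spec or MixedModelSpec(knots=CAS_KNOTS_DEFAULT)
    df = panel.copy()
    df[outcome] = pd.to_numeric(df[outcome], errors="coerce")
    sub = df[df[outcome].notna()]
    if sub[outcome].nunique() < 2:
        raise ValueError("ordinal outcome has fewer than 2 observed categories")
    return _fit_family(df, outcome, spec, OrdinalFamily, cluster)


def fit_lagged_association(
    panel: pd.DataFrame,
    lag_days: int = 1,
    include_interaction: bool = False,
    include_spline: bool = False,
    knots: tuple[float, ...] = CAS_KNOTS_DEFAULT,
    n_quad: int = 7,
    random: str = "intercept+pandemic",
) -> MixedModelFit:
    """Mixed logit of today's CAS on dosing ``lag_days`` days earlier.

    The lagged indicator pairs the dose on day t - lag_days with the CAS
    outcome on day t within participant; the first ``lag_days`` days of each
    participant (no constructable lag) are dropped.
    """
    if lag_days < 1:
        raise ValueError("lag_days must be >= 1")
    df = panel.sort_values(["participant_id", "date"]).copy()
    lagged = df.groupby("participant_id")["dose_day"].shift(lag_days)
    df["lagged_dose"] = lagged.astype(float)
    spec = MixedModelSpec(
        knots=knots,
        include_spline=include_spline,
        include_pandemic=True,
        lagged_dose=True,
        lag_days=lag_days,
        lag_by_pandemic=include_interaction,
        random=random,
        n_quad=n_quad,
    )
    return fit_mixed_logit(df, outcome="cas_day", spec=spec)


def joint_interaction_test(fit_full: MixedModelFit, fit_reduced: MixedModelFit | None = None):
    """Robust Wald chi-square test of the spline x pandemic interaction block.

    If a reduced fit is supplied its fixed part must equal the full fit's
    minus the interaction block (nesting check).  Returns (chi2, df, p).
    """
    idx = fit_full.interaction_indices()
    if not idx:
        raise ValueError("full model has no interaction block")
    if fit_reduced is not None:
        expected = [t for i, t in enumerate(fit_full.terms) if i not in idx]
        if list(fit_reduced.terms) != expected:
            raise ValueError(
                f"models are not nested: reduced terms {fit_reduced.terms} vs "
                f"full-minus-block {expected}"
            )
    b = fit_full.beta[idx]
    V = fit_full.vcov_robust[np.ix_(idx, idx)]
    chi2 = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


# ---------------------------------------------------------------------------
# marginal predictions and likelihood oracle hooks
# ---------------------------------------------------------------------------

def _gh_2d(n):
    nodes, weights = np.polynomial.hermite.hermgauss(n)
    xx, yy = np.meshgrid(nodes, nodes, indexing="ij")
    w = np.outer(weights, weights).ravel() / np.pi  # normalise N(0, I/2)-style
    return np.column_stack([xx.ravel(), yy.ravel()]), w


def marginal_probability(eta_fixed, z, sigma, n_quad=40):
    """Population-averaged P(y=1) integrating the bivariate random effect."""
    eta_fixed = np.atleast_1d(np.asarray(eta_fixed, dtype=float))
    z = np.broadcast_to(np.asarray(z, dtype=float), eta_fixed.shape)
    if sigma is None or np.allclose(sigma, 0):
        return expit(eta_fixed)
    L = np.linalg.cholesky(np.asarray(sigma) + 1e-12 * np.eye(2))
    q, w = _gh_2d(n_quad)
    b = np.sqrt(2.0) * q @ L.T  # (Q, 2) draws from N(0, sigma)
    eta = eta_fixed[None, :] + b[:, 0][:, None] + b[:, 1][:, None] * z[None, :]
    return expit(eta).T @ w


def predict_marginal_prob(
    fit: MixedModelFit, t_grid, n_quad: int = 40, extrapolation_guard: float = 30.0
):
    """Marginal probability curve over ``t_grid`` from a converged binary fit."""
    if fit.family != "binary":
        raise ValueError("marginal probability curve is defined for binary fits")
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    lo, hi = fit.t_range
    if (t_grid < lo - extrapolation_guard).any() or (t_grid > hi + extrapolation_guard).any():
        warnings.warn(
            f"t outside the fitted range [{lo:.0f}, {hi:.0f}] by more than "
            f"{extrapolation_guard:.0f} days: extrapolating a spline",
            stacklevel=2,
        )
    df = pd.DataFrame({"t": t_grid, "pandemic": (t_grid >= 0).astype(int)})
    if fit.spec.lagged_dose:
        raise ValueError("marginal curve for lagged models requires a lag scenario")
    X, names, z = build_design(df, fit.spec, intercept=True)
    eta = X @ fit.beta
    return marginal_probability(eta, z, fit.re_covariance, n_quad=n_quad)


def marginal_loglik(y, X, z, groups, beta, sigma, n_quad=7, family="binary", aux=None):
    """AGQ marginal log-likelihood at given parameters (oracle hook for tests)."""
    family_cls = BinaryFamily if family == "binary" else OrdinalFamily
    problem = AGQProblem(y, X, z, groups, family_cls, n_quad=n_quad)
    theta = np.concatenate(
        [np.asarray(beta, dtype=float), np.asarray(aux if aux is not None else [], dtype=float), theta_from_sigma(sigma)]
    )
    res = problem.eval(theta, want_grad=False)
    return -res.nll, res.loglik_by_cluster
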