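"""Two-level mixed-model machinery: adaptive Gauss-Hermite quadrature (AGQ)
marginal likelihood for binary-logit and cumulative-logit outcomes with a
bivariate (intercept, indicator-slope) normal random effect.

Per cluster g the marginal likelihood integrates

    L_g = int prod_t p(y_gt | eta_gt + b0 + b1 z_gt) phi(b; Sigma) db

over b = (b0, b1).  The integrand's mode and curvature are found by a damped
Newton step per cluster (fully vectorised across clusters), the quadrature
grid is recentred and rescaled there, and with one node per dimension the
scheme reduces exactly to the Laplace approximation.  Scores are computed as
posterior expectations of the complete-data score over the same grid, which
is the quadrature approximation of the exact marginal score.

The random-effect covariance is parameterised through its Cholesky factor
L = [[exp(a), 0], [c, exp(d)]], so Sigma = L L' is unconstrained in
theta_cov = (a, c, d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# outcome families
# ---------------------------------------------------------------------------

class BinaryFamily:
    """Bernoulli-logit rows; no auxiliary parameters (intercept sits in X)."""

    n_aux = 0

    def __init__(self, y: np.ndarray):
        self.y = np.asarray(y, dtype=float)

    def loglik(self, aux, eta):
        return self.y * eta - np.logaddexp(0.0, eta)

    def d_eta(self, aux, eta):
        return self.y - expit(eta)

    def d2_eta(self, aux, eta):
        p = expit(eta)
        return -p * (1.0 - p)

    def d_aux(self, aux, eta):
        return np.empty((eta.size, 0))

    @staticmethod
    def start_aux(y):
        return np.empty(0)


class OrdinalFamily:
    """Cumulative-logit (proportional odds) rows.

    Categories are 0..K-1; P(y <= k) = expit(alpha_k - eta) with strictly
    increasing thresholds.  The auxiliary vector holds (alpha_0,
    log(alpha_1 - alpha_0), ...), keeping the ordering unconstrained.
    Larger eta favours higher categories, so a two-category outcome
    reproduces the binary-logit coefficients with intercept -alpha_0.
    """

    def __init__(self, y: np.ndarray):
        self.y = np.asarray(y, dtype=int)
        self.K = int(self.y.max()) + 1
        if self.K < 2 or len(np.unique(self.y)) < 2:
            raise ValueError("ordinal outcome needs >=2 observed categories")
        self.n_aux = self.K - 1

    def _alphas(self, aux):
        steps = np.concatenate([[aux[0]], np.exp(aux[1:])])
        return np.cumsum(steps)

    def _gammas(self, aux, eta):
        alpha = self._alphas(aux)
        y = self.y
        hi_edge = y <= self.K - 2
        lo_edge = y >= 1
        g_hi = np.ones_like(eta)
        g_lo = np.zeros_like(eta)
        g_hi[hi_edge] = expit(alpha[y[hi_edge]] - eta[hi_edge])
        g_lo[lo_edge] = expit(alpha[y[lo_edge] - 1] - eta[lo_edge])
        return g_hi, g_lo

    def loglik(self, aux, eta):
        g_hi, g_lo = self._gammas(aux, eta)
        return np.log(np.maximum(g_hi - g_lo, 1e-300))

    def d_eta(self, aux, eta):
        g_hi, g_lo = self._gammas(aux, eta)
        P = np.maximum(g_hi - g_lo, 1e-300)
        A = g_hi * (1.0 - g_hi)
        B = g_lo * (1.0 - g_lo)
        return -(A - B) / P

    def d2_eta(self, aux, eta):
        g_hi, g_lo = self._gammas(aux, eta)
        P = np.maximum(g_hi - g_lo, 1e-300)
        A = g_hi * (1.0 - g_hi)
        B = g_lo * (1.0 - g_lo)
        num = ((1.0 - 2.0 * g_hi) * A - (1.0 - 2.0 * g_lo) * B) * P - (A - B) ** 2
        return num / P**2

    def d_aux(self, aux, eta):
        """Row-wise gradient w.r.t. the transformed threshold parameters."""
        g_hi, g_lo = self._gammas(aux, eta)
        P = np.maximum(g_hi - g_lo, 1e-300)
        A = g_hi * (1.0 - g_hi)
        B = g_lo * (1.0 - g_lo)
        y = self.y
        d_alpha = np.zeros((eta.size, self.K - 1))
        hi_edge = y <= self.K - 2
        lo_edge = y >= 1
        idx = np.arange(eta.size)
        d_alpha[idx[hi_edge], y[hi_edge]] = (A / P)[hi_edge]
        d_alpha[idx[lo_edge], y[lo_edge] - 1] += (-B / P)[lo_edge]
        # chain rule alpha -> (alpha_0, log-steps): d alpha_i / d s_j =
        # 1 for j = 0, exp(s_j) * 1{i >= j} for j >= 1
        out = np.empty_like(d_alpha)
        rev = np.cumsum(d_alpha[:, ::-1], axis=1)[:, ::-1]
        out[:, 0] = rev[:, 0]
        if self.K > 2:
            out[:, 1:] = rev[:, 1:] * np.exp(aux[1:])
        return out

    @staticmethod
    def start_aux(y):
        y = np.asarray(y, dtype=int)
        K = int(y.max()) + 1
        cum = np.array([(y <= k).mean() for k in range(K - 1)])
        cum = np.clip(cum, 1e-3, 1 - 1e-3)
        alpha = np.log(cum / (1 - cum))
        alpha = np.maximum.accumulate(alpha + 1e-6 * np.arange(K - 1))
        steps = np.diff(alpha)
        return np.concatenate([[alpha[0]], np.log(np.maximum(steps, 1e-3))])


# ---------------------------------------------------------------------------
# covariance parameterisation
# ---------------------------------------------------------------------------

def chol_from_theta(theta_cov):
    a, c, d = theta_cov
    return np.array([[np.exp(a), 0.0], [c, np.exp(d)]])


def sigma_from_theta(theta_cov):
    L = chol_from_theta(theta_cov)
    return L @ L.T


def theta_from_sigma(sigma):
    L = np.linalg.cholesky(np.asarray(sigma, dtype=float))
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])


def _logphi_and_grad(b0, b1, theta_cov, want_grad):
    """log N((b0,b1); 0, Sigma) and its gradient w.r.t. (a, c, d).

    With u = L^{-1} b:  log phi = -log 2pi - a - d - (u1^2 + u2^2)/2,
    d/da = -1 + u1^2 - c e^{-d} u1 u2,  d/dc = e^{-d} u1 u2,  d/dd = -1 + u2^2.
    """
    a, c, d = theta_cov
    u1 = b0 * np.exp(-a)
    u2 = (b1 - c * u1) * np.exp(-d)
    logphi = -LOG_2PI - a - d - 0.5 * (u1**2 + u2**2)
    if not want_grad:
        return logphi, None
    e_md = np.exp(-d)
    g = np.stack(
        [-1.0 + u1**2 - c * e_md * u1 * u2, e_md * u1 * u2, -1.0 + u2**2], axis=-1
    )
    return logphi, g


# ---------------------------------------------------------------------------
# the AGQ problem
# ---------------------------------------------------------------------------

@dataclass
class AGQResult:
    nll: float
    grad: np.ndarray | None
    loglik_by_cluster: np.ndarray
    score_by_cluster: np.ndarray | None
    b_mode: np.ndarray


class AGQProblem:
    """Marginal likelihood of a 2-level model on pre-sorted flat arrays.

    Rows must be grouped contiguously by cluster.  ``z`` is the random-slope
    covariate (the pandemic indicator).  ``n_quad`` nodes per dimension;
    1 gives the Laplace approximation.
    """

    def __init__(self, y, X, z, group_idx, family_cls, n_quad=7):
        order = np.argsort(group_idx, kind="stable")
        self.y = np.asarray(y, dtype=float)[order]
        self.X = np.asarray(X, dtype=float)[order]
        self.z = np.asarray(z, dtype=float)[order]
        gi = np.asarray(group_idx)[order]
        _, self.gi = np.unique(gi, return_inverse=True)
        self.starts = np.concatenate([[0], 1 + np.flatnonzero(np.diff(self.gi))])
        self.G = self.starts.size
        self.N, self.p = self.X.shape
        self.family = family_cls(self.y)
        self.n_par = self.p + self.family.n_aux + 3
        nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
        xx, yy = np.meshgrid(nodes, nodes, indexing="ij")
        self.qx = np.column_stack([xx.ravel(), yy.ravel()])  # (Q, 2)
        self.logw = (
            np.log(np.outer(weights, weights)).ravel() + (self.qx**2).sum(axis=1)
        )
        self.Q = self.qx.shape[0]
        self._b_cache = np.zeros((self.G, 2))

    def segsum(self, v):
        return np.add.reduceat(v, self.starts)

    # -- inner mode finding -------------------------------------------------
    def _penalised_ll(self, aux, eta_fixed, b, sigma_inv):
        eta = eta_fixed + b[self.gi, 0] + b[self.gi, 1] * self.z
        ll = self.segsum(self.family.loglik(aux, eta))
        quad = (
            sigma_inv[0, 0] * b[:, 0] ** 2
            + 2 * sigma_inv[0, 1] * b[:, 0] * b[:, 1]
            + sigma_inv[1, 1] * b[:, 1] ** 2
        )
        return ll - 0.5 * quad, eta

    def _find_modes(self, aux, eta_fixed, sigma_inv, tol=1e-9, max_iter=80):
        b = self._b_cache.copy()
        pll, eta = self._penalised_ll(aux, eta_fixed, b, sigma_inv)
        for _ in range(max_iter):
            d1 = self.family.d_eta(aux, eta)
            d2 = self.family.d2_eta(aux, eta)
            g0 = self.segsum(d1) - (sigma_inv[0, 0] * b[:, 0] + sigma_inv[0, 1] * b[:, 1])
            g1 = self.segsum(d1 * self.z) - (
                sigma_inv[0, 1] * b[:, 0] + sigma_inv[1, 1] * b[:, 1]
            )
            if max(np.abs(g0).max(initial=0), np.abs(g1).max(initial=0)) < tol:
                break
            w = -d2
            h00 = self.segsum(w) + sigma_inv[0, 0]
            h01 = self.segsum(w * self.z) + sigma_inv[0, 1]
            h11 = self.segsum(w * self.z * self.z) + sigma_inv[1, 1]
            det = h00 * h11 - h01 * h01
            db0 = (h11 * g0 - h01 * g1) / det
            db1 = (h00 * g1 - h01 * g0) / det
            step = 1.0
            for _half in range(12):
                b_new = b + step * np.column_stack([db0, db1])
                pll_new, eta_new = self._penalised_ll(aux, eta_fixed, b_new, sigma_inv)
                if (pll_new >= pll - 1e-12).all():
                    break
                # damp only the clusters that got worse
                worse = pll_new < pll
                db0 = np.where(worse, db0 * 0.5, db0)
                db1 = np.where(worse, db1 * 0.5, db1)
            b, pll, eta = b_new, pll_new, eta_new
        # final curvature at the mode
        d2 = self.family.d2_eta(aux, eta)
        w = -d2
        h00 = self.segsum(w) + sigma_inv[0, 0]
        h01 = self.segsum(w * self.z) + sigma_inv[0, 1]
        h11 = self.segsum(w * self.z * self.z) + sigma_inv[1, 1]
        self._b_cache = b.copy()
        return b, pll, (h00, h01, h11)

    # -- marginal log-likelihood and score ---------------------------------
    def eval(self, theta, want_grad=True) -> AGQResult:
        beta = theta[: self.p]
        aux = theta[self.p : self.p + self.family.n_aux]
        theta_cov = theta[self.p + self.family.n_aux :]
        sigma = sigma_from_theta(theta_cov)
        sigma_inv = np.linalg.inv(sigma)

        eta_fixed = self.X @ beta
        b_hat, _, (h00, h01, h11) = self._find_modes(aux, eta_fixed, sigma_inv)

        # Cholesky of the inverse curvature, per cluster (2x2 closed form)
        det = h00 * h11 - h01 * h01
        q00, q01, q11 = h11 / det, -h01 / det, h00 / det
        c11 = np.sqrt(q00)
        c21 = q01 / c11
        c22 = np.sqrt(np.maximum(q11 - c21**2, 1e-300))

        sqrt2 = np.sqrt(2.0)
        # node locations per cluster: (Q, G)
        b0_nodes = b_hat[:, 0][None, :] + sqrt2 * c11[None, :] * self.qx[:, 0][:, None]
        b1_nodes = (
            b_hat[:, 1][None, :]
            + sqrt2 * (c21[None, :] * self.qx[:, 0][:, None] + c22[None, :] * self.qx[:, 1][:, None])
        )

        h_nodes = np.empty((self.Q, self.G))
        etas = np.empty((self.Q, self.N)) if want_grad else None
        for k in range(self.Q):
            eta_k = eta_fixed + b0_nodes[k][self.gi] + b1_nodes[k][self.gi] * self.z
            logphi, _ = _logphi_and_grad(b0_nodes[k], b1_nodes[k], theta_cov, False)
            h_nodes[k] = self.segsum(self.family.loglik(aux, eta_k)) + logphi
            if want_grad:
                etas[k] = eta_k

        log_jac = np.log(2.0 * c11 * c22)
        ll_g = log_jac + logsumexp(h_nodes + self.logw[:, None], axis=0)
        nll = -float(ll_g.sum())

        if not want_grad:
            return AGQResult(nll, None, ll_g, None, b_hat)

        # posterior node weights, normalised per cluster: (Q, G)
        wpost = np.exp(h_nodes + self.logw[:, None] - (ll_g - log_jac)[None, :])
        wpost /= wpost.sum(axis=0, keepdims=True)  # guard tiny drift

        S = np.zeros((self.G, self.n_par))
        r = np.zeros(self.N)       # accumulated d ll / d eta rows
        aux_acc = np.zeros((self.N, self.family.n_aux)) if self.family.n_aux else None
        cov_acc = np.zeros((self.G, 3))
        for k in range(self.Q):
            d1 = self.family.d_eta(aux, etas[k])
            r += wpost[k][self.gi] * d1
            if self.family.n_aux:
                aux_acc += wpost[k][self.gi, None] * self.family.d_aux(aux, etas[k])
            _, gphi = _logphi_and_grad(b0_nodes[k], b1_nodes[k], theta_cov, True)
            cov_acc += wpost[k][:, None] * gphi
        for j in range(self.p):
            S[:, j] = self.segsum(r * self.X[:, j])
        if self.family.n_aux:
            for j in range(self.family.n_aux):
                S[:, self.p + j] = self.segsum(aux_acc[:, j])
        S[:, self.p + self.family.n_aux :] = cov_acc

        grad = -S.sum(axis=0)
        return AGQResult(nll, grad, ll_g, S, b_hat)


# ---------------------------------------------------------------------------
# no-random-effect fallback (plain ML on the same families)
# ---------------------------------------------------------------------------

class PlainProblem:
    """Same interface as AGQProblem but without random effects."""

    def __init__(self, y, X, z, group_idx, family_cls, n_quad=0):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        gi = np.asarray(group_idx)
        _, self.gi = np.unique(gi, return_inverse=True)
        order = np.argsort(self.gi, kind="stable")
        self.y, self.X, self.gi = self.y[order], self.X[order], self.gi[order]
        self.starts = np.concatenate([[0], 1 + np.flatnonzero(np.diff(self.gi))])
        self.G = self.starts.size
        self.N, self.p = self.X.shape
        self.family = family_cls(self.y)
        self.n_par = self.p + self.family.n_aux

    def segsum(self, v):
        return np.add.reduceat(v, self.starts)

    def eval(self, theta, want_grad=True) -> AGQResult:
        beta = theta[: self.p]
        aux = theta[self.p :]
        eta = self.X @ beta
        ll_rows = self.family.loglik(aux, eta)
        ll_g = self.segsum(ll_rows)
        nll = -float(ll_g.sum())
        if not want_grad:
            return AGQResult(nll, None, ll_g, None, np.zeros((self.G, 2)))
        d1 = self.family.d_eta(aux, eta)
        S = np.zeros((self.G, self.n_par))
        for j in range(self.p):
            S[:, j] = self.segsum(d1 * self.X[:, j])
        if self.family.n_aux:
            da = self.family.d_aux(aux, eta)
            for j in range(self.family.n_aux):
                S[:, self.p + j] = self.segsum(da[:, j])
        return AGQResult(nll, -S.sum(axis=0), ll_g, S, np.zeros((self.G, 2)))
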