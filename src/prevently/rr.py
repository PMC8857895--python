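"""Log-binomial relative risk of episode coverage, with cluster-robust errors.

The binomial GLM with log link makes exp(coefficient) a relative risk.  The
likelihood is maximised by Fisher scoring with step-halving and a boundary
guard keeping every fitted probability below 1; repeated episodes within a
participant are handled by a sandwich covariance aggregating score
contributions per cluster, with the G/(G-1) small-sample factor applied by
default (configurable and reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RRFit", "fit_log_binomial", "sandwich_se", "episodes_to_rows"]

_ETA_MAX = -1e-8  # log-probability must stay strictly negative


class SeparationError(RuntimeError):
    pass


@dataclass
class RRFit:
    rr: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    log_rr: float
    se_log_rr: float
    coef: np.ndarray
    vcov: np.ndarray
    n_episodes: int
    n_clusters: int
    converged: bool
    boundary: bool
    small_sample_factor: float


def sandwich_se(score_by_cluster: np.ndarray, bread: np.ndarray, small_sample: bool = True):
    """Cluster sandwich covariance: bread @ meat @ bread.

    ``score_by_cluster`` holds the summed score of each cluster (G x p);
    ``bread`` is the inverse of the information matrix.  The meat is the sum
    of outer products of cluster scores, times G/(G-1) when ``small_sample``.
    """
    S = np.asarray(score_by_cluster, dtype=float)
    G = S.shape[0]
    if G < 2:
        raise ValueError("cluster-robust covariance needs >=2 clusters")
    factor = G / (G - 1.0) if small_sample else 1.0
    meat = factor * (S.T @ S)
    return bread @ meat @ bread


def episodes_to_rows(episodes: pd.DataFrame, sensitivity: bool = False) -> pd.DataFrame:
    """Expand classified CAS days to one row per episode (covered 0/1).

    Unassessable days are excluded; ``sensitivity=True`` additionally drops
    flagged inconsistent-MEMS intervals.
    """
    df = episodes[episodes["status"] != "unassessable"].copy()
    if sensitivity:
        df = df[df["excluded_sensitivity"] == 0]
    df = df.loc[df.index.repeat(df["n_episodes_on_day"])]
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"].to_numpy(),
            "pandemic": df["pandemic"].to_numpy(dtype=int),
            "covered": (df["status"] == "covered").astype(int).to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def fit_log_binomial(
    rows: pd.DataFrame,
    outcome: str = "covered",
    covariate: str = "pandemic",
    cluster: str = "participant_id",
    small_sample: bool = True,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> RRFit:
    """Fit covered ~ period with a log link; exp(slope) is the RR.

    Episode-level rows (one per episode) are expected; with a single binary
    covariate the point estimate equals the ratio of observed coverage
    proportions exactly.
    """
    y = rows[outcome].to_numpy(dtype=float)
    x = rows[covariate].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    groups = rows[cluster].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need >=2 clusters for cluster-robust errors")
    if y.min() == y.max():
        raise SeparationError("outcome is constant; RR undefined")

    beta = np.array([np.log(np.clip(y.mean(), 1e-6, 1 - 1e-6)), 0.0])
    eta = X @ beta
    mu = np.exp(eta)
    dev = _deviance(y, mu)
    boundary = False
    converged = False
    for _ in range(max_iter):
        # Fisher scoring for log link: W = mu/(1-mu), working response
        # z = eta + (y-mu)/mu
        W = mu / np.maximum(1.0 - mu, 1e-10)
        wz = W * (eta + (y - mu) / mu)
        XtWX = (X * W[:, None]).T @ X
        try:
            beta_new = np.linalg.solve(XtWX, X.T @ wz)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        step = beta_new - beta
        lam = 1.0
        for _half in range(40):
            cand = beta + lam * step
            eta_c = X @ cand
            if eta_c.max() >= _ETA_MAX:
                # boundary guard: fitted probability would reach 1
                lam *= 0.5
                boundary = True
                continue
            mu_c = np.exp(eta_c)
            dev_c = _deviance(y, mu_c)
            if dev_c <= dev + 1e-12:
                break
            lam *= 0.5
        else:
            break
        if np.abs(lam * step).max() < tol:
            beta, eta, mu, dev = cand, eta_c, mu_c, dev_c
            converged = True
            break
        beta, eta, mu, dev = cand, eta_c, mu_c, dev_c
    else:
        converged = np.abs(step).max() < 1e-6

    # sandwich: score rows (y - mu)/(1 - mu) * x, summed per cluster
    resid = (y - mu) / np.maximum(1.0 - mu, 1e-10)
    score_rows = X * resid[:, None]
    order = np.argsort(groups, kind="stable")
    sr = score_rows[order]
    g_sorted = np.asarray(groups)[order]
    starts = np.concatenate([[0], 1 + np.flatnonzero(g_sorted[1:] != g_sorted[:-1])])
    S = np.add.reduceat(sr, starts, axis=0)
    W = mu / np.maximum(1.0 - mu, 1e-10)
    bread = np.linalg.inv((X * W[:, None]).T @ X)
    G = starts.size
    vcov = sandwich_se(S, bread, small_sample=small_sample)

    se = float(np.sqrt(vcov[1, 1]))
    b1 = float(beta[1])
    zstat = b1 / se if se > 0 else np.nan
    return RRFit(
        rr=float(np.exp(b1)),
        ci_low=float(np.exp(b1 - 1.959964 * se)),
        ci_high=float(np.exp(b1 + 1.959964 * se)),
        z=zstat,
        p=float(2 * stats.norm.sf(abs(zstat))),
        log_rr=b1,
        se_log_rr=se,
        coef=beta.copy(),
        vcov=vcov,
        n_episodes=int(len(y)),
        n_clusters=int(G),
        converged=bool(converged),
        boundary=boundary,
        small_sample_factor=G / (G - 1.0) if small_sample else 1.0,
    )


def _deviance(y, mu):
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        term0 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return 2.0 * float((term1 + term0).sum())
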