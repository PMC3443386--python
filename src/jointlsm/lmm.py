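"""Maximum-likelihood linear mixed model with random intercept and slope.

This is stage one of the two-stage approach: fit

    y_ij = beta11 + beta12 * t_ij + U1i + U2i * t_ij + eps_ij,
    (U1i, U2i) ~ N2(0, Sigma),  eps_ij ~ N(0, sigma^2),

by maximizing the marginal Gaussian likelihood (ML, not REML — the joint
model's likelihood is ML-based, so the comparison is like with like), and
compute the BLUPs  U_hat_i = Sigma Z_i' V_i^{-1} (y_i - X_i beta_hat)  with
V_i = Z_i Sigma Z_i' + sigma^2 I.

The optimizer works on (log sigma, Cholesky of Sigma with log diagonal) with
beta profiled out by GLS, and groups subjects sharing the same examination
times so each distinct V is factorized once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["LinearGrowthModel", "LMMResults", "fit_lmm",
           "lmm_marginal_loglik"]


def _group_by_times(df: pd.DataFrame):
    """Split subjects into groups with identical measurement-time vectors."""
    groups = []
    by_key: dict = {}
    for sid, sub in df.groupby("id", sort=True):
        t = sub["time"].to_numpy(dtype=float)
        key = tuple(np.round(t, 12))
        by_key.setdefault(key, ([], []))
        by_key[key][0].append(sid)
        by_key[key][1].append(sub["y"].to_numpy(dtype=float))
    for key, (ids, ys) in by_key.items():
        t = np.asarray(key, dtype=float)
        groups.append((t, np.asarray(ids, dtype=object), np.vstack(ys)))
    return groups


def _theta_to_varparams(theta):
    log_sigma, l11, l21, l22 = theta
    L = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
    return np.exp(log_sigma), L @ L.T


def _profile_loglik(theta, groups, return_all=False):
    # Woodbury form throughout: with M = sigma^2 Sigma^{-1} + X'X,
    #   V^{-1} = (I - X M^{-1} X') / sigma^2,
    #   log det V = (n-2) log sigma^2 + log det M + log det Sigma,
    #   BLUP U_hat_i = M^{-1} X' r_i  (stable even as sigma -> 0).
    sigma, Sigma = _theta_to_varparams(theta)
    sig2 = sigma ** 2
    detS = Sigma[0, 0] * Sigma[1, 1] - Sigma[0, 1] ** 2
    Sinv = np.array([[Sigma[1, 1], -Sigma[0, 1]],
                     [-Sigma[0, 1], Sigma[0, 0]]]) / detS
    A = np.zeros((2, 2))
    bvec = np.zeros(2)
    cache = []
    for t, ids, Y in groups:
        X = np.column_stack([np.ones_like(t), t])
        XtX = X.T @ X
        M = sig2 * Sinv + XtX
        Minv = np.linalg.inv(M)
        sign, logdetM = np.linalg.slogdet(M)
        logdet = ((len(t) - 2) * np.log(sig2) + logdetM + np.log(detS))
        W = XtX - XtX @ Minv @ XtX  # sigma^2 * X' V^{-1} X
        A += len(Y) * W
        XtSy = X.T @ Y.sum(axis=0)
        bvec += XtSy - XtX @ Minv @ XtSy
        cache.append((t, ids, Y, X, Minv, logdet))
    beta = np.linalg.solve(A, bvec)  # the 1/sigma^2 factor cancels
    ll = 0.0
    blup_rows = []
    for t, ids, Y, X, Minv, logdet in cache:
        R = Y - X @ beta  # (m, n_t) residuals
        G = R @ X         # (m, 2)
        quad = (np.sum(R * R)
                - np.einsum("ij,jk,ik->", G, Minv, G)) / sig2
        ll += -0.5 * (len(Y) * (len(t) * np.log(2 * np.pi) + logdet)
                      + quad)
        if return_all:
            blup_rows.append((ids, G @ Minv.T))
    if not return_all:
        return ll
    ids_all = np.concatenate([ids for ids, _ in blup_rows])
    U = np.vstack([u for _, u in blup_rows])
    blups = pd.DataFrame({"id": ids_all, "u1": U[:, 0], "u2": U[:, 1]})
    blups.sort_values("id", inplace=True, ignore_index=True)
    return ll, beta, sigma, Sigma, blups


def lmm_marginal_loglik(longitudinal: pd.DataFrame, beta11, beta12, sigma,
                        Sigma) -> float:
    """Marginal Gaussian log-likelihood at arbitrary fixed parameters."""
    Sigma = np.asarray(Sigma, dtype=float)
    sig2 = sigma ** 2
    beta = np.array([beta11, beta12])
    ll = 0.0
    for t, ids, Y in _group_by_times(longitudinal):
        X = np.column_stack([np.ones_like(t), t])
        V = X @ Sigma @ X.T + sig2 * np.eye(len(t))
        Vinv = np.linalg.inv(V)
        _, logdet = np.linalg.slogdet(V)
        R = Y - X @ beta
        quad = np.einsum("ij,jk,ik->", R, Vinv, R)
        ll += -0.5 * (len(Y) * (len(t) * np.log(2 * np.pi) + logdet) + quad)
    return float(ll)


@dataclass
class LMMResults:
    """ML estimates, BLUPs and fit diagnostics of the growth model."""

    beta11: float
    beta12: float
    sigma: float
    Sigma: np.ndarray
    blups: pd.DataFrame
    llf: float
    converged: bool

    def __post_init__(self):
        self._blup_index = self.blups.set_index("id")

    def effects(self, subject_id):
        try:
            row = self._blup_index.loc[subject_id]
        except KeyError:
            raise KeyError(f"unknown subject {subject_id!r}") from None
        return float(row["u1"]), float(row["u2"])

    def fitted_value(self, subject_id, t):
        """BLUP-based fitted trajectory for one subject at time(s) t."""
        u1, u2 = self.effects(subject_id)
        t = np.asarray(t, dtype=float)
        out = self.beta11 + u1 + (self.beta12 + u2) * t
        return out if out.ndim else float(out)

    def fitted_values(self, subject_ids, t):
        """Vectorized fitted values: one row per subject, one column per t."""
        U = self._blup_index.loc[list(subject_ids), ["u1", "u2"]].to_numpy()
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return (self.beta11 + U[:, 0:1]
                + (self.beta12 + U[:, 1:2]) * t)

    def summary(self) -> str:
        lines = ["Linear growth mixed model (ML)",
                 f"  subjects: {len(self.blups)}   loglik: {self.llf:.4f}"
                 f"   converged: {self.converged}",
                 f"  beta11 (intercept, mm):      {self.beta11:10.4f}",
                 f"  beta12 (slope, mm/year):     {self.beta12:10.4f}",
                 f"  sigma  (residual SD, mm):    {self.sigma:10.4f}",
                 f"  Sigma11, Sigma12, Sigma22:   {self.Sigma[0, 0]:.4f}, "
                 f"{self.Sigma[0, 1]:.4f}, {self.Sigma[1, 1]:.4f}"]
        return "\n".join(lines)


class LinearGrowthModel:
    """Random-intercept-and-slope growth model for long-format data.

    Parameters
    ----------
    longitudinal
        DataFrame with columns ``id``, ``time``, ``y``.
    """

    def __init__(self, longitudinal: pd.DataFrame):
        self.longitudinal = longitudinal[["id", "time", "y"]].copy()
        counts = self.longitudinal.groupby("id").size()
        if len(counts) < 2:
            raise ValueError("need at least 2 subjects")
        self._any_repeat = (counts >= 2).any()

    @classmethod
    def from_joint_data(cls, data) -> "LinearGrowthModel":
        return cls(data.longitudinal)

    def _start(self):
        df = self.longitudinal
        # per-subject OLS lines where possible, population OLS otherwise
        t, y = df["time"].to_numpy(), df["y"].to_numpy()
        if np.ptp(t) > 0:
            beta = np.polyfit(t, y, 1)[::-1]
        else:
            beta = np.array([y.mean(), 0.0])
        ints, slopes = [], []
        for _, sub in df.groupby("id"):
            tt = sub["time"].to_numpy()
            if len(sub) >= 2 and np.ptp(tt) > 0:
                c = np.polyfit(tt, sub["y"].to_numpy(), 1)
                ints.append(c[1])
                slopes.append(c[0])
        vi = np.var(ints) if len(ints) >= 2 else 1.0
        vs = np.var(slopes) if len(slopes) >= 2 else 0.1
        resid = y - beta[0] - beta[1] * t
        s0 = max(np.std(resid) / 2, 1e-2)
        return np.array([np.log(s0), 0.5 * np.log(max(vi, 1e-2)), 0.0,
                         0.5 * np.log(max(vs, 1e-3))])

    def fit(self, tol: float = 1e-8) -> LMMResults:
        groups = _group_by_times(self.longitudinal)
        if not self._any_repeat:
            # every subject measured once: sigma and Sigma not separable
            # (and the slope may be unidentified); report non-convergence
            # with a defensible pooled description rather than fail silently
            try:
                ll, beta, sigma, Sigma, blups = _profile_loglik(
                    self._start(), groups, return_all=True)
            except np.linalg.LinAlgError:
                y = self.longitudinal["y"].to_numpy(dtype=float)
                ids = np.sort(self.longitudinal["id"].unique())
                beta = np.array([y.mean(), 0.0])
                sigma = max(y.std(), 1e-6)
                Sigma = 1e-6 * np.eye(2)
                blups = pd.DataFrame({"id": ids, "u1": 0.0, "u2": 0.0})
                ll = np.nan
            return LMMResults(beta[0], beta[1], sigma, Sigma, blups, ll,
                              converged=False)
        def negll(th):
            try:
                with np.errstate(all="ignore"):
                    return -_profile_loglik(th, groups)
            except np.linalg.LinAlgError:
                return 1e10

        res = optimize.minimize(
            negll, self._start(),
            method="L-BFGS-B", options={"ftol": tol, "gtol": 1e-7,
                                        "maxiter": 500})
        if not res.success or not np.isfinite(res.fun):
            # robust fallback for ill-conditioned corners (e.g. nearly
            # noiseless data, where sigma-hat collapses toward zero)
            res2 = optimize.minimize(negll, res.x, method="Nelder-Mead",
                                     options={"xatol": 1e-10,
                                              "fatol": 1e-10,
                                              "maxiter": 4000})
            if res2.fun <= res.fun:
                res = res2
        with np.errstate(all="ignore"):
            ll, beta, sigma, Sigma, blups = _profile_loglik(
                res.x, groups, return_all=True)
        return LMMResults(beta[0], beta[1], sigma, Sigma, blups, float(ll),
                          converged=bool(res.success))


def fit_lmm(longitudinal: pd.DataFrame, tol: float = 1e-8) -> LMMResults:
    """Convenience wrapper: build and fit :class:`LinearGrowthModel`."""
    return LinearGrowthModel(longitudinal).fit(tol=tol)
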