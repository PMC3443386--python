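"""Classical shared random effects joint model fitted by maximum likelihood.

The marginal likelihood integrates, for each subject, the product of the
Gaussian longitudinal density, the right-censored survival density (with the
closed-form integrated hazard of :mod:`jointlsm.core`) and the bivariate
normal random-effects density over U_i = (U1i, U2i):

    L(theta) = prod_i  int  p(y_i | U) * p(T_i, delta_i | U) * phi(U; 0, Sigma) dU.

Each 2-D integral is computed by adaptive Gauss-Hermite quadrature: the
integrand's mode is found by Newton iteration (the log-integrand is strictly
concave), nodes are recentered at the mode and rescaled by the Cholesky
factor of the inverse negative Hessian.  Nine points per dimension are ample
because rare events leave the subject-level posteriors near-Gaussian.

Optimization runs on an unconstrained parameterization (log sigma, log
lambda, Cholesky of Sigma with log diagonal, free beta and alpha); standard
errors come from the inverse central-finite-difference Hessian at the MLE,
mapped to the natural scale by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .core import JointParams
from .data import JointData
from .lmm import LinearGrowthModel

__all__ = ["JointModel", "JointResults", "marginal_loglik", "SubjectStats"]

ASSOCIATIONS = ("intercept", "slope", "current")
LOG2PI = np.log(2 * np.pi)

# working-scale unit for association parameters: alpha moves in ~0.05 steps,
# matching its curvature, so quasi-Newton line searches do not probe the
# hazard's exponential cliff on their first trial
ALPHA_SCALE = 0.05


@dataclass
class SubjectStats:
    """Per-subject sufficient statistics of a linear-trajectory joint dataset."""

    ids: np.ndarray
    n: np.ndarray      # measurements per subject
    St: np.ndarray     # sum t
    Stt: np.ndarray    # sum t^2
    Sy: np.ndarray     # sum y
    Sty: np.ndarray    # sum t*y
    Syy: np.ndarray    # sum y^2
    T: np.ndarray      # observed time
    delta: np.ndarray  # event indicator

    @classmethod
    def from_joint_data(cls, data: JointData) -> "SubjectStats":
        lon = data.longitudinal
        sur = data.survival
        g = lon.groupby("id", sort=True)
        t = lon["time"].to_numpy(dtype=float)
        y = lon["y"].to_numpy(dtype=float)
        agg = pd.DataFrame({
            "id": lon["id"], "n": 1.0, "St": t, "Stt": t * t,
            "Sy": y, "Sty": t * y, "Syy": y * y,
        }).groupby("id", sort=True).sum()
        sur = sur.set_index("id").loc[agg.index]
        return cls(ids=agg.index.to_numpy(),
                   n=agg["n"].to_numpy(), St=agg["St"].to_numpy(),
                   Stt=agg["Stt"].to_numpy(), Sy=agg["Sy"].to_numpy(),
                   Sty=agg["Sty"].to_numpy(), Syy=agg["Syy"].to_numpy(),
                   T=sur["time"].to_numpy(dtype=float),
                   delta=sur["event"].to_numpy(dtype=float))

    @property
    def n_subjects(self) -> int:
        return len(self.T)


def _logf(b, T):
    """log[(exp(bT)-1)/b], stable for any sign and magnitude of b.

    Both signs reduce to max(bT, 0) + log1p(-exp(-|bT|)) - log|b|; a
    series handles |bT| near zero.
    """
    b = np.asarray(b, dtype=float)
    T = np.asarray(T, dtype=float)
    bT = b * T
    small = np.abs(bT) < 1e-6
    absbT = np.where(small, 1.0, np.abs(bT))
    absb = np.where(small, 1.0, np.abs(b))
    lf = np.maximum(bT, 0.0) + np.log1p(-np.exp(-absbT)) - np.log(absb)
    series = np.log(np.maximum(T, 1e-300)) + np.log1p(bT / 2 + bT ** 2 / 6)
    return np.where(small, series, lf)


def _f012(b, T):
    """f(b) = (exp(bT)-1)/b and its first two b-derivatives (series near 0)."""
    b = np.asarray(b, dtype=float)
    T = np.asarray(T, dtype=float)
    small = np.abs(b) < 1e-5
    bs = np.where(small, 1.0, b)
    # cap the exponent: beyond this the integrated hazard is astronomically
    # large anyway and only its finiteness matters to the Newton search
    ebT = np.exp(np.minimum(b * T, 100.0))
    f_r = (ebT - 1.0) / bs
    fp_r = (ebT * (b * T - 1.0) + 1.0) / bs ** 2
    # from b*f = exp(bT)-1:  f + b f' = T exp(bT),  2f' + b f'' = T^2 exp(bT)
    fpp_r = (T ** 2 * ebT - 2.0 * fp_r) / bs
    bT = b * T
    f_s = T * (1.0 + bT / 2 + bT ** 2 / 6 + bT ** 3 / 24)
    fp_s = T ** 2 * (0.5 + bT / 3 + bT ** 2 / 8 + bT ** 3 / 30)
    fpp_s = T ** 3 * (1.0 / 3 + bT / 4 + bT ** 2 / 10 + bT ** 3 / 36)
    return (np.where(small, f_s, f_r), np.where(small, fp_s, fp_r),
            np.where(small, fpp_s, fpp_r))


class _NumericParams:
    """Scalar parameter bundle used by the vectorized likelihood kernels."""

    __slots__ = ("beta11", "beta12", "sigma", "Sigma", "log_lambda",
                 "alpha1", "alpha2", "alpha3", "center", "Sinv", "logdetS")

    def __init__(self, beta11, beta12, sigma, Sigma, log_lambda,
                 alpha1, alpha2, alpha3, center):
        self.beta11, self.beta12, self.sigma = beta11, beta12, sigma
        self.Sigma = np.asarray(Sigma, dtype=float)
        self.log_lambda = log_lambda
        self.alpha1, self.alpha2, self.alpha3 = alpha1, alpha2, alpha3
        self.center = center
        det = (self.Sigma[0, 0] * self.Sigma[1, 1]
               - self.Sigma[0, 1] ** 2)
        if det <= 0 or self.Sigma[0, 0] <= 0:
            raise ValueError("Sigma must be positive definite")
        self.Sinv = (np.array([[self.Sigma[1, 1], -self.Sigma[0, 1]],
                               [-self.Sigma[0, 1], self.Sigma[0, 0]]]) / det)
        self.logdetS = np.log(det)

    @classmethod
    def from_joint_params(cls, p: JointParams) -> "_NumericParams":
        if not p.is_linear:
            raise ValueError("joint likelihood requires a linear trajectory")
        return cls(p.beta11, p.beta12, p.sigma, p.Sigma[:2, :2], p.log_lambda,
                   p.alpha1, p.alpha2, p.alpha3, p.center)


def _long_terms(stats: SubjectStats, p: _NumericParams):
    """Residual sufficient statistics of the longitudinal contribution."""
    Se = stats.Sy - stats.n * p.beta11 - p.beta12 * stats.St
    Ste = stats.Sty - p.beta11 * stats.St - p.beta12 * stats.Stt
    Q0 = (stats.Syy - 2 * p.beta11 * stats.Sy - 2 * p.beta12 * stats.Sty
          + p.beta11 ** 2 * stats.n + 2 * p.beta11 * p.beta12 * stats.St
          + p.beta12 ** 2 * stats.Stt)
    return Se, Ste, Q0


def _log_integrand(stats: SubjectStats, p: _NumericParams, u1, u2):
    """log[ p(y|u) p(T,delta|u) phi(u) ] for broadcastable u arrays."""
    Se, Ste, Q0 = _long_terms(stats, p)
    sig2 = p.sigma ** 2

    def col(x):
        x = np.asarray(x, dtype=float)
        return x[:, None] if np.ndim(u1) > 1 else x

    SS = (col(Q0) - 2 * (u1 * col(Se) + u2 * col(Ste))
          + u1 ** 2 * col(stats.n) + 2 * u1 * u2 * col(stats.St)
          + u2 ** 2 * col(stats.Stt))
    ll = -0.5 * col(stats.n) * np.log(2 * np.pi * sig2) - SS / (2 * sig2)
    # random-effects density
    q = (p.Sinv[0, 0] * u1 ** 2 + 2 * p.Sinv[0, 1] * u1 * u2
         + p.Sinv[1, 1] * u2 ** 2)
    ll += -LOG2PI - 0.5 * p.logdetS - 0.5 * q
    # survival: delta*log h(T) - H(T)
    T, delta = col(stats.T), col(stats.delta)
    a = ((p.alpha1 + p.alpha3) * u1 + p.alpha2 * u2
         + p.alpha3 * (p.beta11 - p.center))
    b = p.alpha3 * (p.beta12 + u2)
    lpT = p.log_lambda + a + b * T  # log h(T) = loglam + a + bT
    # survival term assembled in log space: H stays consistent with the
    # event term at any trial parameters (finite, monotone, no overflow)
    logH = p.log_lambda + a + _logf(b, T)
    ll += delta * lpT - np.exp(np.minimum(logH, 700.0))
    return ll


def _posterior_modes(stats: SubjectStats, p: _NumericParams, u0=None,
                     tol=1e-9, max_iter=60):
    """Vectorized Newton search for each subject's posterior mode.

    Returns modes (n, 2) and the negative Hessian components (g11, g12, g22),
    all elementwise arrays.  The log-integrand is strictly concave (Gaussian
    terms plus the concave -H), so undamped Newton converges.
    """
    np_err = np.seterr(over="ignore", under="ignore", invalid="ignore",
                       divide="ignore")
    Se, Ste, Q0 = _long_terms(stats, p)
    sig2 = p.sigma ** 2
    n, St, Stt, T, delta = stats.n, stats.St, stats.Stt, stats.T, stats.delta
    a13, a2, a3 = p.alpha1 + p.alpha3, p.alpha2, p.alpha3
    if u0 is None:
        # longitudinal-only posterior mean as starting point
        g11 = n / sig2 + p.Sinv[0, 0]
        g12 = St / sig2 + p.Sinv[0, 1]
        g22 = Stt / sig2 + p.Sinv[1, 1]
        det = g11 * g22 - g12 ** 2
        r1, r2 = Se / sig2, Ste / sig2
        u1 = (g22 * r1 - g12 * r2) / det
        u2 = (g11 * r2 - g12 * r1) / det
    else:
        u1, u2 = u0[:, 0].copy(), u0[:, 1].copy()
    for _ in range(max_iter):
        aa = a13 * u1 + a2 * u2 + a3 * (p.beta11 - p.center)
        b = a3 * (p.beta12 + u2)
        f, fp, fpp = _f012(b, T)
        lam_ea = np.exp(np.minimum(p.log_lambda + aa, 150.0))
        Hval = lam_ea * f
        dH1 = Hval * a13
        dH2 = Hval * a2 + lam_ea * fp * a3
        g1 = ((Se - n * u1 - St * u2) / sig2
              - (p.Sinv[0, 0] * u1 + p.Sinv[0, 1] * u2)
              + delta * a13 - dH1)
        g2 = ((Ste - St * u1 - Stt * u2) / sig2
              - (p.Sinv[0, 1] * u1 + p.Sinv[1, 1] * u2)
              + delta * (a2 + a3 * T) - dH2)
        # negative Hessian (positive definite)
        h11 = n / sig2 + p.Sinv[0, 0] + Hval * a13 ** 2
        h12 = (St / sig2 + p.Sinv[0, 1]
               + a13 * (Hval * a2 + lam_ea * fp * a3))
        h22 = (Stt / sig2 + p.Sinv[1, 1] + Hval * a2 ** 2
               + 2 * a2 * lam_ea * fp * a3 + lam_ea * fpp * a3 ** 2)
        det = h11 * h22 - h12 ** 2
        s1 = (h22 * g1 - h12 * g2) / det
        s2 = (h11 * g2 - h12 * g1) / det
        # trust region: cap the step so overshoot cannot blow up exp(b*T)
        norm = np.hypot(s1, s2)
        scale = np.where(norm > 4.0, 4.0 / np.maximum(norm, 4.0), 1.0)
        u1 = u1 + s1 * scale
        u2 = u2 + s2 * scale
        if max(np.abs(g1).max(initial=0), np.abs(g2).max(initial=0)) < tol:
            break
    aa = a13 * u1 + a2 * u2 + a3 * (p.beta11 - p.center)
    b = a3 * (p.beta12 + u2)
    f, fp, fpp = _f012(b, T)
    lam_ea = np.exp(np.minimum(p.log_lambda + aa, 150.0))
    Hval = lam_ea * f
    h11 = n / sig2 + p.Sinv[0, 0] + Hval * a13 ** 2
    h12 = St / sig2 + p.Sinv[0, 1] + a13 * (Hval * a2 + lam_ea * fp * a3)
    h22 = (Stt / sig2 + p.Sinv[1, 1] + Hval * a2 ** 2
           + 2 * a2 * lam_ea * fp * a3 + lam_ea * fpp * a3 ** 2)
    np.seterr(**np_err)
    return np.column_stack([u1, u2]), h11, h12, h22


def _agq_loglik(stats: SubjectStats, p: _NumericParams, quad_points: int,
                warm=None):
    """Marginal log-likelihood by mode-centered, curvature-scaled quadrature."""
    modes, g11, g12, g22 = _posterior_modes(stats, p, u0=warm)
    np_err = np.seterr(over="ignore", under="ignore", invalid="ignore",
                       divide="ignore")
    det = g11 * g22 - g12 ** 2
    bad = ~((det > 0) & (g11 > 0) & np.isfinite(det)
            & np.isfinite(modes).all(axis=1))
    if np.any(bad):
        # capped arithmetic can corrupt the survival part of the curvature at
        # extreme trial parameters; fall back to the always-PD
        # longitudinal+prior curvature (and its mode) for affected subjects —
        # the nodes are then merely less well adapted, the quadrature stays
        # valid and the optimizer backtracks out of this region anyway
        sig2 = p.sigma ** 2
        g11 = np.where(bad, stats.n / sig2 + p.Sinv[0, 0], g11)
        g12 = np.where(bad, stats.St / sig2 + p.Sinv[0, 1], g12)
        g22 = np.where(bad, stats.Stt / sig2 + p.Sinv[1, 1], g22)
        det = g11 * g22 - g12 ** 2
        Se, Ste, _ = _long_terms(stats, p)
        r1, r2 = Se / sig2, Ste / sig2
        m1 = (g22 * r1 - g12 * r2) / det
        m2 = (g11 * r2 - g12 * r1) / det
        modes = np.column_stack([np.where(bad, m1, modes[:, 0]),
                                 np.where(bad, m2, modes[:, 1])])
    # Cholesky of the inverse negative Hessian
    c11, c12, c22 = g22 / det, -g12 / det, g11 / det
    l11 = np.sqrt(c11)
    l21 = c12 / l11
    l22 = np.sqrt(c22 - l21 ** 2)
    z, w = np.polynomial.hermite.hermgauss(quad_points)
    z1 = np.repeat(z, quad_points)
    z2 = np.tile(z, quad_points)
    logw = (np.log(np.repeat(w, quad_points))
            + np.log(np.tile(w, quad_points)) + z1 ** 2 + z2 ** 2)
    U1 = modes[:, 0:1] + np.sqrt(2.0) * l11[:, None] * z1
    U2 = modes[:, 1:2] + np.sqrt(2.0) * (l21[:, None] * z1
                                         + l22[:, None] * z2)
    with np.errstate(over="ignore", under="ignore"):
        g = _log_integrand(stats, p, U1, U2)
        ll_i = (np.log(2.0) + np.log(l11) + np.log(l22)
                + logsumexp(g + logw, axis=1))
    np.seterr(**np_err)
    # a subject whose likelihood underflows to 0 at these (extreme) trial
    # parameters contributes a large finite penalty so optimizers backtrack
    ll_i = np.where(np.isneginf(ll_i), -1e10, ll_i)
    if not np.all(np.isfinite(ll_i)):
        bad = stats.ids[~np.isfinite(ll_i)]
        raise FloatingPointError(
            f"quadrature failed for subject(s) {bad.tolist()}")
    return float(ll_i.sum()), modes


def marginal_loglik(params: JointParams, data: JointData,
                    quad_points: int = 9) -> float:
    """Marginal joint log-likelihood at fixed parameters."""
    if quad_points < 3:
        raise ValueError("quad_points must be >= 3")
    stats_ = SubjectStats.from_joint_data(data)
    p = _NumericParams.from_joint_params(params)
    ll, _ = _agq_loglik(stats_, p, quad_points)
    return ll


_PARAM_ORDER = ["beta11", "beta12", "sigma", "Sigma11", "Sigma12", "Sigma22",
                "log_lambda", "alpha1", "alpha2", "alpha3"]


@dataclass
class JointResults:
    """MLE of the shared random effects joint model."""

    params: JointParams
    ses: dict | None
    llf: float
    converged: bool
    eb_effects: pd.DataFrame
    association: tuple
    cov_params: np.ndarray | None = None
    free_names: list = field(default_factory=list)
    n_subjects: int = 0
    n_events: int = 0

    def estimate(self, name: str) -> float:
        return self.params.to_dict()[name]

    def wald_interval(self, param: str, level: float = 0.95):
        """estimate +/- z_{(1+level)/2} * SE on the natural scale."""
        if self.ses is None or param not in self.ses:
            raise ValueError(f"no standard error available for {param!r}")
        if not 0 <= level < 1:
            raise ValueError("level must be in [0, 1)")
        z = stats.norm.ppf(0.5 + level / 2)
        est = self.estimate(param)
        se = self.ses[param]
        return est - z * se, est + z * se

    def summary(self) -> str:
        d = self.params.to_dict()
        lines = [
            "Shared random effects joint model (MLE, adaptive Gauss-Hermite)",
            f"  subjects: {self.n_subjects}   events: {self.n_events}   "
            f"loglik: {self.llf:.4f}   converged: {self.converged}",
            f"  association: {'+'.join(self.association)}",
            f"  {'parameter':<12}{'estimate':>12}{'SE':>12}"
            f"{'95% CI':>26}",
        ]
        for name in _PARAM_ORDER:
            if name.startswith("alpha") and name not in [
                    f"alpha{i}" for i in self._free_alpha_idx()]:
                lines.append(f"  {name:<12}{d[name]:>12.4f}"
                             f"{'(fixed)':>12}{'':>26}")
                continue
            if self.ses is not None and name in self.ses:
                lo, hi = self.wald_interval(name)
                lines.append(f"  {name:<12}{d[name]:>12.4f}"
                             f"{self.ses[name]:>12.4f}"
                             f"{f'({lo:.4f}, {hi:.4f})':>26}")
            else:
                lines.append(f"  {name:<12}{d[name]:>12.4f}{'--':>12}{'':>26}")
        return "\n".join(lines)

    def _free_alpha_idx(self):
        return [ASSOCIATIONS.index(a) + 1 for a in self.association]

    def to_frame(self) -> pd.DataFrame:
        """Flat (parameter, estimate, SE, CI_low, CI_high, fixed) table."""
        d = self.params.to_dict()
        rows = []
        free_alphas = {f"alpha{i}" for i in self._free_alpha_idx()}
        for name in _PARAM_ORDER:
            fixed = name.startswith("alpha") and name not in free_alphas
            se = lo = hi = np.nan
            if not fixed and self.ses is not None and name in self.ses:
                se = self.ses[name]
                lo, hi = self.wald_interval(name)
            rows.append({"parameter": name, "estimate": d[name], "SE": se,
                         "CI_low": lo, "CI_high": hi, "fixed": fixed})
        return pd.DataFrame(rows)


class JointModel:
    """Shared random effects joint model for a :class:`JointData` dataset.

    Parameters
    ----------
    data
        Validated joint dataset.
    association
        Nonempty subset of {"intercept", "slope", "current"}: which
        association parameters (alpha1, alpha2, alpha3) are free; the rest
        are fixed at 0.
    center
        Centering constant c (mm) of the current-value covariate.  Fixed,
        not estimated; 47.15 mm by default (the linear-truth process mean
        over a 10-year follow-up).
    """

    def __init__(self, data: JointData, association=("current",),
                 center: float = 47.15):
        association = tuple(association)
        if not association or any(a not in ASSOCIATIONS for a in association):
            raise ValueError(f"association must be a nonempty subset of "
                             f"{ASSOCIATIONS}")
        self.data = data
        self.association = association
        self.center = float(center)
        self.stats = SubjectStats.from_joint_data(data)
        if self.stats.delta.sum() < 1:
            raise ValueError("need at least one event")
        self._free_alpha = [a in association for a in ASSOCIATIONS]

    # ---- unconstrained parameterization -------------------------------
    def _pack(self, p: _NumericParams) -> np.ndarray:
        L = np.linalg.cholesky(p.Sigma)
        theta = [p.beta11, p.beta12, np.log(p.sigma), np.log(L[0, 0]),
                 L[1, 0], np.log(L[1, 1]), p.log_lambda]
        for free, a in zip(self._free_alpha,
                           (p.alpha1, p.alpha2, p.alpha3)):
            if free:
                theta.append(a / ALPHA_SCALE)
        return np.array(theta)

    def _unpack(self, theta: np.ndarray) -> _NumericParams:
        b11, b12, ls, l11, l21, l22, loglam = theta[:7]
        L = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
        alphas = [0.0, 0.0, 0.0]
        k = 7
        for i, free in enumerate(self._free_alpha):
            if free:
                alphas[i] = theta[k] * ALPHA_SCALE
                k += 1
        return _NumericParams(b11, b12, np.exp(ls), L @ L.T, loglam,
                              *alphas, self.center)

    def free_param_names(self):
        names = ["beta11", "beta12", "log_sigma", "chol11", "chol21",
                 "chol22", "log_lambda"]
        names += [f"alpha{i + 1}" for i, f in enumerate(self._free_alpha)
                  if f]
        return names

    # ---- likelihood ----------------------------------------------------
    def loglik(self, params: JointParams, quad_points: int = 9) -> float:
        p = _NumericParams.from_joint_params(params)
        ll, _ = _agq_loglik(self.stats, p, quad_points)
        return ll

    def _negll(self, theta, quad_points):
        # stateless on purpose: each evaluation re-finds the subject modes
        # from the longitudinal-only posterior mean, so the objective is a
        # deterministic function of theta (quasi-Newton methods require it)
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                p = self._unpack(theta)
            ll, _ = _agq_loglik(self.stats, p, quad_points)
        except (FloatingPointError, ValueError, np.linalg.LinAlgError):
            return 1e10
        return -ll

    def _start_theta(self):
        lmm = LinearGrowthModel(self.data.longitudinal).fit()
        lam0 = self.stats.delta.sum() / self.stats.T.sum()
        Sigma0 = lmm.Sigma
        if np.linalg.eigvalsh(Sigma0).min() <= 1e-8:
            Sigma0 = Sigma0 + 1e-6 * np.eye(2)
        p0 = _NumericParams(lmm.beta11, lmm.beta12, lmm.sigma, Sigma0,
                            np.log(lam0), 0.0, 0.0, 0.0, self.center)
        return self._pack(p0)

    def fit(self, start: JointParams | None = None, quad_points: int = 9,
            compute_se: bool = True, fd_eps: float = 1e-6) -> JointResults:
        """Maximize the marginal likelihood; SEs from the FD Hessian."""
        if start is not None:
            theta0 = self._pack(_NumericParams.from_joint_params(start))
        else:
            theta0 = self._start_theta()
        opts = {"ftol": 1e-12, "gtol": 1e-6, "eps": fd_eps,
                "maxiter": 500, "maxls": 60}
        res = optimize.minimize(
            self._negll, theta0, args=(quad_points,), method="L-BFGS-B",
            options=opts)
        converged = bool(res.success)
        if not converged:
            # restart with a fresh quasi-Newton state: line searches on the
            # flat finite-difference plateau often trip the first run; a
            # restart that cannot improve the objective means we are at the
            # optimum to working precision
            res2 = optimize.minimize(
                self._negll, res.x, args=(quad_points,), method="L-BFGS-B",
                options=opts)
            if res2.fun <= res.fun:
                improvement = res.fun - res2.fun
                res = res2
                converged = bool(res2.success) or improvement < 1e-5
        if res.fun >= 1e9:  # stranded on the inadmissible-region penalty
            converged = False
        theta = res.x
        p = self._unpack(theta)
        ll = -res.fun
        modes, *_ = _posterior_modes(self.stats, p)
        eb = pd.DataFrame({"id": self.stats.ids, "u1": modes[:, 0],
                           "u2": modes[:, 1]})
        Sig = p.Sigma
        lo = np.linalg.eigvalsh(Sig).min()
        if lo <= 0:  # ridge away numerically semidefinite estimates
            Sig = Sig + (abs(lo) + 1e-10) * np.eye(2)
            p = _NumericParams(p.beta11, p.beta12, p.sigma, Sig,
                               p.log_lambda, p.alpha1, p.alpha2, p.alpha3,
                               p.center)
        params = JointParams(
            beta11=p.beta11, beta12=p.beta12, sigma=p.sigma,
            Sigma=p.Sigma, log_lambda=p.log_lambda, alpha1=p.alpha1,
            alpha2=p.alpha2, alpha3=p.alpha3, center=self.center)
        ses = cov_nat = None
        if compute_se:
            for rel_step in (1e-4, 5e-4, 2e-3):
                ses, cov_nat = self._standard_errors(theta, quad_points,
                                                     rel_step=rel_step)
                if ses is not None:
                    break
        return JointResults(
            params=params, ses=ses, llf=ll, converged=converged,
            eb_effects=eb, association=self.association,
            cov_params=cov_nat, free_names=self.free_param_names(),
            n_subjects=self.stats.n_subjects,
            n_events=int(self.stats.delta.sum()))

    def _standard_errors(self, theta, quad_points, rel_step=1e-4):
        """Central-FD Hessian in the working space; delta method to natural."""
        f = lambda th: -self._negll(th, quad_points)
        k = len(theta)
        h = rel_step * np.maximum(np.abs(theta), 1.0)
        H = np.zeros((k, k))
        f0 = f(theta)
        for i in range(k):
            ei = np.zeros(k); ei[i] = h[i]
            H[i, i] = (f(theta + ei) + f(theta - ei) - 2 * f0) / h[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
        info = -H
        d_info = np.diag(info)
        if np.any(d_info <= 0):
            return None, None
        try:
            cov_theta = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return None, None
        d_cov = np.diag(cov_theta)
        # for a PD information matrix, diag(inv(I)) >= 1/diag(I); a
        # violation means the finite-difference Hessian is numerically
        # corrupted and its inverse untrustworthy
        if np.any(d_cov <= 0) or np.any(d_cov < (1 - 1e-6) / d_info):
            return None, None

        def natural(th):
            p = self._unpack(th)
            out = [p.beta11, p.beta12, p.sigma, p.Sigma[0, 0], p.Sigma[0, 1],
                   p.Sigma[1, 1], p.log_lambda]
            out += [a for a, fr in zip((p.alpha1, p.alpha2, p.alpha3),
                                       self._free_alpha) if fr]
            return np.array(out)

        J = optimize.approx_fprime(theta, natural, 1e-7)
        cov_nat = J @ cov_theta @ J.T
        names = ["beta11", "beta12", "sigma", "Sigma11", "Sigma12",
                 "Sigma22", "log_lambda"]
        names += [f"alpha{i + 1}" for i, fr in enumerate(self._free_alpha)
                  if fr]
        diag = np.diag(cov_nat)
        if np.any(diag < 0):
            return None, None
        ses = dict(zip(names, np.sqrt(diag)))
        return ses, cov_nat
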