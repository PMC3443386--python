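"""Core model quantities shared by every fitter.

The model couples a linear (optionally quadratic) mixed-effects growth model

    m_i(t) = beta11 + beta12*t + beta13*t^2 + U1i + U2i*t + U3i*t^2

with a proportional-hazards survival model whose constant baseline hazard
``lambda`` is multiplied by a log-linear function of the subject's random
intercept, random slope and current underlying (error-free) value:

    h_i(t) = lambda * exp(alpha1*U1i + alpha2*U2i + alpha3*(m_i(t) - c))

``c`` is a fixed centering constant so that ``lambda`` is the hazard for a
subject whose underlying value equals ``c``; by default it is the mean of the
population trajectory over a 10-year follow-up, c = beta11 + 5*beta12.

For a linear trajectory the integrated hazard has the closed form

    H_i(t) = lambda * exp(a) * (exp(b*t) - 1) / b,
    a = alpha1*U1i + alpha2*U2i + alpha3*(beta11 + U1i - c),
    b = alpha3*(beta12 + U2i),

with a second-order series continuation when b is numerically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LongitudinalRecord",
    "SurvivalRecord",
    "SubjectEffects",
    "JointParams",
    "trajectory",
    "hazard",
    "cumulative_hazard",
    "piecewise_cumulative_hazard",
    "survival_loglik_contribution",
    "longitudinal_loglik_contribution",
]

#: |b| below which the series branch of the integrated hazard is used.
B_SWITCH_TOL = 1e-8


@dataclass(frozen=True)
class LongitudinalRecord:
    """One longitudinal measurement: subject, years since first exam, mm."""

    subject_id: object
    time: float
    response: float

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"time must be finite and >= 0, got {self.time}")
        if not np.isfinite(self.response):
            raise ValueError("response must be finite")


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-subject observed follow-up time (years) and event indicator."""

    subject_id: object
    observed_time: float
    event: int

    def __post_init__(self):
        if not np.isfinite(self.observed_time) or self.observed_time <= 0:
            raise ValueError("observed_time must be finite and > 0")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class SubjectEffects:
    """A subject's random-effect deviations (intercept, slope[, quadratic])."""

    u1: float
    u2: float
    u3: float = 0.0

    def __post_init__(self):
        for v in (self.u1, self.u2, self.u3):
            if not np.all(np.isfinite(v)):
                raise ValueError("random effects must be finite")


def _default_center(beta11, beta12):
    # mean of the linear population trajectory over a 10-year follow-up
    return beta11 + 5.0 * beta12


@dataclass
class JointParams:
    """Full parameter set of the joint model.

    Parameters
    ----------
    beta11, beta12, beta13
        Fixed effects of the growth model (mm, mm/year, mm/year^2).
        ``beta13 = 0`` gives the linear model.
    sigma
        Residual (within-subject measurement error) SD in mm.
    Sigma
        q x q positive-definite between-subject covariance of the random
        effects, q in {2, 3}.
    log_lambda
        Log constant baseline hazard (per year).
    alpha1, alpha2, alpha3
        Association of the hazard with the random intercept, random slope
        and current underlying value.
    center
        Centering constant c (mm) for the current-value covariate; defaults
        to beta11 + 5*beta12.
    """

    beta11: float
    beta12: float
    sigma: float
    Sigma: np.ndarray
    log_lambda: float
    beta13: float = 0.0
    alpha1: float = 0.0
    alpha2: float = 0.0
    alpha3: float = 0.0
    center: float | None = None

    def __post_init__(self):
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.center is None:
            self.center = _default_center(self.beta11, self.beta12)
        scalars = [self.beta11, self.beta12, self.beta13, self.sigma,
                   self.log_lambda, self.alpha1, self.alpha2, self.alpha3,
                   self.center]
        if not all(np.isfinite(v) for v in scalars):
            raise ValueError("all parameters must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        S = self.Sigma
        if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] not in (2, 3):
            raise ValueError("Sigma must be 2x2 or 3x3")
        if not np.allclose(S, S.T):
            raise ValueError("Sigma must be symmetric")
        if not np.all(np.isfinite(S)):
            raise ValueError("Sigma must be finite")
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValueError("Sigma must be positive definite")

    @property
    def q(self) -> int:
        return self.Sigma.shape[0]

    @property
    def is_linear(self) -> bool:
        return self.beta13 == 0.0

    def to_dict(self) -> dict:
        """Flat key-value serialization (Sigma by upper-triangle entries)."""
        d = {
            "beta11": self.beta11, "beta12": self.beta12,
            "beta13": self.beta13, "sigma": self.sigma,
            "log_lambda": self.log_lambda, "alpha1": self.alpha1,
            "alpha2": self.alpha2, "alpha3": self.alpha3,
            "center": self.center,
        }
        q = self.q
        for i in range(q):
            for j in range(i, q):
                d[f"Sigma{i + 1}{j + 1}"] = float(self.Sigma[i, j])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "JointParams":
        q = 3 if "Sigma33" in d else 2
        S = np.zeros((q, q))
        for i in range(q):
            for j in range(i, q):
                S[i, j] = S[j, i] = d[f"Sigma{i + 1}{j + 1}"]
        return cls(
            beta11=d["beta11"], beta12=d["beta12"],
            beta13=d.get("beta13", 0.0), sigma=d["sigma"], Sigma=S,
            log_lambda=d["log_lambda"], alpha1=d.get("alpha1", 0.0),
            alpha2=d.get("alpha2", 0.0), alpha3=d.get("alpha3", 0.0),
            center=d.get("center"),
        )


def _check_finite(*vals):
    for v in vals:
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite input")


def trajectory(params: JointParams, effects: SubjectEffects, t):
    """Underlying (error-free) value m_i(t) in mm at time t >= 0."""
    t = np.asarray(t, dtype=float)
    _check_finite(t)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = (params.beta11 + effects.u1
           + (params.beta12 + effects.u2) * t
           + (params.beta13 + effects.u3) * t ** 2)
    return out if out.ndim else float(out)


def linear_predictor_ab(params: JointParams, effects: SubjectEffects):
    """Coefficients (a, b) of the log-hazard log h(t) = log lambda + a + b*t.

    Valid for a linear trajectory.  ``a`` collects the time-constant part of
    the association, ``b`` the per-year drift induced by the current-value
    association.
    """
    a = (params.alpha1 * effects.u1 + params.alpha2 * effects.u2
         + params.alpha3 * (params.beta11 + effects.u1 - params.center))
    b = params.alpha3 * (params.beta12 + effects.u2)
    return a, b


def hazard(params: JointParams, effects: SubjectEffects, t):
    """Hazard h_i(t) = lambda * exp(alpha1 U1 + alpha2 U2 + alpha3 (m(t)-c))."""
    t = np.asarray(t, dtype=float)
    _check_finite(t)
    m = trajectory(params, effects, t)
    lp = (params.log_lambda + params.alpha1 * effects.u1
          + params.alpha2 * effects.u2 + params.alpha3 * (m - params.center))
    out = np.exp(lp)
    return out if out.ndim else float(out)


def _expm1_over_b(b, t):
    """(exp(b*t) - 1)/b, with the series t*(1 + b*t/2) when |b| is tiny."""
    b = np.asarray(b, dtype=float)
    t = np.asarray(t, dtype=float)
    small = np.abs(b) < B_SWITCH_TOL
    b_safe = np.where(small, 1.0, b)
    ratio = np.expm1(b_safe * t) / b_safe
    series = t * (1.0 + b * t / 2.0)
    return np.where(small, series, ratio)


def cumulative_hazard(params: JointParams, effects: SubjectEffects, t):
    """Closed-form integrated hazard H_i(t) for the linear-trajectory model."""
    t = np.asarray(t, dtype=float)
    _check_finite(t)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if params.beta13 != 0.0 or effects.u3 != 0.0:
        raise ValueError("closed-form cumulative hazard requires a linear "
                         "trajectory (beta13 = U3 = 0)")
    a, b = linear_predictor_ab(params, effects)
    _check_finite(a, b)
    out = np.exp(params.log_lambda + a) * _expm1_over_b(b, t)
    return out if out.ndim else float(out)


def piecewise_cumulative_hazard(params: JointParams,
                                cutpoints: Sequence[float],
                                log_lambdas: Sequence[float],
                                effects: SubjectEffects, t):
    """Integrated hazard under a piecewise-constant baseline hazard.

    ``cutpoints`` are the strictly increasing interior band boundaries
    (the first band starts at 0, the last band is open-ended), and
    ``log_lambdas`` gives one log baseline hazard per band, so
    ``len(log_lambdas) == len(cutpoints) + 1``.  With a single band this
    reduces exactly to :func:`cumulative_hazard`.
    """
    cutpoints = np.asarray(cutpoints, dtype=float)
    log_lambdas = np.asarray(log_lambdas, dtype=float)
    if cutpoints.size and (np.any(np.diff(cutpoints) <= 0)
                           or cutpoints[0] <= 0):
        raise ValueError("cutpoints must be strictly increasing and > 0")
    if log_lambdas.size != cutpoints.size + 1:
        raise ValueError("need one log hazard per band")
    if params.beta13 != 0.0 or effects.u3 != 0.0:
        raise ValueError("requires a linear trajectory")
    t = np.asarray(t, dtype=float)
    _check_finite(t, cutpoints, log_lambdas)
    a, b = linear_predictor_ab(params, effects)

    lo = np.concatenate([[0.0], cutpoints])
    hi = np.concatenate([cutpoints, [np.inf]])
    total = np.zeros_like(t, dtype=float)
    for lam_log, l, h in zip(log_lambdas, lo, hi):
        seg_hi = np.minimum(t, h)
        seg = np.clip(seg_hi - l, 0.0, None)
        # integral of exp(a + b*s) over (l, l+seg]
        contrib = np.exp(lam_log + a + b * l) * _expm1_over_b(b, seg)
        total += np.where(seg > 0, contrib, 0.0)
    return total if total.ndim else float(total)


def survival_loglik_contribution(params: JointParams, effects: SubjectEffects,
                                 record: SurvivalRecord) -> float:
    """delta * log h(T) - H(T) for one subject's right-censored record."""
    T = record.observed_time
    ll = -cumulative_hazard(params, effects, T)
    if record.event:
        ll += np.log(hazard(params, effects, T))
    return float(ll)


def longitudinal_loglik_contribution(params: JointParams,
                                     effects: SubjectEffects,
                                     records: Sequence[LongitudinalRecord],
                                     ) -> float:
    """Gaussian log-likelihood of one subject's measurements given effects."""
    if len(records) == 0:
        raise ValueError("records must be nonempty")
    t = np.array([r.time for r in records])
    y = np.array([r.response for r in records])
    mu = trajectory(params, effects, t)
    sig2 = params.sigma ** 2
    return float(-0.5 * len(y) * np.log(2 * np.pi * sig2)
                 - 0.5 * np.sum((y - mu) ** 2) / sig2)
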