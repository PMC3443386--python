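"""Synthetic joint datasets under the simulation study's generating process.

Subjects are examined at fixed times (default 0, 2, 4, 6, 8 years).  The
underlying value follows the linear (or quadratic) mixed model of
:mod:`jointlsm.core`; observed measurements add N(0, sigma^2) noise.  Latent
failure times are drawn from the hazard linked to the current underlying
value by inverse-transform sampling.  Two censoring mechanisms operate:

* random censoring at C1 ~ Uniform(0, random_censoring_range);
* optional threshold censoring at the first examination where the *observed*
  measurement reaches the referral threshold (default 55 mm), mimicking
  referral-to-surgery policies.

The observed time is the minimum of the latent failure time, both censoring
times and the administrative horizon; measurements after the observed time
are discarded (the threshold-triggering measurement itself is retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import JointParams, SubjectEffects, B_SWITCH_TOL
from .data import JointData

__all__ = ["ScenarioSpec", "SimulatedDataset", "make_scenario", "simulate",
           "draw_subject_effects", "simulate_measurements",
           "simulate_event_times", "apply_censoring", "SCENARIO_NAMES"]

#: minimum allowed random censoring time (~1 day); C1 below is resampled so
#: every subject retains at least the first examination.
MIN_CENSOR_TIME = 0.003

SCENARIO_NAMES = ("table1", "table2", "table3_mild", "table3_gross")

_SIGMA2 = np.array([[43.5, 3.2], [3.2, 1.7]])
_SIGMA3 = np.array([[43.5, 3.2, -0.3],
                    [3.2, 1.7, -0.2],
                    [-0.3, -0.2, 0.08]])
_CENTER = 47.15  # beta11 + 5*beta12 for the linear truth


@dataclass
class ScenarioSpec:
    """Complete description of one data-generating condition."""

    params: JointParams
    n_subjects: int = 1000
    exam_times: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 2.0, 4.0, 6.0, 8.0]))
    random_censoring_range: float = 10.0
    threshold: float | None = None
    admin_horizon: float = 10.0
    seed: int | None = None
    name: str = "custom"

    def __post_init__(self):
        self.exam_times = np.asarray(self.exam_times, dtype=float)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.exam_times[0] != 0 or np.any(np.diff(self.exam_times) <= 0):
            raise ValueError("exam_times must start at 0, strictly increase")
        if np.any(self.exam_times >= self.admin_horizon):
            raise ValueError("exam_times must all precede admin_horizon")


@dataclass
class SimulatedDataset:
    """Observed data plus simulation truth.

    ``truth`` has one row per subject: the random effects (u1, u2[, u3]) and
    the latent failure time (``inf`` when the subject never fails).
    """

    data: JointData
    truth: pd.DataFrame
    spec: ScenarioSpec

    def effects_for(self, subject_id) -> SubjectEffects:
        row = self.truth.set_index("id").loc[subject_id]
        return SubjectEffects(u1=row["u1"], u2=row["u2"],
                              u3=row.get("u3", 0.0))

    def write(self, outdir, prefix=""):
        paths = self.data.write(outdir, prefix=prefix)
        tp = paths[0].parent / f"{prefix}truth.csv"
        self.truth.to_csv(tp, index=False)
        return (*paths, tp)


def make_scenario(name: str, n_subjects: int = 1000,
                  seed: int | None = None, true_alpha: float | None = None,
                  ) -> ScenarioSpec:
    """Published simulation-study scenarios.

    ``table1``: linear truth, random censoring only, alpha = 0.2.
    ``table2``: linear truth, random + 55 mm threshold censoring,
    alpha = 0.22.  ``table3_mild`` / ``table3_gross``: quadratic truth
    (mild/gross curvature), both censoring mechanisms, alpha = 0.22.
    The current-value covariate is centered at 47.15 mm in every scenario,
    so lambda = 0.008 is the hazard at the linear-truth process mean.
    """
    loglam = float(np.log(0.008))
    if name == "table1":
        alpha = 0.2 if true_alpha is None else true_alpha
        params = JointParams(beta11=38.5, beta12=1.73, sigma=2.8,
                             Sigma=_SIGMA2.copy(), log_lambda=loglam,
                             alpha3=alpha, center=_CENTER)
        return ScenarioSpec(params=params, n_subjects=n_subjects,
                            threshold=None, seed=seed, name=name)
    alpha = 0.22 if true_alpha is None else true_alpha
    if name == "table2":
        params = JointParams(beta11=38.5, beta12=1.73, sigma=2.8,
                             Sigma=_SIGMA2.copy(), log_lambda=loglam,
                             alpha3=alpha, center=_CENTER)
    elif name == "table3_mild":
        params = JointParams(beta11=38.5, beta12=1.3, beta13=0.1, sigma=2.8,
                             Sigma=_SIGMA3.copy(), log_lambda=loglam,
                             alpha3=alpha, center=_CENTER)
    elif name == "table3_gross":
        params = JointParams(beta11=38.5, beta12=0.8, beta13=0.3, sigma=2.8,
                             Sigma=_SIGMA3.copy(), log_lambda=loglam,
                             alpha3=alpha, center=_CENTER)
    else:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"choose from {SCENARIO_NAMES}")
    return ScenarioSpec(params=params, n_subjects=n_subjects, threshold=55.0,
                        seed=seed, name=name)


def draw_subject_effects(spec: ScenarioSpec, rng: np.random.Generator,
                         ) -> np.ndarray:
    """(n_subjects, q) multivariate-normal random effects, zero mean, cov Sigma."""
    S = spec.params.Sigma
    L = np.linalg.cholesky(S)  # raises on non-PD
    z = rng.standard_normal((spec.n_subjects, S.shape[0]))
    return z @ L.T


def _trajectories(params: JointParams, effects: np.ndarray, t: np.ndarray,
                  ) -> np.ndarray:
    """(n, len(t)) underlying values for row-wise effects at times t."""
    if effects.shape[1] == 3:
        quad = (params.beta13 + effects[:, 2:3]) * t ** 2
    else:
        quad = params.beta13 * t ** 2
    return (params.beta11 + effects[:, 0:1]
            + (params.beta12 + effects[:, 1:2]) * t + quad)


def simulate_measurements(spec: ScenarioSpec, effects: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """(n, n_exams) noisy measurements at every exam time (pre-censoring)."""
    mu = _trajectories(spec.params, effects, spec.exam_times)
    return mu + spec.params.sigma * rng.standard_normal(mu.shape)


def simulate_event_times(params: JointParams, effects: np.ndarray,
                         rng: np.random.Generator,
                         horizon: float = 10.0) -> np.ndarray:
    """Latent failure times by inverse-transform sampling; inf = never fails.

    Linear truth uses the closed-form inverse of the integrated hazard.
    Quadratic truth inverts a dense cumulative-trapezoid grid on
    [0, horizon]; failures beyond the horizon are recorded as infinite
    (they are always administratively censored).
    """
    n = effects.shape[0]
    E = rng.exponential(1.0, size=n)
    u3 = effects[:, 2] if effects.shape[1] == 3 else np.zeros(n)
    quadratic = params.beta13 != 0.0 or np.any(u3 != 0.0)
    base = (params.alpha1 * effects[:, 0] + params.alpha2 * effects[:, 1])
    if not quadratic:
        a = base + params.alpha3 * (params.beta11 + effects[:, 0]
                                    - params.center)
        b = params.alpha3 * (params.beta12 + effects[:, 1])
        lam_ea = np.exp(params.log_lambda + a)
        small = np.abs(b) < B_SWITCH_TOL
        b_safe = np.where(small, 1.0, b)
        arg = 1.0 + b_safe * E / lam_ea
        with np.errstate(divide="ignore", invalid="ignore"):
            t_exact = np.log(arg) / b_safe
        t0 = E / lam_ea
        t_series = t0 * (1.0 - b * t0 / 2.0)
        t = np.where(small, t_series, t_exact)
        t = np.where(arg <= 0, np.inf, t)  # E beyond H(inf) when b < 0
        return t
    # quadratic: grid-based inversion of H on [0, horizon]
    grid = np.linspace(0.0, horizon, 481)
    m = _trajectories(params, effects, grid)
    h = np.exp(params.log_lambda + base[:, None]
               + params.alpha3 * (m - params.center))
    dt = grid[1] - grid[0]
    H = np.concatenate(
        [np.zeros((n, 1)), np.cumsum((h[:, 1:] + h[:, :-1]) / 2 * dt, axis=1)],
        axis=1)
    beyond = E >= H[:, -1]
    idx = np.clip((H < E[:, None]).sum(axis=1), 1, len(grid) - 1)
    rows = np.arange(n)
    H0, H1 = H[rows, idx - 1], H[rows, idx]
    frac = np.where(H1 > H0, (E - H0) / np.where(H1 > H0, H1 - H0, 1.0), 0.0)
    t = grid[idx - 1] + frac * dt
    return np.where(beyond, np.inf, t)


def apply_censoring(spec: ScenarioSpec, true_times: np.ndarray,
                    measurements: np.ndarray, effects: np.ndarray,
                    censor_times: np.ndarray) -> SimulatedDataset:
    """Resolve observed times/events and truncate measurements.

    ``observed = min(latent T, C1, C2, admin_horizon)`` with C2 the first
    exam where the observed measurement reaches the threshold (inactive when
    the spec has none).  The event indicator is 1 only when the latent
    failure time is the strict minimum (ties resolve to censoring).
    """
    n = spec.n_subjects
    exam = spec.exam_times
    c2 = np.full(n, np.inf)
    if spec.threshold is not None:
        over = measurements >= spec.threshold
        any_over = over.any(axis=1)
        first = np.argmax(over, axis=1)
        c2[any_over] = exam[first[any_over]]
        # threshold at t=0 would leave follow-up of length zero; nudge to the
        # minimum retainable follow-up like degenerate random censoring
        c2 = np.maximum(c2, MIN_CENSOR_TIME)
    censor = np.minimum.reduce([censor_times, c2,
                                np.full(n, spec.admin_horizon)])
    observed = np.minimum(true_times, censor)
    event = (true_times < censor).astype(int)

    ids = np.arange(1, n + 1)
    keep = exam[None, :] <= observed[:, None] + 1e-12
    subj_idx, exam_idx = np.nonzero(keep)
    lon = pd.DataFrame({"id": ids[subj_idx],
                        "time": exam[exam_idx],
                        "y": measurements[subj_idx, exam_idx]})
    sur = pd.DataFrame({"id": ids, "time": observed, "event": event})
    truth = pd.DataFrame({"id": ids, "u1": effects[:, 0], "u2": effects[:, 1]})
    if effects.shape[1] == 3:
        truth["u3"] = effects[:, 2]
    truth["true_time"] = true_times
    return SimulatedDataset(data=JointData(longitudinal=lon, survival=sur),
                            truth=truth, spec=spec)


def simulate(spec: ScenarioSpec,
             rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Run the full generating process; same seed gives an identical dataset."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    effects = draw_subject_effects(spec, rng)
    measurements = simulate_measurements(spec, effects, rng)
    true_times = simulate_event_times(spec.params, effects, rng,
                                      horizon=spec.admin_horizon)
    c1 = rng.uniform(0.0, spec.random_censoring_range, size=spec.n_subjects)
    bad = c1 < MIN_CENSOR_TIME
    while bad.any():  # resample degenerate censoring times (< ~1 day)
        c1[bad] = rng.uniform(0.0, spec.random_censoring_range, bad.sum())
        bad = c1 < MIN_CENSOR_TIME
    return apply_censoring(spec, true_times, measurements, effects, c1)
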