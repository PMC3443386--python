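"""Bayesian shared random effects joint model and posterior prediction.

The model is that of :mod:`jointlsm.joint` — linear growth trajectories,
constant baseline hazard, association through the random intercept, slope
and/or current underlying value — sampled by Metropolis-within-Gibbs:

* fixed effects (beta11, beta12) — joint random-walk block;
* (log lambda, free alphas) — joint random-walk block;
* log sigma — random walk against its Uniform(0, 100) prior on sigma;
* per-subject random effects U_i — simultaneous elementwise Metropolis
  updates (subjects are conditionally independent given theta);
* between-subject covariance — scaled inverse-Wishart (Gelman-Hill):
  Sigma = Diag(xi) Q Diag(xi) with a conjugate inverse-Wishart Gibbs draw
  for Q (df = q + 1 + m) and Metropolis on log xi against half-uniform
  scale priors.

Fixed effects, log lambda and alphas carry Normal(0, 10^4) priors.
Proposal scales adapt during warmup (Robbins-Monro, targeting ~30%
acceptance) and are frozen afterwards.

Posterior prediction for a new subject draws their random effects from the
conditional posterior given their measurements *and* survival to time s
(sampling-importance-resampling with a Laplace t proposal, the survival
factor exp(-H(s)) included in the target), then propagates each retained
draw through the trajectory (future measurements) or the closed-form
integrated hazard (conditional survival probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import JointData
from .joint import SubjectStats, _f012, ASSOCIATIONS
from .lmm import LinearGrowthModel

__all__ = ["PriorSpec", "PosteriorDraws", "NewSubjectData",
           "BayesianJointModel", "predict_longitudinal", "predict_survival"]

LOG2PI = np.log(2 * np.pi)


@dataclass
class PriorSpec:
    """Minimally informative priors for the Bayesian joint model."""

    fixed_effect_sd: float = 100.0   # Normal(0, sd^2): beta, log lambda, alpha
    sigma_upper: float = 100.0       # Uniform(0, upper) on residual SD
    wishart_df: float | None = None  # default q + 1
    xi_upper: float = 100.0          # half-uniform inverse-Wishart scales

    def __post_init__(self):
        if min(self.fixed_effect_sd, self.sigma_upper, self.xi_upper) <= 0:
            raise ValueError("prior hyperparameters must be positive")


@dataclass
class PosteriorDraws:
    """Post-warmup posterior sample with convergence diagnostics.

    ``params`` has shape (chains, draws, k) in the order of ``names``;
    ``u_draws`` holds thinned per-subject random-effect draws with shape
    (chains, draws_u, m, 2).  ``diagnostics`` reports the split-chain
    rank-normalized R-hat and bulk effective sample size per parameter,
    computed on post-warmup samples only.
    """

    names: list
    params: np.ndarray
    u_draws: np.ndarray
    u_thin: int
    diagnostics: pd.DataFrame
    center: float
    association: tuple
    warnings: list = field(default_factory=list)

    def flat(self, name: str) -> np.ndarray:
        return self.params[:, :, self.names.index(name)].ravel()

    @classmethod
    def from_frame(cls, df: pd.DataFrame, center: float,
                   association=("current",)) -> "PosteriorDraws":
        """Rebuild a draws object from a :meth:`to_frame`-style table."""
        df = df.copy()
        chain = df.pop("chain").to_numpy() if "chain" in df else \
            np.zeros(len(df), dtype=int)
        names = list(df.columns)
        n_chains = int(chain.max()) + 1
        per = [df[chain == c].to_numpy() for c in range(n_chains)]
        d = min(len(p) for p in per)
        params = np.stack([p[:d] for p in per])
        diag = _diagnostics(names, params) if d > 3 else pd.DataFrame(
            {"rhat": np.nan, "ess": np.nan}, index=names)
        return cls(names=names, params=params,
                   u_draws=np.zeros((n_chains, 0, 0, 2)), u_thin=1,
                   diagnostics=diag, center=center,
                   association=tuple(association))

    def to_frame(self) -> pd.DataFrame:
        """One row per retained draw, one column per parameter."""
        k = self.params.shape[2]
        df = pd.DataFrame(self.params.reshape(-1, k), columns=self.names)
        df.insert(0, "chain", np.repeat(np.arange(self.params.shape[0]),
                                        self.params.shape[1]))
        return df

    def summary(self) -> str:
        lines = ["Bayesian joint model posterior "
                 f"({self.params.shape[0]} chains x "
                 f"{self.params.shape[1]} draws)"]
        if self.warnings:
            lines += [f"  WARNING: {w}" for w in self.warnings]
        lines.append(f"  {'parameter':<12}{'mean':>10}{'sd':>10}"
                     f"{'2.5%':>10}{'97.5%':>10}{'rhat':>8}{'ess':>8}")
        for i, name in enumerate(self.names):
            x = self.params[:, :, i].ravel()
            d = self.diagnostics.loc[name]
            lines.append(f"  {name:<12}{x.mean():>10.4f}{x.std():>10.4f}"
                         f"{np.percentile(x, 2.5):>10.4f}"
                         f"{np.percentile(x, 97.5):>10.4f}"
                         f"{d['rhat']:>8.3f}{d['ess']:>8.0f}")
        return "\n".join(lines)


@dataclass
class NewSubjectData:
    """Measurement history and known event-free time of a new subject."""

    times: np.ndarray
    responses: np.ndarray
    survival_to: float

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.responses = np.atleast_1d(np.asarray(self.responses,
                                                  dtype=float))
        if self.times.size != self.responses.size:
            raise ValueError("times and responses must have equal length")
        if self.times.size and self.survival_to < self.times.max():
            raise ValueError("survival_to must be >= last measurement time")


def _diagnostics(names, params):
    """Split-chain R-hat and bulk ESS via arviz."""
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        import arviz as az
        data = {n: params[:, :, i] for i, n in enumerate(names)}
        rhat = az.rhat(data)
        ess = az.ess(data)
    return pd.DataFrame(
        {"rhat": [float(rhat[n].values) for n in names],
         "ess": [float(ess[n].values) for n in names]}, index=names)


class BayesianJointModel:
    """MCMC sampler for the shared random effects joint model.

    Parameters mirror :class:`~jointlsm.joint.JointModel`; ``data`` may be
    ``None`` for a prior-only run (the sampler then explores the priors
    alone, useful for prior predictive checks).
    """

    def __init__(self, data: JointData | None, association=("current",),
                 center: float = 47.15, priors: PriorSpec | None = None):
        association = tuple(association)
        if not association or any(a not in ASSOCIATIONS for a in association):
            raise ValueError(f"association must be a nonempty subset of "
                             f"{ASSOCIATIONS}")
        self.association = association
        self.center = float(center)
        self.priors = priors or PriorSpec()
        self.data = data
        if data is not None:
            self.stats = SubjectStats.from_joint_data(data)
            if self.stats.delta.sum() < 1:
                raise ValueError("need at least one event")
            self.m = self.stats.n_subjects
        else:
            self.stats = None
            self.m = 0
        self._free_alpha = np.array([a in association for a in ASSOCIATIONS])

    # ------------------------------------------------------------------
    def _data_loglik(self, u1, u2, beta11, beta12, sigma, loglam, alphas):
        """Per-subject longitudinal + survival log-likelihood (no u-prior)."""
        st = self.stats
        Se = st.Sy - st.n * beta11 - beta12 * st.St
        Ste = st.Sty - beta11 * st.St - beta12 * st.Stt
        Q0 = (st.Syy - 2 * beta11 * st.Sy - 2 * beta12 * st.Sty
              + beta11 ** 2 * st.n + 2 * beta11 * beta12 * st.St
              + beta12 ** 2 * st.Stt)
        sig2 = sigma ** 2
        SS = (Q0 - 2 * (u1 * Se + u2 * Ste) + u1 ** 2 * st.n
              + 2 * u1 * u2 * st.St + u2 ** 2 * st.Stt)
        ll = -0.5 * st.n * np.log(2 * np.pi * sig2) - SS / (2 * sig2)
        a1, a2, a3 = alphas
        a = (a1 + a3) * u1 + a2 * u2 + a3 * (beta11 - self.center)
        b = a3 * (beta12 + u2)
        f, _, _ = _f012(b, st.T)
        with np.errstate(over="ignore"):
            ll = ll + (st.delta * (loglam + a + b * st.T)
                       - np.exp(loglam + a) * f)
        return ll

    @staticmethod
    def _u_prior_loglik(u1, u2, Sigma):
        det = Sigma[0, 0] * Sigma[1, 1] - Sigma[0, 1] ** 2
        i00, i01, i11 = (Sigma[1, 1] / det, -Sigma[0, 1] / det,
                         Sigma[0, 0] / det)
        q = i00 * u1 ** 2 + 2 * i01 * u1 * u2 + i11 * u2 ** 2
        return -LOG2PI - 0.5 * np.log(det) - 0.5 * q

    def _theta_prior_loglik(self, beta11, beta12, loglam, alphas, sigma):
        sd2 = self.priors.fixed_effect_sd ** 2
        vals = [beta11, beta12, loglam] + [
            a for a, fr in zip(alphas, self._free_alpha) if fr]
        lp = sum(-0.5 * v ** 2 / sd2 for v in vals)
        if not 0 < sigma < self.priors.sigma_upper:
            return -np.inf
        return lp

    # ------------------------------------------------------------------
    def run(self, chains: int = 3, warmup: int = 2000,
            iterations: int = 5000, seed: int | None = None,
            thin: int = 1, u_thin: int = 10) -> PosteriorDraws:
        """Sample the posterior; identical seeds give identical draws."""
        from scipy.stats import invwishart

        prs = self.priors
        df_w = prs.wishart_df if prs.wishart_df is not None else 3.0
        chains_out = []
        u_out = []
        for c in range(chains):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=0 if seed is None else seed,
                                       spawn_key=(c,)))
            out, uout = self._run_chain(rng, warmup, iterations, thin,
                                        u_thin, df_w, invwishart)
            chains_out.append(out)
            u_out.append(uout)
        params = np.stack(chains_out)
        u_draws = (np.stack(u_out) if self.m
                   else np.zeros((chains, 0, 0, 2)))
        names = self._param_names()
        diag = _diagnostics(names, params)
        warnings_ = []
        bad = diag.index[diag["rhat"] > 1.05].tolist()
        if bad:
            warnings_.append(f"rhat > 1.05 for {bad}; consider longer runs")
        return PosteriorDraws(names=names, params=params, u_draws=u_draws,
                              u_thin=u_thin, diagnostics=diag,
                              center=self.center,
                              association=self.association,
                              warnings=warnings_)

    def _param_names(self):
        names = ["beta11", "beta12", "sigma", "Sigma11", "Sigma12",
                 "Sigma22", "log_lambda"]
        names += [f"alpha{i + 1}" for i in range(3) if self._free_alpha[i]]
        return names

    def _init_state(self):
        if self.data is not None:
            lmm = LinearGrowthModel(self.data.longitudinal).fit()
            Sigma = lmm.Sigma
            if np.linalg.eigvalsh(Sigma).min() <= 1e-6:
                Sigma = Sigma + 1e-4 * np.eye(2)
            blups = lmm.blups.set_index("id").loc[self.stats.ids]
            u = blups[["u1", "u2"]].to_numpy().copy()
            loglam = float(np.log(max(self.stats.delta.sum(), 1.0)
                                  / self.stats.T.sum()))
            return dict(beta11=lmm.beta11, beta12=lmm.beta12,
                        sigma=lmm.sigma, Sigma=Sigma, loglam=loglam,
                        alphas=np.zeros(3), u=u)
        return dict(beta11=0.0, beta12=0.0, sigma=1.0, Sigma=np.eye(2),
                    loglam=0.0, alphas=np.zeros(3), u=np.zeros((0, 2)))

    def _run_chain(self, rng, warmup, iterations, thin, u_thin, df_w,
                   invwishart):
        st = self._init_state()
        m = self.m
        xi = np.sqrt(np.diag(st["Sigma"]))
        Q = st["Sigma"] / np.outer(xi, xi)
        n_alpha = int(self._free_alpha.sum())

        # adaptive proposal log-scales per block
        ls_beta, ls_haz, ls_sig, ls_xi = 0.0, 0.0, -1.5, -1.5
        ls_u = np.zeros(m)
        beta_dirs = np.array([[0.5, 0.0], [0.0, 0.12]])
        haz_dirs = np.diag([0.3] + [0.05] * n_alpha)

        if m:
            dll = self._data_loglik(st["u"][:, 0], st["u"][:, 1],
                                    st["beta11"], st["beta12"], st["sigma"],
                                    st["loglam"], st["alphas"])
        else:
            dll = np.zeros(0)

        keep = []
        keep_u = []
        total = warmup + iterations
        for it in range(total):
            adapting = it < warmup
            gamma = 2.0 / (1 + it) ** 0.6  # Robbins-Monro step size

            # ---- block: (beta11, beta12) ------------------------------
            step = np.exp(ls_beta) * (beta_dirs @ rng.standard_normal(2))
            prop = (st["beta11"] + step[0], st["beta12"] + step[1])
            new_dll = (self._data_loglik(st["u"][:, 0], st["u"][:, 1],
                                         prop[0], prop[1], st["sigma"],
                                         st["loglam"], st["alphas"])
                       if m else np.zeros(0))
            logr = (new_dll.sum() - dll.sum()
                    + self._theta_prior_loglik(prop[0], prop[1],
                                               st["loglam"], st["alphas"],
                                               st["sigma"])
                    - self._theta_prior_loglik(st["beta11"], st["beta12"],
                                              st["loglam"], st["alphas"],
                                              st["sigma"]))
            acc = np.log(rng.uniform()) < logr
            if acc:
                st["beta11"], st["beta12"] = prop
                dll = new_dll
            if adapting:
                ls_beta += gamma * ((1.0 if acc else 0.0) - 0.3)

            # ---- block: (log lambda, alphas) --------------------------
            z = rng.standard_normal(1 + n_alpha)
            step = np.exp(ls_haz) * (haz_dirs @ z)
            prop_ll = st["loglam"] + step[0]
            prop_al = st["alphas"].copy()
            prop_al[self._free_alpha] += step[1:]
            new_dll = (self._data_loglik(st["u"][:, 0], st["u"][:, 1],
                                         st["beta11"], st["beta12"],
                                         st["sigma"], prop_ll, prop_al)
                       if m else np.zeros(0))
            logr = (new_dll.sum() - dll.sum()
                    + self._theta_prior_loglik(st["beta11"], st["beta12"],
                                               prop_ll, prop_al,
                                               st["sigma"])
                    - self._theta_prior_loglik(st["beta11"], st["beta12"],
                                              st["loglam"], st["alphas"],
                                              st["sigma"]))
            acc = np.log(rng.uniform()) < logr
            if acc:
                st["loglam"], st["alphas"] = prop_ll, prop_al
                dll = new_dll
            if adapting:
                ls_haz += gamma * ((1.0 if acc else 0.0) - 0.3)

            # ---- block: log sigma ------------------------------------
            prop_sig = st["sigma"] * np.exp(np.exp(ls_sig)
                                            * rng.standard_normal())
            acc = False
            if 0 < prop_sig < self.priors.sigma_upper:
                new_dll = (self._data_loglik(st["u"][:, 0], st["u"][:, 1],
                                             st["beta11"], st["beta12"],
                                             prop_sig, st["loglam"],
                                             st["alphas"])
                           if m else np.zeros(0))
                # log-scale random walk: Jacobian ratio sigma'/sigma
                logr = (new_dll.sum() - dll.sum()
                        + np.log(prop_sig / st["sigma"]))
                acc = np.log(rng.uniform()) < logr
                if acc:
                    st["sigma"] = prop_sig
                    dll = new_dll
            if adapting:
                ls_sig += gamma * ((1.0 if acc else 0.0) - 0.3)

            # ---- block: per-subject U_i (vectorized) ------------------
            if m:
                sds = np.sqrt(np.diag(st["Sigma"]))
                prop_u = st["u"] + (np.exp(ls_u)[:, None]
                                    * rng.standard_normal((m, 2)) * sds)
                new_dll = self._data_loglik(prop_u[:, 0], prop_u[:, 1],
                                            st["beta11"], st["beta12"],
                                            st["sigma"], st["loglam"],
                                            st["alphas"])
                logr = (new_dll - dll
                        + self._u_prior_loglik(prop_u[:, 0], prop_u[:, 1],
                                               st["Sigma"])
                        - self._u_prior_loglik(st["u"][:, 0],
                                               st["u"][:, 1], st["Sigma"]))
                accv = np.log(rng.uniform(size=m)) < logr
                st["u"][accv] = prop_u[accv]
                dll = np.where(accv, new_dll, dll)
                if adapting:
                    ls_u += gamma * (accv.astype(float) - 0.3)

            # ---- block: Sigma = Diag(xi) Q Diag(xi) -------------------
            if m:
                v = st["u"] / xi  # (m, 2)
                S = np.eye(2) + v.T @ v
                Q = invwishart.rvs(df=df_w + m, scale=S, random_state=rng)
                st["Sigma"] = np.outer(xi, xi) * Q
                # Metropolis on log xi against half-uniform scale priors
                prop_xi = xi * np.exp(np.exp(ls_xi)
                                      * rng.standard_normal(2))
                acc = False
                if np.all(prop_xi < self.priors.xi_upper):
                    Sig_p = np.outer(prop_xi, prop_xi) * Q
                    lp_new = self._u_prior_loglik(st["u"][:, 0],
                                                  st["u"][:, 1],
                                                  Sig_p).sum()
                    lp_old = self._u_prior_loglik(st["u"][:, 0],
                                                  st["u"][:, 1],
                                                  st["Sigma"]).sum()
                    logr = (lp_new - lp_old
                            + np.log(prop_xi / xi).sum())  # Jacobian
                    acc = np.log(rng.uniform()) < logr
                    if acc:
                        xi = prop_xi
                        st["Sigma"] = Sig_p
                if adapting:
                    ls_xi += gamma * ((1.0 if acc else 0.0) - 0.3)
            else:
                # prior-only: Sigma explored through the Q and xi priors
                Q = invwishart.rvs(df=df_w, scale=np.eye(2),
                                   random_state=rng)
                xi = rng.uniform(0, self.priors.xi_upper, 2)
                st["Sigma"] = np.outer(xi, xi) * Q

            if it >= warmup and (it - warmup) % thin == 0:
                row = [st["beta11"], st["beta12"], st["sigma"],
                       st["Sigma"][0, 0], st["Sigma"][0, 1],
                       st["Sigma"][1, 1], st["loglam"]]
                row += [st["alphas"][i] for i in range(3)
                        if self._free_alpha[i]]
                keep.append(row)
                if m and (it - warmup) % (thin * u_thin) == 0:
                    keep_u.append(st["u"].copy())
        out = np.array(keep)
        uout = np.array(keep_u) if keep_u else np.zeros((0, m, 2))
        return out, uout


# ----------------------------------------------------------------------
# posterior prediction for a new subject
# ----------------------------------------------------------------------

def _col(x):
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def _draw_params(draws: PosteriorDraws, max_draws: int):
    """Flatten and evenly thin the posterior parameter draws."""
    k = draws.params.shape[2]
    flat = draws.params.reshape(-1, k)
    if len(flat) > max_draws:
        idx = np.linspace(0, len(flat) - 1, max_draws).astype(int)
        flat = flat[idx]
    cols = {n: flat[:, i] for i, n in enumerate(draws.names)}
    for a in ("alpha1", "alpha2", "alpha3"):
        cols.setdefault(a, np.zeros(len(flat)))
    return cols


def _sample_new_effects(draws: PosteriorDraws, new: NewSubjectData,
                        rng: np.random.Generator, max_draws: int = 2000,
                        n_prop: int = 16):
    """One U_{m+1} per retained theta draw, conditioned on the new
    subject's measurements and on survival to s (SIR with a Laplace-t
    proposal; the target includes the exp(-H(s)) survival factor)."""
    th = _draw_params(draws, max_draws)
    D = len(th["beta11"])
    t, y, s = new.times, new.responses, new.survival_to
    n = float(len(t))
    St, Stt = t.sum(), (t * t).sum()
    Sy, Sty, Syy = y.sum(), (t * y).sum(), (y * y).sum()
    b11, b12, sig = th["beta11"], th["beta12"], th["sigma"]
    a1, a2, a3 = th["alpha1"], th["alpha2"], th["alpha3"]
    loglam = th["log_lambda"]
    c = draws.center
    S11, S12, S22 = th["Sigma11"], th["Sigma12"], th["Sigma22"]
    det = S11 * S22 - S12 ** 2
    i00, i01, i11 = S22 / det, -S12 / det, S11 / det
    sig2 = sig ** 2
    Se = Sy - n * b11 - b12 * St
    Ste = Sty - b11 * St - b12 * Stt
    Q0 = (Syy - 2 * b11 * Sy - 2 * b12 * Sty + b11 ** 2 * n
          + 2 * b11 * b12 * St + b12 ** 2 * Stt)
    a13 = a1 + a3

    def log_target(u1, u2):
        SS = (_col(Q0) - 2 * (u1 * _col(Se) + u2 * _col(Ste))
              + u1 ** 2 * n + 2 * u1 * u2 * St + u2 ** 2 * Stt)
        ll = (-0.5 * n * np.log(2 * np.pi * _col(sig2))
              - SS / (2 * _col(sig2)))
        qf = (_col(i00) * u1 ** 2 + 2 * _col(i01) * u1 * u2
              + _col(i11) * u2 ** 2)
        ll = ll - 0.5 * np.log(_col(det)) - LOG2PI - 0.5 * qf
        aa = _col(a13) * u1 + _col(a2) * u2 + _col(a3) * (_col(b11) - c)
        b = _col(a3) * (_col(b12) + u2)
        f, _, _ = _f012(b, s)
        with np.errstate(over="ignore"):
            ll = ll - np.exp(_col(loglam) + aa) * f
        return ll

    # Newton to the per-draw conditional mode (concave target)
    u1 = np.zeros(D)
    u2 = np.zeros(D)
    h11 = h12 = h22 = None
    for _ in range(40):
        aa = a13 * u1 + a2 * u2 + a3 * (b11 - c)
        b = a3 * (b12 + u2)
        f, fp, fpp = _f012(b, s)
        lam_ea = np.exp(loglam + aa)
        Hval = lam_ea * f
        g1 = ((Se - n * u1 - St * u2) / sig2 - (i00 * u1 + i01 * u2)
              - Hval * a13)
        g2 = ((Ste - St * u1 - Stt * u2) / sig2 - (i01 * u1 + i11 * u2)
              - (Hval * a2 + lam_ea * fp * a3))
        h11 = n / sig2 + i00 + Hval * a13 ** 2
        h12 = St / sig2 + i01 + a13 * (Hval * a2 + lam_ea * fp * a3)
        h22 = (Stt / sig2 + i11 + Hval * a2 ** 2
               + 2 * a2 * lam_ea * fp * a3 + lam_ea * fpp * a3 ** 2)
        dd = h11 * h22 - h12 ** 2
        s1 = (h22 * g1 - h12 * g2) / dd
        s2 = (h11 * g2 - h12 * g1) / dd
        nrm = np.hypot(s1, s2)
        sc = np.where(nrm > 4.0, 4.0 / np.maximum(nrm, 4.0), 1.0)
        u1 = u1 + s1 * sc
        u2 = u2 + s2 * sc
        if max(np.abs(g1).max(), np.abs(g2).max()) < 1e-8:
            break
    # Laplace covariance Cholesky
    dd = h11 * h22 - h12 ** 2
    c11, c12, c22 = h22 / dd, -h12 / dd, h11 / dd
    l11 = np.sqrt(c11)
    l21 = c12 / l11
    l22 = np.sqrt(np.maximum(c22 - l21 ** 2, 1e-300))
    # SIR with a multivariate-t (df 7) proposal around the Laplace fit
    df_t = 7.0
    z = rng.standard_normal((D, n_prop, 2))
    w_chi = rng.chisquare(df_t, (D, n_prop)) / df_t
    z = z / np.sqrt(w_chi)[:, :, None]
    U1 = u1[:, None] + l11[:, None] * z[:, :, 0]
    U2 = (u2[:, None] + l21[:, None] * z[:, :, 0]
          + l22[:, None] * z[:, :, 1])
    lt = log_target(U1, U2)
    zz = z[:, :, 0] ** 2 + z[:, :, 1] ** 2
    lq = -0.5 * (df_t + 2) * np.log1p(zz / df_t)  # t density up to consts
    lw = lt - lq
    lw = lw - lw.max(axis=1, keepdims=True)
    w = np.exp(lw)
    w = w / w.sum(axis=1, keepdims=True)
    pick = (w.cumsum(axis=1)
            > rng.uniform(size=D)[:, None]).argmax(axis=1)
    rows = np.arange(D)
    return th, U1[rows, pick], U2[rows, pick]


def predict_longitudinal(draws: PosteriorDraws, new_subject: NewSubjectData,
                         horizon_times, seed: int | None = None,
                         max_draws: int = 2000) -> pd.DataFrame:
    """Posterior predictive future measurements for a new subject.

    Returns a frame with columns ``time``, ``mean``, ``lo95``, ``hi95``:
    the predictive mean and central 95% interval of a new noisy
    measurement y* at each horizon time.
    """
    horizon_times = np.atleast_1d(np.asarray(horizon_times, dtype=float))
    if new_subject.times.size and np.any(
            horizon_times <= new_subject.times.max()):
        raise ValueError("horizon times must exceed the last measurement")
    rng = np.random.default_rng(seed)
    th, u1, u2 = _sample_new_effects(draws, new_subject, rng, max_draws)
    rows = []
    for t in horizon_times:
        mu = (th["beta11"] + u1) + (th["beta12"] + u2) * t
        ystar = mu + th["sigma"] * rng.standard_normal(len(mu))
        rows.append({"time": float(t), "mean": ystar.mean(),
                     "lo95": np.percentile(ystar, 2.5),
                     "hi95": np.percentile(ystar, 97.5)})
    return pd.DataFrame(rows)


def predict_survival(draws: PosteriorDraws, new_subject: NewSubjectData,
                     times, seed: int | None = None,
                     max_draws: int = 2000) -> pd.DataFrame:
    """Predicted conditional survival P(T > t | T > s, history).

    Per retained draw, exp(-(H(t) - H(s))) at the drawn (theta, U);
    returns the posterior mean and central 95% interval per requested
    time, plus the complementary cumulative incidence.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    s = new_subject.survival_to
    if np.any(times < s):
        raise ValueError("prediction times must be >= survival_to")
    rng = np.random.default_rng(seed)
    th, u1, u2 = _sample_new_effects(draws, new_subject, rng, max_draws)
    a = ((th["alpha1"] + th["alpha3"]) * u1 + th["alpha2"] * u2
         + th["alpha3"] * (th["beta11"] - draws.center))
    b = th["alpha3"] * (th["beta12"] + u2)
    lam_ea = np.exp(th["log_lambda"] + a)
    fs, _, _ = _f012(b, s)
    Hs = lam_ea * fs
    rows = []
    for t in times:
        ft, _, _ = _f012(b, float(t))
        Ht = lam_ea * ft
        surv = np.exp(-(Ht - Hs))
        rows.append({"time": float(t), "mean": surv.mean(),
                     "lo95": np.percentile(surv, 2.5),
                     "hi95": np.percentile(surv, 97.5),
                     "cuminc": 1.0 - surv.mean()})
    return pd.DataFrame(rows)
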