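"""Maximum-likelihood estimation by Stochastic Approximation EM (SAEM).

The model is y_ij = f(t_ij, psi_i) + e_ij with e_ij ~ N(0, sigma^2),
psi_ik = alpha_k + beta_k' X_ki + eta_ik, and eta_i ~ MVN(0, B) on the
parameters that carry a random effect. The intractable E-step is replaced by
Metropolis-Hastings draws of each subject's random effects from their
conditional distribution, a Robbins-Monro stochastic approximation of the
complete-data sufficient statistics, and closed-form M-step updates:

* fixed effects of random parameters — generalised least squares of the
  approximated subject parameters on their covariate designs, weighted by
  B^{-1};
* B — approximated second moments, masked to the model's sparsity and
  projected block-wise to positive semi-definite when needed;
* sigma^2 — approximated residual sum of squares over the observation count;
* parameters without a random effect (the sigmoid midpoint and Hill slope,
  kept marginal for convergence) — one damped Gauss-Newton step per
  iteration on the complete-data residual sum of squares.

The step is gamma_k = 1 during the K1 burn-in iterations (memoryless
exploration) and (k - K1)^(-a) afterwards, with a in (0.5, 1] so the
Robbins-Monro conditions hold.

Standard errors come from the linearized Fisher information evaluated at
the empirical-Bayes estimates (a Louis-identity stochastic approximation of
the observed information is provided as :func:`estimate_standard_errors`,
but needs far more conditional draws than a fit produces whenever the
missing-information fraction is high); the marginal log-likelihood is an
importance-sampling estimate with Gaussian proposals built from conditional
draws; p-values are two-sided Wald tests for every fixed effect, including
the four main parameters.
"""

from __future__ import annotations

import logging
import math
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .data import LongData
from .errors import ConfigurationError, InitializationError
from .initials import InitialValues, pmm_initials, smm_initials, variance_initials
from .models import MODELS, ModelDef, ParameterLink, SmoothConfig, to_positive_time

logger = logging.getLogger("trajmix")

__all__ = [
    "ModelSpec",
    "SAEMSettings",
    "FitResult",
    "ParameterSet",
    "fit",
    "wald_pvalues",
    "marginal_loglik",
    "empirical_bayes",
    "estimate_standard_errors",
]

#: Estimates live on the same container as generative truths.
ParameterSet = ParameterLink


@dataclass
class ModelSpec:
    """Which structural model to fit, with which covariates where.

    ``predictors`` holds one tuple of covariate names per structural
    parameter (software order). ``start`` optionally overrides the automated
    initial values (model 1 order: last level, initial level, midpoint, Hill
    slope; models 2-3: intercept, slope1, slope2, changepoint).
    """

    model_id: int
    predictors: tuple = ((), (), (), ())
    smooth: SmoothConfig | None = None
    start: object = None
    custom_model: ModelDef | None = None

    def __post_init__(self):
        if self.custom_model is None and self.model_id not in MODELS:
            raise ConfigurationError(
                f"unknown model id {self.model_id}; choose one of {sorted(MODELS)}"
            )
        if self.model_id == 3 and self.smooth is None:
            self.smooth = SmoothConfig()
        if self.model_id != 3 and self.smooth is not None and self.custom_model is None:
            raise ConfigurationError("smooth config applies to model 3 only")
        m = self.model()
        self.predictors = tuple(tuple(p) for p in self.predictors)
        if len(self.predictors) != m.n_params:
            raise ConfigurationError(
                f"predictors must give one tuple per parameter ({m.n_params})"
            )

    def model(self) -> ModelDef:
        return self.custom_model if self.custom_model is not None else MODELS[self.model_id]

    def n_fixed_effects(self) -> int:
        return self.model().n_params + sum(len(p) for p in self.predictors)

    def covariate_names(self):
        seen = []
        for p in self.predictors:
            for name in p:
                if name not in seen:
                    seen.append(name)
        return seen


@dataclass
class SAEMSettings:
    """Algorithmic knobs; the defaults suit a few hundred subjects.

    ``n_burn_iters`` (K1) constant-step iterations, ``n_sa_iters`` (K2)
    decreasing-step iterations with gamma_k = (k - K1)^(-step_exponent).
    ``n_chains`` defaults to ceil(400 / N) so small samples still produce
    stable sufficient statistics; the schedule must be long enough that the
    per-iteration parameter updates (proportional to gamma_k times the
    Monte-Carlo fluctuation of the sufficient statistics) fall below the
    convergence tolerance.
    """

    n_burn_iters: int = 800
    n_sa_iters: int = 400
    step_exponent: float = 1.0
    n_chains: int | None = None
    mh_steps_per_iter: int = 1
    n_anneal_iters: int | None = None  # default: half the burn-in
    anneal_factor: float = 0.97
    seed: int = 0
    convergence_tol: float = 1e-3
    convergence_window: int = 50
    sigma2_floor: float = 1e-10
    var_floor: float = 1e-12
    se_window: int = 50
    n_is_samples: int = 500
    compute_se: bool = True
    compute_loglik: bool = True

    def __post_init__(self):
        if self.n_burn_iters <= 0 or self.n_sa_iters <= 0:
            raise ConfigurationError("K1 and K2 must be positive")
        if not 0.5 < self.step_exponent <= 1.0:
            raise ConfigurationError(
                "step_exponent must lie in (0.5, 1] (Robbins-Monro condition)"
            )
        if self.mh_steps_per_iter < 1 or (self.n_chains or 1) < 1:
            raise ConfigurationError("chain and sweep counts must be >= 1")


@dataclass
class FitResult:
    """Estimates, uncertainty, fit criteria and the convergence record."""

    model_id: int
    model_name: str
    param_names: tuple
    estimates: ParameterSet
    ses: dict
    cv_pct: dict
    pvalues: dict
    loglik: float
    loglik_se: float
    aic: float
    bic: float
    n_free_parameters: int
    converged: bool
    max_rel_change: float
    trace: np.ndarray
    trace_names: tuple
    runtime_s: float
    n_subjects: int
    n_obs: int
    time_range: tuple
    time_shift: float
    smooth: SmoothConfig | None
    initials: InitialValues
    eta: pd.DataFrame
    psi: pd.DataFrame
    covariates: pd.DataFrame
    warnings: list = field(default_factory=list)
    outcome_col: str = "outcome"
    time_col: str = "time"
    id_col: str = "ID"

    def packed_estimates(self) -> dict:
        return dict(zip(self.trace_names, self.trace[-1]))

    def to_dict(self) -> dict:
        est = self.packed_estimates()
        return {
            "model_id": self.model_id,
            "model_name": self.model_name,
            "estimates": est,
            "ses": self.ses,
            "cv_pct": self.cv_pct,
            "pvalues": self.pvalues,
            "loglik": self.loglik,
            "AIC": self.aic,
            "BIC": self.bic,
            "n_free_parameters": self.n_free_parameters,
            "converged": bool(self.converged),
            "max_rel_change": self.max_rel_change,
            "runtime_s": self.runtime_s,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "time_shift": self.time_shift,
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# Internal problem representation
# ---------------------------------------------------------------------------

class _Problem:
    """Arrays and designs extracted once from (data, spec)."""

    def __init__(self, data: LongData, spec: ModelSpec):
        self.spec = spec
        self.model = spec.model()
        self.smooth = spec.smooth
        m = self.model
        d = m.n_params

        df = data.df
        codes, uniques = pd.factorize(df[data.id_col], sort=False)
        order = np.lexsort((df[data.time_col].to_numpy(float), codes))
        self.code = codes[order]
        self.t_raw = df[data.time_col].to_numpy(float)[order]
        self.y = df[data.outcome_col].to_numpy(float)[order]
        self.subject_ids = np.asarray(uniques)
        self.N = len(uniques)
        self.n_obs = len(self.y)
        self.offsets = np.searchsorted(self.code, np.arange(self.N))
        self.n_i = np.bincount(self.code, minlength=self.N)

        if m.positive_time:
            self.t_eval, self.time_shift = to_positive_time(self.t_raw)
        else:
            self.t_eval, self.time_shift = self.t_raw, 0.0

        cov_names = spec.covariate_names()
        cov_tab = data.covariate_table(cov_names)  # indexed by subject id
        self.covariates = cov_tab
        # per-parameter designs: intercept + that parameter's covariates
        self.designs = []
        self.coef_names = []
        for k in range(d):
            cols = [np.ones(self.N)]
            names = [f"alpha.{m.param_names[k]}"]
            for name in spec.predictors[k]:
                cols.append(cov_tab[name].to_numpy(float))
                names.append(f"beta.{name}({m.param_names[k]})")
            self.designs.append(np.column_stack(cols))
            self.coef_names.append(names)

        self.r_idx = [k for k in range(d) if m.random_mask[k]]
        self.q = len(self.r_idx)
        self.nr_idx = [k for k in range(d) if not m.random_mask[k]]
        sub = np.ix_(self.r_idx, self.r_idx)
        self.bmask = np.asarray(m.cov_allowed, bool)[sub]
        # B free entries (i <= j within the random submatrix, allowed only)
        self.b_free = [
            (i, j)
            for i in range(self.q)
            for j in range(i, self.q)
            if self.bmask[i, j]
        ]

        names = [n for k in range(d) for n in self.coef_names[k]]
        pn = [m.param_names[k] for k in self.r_idx]
        for i, j in self.b_free:
            names.append(
                f"omega2.{pn[i]}" if i == j else f"cov.{pn[i]}.{pn[j]}"
            )
        names.append("sigma2")
        self.packed_names = tuple(names)
        self.n_coef = [dd.shape[1] for dd in self.designs]

    # -- parameter plumbing -------------------------------------------------

    def mean_psi(self, theta):
        """(N, d) population parameter values from per-parameter coefficients."""
        cols = [self.designs[k] @ theta[k] for k in range(self.model.n_params)]
        return np.column_stack(cols)

    def full_psi(self, mean_psi, eta):
        """Expand (N, q) random effects into clipped (N, d) parameters."""
        Psi = mean_psi.copy()
        if self.q:
            Psi[:, self.r_idx] += eta
        return self.model.clip_psi(Psi)

    def predict_obs(self, Psi):
        return self.model.evaluate(self.t_eval, Psi[self.code], self.smooth)

    def rss_by_subject(self, Psi):
        r = self.y - self.predict_obs(Psi)
        return np.add.reduceat(r * r, self.offsets)

    def pack(self, theta, B, sigma2):
        out = [c for k in range(self.model.n_params) for c in theta[k]]
        out += [B[i, j] for i, j in self.b_free]
        out.append(sigma2)
        return np.array(out)

    def unpack(self, vec):
        theta = []
        pos = 0
        for k in range(self.model.n_params):
            theta.append(np.array(vec[pos:pos + self.n_coef[k]]))
            pos += self.n_coef[k]
        B = np.zeros((self.q, self.q))
        for (i, j), val in zip(self.b_free, vec[pos:pos + len(self.b_free)]):
            B[i, j] = B[j, i] = val
        pos += len(self.b_free)
        return theta, B, vec[pos]

    def complete_loglik(self, vec, eta):
        """Complete-data log-likelihood at packed parameters, given draws."""
        theta, B, sigma2 = self.unpack(vec)
        if sigma2 <= 0:
            return -np.inf
        Psi = self.full_psi(self.mean_psi(theta), eta)
        rss = float(self.rss_by_subject(Psi).sum())
        ll = -0.5 * self.n_obs * math.log(2 * math.pi * sigma2) - rss / (2 * sigma2)
        if self.q:
            try:
                L = np.linalg.cholesky(B)
            except np.linalg.LinAlgError:
                return -np.inf
            sol = np.linalg.solve(L, eta.T)
            quad = float(np.sum(sol * sol))
            logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            ll += -0.5 * self.N * (self.q * math.log(2 * math.pi) + logdet) - 0.5 * quad
        return ll


def _blockwise_psd(B, mask, floor):
    """Project a masked covariance to PSD block by block; returns (B, clipped)."""
    q = B.shape[0]
    out = B.copy()
    clipped = False
    seen = np.zeros(q, bool)
    for start in range(q):
        if seen[start]:
            continue
        block = [start]
        frontier = [start]
        while frontier:
            i = frontier.pop()
            for j in range(q):
                if mask[i, j] and j not in block:
                    block.append(j)
                    frontier.append(j)
        block = sorted(block)
        seen[block] = True
        sub = out[np.ix_(block, block)]
        w, V = np.linalg.eigh(sub)
        if np.min(w) < floor:
            w = np.maximum(w, floor)
            out[np.ix_(block, block)] = (V * w) @ V.T
            clipped = True
        out[np.ix_(block, block)] = np.where(
            mask[np.ix_(block, block)], out[np.ix_(block, block)], 0.0
        )
    return out, clipped


# ---------------------------------------------------------------------------
# The SAEM loop
# ---------------------------------------------------------------------------

def _initial_values(data, spec, prob) -> InitialValues:
    if spec.start is not None:
        return InitialValues.from_user(spec.start, spec.model_id)
    if spec.custom_model is not None:
        raise ConfigurationError("custom models require explicit start values")
    if spec.model_id == 1:
        return smm_initials(data)
    return pmm_initials(data)


class _SAEMState:
    """Mutable state carried across iterations (also the SE accumulator)."""

    def __init__(self, prob, theta, B, sigma2, settings, rng):
        self.prob = prob
        self.theta = theta
        self.B = B
        self.sigma2 = sigma2
        self.settings = settings
        self.rng = rng
        L = settings.n_chains or max(1, math.ceil(400 / prob.N))
        self.L = L
        self.eta = np.zeros((L, prob.N, prob.q))
        self.rss = None  # (L, N) cache of current residual SS per subject
        # per-subject proposal scales: conditional widths differ strongly
        # across subjects (e.g. changepoints inside vs outside follow-up)
        self.scales = np.full((prob.N, prob.q), 0.5)
        self.scale_joint = np.full(prob.N, 0.5)
        self.H_phi = np.zeros((prob.N, prob.q))
        self.S2 = np.zeros((prob.q, prob.q))
        self.s3 = 0.0
        self.eta_eb = np.zeros((prob.N, prob.q))
        self.se_draws = []
        self.psd_clipped = False
        self.trace = []

    # -- Metropolis-Hastings simulation step --------------------------------

    def _refresh_rss(self):
        prob = self.prob
        mp = prob.mean_psi(self.theta)
        self.rss = np.stack(
            [prob.rss_by_subject(prob.full_psi(mp, self.eta[c]))
             for c in range(self.L)]
        )
        self._mp = mp

    def _accept(self, c, eta_new, rss_new, extra_logratio=0.0):
        dll = -(rss_new - self.rss[c]) / (2 * self.sigma2) + extra_logratio
        u = np.log(self.rng.random(self.prob.N))
        acc = u < dll
        self.eta[c][acc] = eta_new[acc]
        self.rss[c][acc] = rss_new[acc]
        return acc

    def mh_sweep(self, adapt):
        prob = self.prob
        if prob.q == 0:
            self._refresh_rss()
            return
        B = self.B
        w, V = np.linalg.eigh(B)
        w = np.maximum(w, self.settings.var_floor)
        Lb = V * np.sqrt(w)
        Binv = V @ np.diag(1.0 / w) @ V.T
        sd = np.sqrt(np.diag(B).clip(min=self.settings.var_floor))
        self._refresh_rss()
        mp = self._mp

        def prior_quad(e):
            return np.einsum("nq,qk,nk->n", e, Binv, e)

        for c in range(self.L):
            for _ in range(self.settings.mh_steps_per_iter):
                # kernel 1: independent draw from the prior
                z = self.rng.standard_normal((prob.N, prob.q))
                eta_new = z @ Lb.T
                rss_new = prob.rss_by_subject(prob.full_psi(mp, eta_new))
                self._accept(c, eta_new, rss_new)

                # kernel 2: componentwise random walk, per-subject scales
                for j in range(prob.q):
                    eta_new = self.eta[c].copy()
                    eta_new[:, j] += (
                        self.scales[:, j] * sd[j]
                        * self.rng.standard_normal(prob.N)
                    )
                    rss_new = prob.rss_by_subject(prob.full_psi(mp, eta_new))
                    dprior = -0.5 * (prior_quad(eta_new) - prior_quad(self.eta[c]))
                    acc = self._accept(c, eta_new, rss_new, dprior)
                    if adapt:
                        self.scales[:, j] = np.clip(
                            self.scales[:, j] * np.exp(0.2 * (acc - 0.35)),
                            1e-3, 1e2,
                        )

                # kernel 3: joint random walk along the prior factor
                z = self.rng.standard_normal((prob.N, prob.q))
                eta_new = self.eta[c] + self.scale_joint[:, None] * (z @ Lb.T)
                rss_new = prob.rss_by_subject(prob.full_psi(mp, eta_new))
                dprior = -0.5 * (prior_quad(eta_new) - prior_quad(self.eta[c]))
                acc = self._accept(c, eta_new, rss_new, dprior)
                if adapt:
                    self.scale_joint = np.clip(
                        self.scale_joint * np.exp(0.2 * (acc - 0.35)),
                        1e-3, 1e2,
                    )

    # -- stochastic approximation and M-step --------------------------------

    def sa_update(self, gamma):
        prob = self.prob
        if prob.q:
            phi = self._mp[:, prob.r_idx][None] + self.eta  # (L, N, q)
            phi_bar = phi.mean(axis=0)
            s2 = np.einsum("lnq,lnk->qk", phi, phi) / self.L
            self.H_phi += gamma * (phi_bar - self.H_phi)
            self.S2 += gamma * (s2 - self.S2)
        self.s3 += gamma * (float(self.rss.sum(axis=1).mean(axis=0)) - self.s3)

    def m_step(self, gamma, anneal=False):
        prob = self.prob
        st = self.settings
        q = prob.q
        B_prev = self.B.copy()
        sigma2_prev = self.sigma2
        if q:
            # GLS update of the coefficients of random parameters
            w, V = np.linalg.eigh(self.B)
            Binv = V @ np.diag(1.0 / np.maximum(w, st.var_floor)) @ V.T
            sizes = [prob.n_coef[k] for k in prob.r_idx]
            ptot = sum(sizes)
            A = np.zeros((ptot, ptot))
            b = np.zeros(ptot)
            pos_i = 0
            for a_, ka in enumerate(prob.r_idx):
                Da = prob.designs[ka]
                pos_j = 0
                for b_, kb in enumerate(prob.r_idx):
                    Db = prob.designs[kb]
                    A[pos_i:pos_i + sizes[a_], pos_j:pos_j + sizes[b_]] = (
                        Binv[a_, b_] * (Da.T @ Db)
                    )
                    pos_j += sizes[b_]
                b[pos_i:pos_i + sizes[a_]] = Da.T @ (self.H_phi @ Binv[a_])
                pos_i += sizes[a_]
            gam = np.linalg.solve(A + 1e-12 * np.eye(ptot), b)
            pos = 0
            for a_, ka in enumerate(prob.r_idx):
                self.theta[ka] = gam[pos:pos + sizes[a_]]
                pos += sizes[a_]

            # B from approximated second moments, masked and PSD-projected
            mcols = np.column_stack(
                [prob.designs[k] @ self.theta[k] for k in prob.r_idx]
            )
            Bnew = (
                self.S2
                - mcols.T @ self.H_phi
                - self.H_phi.T @ mcols
                + mcols.T @ mcols
            ) / prob.N
            Bnew = 0.5 * (Bnew + Bnew.T)
            Bnew = np.where(self.prob.bmask, Bnew, 0.0)
            Bnew, clipped = _blockwise_psd(Bnew, prob.bmask, st.var_floor)
            if clipped:
                self.psd_clipped = True
            self.B = Bnew

        self.sigma2 = max(self.s3 / prob.n_obs, st.sigma2_floor)

        if anneal:
            # simulated-annealing phase: variances may grow freely but can
            # shrink only by a bounded factor per iteration, so the means
            # explore a flat likelihood before the fit sharpens
            a = st.anneal_factor
            self.sigma2 = max(self.sigma2, a * sigma2_prev)
            if q:
                d_new = np.diag(self.B).copy()
                d_floor = a * np.diag(B_prev)
                scale = np.sqrt(np.maximum(d_floor / np.maximum(d_new, 1e-300), 1.0))
                self.B = self.B * np.outer(scale, scale)

        if prob.nr_idx:
            self._update_nonrandom(gamma)

    def _update_nonrandom(self, gamma):
        """Damped Gauss-Newton step for parameters without random effects."""
        prob = self.prob
        cols = []
        resid = []
        mp = prob.mean_psi(self.theta)
        for c in range(self.L):
            Psi = prob.full_psi(mp, self.eta[c])
            Pobs = Psi[prob.code]
            r = prob.y - prob.model.evaluate(prob.t_eval, Pobs, prob.smooth)
            dp = prob.model.dpsi(prob.t_eval, Pobs, prob.smooth)
            Jc = [dp[:, [k]] * prob.designs[k][prob.code] for k in prob.nr_idx]
            cols.append(np.hstack(Jc))
            resid.append(r)
        J = np.vstack(cols)
        r = np.concatenate(resid)
        JtJ = J.T @ J
        ridge = 1e-8 * (np.trace(JtJ) + 1.0)
        try:
            delta = np.linalg.solve(JtJ + ridge * np.eye(JtJ.shape[0]), J.T @ r)
        except np.linalg.LinAlgError:
            return
        rss0 = float(r @ r)
        theta0 = [self.theta[k].copy() for k in prob.nr_idx]
        step = gamma
        for _ in range(5):
            pos = 0
            for idx, k in enumerate(prob.nr_idx):
                nk = prob.n_coef[k]
                self.theta[k] = theta0[idx] + step * delta[pos:pos + nk]
                pos += nk
            mp = prob.mean_psi(self.theta)
            rss1 = 0.0
            for c in range(self.L):
                rss1 += float(prob.rss_by_subject(prob.full_psi(mp, self.eta[c])).sum())
            if rss1 <= rss0 * (1 + 1e-12):
                return
            step *= 0.5
        for idx, k in enumerate(prob.nr_idx):  # no improvement: keep previous
            self.theta[k] = theta0[idx]

    def packed(self):
        Bfull = np.zeros((self.prob.q, self.prob.q))
        Bfull[:] = self.B
        return self.prob.pack(self.theta, Bfull, self.sigma2)


def fit(data: LongData, spec: ModelSpec, settings: SAEMSettings | None = None) -> FitResult:
    """Fit the model by SAEM and return the full :class:`FitResult`."""
    t0 = _time.perf_counter()
    settings = settings or SAEMSettings()
    prob = _Problem(data, spec)
    m = prob.model
    rng = np.random.default_rng(settings.seed)

    initials = _initial_values(data, spec, prob)
    start = initials.start.copy()
    theta = []
    for k in range(m.n_params):
        vec = np.zeros(prob.n_coef[k])
        vec[0] = start[k]
        theta.append(vec)
    B0, sigma0 = variance_initials(data, m, start, prob.smooth)
    B = B0[np.ix_(prob.r_idx, prob.r_idx)]
    sigma2 = float(sigma0**2)

    mp0 = prob.mean_psi(theta)
    f0 = prob.predict_obs(prob.model.clip_psi(mp0))
    if not np.all(np.isfinite(f0)):
        raise InitializationError(
            "non-finite likelihood at the initial values; supply start= explicitly"
        )

    state = _SAEMState(prob, theta, B, sigma2, settings, rng)
    K1, K2 = settings.n_burn_iters, settings.n_sa_iters
    n_anneal = settings.n_anneal_iters
    if n_anneal is None:
        n_anneal = K1 // 2
    se_start = K1 + K2 - min(settings.se_window, K2)
    for k in range(K1 + K2):
        gamma = 1.0 if k < K1 else (k - K1 + 1) ** (-settings.step_exponent)
        state.mh_sweep(adapt=k < K1)
        state.sa_update(gamma)
        state.m_step(gamma, anneal=k < n_anneal)
        state.trace.append(state.packed())
        if k >= K1:
            state.eta_eb += gamma * (state.eta.mean(axis=0) - state.eta_eb)
        if settings.compute_se and k >= se_start:
            state.se_draws.append(state.eta[0].copy())

    trace = np.asarray(state.trace)
    final = trace[-1]
    # converged when every per-iteration update in the trailing window is
    # below tolerance relative to the final value (scale floor 0.1): the
    # update size is gamma_k times the innovation, so it contracts as the
    # SA step decreases only if the chain has stopped drifting
    window = min(settings.convergence_window, K2)
    tail = trace[-(window + 1):]
    denom = np.maximum(np.abs(final), 0.1)
    # a covariance entry near zero has no scale of its own: measure it on
    # the correlation scale sqrt(B_ii * B_jj)
    n_fixed_ = sum(prob.n_coef)
    _, Bq_, _ = prob.unpack(final)
    for pos, (i, j) in enumerate(prob.b_free):
        if i != j:
            corr_scale = math.sqrt(max(Bq_[i, i] * Bq_[j, j], 0.0))
            denom[n_fixed_ + pos] = max(denom[n_fixed_ + pos], corr_scale)
    max_rel = float(np.max(np.abs(np.diff(tail, axis=0)) / denom))
    converged = (
        np.all(np.isfinite(final))
        and max_rel < settings.convergence_tol
    )

    theta_hat, Bq, sigma2_hat = prob.unpack(final)
    d = m.n_params
    alpha = np.array([theta_hat[k][0] for k in range(d)])
    beta = tuple(
        {name: theta_hat[k][1 + j] for j, name in enumerate(spec.predictors[k])}
        for k in range(d)
    )
    Bfull = np.zeros((d, d))
    Bfull[np.ix_(prob.r_idx, prob.r_idx)] = Bq
    estimates = ParameterSet(
        alpha=alpha,
        beta=beta,
        random_mask=m.random_mask,
        B=Bfull,
        sigma=float(np.sqrt(sigma2_hat)),
    )

    warnings_ = []
    if state.psd_clipped:
        warnings_.append("B update lost positive semi-definiteness; projected to PSD")

    ses = {name: None for name in prob.packed_names}
    if settings.compute_se:
        # linearized Fisher information at the EB estimates; the Louis
        # stochastic approximation (estimate_standard_errors) needs orders
        # of magnitude more conditional draws than a fit produces whenever
        # the missing-information fraction is high, as it is for all three
        # structural models
        ses, se_warn = _linearized_ses(
            prob, theta_hat, Bq, sigma2_hat, state.eta_eb
        )
        warnings_.extend(se_warn)
    est_map = dict(zip(prob.packed_names, final))
    cv = {
        name: (100.0 * ses[name] / abs(est_map[name])
               if ses[name] is not None and est_map[name] != 0 else None)
        for name in prob.packed_names
    }
    n_fixed = sum(prob.n_coef)
    fixed_names = prob.packed_names[:n_fixed]
    pvalues = wald_pvalues(
        {n: est_map[n] for n in fixed_names}, {n: ses[n] for n in fixed_names}
    )

    n_free = n_fixed + len(prob.b_free) + 1
    loglik = loglik_se = float("nan")
    if settings.compute_loglik:
        loglik, loglik_se = _marginal_loglik_state(
            prob, theta_hat, Bq, sigma2_hat, state.eta_eb,
            settings.n_is_samples, settings.seed + 1,
        )
    aic = -2 * loglik + 2 * n_free
    bic = -2 * loglik + math.log(prob.N) * n_free

    eta_full = np.zeros((prob.N, d))
    eta_full[:, prob.r_idx] = state.eta_eb
    psi_hat = prob.full_psi(prob.mean_psi(theta_hat), state.eta_eb)
    idx = pd.Index(prob.subject_ids, name=data.id_col)
    result = FitResult(
        model_id=spec.model_id,
        model_name=m.name,
        param_names=m.param_names,
        estimates=estimates,
        ses=ses,
        cv_pct=cv,
        pvalues=pvalues,
        loglik=loglik,
        loglik_se=loglik_se,
        aic=aic,
        bic=bic,
        n_free_parameters=n_free,
        converged=bool(converged),
        max_rel_change=max_rel,
        trace=trace,
        trace_names=prob.packed_names,
        runtime_s=_time.perf_counter() - t0,
        n_subjects=prob.N,
        n_obs=prob.n_obs,
        time_range=(float(prob.t_raw.min()), float(prob.t_raw.max())),
        time_shift=prob.time_shift,
        smooth=prob.smooth,
        initials=initials,
        eta=pd.DataFrame(eta_full, index=idx, columns=m.param_names),
        psi=pd.DataFrame(psi_hat, index=idx, columns=m.param_names),
        covariates=prob.covariates,
        warnings=warnings_,
        outcome_col=data.outcome_col,
        time_col=data.time_col,
        id_col=data.id_col,
    )
    logger.info(
        "SAEM finished in %.1f s (converged=%s, max rel change %.2g)",
        result.runtime_s, result.converged, max_rel,
    )
    return result


# ---------------------------------------------------------------------------
# Standard errors (Louis' identity)
# ---------------------------------------------------------------------------

def _numeric_score(fun, x, h):
    g = np.empty(x.size)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (fun(x + e) - fun(x - e)) / (2 * h[i])
    return g


def _numeric_hessian(fun, x, h):
    n = x.size
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros_like(x)
        ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros_like(x)
            ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def estimate_standard_errors(prob: _Problem, theta_packed, eta_draws):
    """Louis-identity SEs from conditional draws accumulated in the SA phase.

    The observed information is E[-d2 lc] - E[dlc dlc'] + E[dlc] E[dlc]'
    with expectations over the stored conditional draws of the random
    effects; derivatives of the complete-data log-likelihood are numerical.
    Returns ``(ses, warnings)`` with missing (None) SEs when the information
    matrix is singular.
    """
    names = prob.packed_names
    if not eta_draws:
        return {n: None for n in names}, ["no draws stored for standard errors"]
    x = np.asarray(theta_packed, float)

    # differentiate in a balanced space: log for variances and sigma^2
    # (their scales span orders of magnitude), identity elsewhere
    n_fixed = sum(prob.n_coef)
    is_log = np.zeros(x.size, bool)
    for pos, (i, j) in enumerate(prob.b_free):
        if i == j:
            is_log[n_fixed + pos] = True
    is_log[-1] = True
    safe = np.where(is_log, np.maximum(x, 1e-12), x)

    def to_packed(z):
        return np.where(is_log, np.exp(z), z)

    z0 = safe.copy()
    z0[is_log] = np.log(safe[is_log])
    h = 1e-4 * np.maximum(np.abs(z0), 1e-2)
    Hbar = np.zeros((x.size, x.size))
    Gbar = np.zeros((x.size, x.size))
    gbar = np.zeros(x.size)
    M = len(eta_draws)
    for eta in eta_draws:
        fun = lambda z: prob.complete_loglik(to_packed(z), eta)
        g = _numeric_score(fun, z0, h)
        H = _numeric_hessian(fun, z0, h)
        gbar += g / M
        Gbar += np.outer(g, g) / M
        Hbar += H / M
    info = -Hbar - Gbar + np.outer(gbar, gbar)
    info = 0.5 * (info + info.T)
    warnings_ = []
    try:
        w = np.linalg.eigvalsh(info)
        if np.min(w) <= 0:
            raise np.linalg.LinAlgError
        cov = np.linalg.inv(info)
        # delta method back to the natural scale: d theta / d log theta = theta
        jac = np.where(is_log, safe, 1.0)
        ses = {
            n: float(np.sqrt(max(cov[i, i], 0.0)) * jac[i])
            for i, n in enumerate(names)
        }
    except np.linalg.LinAlgError:
        warnings_.append("information matrix singular; standard errors not available")
        ses = {n: None for n in names}
    return ses, warnings_


def _linearized_ses(prob: _Problem, theta, Bq, sigma2, eta_eb):
    """First-order (linearized) Fisher information at the EB estimates.

    The structural model is linearized around each subject's conditional
    random-effect estimate, giving the classical marginal normal model
    V_i = Z_i B Z_i' + sigma^2 I. Fixed-effect information is
    sum A_i' V_i^{-1} A_i; variance-parameter information is
    0.5 tr(V^{-1} dV_a V^{-1} dV_b); the two blocks are orthogonal under
    normality. Better conditioned than Louis' identity when B is nearly
    singular, at the price of the linearization.
    """
    names = prob.packed_names
    d = prob.model.n_params
    mp = prob.mean_psi(theta)
    Psi = prob.full_psi(mp, eta_eb)
    Pobs = Psi[prob.code]
    dp = prob.model.dpsi(prob.t_eval, Pobs, prob.smooth)  # (n_obs, d)

    n_fixed = sum(prob.n_coef)
    nv = len(prob.b_free) + 1
    I_ff = np.zeros((n_fixed, n_fixed))
    I_vv = np.zeros((nv, nv))
    col_of = np.cumsum([0] + prob.n_coef)
    for i in range(prob.N):
        sl = slice(prob.offsets[i], prob.offsets[i] + prob.n_i[i])
        ni = prob.n_i[i]
        dpi = dp[sl]
        Z = dpi[:, prob.r_idx]                       # (ni, q)
        V = Z @ Bq @ Z.T + sigma2 * np.eye(ni)
        Vinv = np.linalg.inv(V)
        A = np.empty((ni, n_fixed))
        for k in range(d):
            A[:, col_of[k]:col_of[k + 1]] = dpi[:, [k]] * prob.designs[k][i]
        I_ff += A.T @ Vinv @ A
        dVs = []
        for (a, b) in prob.b_free:
            za, zb = Z[:, [a]], Z[:, [b]]
            dV = za @ zb.T
            if a != b:
                dV = dV + dV.T
            dVs.append(dV)
        dVs.append(np.eye(ni))
        W = [Vinv @ dV for dV in dVs]
        for a in range(nv):
            for b in range(a, nv):
                val = 0.5 * np.trace(W[a] @ W[b])
                I_vv[a, b] += val
                if a != b:
                    I_vv[b, a] += val

    ses = {n: None for n in names}
    warnings_ = []
    for block, offset, size in ((I_ff, 0, n_fixed), (I_vv, n_fixed, nv)):
        try:
            w = np.linalg.eigvalsh(block)
            if np.min(w) <= 0:
                raise np.linalg.LinAlgError
            cov = np.linalg.inv(block)
            for j in range(size):
                ses[names[offset + j]] = float(np.sqrt(max(cov[j, j], 0.0)))
        except np.linalg.LinAlgError:
            warnings_.append(
                "linearized information block singular; SEs partially missing"
            )
    return ses, warnings_


# ---------------------------------------------------------------------------
# Wald p-values
# ---------------------------------------------------------------------------

def wald_pvalues(estimates: dict, ses: dict) -> dict:
    """Two-sided p = 2(1 - Phi(|est| / SE)) for every fixed effect.

    A missing SE yields a missing p-value, never 0.
    """
    out = {}
    for name, est in estimates.items():
        se = ses.get(name)
        if se is None or se <= 0:
            out[name] = None
        else:
            out[name] = float(2.0 * stats.norm.sf(abs(est) / se))
    return out


# ---------------------------------------------------------------------------
# Marginal log-likelihood by importance sampling
# ---------------------------------------------------------------------------

def _marginal_loglik_state(prob, theta, Bq, sigma2, eta_start, n_is, seed):
    """Importance sampling in the whitened random-effect space.

    With eta = L z (L the Cholesky factor of the non-degenerate block of B)
    the integral becomes an expectation over z ~ N(0, I); the proposal is a
    Gaussian centred at the conditional mode of z with an inflated Laplace
    covariance. Components whose variance is numerically zero are pinned at
    0 (the integral collapses in that direction).
    """
    rng = np.random.default_rng(seed)
    mp = prob.mean_psi(theta)
    q = prob.q
    const_i = -0.5 * prob.n_i * math.log(2 * math.pi * sigma2)

    active = [j for j in range(q) if Bq[j, j] > 1e-10]
    qa = len(active)
    if qa == 0:
        Psi = prob.full_psi(mp, np.zeros((prob.N, q)))
        rss = prob.rss_by_subject(Psi)
        return float(np.sum(const_i - rss / (2 * sigma2))), 0.0

    Ba = Bq[np.ix_(active, active)]
    wb, Vb = np.linalg.eigh(Ba)
    wb = np.maximum(wb, 1e-12)
    Binv = (Vb / wb) @ Vb.T
    logdetB = float(np.sum(np.log(wb)))

    # per-subject proposal moments from conditional MH draws at fixed theta
    theta_full = [t.copy() for t in theta]
    settings = SAEMSettings(n_burn_iters=1, n_sa_iters=1, seed=seed,
                            n_chains=1, compute_se=False, compute_loglik=False)
    state = _SAEMState(prob, theta_full, Bq, sigma2, settings,
                       np.random.default_rng(seed + 1))
    state.eta[0] = eta_start
    n_burn, n_keep = 100, 150
    m1 = np.zeros((prob.N, q))
    m2 = np.zeros((prob.N, q, q))
    for k in range(n_burn + n_keep):
        state.mh_sweep(adapt=k < n_burn)
        if k >= n_burn:
            m1 += state.eta[0] / n_keep
            m2 += np.einsum("nq,nk->nqk", state.eta[0], state.eta[0]) / n_keep
    mean = m1[:, active]
    cov = (m2 - np.einsum("nq,nk->nqk", m1, m1))[np.ix_(range(prob.N), active, active)]
    cov = 1.5 * cov + 1e-6 * np.eye(qa)  # inflate; jitter for stability
    Lp = np.linalg.cholesky(cov)
    logdetP = 2.0 * np.sum(np.log(np.diagonal(Lp, axis1=1, axis2=2)), axis=1)

    # vectorised importance sampling: one full-population pass per sample
    logw = np.empty((n_is, prob.N))
    for s in range(n_is):
        z = rng.standard_normal((prob.N, qa))
        e_act = mean + np.einsum("nqk,nk->nq", Lp, z)
        eta = np.zeros((prob.N, q))
        eta[:, active] = e_act
        rss = prob.rss_by_subject(prob.full_psi(mp, eta))
        log_lik = const_i - rss / (2 * sigma2)
        log_prior = (
            -0.5 * (qa * math.log(2 * math.pi) + logdetB)
            - 0.5 * np.einsum("nq,qk,nk->n", e_act, Binv, e_act)
        )
        log_prop = (
            -0.5 * (qa * math.log(2 * math.pi) + logdetP)
            - 0.5 * np.sum(z * z, axis=1)
        )
        logw[s] = log_lik + log_prior - log_prop
    li = logsumexp(logw, axis=0) - math.log(n_is)
    wts = np.exp(logw - logw.max(axis=0, keepdims=True))
    wbar = wts.mean(axis=0)
    var_i = np.where(wbar > 0, wts.var(axis=0) / (n_is * wbar**2), 0.0)
    return float(li.sum()), float(np.sqrt(var_i.sum()))


def marginal_loglik(data: LongData, spec: ModelSpec, estimates: ParameterSet,
                    n_is_samples=500, seed=0):
    """Importance-sampling marginal log-likelihood at given estimates.

    Returns ``(loglik, mc_se)``; reproducible for a fixed seed.
    """
    prob = _Problem(data, spec)
    m = prob.model
    theta = []
    for k in range(m.n_params):
        vec = np.zeros(prob.n_coef[k])
        vec[0] = estimates.alpha[k]
        for j, name in enumerate(spec.predictors[k]):
            vec[1 + j] = estimates.beta[k].get(name, 0.0)
        theta.append(vec)
    Bq = estimates.B[np.ix_(prob.r_idx, prob.r_idx)]
    sigma2 = float(max(estimates.sigma, 1e-8) ** 2)
    eta0 = np.zeros((prob.N, prob.q))
    return _marginal_loglik_state(prob, theta, Bq, sigma2, eta0, n_is_samples, seed)


# ---------------------------------------------------------------------------
# Empirical Bayes estimates at fixed parameters
# ---------------------------------------------------------------------------

def empirical_bayes(data: LongData, spec: ModelSpec, estimates: ParameterSet,
                    n_burn=100, n_keep=200, seed=0):
    """Conditional means of the random effects at fixed parameter values.

    Runs Metropolis-Hastings at the supplied estimates and averages the kept
    draws. Returns ``(eta, psi)`` as subject-indexed data frames.
    """
    prob = _Problem(data, spec)
    m = prob.model
    theta = []
    for k in range(m.n_params):
        vec = np.zeros(prob.n_coef[k])
        vec[0] = estimates.alpha[k]
        for j, name in enumerate(spec.predictors[k]):
            vec[1 + j] = estimates.beta[k].get(name, 0.0)
        theta.append(vec)
    Bq = estimates.B[np.ix_(prob.r_idx, prob.r_idx)]
    sigma2 = float(max(estimates.sigma, 1e-8) ** 2)
    settings = SAEMSettings(
        n_burn_iters=1, n_sa_iters=1, seed=seed, n_chains=1,
        compute_se=False, compute_loglik=False,
    )
    state = _SAEMState(prob, theta, Bq, sigma2, settings, np.random.default_rng(seed))
    acc = np.zeros((prob.N, prob.q))
    for k in range(n_burn + n_keep):
        state.mh_sweep(adapt=k < n_burn)
        if k >= n_burn:
            acc += state.eta[0] / n_keep
    eta_full = np.zeros((prob.N, m.n_params))
    eta_full[:, prob.r_idx] = acc
    psi = prob.full_psi(prob.mean_psi(theta), acc)
    idx = pd.Index(prob.subject_ids, name=data.id_col)
    return (
        pd.DataFrame(eta_full, index=idx, columns=m.param_names),
        pd.DataFrame(psi, index=idx, columns=m.param_names),
    )
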