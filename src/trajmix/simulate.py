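"""Synthetic longitudinal data with the structure of decedent cohort studies.

The generator emulates retrospective cognitive-decline data: subjects have
roughly annual visits jittered uniformly within +/-2 months, from up to 24
years before death (time 0), with follow-up length drawn from a truncated
normal and at least 4 observations each. Outcomes follow either the
sigmoidal (model 1) or the piecewise-linear (model 2) structural model with
Gaussian random effects and residual noise.

Two stock scenarios, :func:`smm_scenario` and :func:`pmm_scenario`, carry the
generative values of the performance simulation study (sigmoid: last level
-1.03, initial level 0.37, midpoint 4.0 on the time-before-death scale, Hill
slope 1.69, random-effect SDs 1.46 and 0.51; piecewise: intercept -1.21,
early slope -0.03, terminal slope -0.32, changepoint -3, random-effect SDs
1.70, 0.01, 0.05, 6.91 with correlation -0.07 between the slopes; residual
SD 0.28 in both).

The follow-up truncated normal is location-calibrated so its post-truncation
mean equals the stated mean follow-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import LongData, from_frame
from .errors import ConfigurationError
from .models import MODELS, ParameterLink, SmoothConfig

__all__ = [
    "SimScenario",
    "SimResult",
    "smm_scenario",
    "pmm_scenario",
    "generate_visits",
    "simulate_dataset",
    "make_example_dataset",
    "scenario_to_dict",
    "scenario_from_dict",
]


@dataclass
class SimScenario:
    """Generative configuration for one simulated dataset."""

    model_id: int
    n_subjects: int
    truth: ParameterLink
    visit_window_years: float = 2.0 / 12.0
    max_span_years: float = 24.0
    mean_followup: float = 10.0
    sd_followup: float = 5.0
    min_obs: int = 4
    n_covariates_per_param: int = 0
    covariate_effect: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.model_id not in (1, 2):
            raise ConfigurationError("simulation model_id must be 1 (SMM) or 2 (PMM)")
        if self.min_obs < 1:
            raise ConfigurationError("min_obs must be >= 1")
        if self.n_covariates_per_param not in (0, 1, 2):
            raise ConfigurationError("n_covariates_per_param must be 0, 1 or 2")


@dataclass
class SimResult:
    """A simulated table plus its generative truth, for oracle tests."""

    data: LongData
    scenario: SimScenario
    eta: np.ndarray          # (N, 4) subject random effects (zeros where fixed)
    psi: np.ndarray          # (N, 4) realised structural parameters
    covariates: pd.DataFrame


def smm_scenario(n_subjects=100, n_covariates_per_param=0, seed=0) -> SimScenario:
    """Sigmoidal generative scenario of the performance study."""
    sd1, sd2 = 1.46, 0.51
    B = np.zeros((4, 4))
    B[0, 0], B[1, 1] = sd1**2, sd2**2
    beta = tuple(
        {f"cov{j + 1}": 0.1 for j in range(n_covariates_per_param)} for _ in range(4)
    )
    truth = ParameterLink(
        alpha=[-1.03, 0.37, 4.0, 1.69],
        beta=beta,
        random_mask=(True, True, False, False),
        B=B,
        sigma=0.28,
    )
    return SimScenario(
        model_id=1,
        n_subjects=n_subjects,
        truth=truth,
        n_covariates_per_param=n_covariates_per_param,
        seed=seed,
    )


def pmm_scenario(n_subjects=100, n_covariates_per_param=0, seed=0) -> SimScenario:
    """Piecewise generative scenario of the performance study.

    Random-effect SDs (1.70, 0.01, 0.05, 6.91) and the -0.07 correlation
    between the two slope effects define B directly.
    """
    sds = np.array([1.70, 0.01, 0.05, 6.91])
    B = np.diag(sds**2)
    B[1, 2] = B[2, 1] = -0.07 * sds[1] * sds[2]
    beta = tuple(
        {f"cov{j + 1}": 0.1 for j in range(n_covariates_per_param)} for _ in range(4)
    )
    truth = ParameterLink(
        alpha=[-1.21, -0.03, -0.32, -3.0],
        beta=beta,
        random_mask=(True, True, True, True),
        B=B,
        sigma=0.28,
    )
    return SimScenario(
        model_id=2,
        n_subjects=n_subjects,
        truth=truth,
        n_covariates_per_param=n_covariates_per_param,
        seed=seed,
    )


@lru_cache(maxsize=64)
def _calibrated_mu(target_mean, sd, lo, hi):
    """Latent normal location so the OBSERVED mean follow-up hits the target.

    Visits sit on the annual grid 0..floor(span), so the realised follow-up
    of a subject is floor(span); the location is solved so that
    E[floor(span)] under the [lo, hi]-truncated normal equals the target.
    """
    ks = np.arange(int(np.floor(lo)), int(np.floor(hi)) + 1)

    def floor_mean(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        upper = np.minimum(ks + 1.0, hi)
        lower = np.maximum(ks.astype(float), lo)
        p = (stats.truncnorm.cdf(upper, a, b, loc=mu, scale=sd)
             - stats.truncnorm.cdf(lower, a, b, loc=mu, scale=sd))
        return float((ks * p).sum())

    return optimize.brentq(
        lambda mu: floor_mean(mu) - target_mean, lo - 6 * sd, hi + 6 * sd, xtol=1e-8
    )


def _draw_span(rng, mu, sd, lo, hi):
    # regenerate-on-violation: exact truncated normal, smooth distribution
    for _ in range(10000):
        s = rng.normal(mu, sd)
        if lo <= s <= hi:
            return s
    raise RuntimeError("follow-up span rejection sampling failed")


def generate_visits(scenario: SimScenario, rng) -> np.ndarray:
    """Visit times (years, ascending, <= 0) for one subject.

    Annual grid from -span to 0, each visit jittered uniformly within the
    visit window; regenerated until at least ``min_obs`` visits land inside
    [-max_span, 0].
    """
    lo = float(scenario.min_obs)
    hi = scenario.max_span_years
    mu = _calibrated_mu(scenario.mean_followup, scenario.sd_followup, lo, hi)
    w = scenario.visit_window_years
    while True:
        span = _draw_span(rng, mu, scenario.sd_followup, lo, hi)
        grid = -np.arange(int(np.floor(span)) + 1, dtype=float)
        t = grid + rng.uniform(-w, w, size=grid.size)
        t = np.clip(t, -scenario.max_span_years, 0.0)
        if t.size >= scenario.min_obs:
            return np.sort(t)


def _draw_eta(rng, truth: ParameterLink, n):
    eta = np.zeros((n, 4))
    idx = truth.random_idx
    if idx:
        sub = truth.B_sub()
        # eigen factorisation tolerates the near-singular B of noise-free tests
        w, V = np.linalg.eigh(sub)
        L = V * np.sqrt(np.maximum(w, 0.0))
        eta[:, idx] = rng.standard_normal((n, len(idx))) @ L.T
    return eta


def simulate_dataset(scenario: SimScenario, smooth: SmoothConfig | None = None) -> SimResult:
    """Generate one dataset under the scenario; returns data plus the truth.

    Random effects are drawn MVN(0, B) with the model's sparsity, structural
    parameters assembled as alpha + beta'X + eta, the mean evaluated at the
    visit times and Gaussian residual noise added. Covariates (if any) are
    standard normal, subject-constant.
    """
    rng = np.random.default_rng(scenario.seed)
    model = MODELS[scenario.model_id]
    truth = scenario.truth
    n = scenario.n_subjects

    cov_names = truth.covariate_names()
    X = pd.DataFrame(
        rng.standard_normal((n, len(cov_names))), columns=cov_names
    )
    eta = _draw_eta(rng, truth, n)
    psi = np.tile(truth.alpha, (n, 1))
    for k in range(4):
        for name, coef in truth.beta[k].items():
            psi[:, k] += coef * X[name].to_numpy()
    psi += eta
    psi = model.clip_psi(psi)

    rows = []
    ids = np.arange(1000, 1000 + n)
    for i in range(n):
        t = generate_visits(scenario, rng)
        s = -t if model.positive_time else t
        mean = model.evaluate(s, np.tile(psi[i], (t.size, 1)), smooth)
        y = mean + rng.normal(0.0, truth.sigma, size=t.size)
        for tj, yj in zip(t, y):
            rows.append((ids[i], tj, yj))
    df = pd.DataFrame(rows, columns=["ID", "time", "outcome"])
    for name in cov_names:
        df[name] = df["ID"].map(dict(zip(ids, X[name])))
    data = from_frame(df, "ID", "outcome", "time")
    X.index = ids
    return SimResult(data=data, scenario=scenario, eta=eta, psi=psi, covariates=X)


def make_example_dataset(seed=123) -> LongData:
    """Demo cohort: 1200 decedents with annual cognitive testing.

    A synthetic stand-in (not a copy of any packaged or real dataset):
    piecewise-linear decline with intercept -1.2, early slope -0.03, terminal
    slope -0.32 and changepoint -3 years before death; age at death drawn
    N(90, 6) truncated to [65, 108] and linked with small negative effects to
    the last level and the changepoint, so older age at death goes with lower
    terminal cognition and earlier accelerated decline. Mean follow-up 7
    years (SD 5), minimum 4 visits. Columns: ID, time, cognition, ageDeath.
    """
    sds = np.array([1.04, 0.025, 0.196, 0.77])
    B = np.diag(sds**2)
    B[1, 2] = B[2, 1] = 0.0038
    truth = ParameterLink(
        alpha=[-1.2, -0.03, -0.32, -3.0],
        beta=({"ageDeath90": -0.02}, {}, {}, {"ageDeath90": -0.05}),
        random_mask=(True, True, True, True),
        B=B,
        sigma=0.28,
    )
    scenario = SimScenario(
        model_id=2,
        n_subjects=1200,
        truth=truth,
        mean_followup=7.0,
        sd_followup=5.0,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    n = scenario.n_subjects
    age = np.empty(n)
    for i in range(n):
        age[i] = _draw_span(rng, 90.0, 6.0, 65.0, 108.0)
    age = np.round(age)
    eta = _draw_eta(rng, truth, n)
    psi = np.tile(truth.alpha, (n, 1))
    psi[:, 0] += truth.beta[0]["ageDeath90"] * (age - 90.0)
    psi[:, 3] += truth.beta[3]["ageDeath90"] * (age - 90.0)
    psi += eta
    rows = []
    ids = np.arange(1000, 1000 + n)
    for i in range(n):
        t = generate_visits(scenario, rng)
        mean = MODELS[2].evaluate(t, np.tile(psi[i], (t.size, 1)))
        y = mean + rng.normal(0.0, truth.sigma, size=t.size)
        for tj, yj in zip(t, y):
            rows.append((ids[i], round(tj, 2), round(yj, 2), age[i]))
    df = pd.DataFrame(rows, columns=["ID", "time", "cognition", "ageDeath"])
    return from_frame(df, "ID", "cognition", "time")


# ---------------------------------------------------------------------------
# Scenario (de)serialisation for the CLI and truth JSON round-trips
# ---------------------------------------------------------------------------

def scenario_to_dict(scenario: SimScenario) -> dict:
    d = asdict(scenario)
    t = scenario.truth
    d["truth"] = {
        "alpha": t.alpha.tolist(),
        "beta": [dict(b) for b in t.beta],
        "random_mask": list(t.random_mask),
        "B": t.B.tolist(),
        "sigma": t.sigma,
    }
    return d


def scenario_from_dict(d: dict) -> SimScenario:
    d = dict(d)
    try:
        t = d.pop("truth")
        truth = ParameterLink(
            alpha=t["alpha"],
            beta=tuple(t.get("beta", [{}, {}, {}, {}])),
            random_mask=tuple(t.get("random_mask", (True,) * 4)),
            B=np.asarray(t["B"], float) if "B" in t else None,
            sigma=t.get("sigma", 1.0),
        )
        return SimScenario(truth=truth, **d)
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed scenario: {exc}") from None


def scenario_to_json(scenario: SimScenario, path) -> None:
    with open(path, "w") as fh:
        json.dump(scenario_to_dict(scenario), fh, indent=1)


def scenario_from_json(path) -> SimScenario:
    with open(path) as fh:
        return scenario_from_dict(json.load(fh))
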