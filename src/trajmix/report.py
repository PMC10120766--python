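"""Marginal trajectories, group contrasts, spaghetti plots, text summary.

The marginal trajectory is the population mean curve: the structural model
evaluated at alpha-hat + beta-hat' x with the random effects set to zero, at
a fixed covariate profile (by default the "most common" profile: mode for
discrete covariates, median for continuous ones). Group contrasts evaluate
that curve at two values of one covariate — its observed 10th and 90th
percentile values for a continuous variable (linear-interpolation
percentiles), or its two levels for a binary one.

Plots are artifacts; every plotted series is also returned as a table so the
numeric pipeline never depends on a figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LongData
from .errors import ConfigurationError
from .models import MODELS
from .saem import FitResult

__all__ = [
    "TrajectoryRequest",
    "marginal_trajectory",
    "group_contrast",
    "spaghetti_plot",
    "render_summary",
    "most_common_profile",
]

#: Covariates with at most this many distinct values count as discrete.
DISCRETE_MAX_LEVELS = 10


@dataclass
class TrajectoryRequest:
    """What to evaluate: grid, covariate profile, optional group contrast."""

    time_grid: np.ndarray | None = None
    profile: dict = field(default_factory=dict)
    group_var: str | None = None
    group_percentiles: tuple = (0.10, 0.90)

    def __post_init__(self):
        lo, hi = self.group_percentiles
        if not (0 < lo < hi < 1):
            raise ConfigurationError(
                "group_percentiles must satisfy 0 < first < second < 1"
            )


def most_common_profile(fit: FitResult) -> dict:
    """Mode (discrete) or median (continuous) of each model covariate."""
    profile = {}
    for name in fit.covariates.columns:
        vals = fit.covariates[name].dropna()
        if vals.empty:
            continue
        if vals.nunique() <= DISCRETE_MAX_LEVELS:
            profile[name] = float(vals.mode().iloc[0])
        else:
            profile[name] = float(vals.median())
    return profile


def _grid(fit: FitResult, req: TrajectoryRequest) -> np.ndarray:
    if req.time_grid is not None:
        return np.asarray(req.time_grid, float)
    lo, hi = fit.time_range
    return np.linspace(lo, hi, 101)


def _profile_psi(fit: FitResult, profile: dict) -> np.ndarray:
    est = fit.estimates
    psi = est.alpha.copy()
    for k in range(est.n_params):
        for name, coef in est.beta[k].items():
            if name not in profile:
                raise ConfigurationError(
                    f"profile is missing covariate {name!r} used by the model"
                )
            psi[k] += coef * float(profile[name])
    return psi


def _curve(fit: FitResult, psi: np.ndarray, grid: np.ndarray) -> np.ndarray:
    model = MODELS.get(fit.model_id)
    if model is None:
        raise ConfigurationError("trajectories require one of the stock models")
    t = fit.time_shift - grid if model.positive_time else grid
    Psi = model.clip_psi(np.tile(psi, (grid.size, 1)))
    return np.asarray(model.evaluate(t, Psi, fit.smooth), float)


def marginal_trajectory(fit: FitResult, req: TrajectoryRequest | None = None) -> pd.DataFrame:
    """Population mean trajectory at the fitted fixed effects (eta = 0)."""
    req = req or TrajectoryRequest()
    profile = dict(most_common_profile(fit))
    profile.update(req.profile)
    grid = _grid(fit, req)
    pred = _curve(fit, _profile_psi(fit, profile), grid)
    return pd.DataFrame({fit.time_col: grid, "predicted": pred})


def group_contrast(fit: FitResult, req: TrajectoryRequest) -> pd.DataFrame:
    """Two labelled marginal trajectories contrasted on one covariate.

    Continuous group variable: trajectories at its empirical percentile
    values (default 10th/90th). Binary: the two observed levels.
    """
    name = req.group_var
    if name is None:
        raise ConfigurationError("group_contrast requires group_var")
    used = any(name in b for b in fit.estimates.beta)
    if not used or name not in fit.covariates.columns:
        raise ConfigurationError(
            f"group variable {name!r} is not a covariate of the fitted model"
        )
    vals = fit.covariates[name].to_numpy(float)
    uniq = np.unique(vals)
    if uniq.size == 2:
        levels = [float(uniq[0]), float(uniq[1])]
        labels = [f"{name}={v:g}" for v in levels]
    else:
        lo, hi = req.group_percentiles
        levels = [
            float(np.percentile(vals, 100 * lo)),
            float(np.percentile(vals, 100 * hi)),
        ]
        labels = [
            f"{name} p{100 * lo:g} ({levels[0]:g})",
            f"{name} p{100 * hi:g} ({levels[1]:g})",
        ]
    grid = _grid(fit, req)
    base = dict(most_common_profile(fit))
    base.update(req.profile)
    frames = []
    for lev, lab in zip(levels, labels):
        profile = dict(base)
        profile[name] = lev
        pred = _curve(fit, _profile_psi(fit, profile), grid)
        frames.append(pd.DataFrame(
            {fit.time_col: grid, "group": lab, "predicted": pred}
        ))
    return pd.concat(frames, ignore_index=True)


def spaghetti_plot(data: LongData, n_shown: int = 70, seed: int = 0,
                   xlabel: str | None = None, ylabel: str | None = None,
                   ax=None):
    """Observed individual trajectories for a random subset of subjects.

    Samples ``min(n_shown, N)`` subjects without replacement (seeded) and
    draws one polyline each. Axis labels default to the raw column names.
    Returns ``(figure, sampled_ids)``.
    """
    import matplotlib
    import matplotlib.pyplot as plt

    ids = data.subject_ids
    rng = np.random.default_rng(seed)
    k = min(n_shown, len(ids))
    chosen = rng.choice(ids, size=k, replace=False)
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 4.5))
    else:
        fig = ax.figure
    grouped = data.df.set_index(data.id_col)
    for sid in chosen:
        sub = grouped.loc[[sid]].sort_values(data.time_col)
        ax.plot(sub[data.time_col], sub[data.outcome_col],
                lw=0.7, alpha=0.6, color="steelblue")
    ax.set_xlabel(xlabel or data.time_col)
    ax.set_ylabel(ylabel or data.outcome_col)
    return fig, list(chosen)


def plot_trajectories(table: pd.DataFrame, time_col, path=None, ax=None,
                      xlabel=None, ylabel="predicted"):
    """Plot a (grouped) trajectory table; writes to ``path`` when given."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 4.5))
    else:
        fig = ax.figure
    if "group" in table.columns:
        for lab, sub in table.groupby("group", sort=False):
            ax.plot(sub[time_col], sub["predicted"], label=str(lab))
        ax.legend()
    else:
        ax.plot(table[time_col], table["predicted"], color="firebrick")
    ax.set_xlabel(xlabel or time_col)
    ax.set_ylabel(ylabel)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig


# ---------------------------------------------------------------------------
# Text summary
# ---------------------------------------------------------------------------

def _fmt(x, width=12):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA".rjust(width)
    if isinstance(x, float):
        if x != 0 and (abs(x) < 1e-3 or abs(x) >= 1e5):
            return f"{x:.3e}".rjust(width)
        return f"{x:.5g}".rjust(width)
    return str(x).rjust(width)


def _fmt_cv(cv):
    return "NA".rjust(8) if cv is None else f"{cv:.1f}".rjust(8)


def render_summary(fit: FitResult) -> str:
    """Annotated plain-text summary of a fitted model."""
    est = fit.packed_estimates()
    lines = []
    bar = "-" * 64
    lines += [bar, "Data summary", bar]
    lines.append(f"  Subjects (N):       {fit.n_subjects}")
    lines.append(f"  Observations:       {fit.n_obs}")
    lines.append(f"  Outcome:            {fit.outcome_col}")
    lines.append(
        f"  Time:               {fit.time_col} "
        f"(range {fit.time_range[0]:.2f} to {fit.time_range[1]:.2f})"
    )
    if fit.time_shift or fit.model_id == 1:
        lines.append(
            "  Note: model 1 is fitted on the positive time-before-zero "
            "scale; the midpoint is reported in positive time units."
        )
    lines += ["", bar, "Model", bar, f"  {fit.model_name}"]
    if fit.smooth is not None:
        lines.append(f"  Transition window v = {fit.smooth.v:g}")
    for k, pname in enumerate(fit.param_names):
        covs = ", ".join(fit.estimates.beta[k]) or "none"
        lines.append(f"  {pname}: covariates = {covs}")
    st = fit.initials
    lines.append(
        "  Initial values: "
        + ", ".join(f"{v:.4g} [{p}]" for v, p in zip(st.start, st.provenance))
    )

    n_fixed = sum(1 for n in fit.trace_names if n.startswith(("alpha.", "beta.")))
    lines += ["", bar, "Fixed effects", bar]
    header = f"{'Parameter':<34}{'Estimate':>12}{'SE':>12}{'CV(%)':>8}{'p-value':>12}"
    lines.append(header)
    for name in fit.trace_names[:n_fixed]:
        lines.append(
            f"{name:<34}" + _fmt(float(est[name]))
            + _fmt(fit.ses.get(name)) + _fmt_cv(fit.cv_pct.get(name))
            + _fmt(fit.pvalues.get(name))
        )

    lines += ["", bar, "Variance of random effects", bar]
    lines.append(f"{'Parameter':<34}{'Estimate':>12}{'SE':>12}{'CV(%)':>8}")
    for name in fit.trace_names[n_fixed:-1]:
        lines.append(
            f"{name:<34}" + _fmt(float(est[name]))
            + _fmt(fit.ses.get(name)) + _fmt_cv(fit.cv_pct.get(name))
        )

    lines += ["", bar, "Residual error", bar]
    lines.append(
        f"{'sigma2':<34}" + _fmt(float(est['sigma2']))
        + _fmt(fit.ses.get("sigma2")) + _fmt_cv(fit.cv_pct.get("sigma2"))
    )

    lines += ["", bar, "Statistical criteria", bar]
    lines.append(f"  Log-likelihood (importance sampling): {_fmt(fit.loglik, 0)}")
    lines.append(f"  AIC: {_fmt(fit.aic, 0)}   BIC: {_fmt(fit.bic, 0)}")
    lines.append(
        f"  Convergence: {'yes' if fit.converged else 'NO'} "
        f"(max relative change {fit.max_rel_change:.2g} over trailing window)"
    )
    for w in fit.warnings:
        lines.append(f"  Warning: {w}")
    lines += ["", f"The program took {fit.runtime_s:.2f} seconds"]
    return "\n".join(lines)
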