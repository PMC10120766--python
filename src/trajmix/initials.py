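"""Automated starting values for the four structural parameters.

SAEM needs starting values for the population means. Both heuristics are
purely data-driven:

* **Sigmoid (model 1)** — the last- and initial-level starts are the mean
  outcome in narrow bands around the 5th and 95th percentiles of the
  time-before-zero distribution; the midpoint start is 300 when the pooled
  trend is nearly linear (a sigmoid midpoint far beyond the data makes the
  curve locally linear) and 2 otherwise; the Hill-slope start is whichever of
  the candidates {0.5, 1.05} gives the smaller pooled residual sum of squares.

* **Piecewise (models 2-3)** — the intercept start is the mean outcome in the
  band at the 95th percentile of the time distribution; the time axis is cut
  into quintile bands, an OLS trend is fitted in each, and the changepoint
  start is the lower bound of the band with the largest absolute slope
  (the onset of the fastest change); the two slope starts are pooled OLS
  trends on the data before and after that approximate changepoint.

A band of +/-2.5 percentile ranks stands in for the point percentiles (a
point percentile has measure zero), and "nearly linear" means pooled R^2 of
at least 0.99 or a mid-band mean within 5% of the range of the straight line
through the extreme band means; both thresholds are overridable arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import LongData
from .errors import ConfigurationError, DataError
from .models import eval_smm, to_positive_time

logger = logging.getLogger("trajmix")

__all__ = ["InitialValues", "smm_initials", "pmm_initials"]

#: Midpoint start used when the pooled trend is nearly linear.
LINEAR_MIDPOINT = 300.0
#: Midpoint start otherwise.
CURVED_MIDPOINT = 2.0
#: Candidate Hill-slope starts (low, high); ties keep the high value.
HILL_CANDIDATES = (0.5, 1.05)


@dataclass
class InitialValues:
    """4-vector of starting values plus a per-entry provenance tag."""

    start: np.ndarray
    provenance: tuple

    def __post_init__(self):
        self.start = np.asarray(self.start, float)
        # stock models take 4 values; a custom structural model may differ
        if self.start.ndim != 1 or self.start.size == 0 \
                or not np.all(np.isfinite(self.start)):
            raise ConfigurationError("start must be a vector of finite values")

    @classmethod
    def from_user(cls, start, model_id) -> "InitialValues":
        """Wrap user-supplied starts verbatim, order-checked per model.

        Model 1 order: last level, initial level, midpoint, Hill slope
        (midpoint must be positive). Models 2-3 order: intercept, slope1,
        slope2, changepoint.
        """
        start = np.asarray(start, float)
        iv = cls(start, ("user",) * start.size)
        if model_id in (1, 2, 3) and start.size != 4:
            raise ConfigurationError("start must have 4 entries for models 1-3")
        if model_id == 1 and iv.start[2] <= 0:
            raise ConfigurationError(
                "model 1 start order is (last level, initial level, midpoint, "
                "Hill slope); the midpoint must be > 0"
            )
        return iv


def _band_mean(values, ranks, center, halfwidth):
    lo, hi = center - halfwidth, center + halfwidth
    sel = (ranks >= lo) & (ranks <= hi)
    return float(np.mean(values[sel])) if sel.any() else np.nan


def _percentile_ranks(t):
    order = np.argsort(t, kind="stable")
    ranks = np.empty(t.size)
    ranks[order] = 100.0 * (np.arange(t.size) + 0.5) / t.size
    return ranks


def _ols_slope(t, y):
    if np.unique(t).size < 2:
        return np.nan
    return float(np.polyfit(t, y, 1)[0])


def _within_slope(t, y, code):
    """Within-subject (demeaned) OLS slope pooled across subjects.

    Centring time and outcome inside each subject removes the
    between-subject level variance, which would otherwise dominate a naive
    pooled trend; this approximates the slope a random-intercept linear
    mixed model would estimate on the same segment.
    """
    sxy = sxx = 0.0
    for c in np.unique(code):
        sel = code == c
        if sel.sum() < 2:
            continue
        tc = t[sel] - t[sel].mean()
        yc = y[sel] - y[sel].mean()
        sxy += float(tc @ yc)
        sxx += float(tc @ tc)
    if sxx <= 0:
        return np.nan
    return sxy / sxx


def smm_initials(data: LongData, band_halfwidth=2.5,
                 linear_r2=0.99, mid_tol=0.05) -> InitialValues:
    """Starting values (last level, initial level, midpoint, Hill slope)."""
    t_raw = data.time
    y = data.outcome
    if np.unique(t_raw).size < 2:
        raise DataError("at least 2 distinct time values are required")
    s, _ = to_positive_time(t_raw)  # s = 0 nearest the alignment point
    ranks = _percentile_ranks(s)

    last_start = _band_mean(y, ranks, 5.0, band_halfwidth)
    init_start = _band_mean(y, ranks, 95.0, band_halfwidth)

    # linearity rule: pooled R^2, or mid-band mean on the chord
    slope, icept = np.polyfit(s, y, 1)
    resid = y - (icept + slope * s)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if tss == 0 else 1.0 - float(np.sum(resid**2)) / tss
    mid_mean = _band_mean(y, ranks, 50.0, band_halfwidth)
    chord = 0.5 * (last_start + init_start)
    level_range = abs(init_start - last_start)
    nearly_linear = r2 >= linear_r2 or (
        np.isfinite(mid_mean) and abs(mid_mean - chord) <= mid_tol * max(level_range, 1e-12)
    )
    midpoint = LINEAR_MIDPOINT if nearly_linear else CURVED_MIDPOINT

    def rss(hill):
        f = eval_smm(s, np.array([last_start, init_start, midpoint, hill]))
        return float(np.sum((y - f) ** 2))

    lo, hi = HILL_CANDIDATES
    hill = hi if rss(hi) <= rss(lo) else lo

    logger.info(
        "sigmoid initials: levels (%.3g, %.3g), midpoint %g (%s), hill %g",
        last_start, init_start, midpoint,
        "nearly linear" if nearly_linear else "curved", hill,
    )
    return InitialValues(
        np.array([last_start, init_start, midpoint, hill]),
        ("percentile-level", "percentile-level", "linearity-rule", "linearity-rule"),
    )


def _band_slopes(t, y, code, edges):
    """Within-subject slope in each band [edges[k], edges[k+1]); last closed."""
    slopes, bounds, ok = [], [], True
    for k in range(len(edges) - 1):
        lo, hi = edges[k], edges[k + 1]
        sel = (t >= lo) & ((t < hi) if k < len(edges) - 2 else (t <= hi))
        s = _within_slope(t[sel], y[sel], code[sel]) if sel.sum() >= 2 else np.nan
        if not np.isfinite(s):
            ok = False
        slopes.append(s)
        bounds.append(lo)
    return np.array(slopes), np.array(bounds), ok


def pmm_initials(data: LongData, band_halfwidth=2.5) -> InitialValues:
    """Starting values (intercept, slope1, slope2, changepoint)."""
    t = data.time
    y = data.outcome
    code = np.asarray(data.df[data.id_col].factorize()[0])
    if np.unique(t).size < 5:
        raise DataError("at least 5 distinct time values are required")
    ranks = _percentile_ranks(t)
    icept_start = _band_mean(y, ranks, 95.0, band_halfwidth)

    edges = np.percentile(t, [0, 20, 40, 60, 80, 100])
    slopes, bounds, ok = _band_slopes(t, y, code, edges)
    if not ok:
        logger.warning("empty/degenerate quintile band; falling back to tertiles")
        edges = np.percentile(t, [0, 100 / 3, 200 / 3, 100])
        slopes, bounds, ok = _band_slopes(t, y, code, edges)
        if not ok:
            raise DataError("too few observations per time band for initials")

    amax = np.nanmax(np.abs(slopes))
    tied = np.flatnonzero(np.abs(slopes) >= amax - 1e-9 * max(1.0, amax))
    # the changepoint is where the fast phase begins: earliest tied band,
    # but never the first band (its lower bound is the data minimum) unless
    # it is the only candidate
    if tied.size > 1 and np.any(tied > 0):
        tied = tied[tied > 0]
    winner = int(tied[0])
    cp = float(bounds[winner])
    t_min, t_max = float(t.min()), float(t.max())
    if cp <= t_min:  # keep the changepoint strictly inside the observed range
        cp = t_min + 1e-6 * (t_max - t_min)

    pooled = _within_slope(t, y, code)
    if not np.isfinite(pooled):
        pooled = _ols_slope(t, y)
    before, after = t < cp, t >= cp
    slope1 = _within_slope(t[before], y[before], code[before]) if before.sum() >= 3 else pooled
    slope2 = _within_slope(t[after], y[after], code[after]) if after.sum() >= 3 else pooled
    if not np.isfinite(slope1):
        slope1 = pooled
    if not np.isfinite(slope2):
        slope2 = pooled

    logger.info(
        "piecewise initials: intercept %.3g, slopes (%.3g, %.3g), changepoint %.3g",
        icept_start, slope1, slope2, cp,
    )
    return InitialValues(
        np.array([icept_start, slope1, slope2, cp]),
        ("percentile-level", "segment-slope", "segment-slope", "segment-slope"),
    )


def variance_initials(data: LongData, model, start, smooth=None):
    """Method-of-moments defaults for B and sigma.

    Residuals of the pooled structural curve at the starting values define a
    pooled residual variance v; half of v seeds the residual variance and the
    level random effect(s), one tenth of v (scaled by the time variance for
    slope-like parameters) seeds the others.
    """
    t = data.time
    y = data.outcome
    s = -t + max(t.max(), 0.0) if model.positive_time else t
    Psi = np.tile(np.asarray(start, float), (t.size, 1))
    f = model.evaluate(s, model.clip_psi(Psi), smooth)
    v = float(np.var(y - f))
    v = max(v, 1e-8)
    vt = max(float(np.var(t)), 1e-8)
    d = model.n_params
    B0 = np.zeros((d, d))
    for k in range(d):
        if not model.random_mask[k]:
            continue
        if model.model_id == 1:  # both random effects are level parameters
            B0[k, k] = 0.5 * v
        elif k == 0:
            B0[k, k] = 0.5 * v
        elif k == 3:
            # the observed time spread is the natural prior scale for a
            # subject-specific changepoint location
            B0[k, k] = vt
        else:
            B0[k, k] = 0.1 * v / vt
    sigma0 = np.sqrt(0.5 * v)
    return B0, sigma0
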