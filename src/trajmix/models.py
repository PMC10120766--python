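"""Structural mean functions and the parameter-linking layer.

Three structural models for a longitudinal outcome y_ij = f(t_ij, psi_i) + e_ij:

* **SMM** (model 1) — four-parameter logistic on the positive
  time-before-zero scale s (s = 0 at the alignment point, e.g. death)::

      f(s) = initial + (last - initial) / (1 + (s / midpoint)^hill)

  so f(0) = last level, f(s) -> initial level as s grows, and
  f(midpoint) = (last + initial)/2 (the time of half decline).

* **PMM-abrupt** (model 2) — broken stick on the raw timescale: intercept at
  t = 0, terminal slope ``slope2`` on the segment containing t = 0, early
  slope ``slope1`` on the other side of the subject-specific changepoint.

* **PMM-smooth** (model 3) — the same two lines joined by a cubic
  transition of length ``v`` starting at the changepoint; the two extended
  lines intersect at the middle of the window (the lambda constraint), and
  the curve is C1 by construction. ``v = 0`` reduces exactly to model 2.

Structural parameters are linked to population fixed effects, covariates and
subject random effects as ``psi_k = alpha_k + beta_k' X_k + eta_k``; the SMM
keeps the midpoint and Hill slope marginal (no random effect) for convergence,
while the PMMs put a random effect on all four parameters with B diagonal
except the (slope1, slope2) covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError, DomainError

__all__ = [
    "StructuralParams",
    "ParameterLink",
    "SmoothConfig",
    "ModelDef",
    "MODELS",
    "eval_smm",
    "eval_pmm_abrupt",
    "eval_pmm_smooth",
    "solve_transition_poly",
    "link_parameters",
    "to_positive_time",
]

_MIN_MIDPOINT = 1e-6


@dataclass
class StructuralParams:
    """One subject's four structural parameters, in software order.

    model 1: (last level, initial level, midpoint, Hill slope);
    models 2-3: (intercept at t=0, slope1 = early slope away from t=0,
    slope2 = slope adjacent to t=0, changepoint time).
    """

    par1: float
    par2: float
    par3: float
    par4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.par1, self.par2, self.par3, self.par4], float)


@dataclass
class SmoothConfig:
    """Length v >= 0 (timescale units) of the cubic transition window."""

    v: float = 2.0

    def __post_init__(self):
        if self.v < 0:
            raise DomainError("transition length v must be >= 0")


# ---------------------------------------------------------------------------
# Evaluators (vectorised; Psi may be a (..., 4) array broadcast against t)
# ---------------------------------------------------------------------------

def _psi_cols(p):
    if isinstance(p, StructuralParams):
        p = p.as_array()
    p = np.asarray(p, float)
    return p[..., 0], p[..., 1], p[..., 2], p[..., 3]


def eval_smm(t, p):
    """Four-parameter logistic at time-before-zero ``t >= 0``.

    Equals par1 (last level) at t = 0 and tends to par2 (initial level) as
    t -> infinity; f(par3) is the half-decline level.
    """
    last, init, mid, hill = _psi_cols(p)
    if np.any(np.asarray(mid) <= 0):
        raise DomainError("SMM midpoint (par3) must be > 0")
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise DomainError("SMM evaluation requires time-before-zero t >= 0")
    with np.errstate(over="ignore", divide="ignore"):
        u = np.power(t / mid, hill)
        out = init + (last - init) / (1.0 + u)
    return out if out.ndim else float(out)


def _smm_dpsi(t, Psi):
    """(n, 4) partial derivatives of the SMM mean wrt the four parameters."""
    last, init, mid, hill = Psi[:, 0], Psi[:, 1], Psi[:, 2], Psi[:, 3]
    t = np.asarray(t, float)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        u = np.power(t / mid, hill)
        denom = 1.0 + u
        d1 = 1.0 / denom
        d2 = u / denom
        dfdu = -(last - init) / denom**2
        dfdu = np.where(np.isfinite(dfdu), dfdu, 0.0)
        du3 = -hill * u / mid
        logratio = np.where(t > 0, np.log(np.maximum(t, 1e-300) / mid), 0.0)
        du4 = u * logratio
        d3 = np.where(np.isfinite(du3), dfdu * du3, 0.0)
        d4 = np.where(np.isfinite(du4), dfdu * du4, 0.0)
    return np.stack([d1, d2, d3, d4], axis=-1)


def eval_pmm_abrupt(t, p):
    """Broken-stick mean on the raw timescale, continuous at the changepoint."""
    icept, slope1, slope2, cp = _psi_cols(p)
    t = np.asarray(t, float)
    late = icept + slope2 * t
    early = icept + slope2 * cp + slope1 * (t - cp)
    out = np.where(t >= cp, late, early)
    return out if out.ndim else float(out)


def _pmm_abrupt_dpsi(t, Psi):
    icept, slope1, slope2, cp = Psi[:, 0], Psi[:, 1], Psi[:, 2], Psi[:, 3]
    t = np.asarray(t, float)
    late = t >= cp
    d1 = np.ones_like(t)
    d2 = np.where(late, 0.0, t - cp)
    d3 = np.where(late, t, cp)
    d4 = np.where(late, 0.0, slope2 - slope1)
    return np.stack([d1, d2, d3, d4], axis=-1)


def solve_transition_poly(p, cfg: SmoothConfig):
    """Cubic transition g(t) = a0 + a1 t + a2 t^2 + a3 t^3 on [cp, cp + v].

    Solves the explicit 4x4 linear system pinning the values and first
    derivatives of g at the window edges to the two straight lines, with the
    intersection constraint lambda = par1 + (slope2 - slope1)(cp + v/2).

    Returns ``(coeffs, lam)`` with ``coeffs`` shaped (..., 4). Scalar inputs
    give a length-4 coefficient vector.
    """
    if cfg.v <= 0:
        raise DomainError("transition solve requires v > 0; use the abrupt model")
    icept, slope1, slope2, cp = _psi_cols(p)
    icept, slope1, slope2, cp = np.broadcast_arrays(
        np.asarray(icept, float), slope1, slope2, cp
    )
    v = float(cfg.v)
    tc = cp + v
    lam = icept + (slope2 - slope1) * (cp + v / 2.0)
    shape = cp.shape
    A = np.empty(shape + (4, 4))
    one = np.ones_like(cp)
    zero = np.zeros_like(cp)
    A[..., 0, :] = np.stack([one, cp, cp**2, cp**3], axis=-1)
    A[..., 1, :] = np.stack([one, tc, tc**2, tc**3], axis=-1)
    A[..., 2, :] = np.stack([zero, one, 2 * cp, 3 * cp**2], axis=-1)
    A[..., 3, :] = np.stack([zero, one, 2 * tc, 3 * tc**2], axis=-1)
    b = np.stack(
        [lam + slope1 * cp, icept + slope2 * tc, slope1 + zero, slope2 + zero],
        axis=-1,
    )
    coeffs = np.linalg.solve(A, b[..., None])[..., 0]
    if not shape:
        return coeffs.reshape(4), float(lam)
    return coeffs, lam


def eval_pmm_smooth(t, p, cfg: SmoothConfig):
    """Piecewise-linear mean with a cubic C1 transition of length v.

    Early line (t <= cp): lambda + slope1 t; late line (t >= cp + v):
    par1 + slope2 t; cubic in between. v = 0 dispatches to the abrupt model.
    """
    if cfg.v == 0:
        return eval_pmm_abrupt(t, p)
    icept, slope1, slope2, cp = _psi_cols(p)
    t = np.asarray(t, float)
    tb, icept, slope1, slope2, cp = np.broadcast_arrays(t, icept, slope1, slope2, cp)
    lam = icept + (slope2 - slope1) * (cp + cfg.v / 2.0)
    out = np.where(tb <= cp, lam + slope1 * tb, icept + slope2 * tb)
    win = (tb > cp) & (tb < cp + cfg.v)
    if np.any(win):
        pw = np.stack([icept[win], slope1[win], slope2[win], cp[win]], axis=-1)
        coeffs, _ = solve_transition_poly(pw, cfg)
        tw = tb[win]
        gv = coeffs[..., 0] + coeffs[..., 1] * tw + coeffs[..., 2] * tw**2 \
            + coeffs[..., 3] * tw**3
        out = out.copy()
        out[win] = gv
    return out if out.ndim else float(out)


def _numeric_dpsi(f, t, Psi):
    """Central-difference (n, 4) Jacobian of a structural mean wrt psi."""
    out = np.empty(Psi.shape)
    for k in range(Psi.shape[1]):
        h = 1e-5 * np.maximum(1.0, np.abs(Psi[:, k]))
        up = Psi.copy()
        up[:, k] += h
        dn = Psi.copy()
        dn[:, k] -= h
        out[:, k] = (f(t, up) - f(t, dn)) / (2 * h)
    return out


# ---------------------------------------------------------------------------
# Parameter linking
# ---------------------------------------------------------------------------

@dataclass
class ParameterLink:
    """Population parameterisation: psi_k = alpha_k + beta_k' X_k + eta_k.

    Attributes
    ----------
    alpha : array (4,)
        Population means of the structural parameters.
    beta : tuple of 4 dicts
        Covariate coefficients per parameter, ``{covariate_name: coef}``.
    random_mask : tuple of 4 bool
        Which parameters carry a random effect (eta term).
    B : array (4, 4)
        Random-effect covariance on the full parameter index; rows/columns of
        non-random parameters are zero, and off-diagonals outside the model's
        allowed structure must be zero.
    sigma : float
        Residual SD (> 0).
    """

    alpha: np.ndarray
    beta: tuple = ({}, {}, {}, {})
    random_mask: tuple = (True, True, True, True)
    B: np.ndarray = None
    sigma: float = 1.0

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, float)
        n = self.alpha.size  # 4 for the stock models; generic for harnesses
        if self.beta == ({}, {}, {}, {}) and n != 4:
            self.beta = tuple({} for _ in range(n))
        self.beta = tuple(dict(b) for b in self.beta)
        if len(self.beta) != n:
            raise ConfigurationError("beta must give one map per parameter")
        if self.random_mask == (True, True, True, True) and n != 4:
            self.random_mask = (True,) * n
        self.random_mask = tuple(bool(m) for m in self.random_mask)
        if len(self.random_mask) != n:
            raise ConfigurationError("random_mask length must match alpha")
        if self.B is None:
            self.B = np.diag([1.0 if m else 0.0 for m in self.random_mask])
        self.B = np.asarray(self.B, float)
        if self.B.shape != (n, n):
            raise ConfigurationError(
                "B must be square over all parameters (zero rows where fixed)"
            )
        if not np.allclose(self.B, self.B.T):
            raise ConfigurationError("B must be symmetric")
        idx = [k for k in range(n) if self.random_mask[k]]
        sub = self.B[np.ix_(idx, idx)]
        if len(idx) and np.min(np.linalg.eigvalsh(sub)) < -1e-10:
            raise ConfigurationError("B must be positive semi-definite")
        off = self.B.copy()
        off[np.ix_(idx, idx)] = 0.0
        if np.any(off != 0):
            raise ConfigurationError("B has entries for parameters without random effects")
        # sigma = 0 is tolerated as the noise-free simulation limit
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")

    @property
    def n_params(self) -> int:
        return self.alpha.size

    @property
    def random_idx(self):
        return [k for k in range(self.n_params) if self.random_mask[k]]

    def n_random(self) -> int:
        return sum(self.random_mask)

    def B_sub(self) -> np.ndarray:
        idx = self.random_idx
        return self.B[np.ix_(idx, idx)]

    def covariate_names(self):
        """All covariate names used anywhere, in stable order."""
        seen = []
        for b in self.beta:
            for name in b:
                if name not in seen:
                    seen.append(name)
        return seen

    def n_fixed_effects(self) -> int:
        return self.n_params + sum(len(b) for b in self.beta)


def link_parameters(link: ParameterLink, covariate_row, eta) -> StructuralParams:
    """Assemble one subject's structural parameters.

    ``covariate_row`` maps covariate names to values; ``eta`` is either a
    length-4 vector (entries for parameters without a random effect must be
    exactly 0) or a vector over the random parameters only.
    """
    eta = np.asarray(eta, float)
    q = link.n_random()
    full_eta = np.zeros(4)
    if eta.shape == (4,):
        for k in range(4):
            if not link.random_mask[k] and eta[k] != 0:
                raise ConfigurationError(
                    f"parameter {k + 1} has no random effect; eta must be 0"
                )
        full_eta = eta
    elif eta.shape == (q,):
        full_eta[link.random_idx] = eta
    else:
        raise ConfigurationError(
            f"eta must have length 4 or {q} (number of random effects)"
        )
    psi = np.empty(4)
    for k in range(4):
        val = link.alpha[k]
        for name, coef in link.beta[k].items():
            if name not in covariate_row:
                raise DataError(f"missing covariate value for {name!r}")
            val += coef * float(covariate_row[name])
        psi[k] = val + full_eta[k]
    return StructuralParams(*psi)


def to_positive_time(t):
    """Map raw times to the positive time-before-zero scale used by the SMM.

    Returns ``(s, shift)`` with ``s = shift - t >= 0``; ``shift`` is 0 when
    all times are <= 0 (the usual retrospective alignment) and ``max(t)``
    otherwise. Raw time recovers as ``t = shift - s``.
    """
    t = np.asarray(t, float)
    shift = float(max(t.max(), 0.0)) if t.size else 0.0
    return shift - t, shift


# ---------------------------------------------------------------------------
# Model registry used by the estimation engine, simulator and reporting
# ---------------------------------------------------------------------------

@dataclass
class ModelDef:
    """Everything the engine needs to know about one structural model.

    The three stock models are registered in :data:`MODELS`; a custom mean
    function (e.g. a plain linear trend for validation against closed-form
    linear mixed-model results) can be supplied through ``f``/``df``.
    """

    model_id: int
    name: str
    param_names: tuple
    random_mask: tuple
    cov_allowed: np.ndarray  # bool matrix: free entries of B
    positive_time: bool      # evaluate on the time-before-zero scale
    smooth: bool = False
    f: object = None         # optional custom mean: f(t, Psi) -> values
    df: object = None        # optional custom Jacobian: df(t, Psi) -> (n, p)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def evaluate(self, t, Psi, cfg: SmoothConfig | None = None):
        if self.f is not None:
            return self.f(t, Psi)
        if self.model_id == 1:
            return eval_smm(t, Psi)
        if self.model_id == 2:
            return eval_pmm_abrupt(t, Psi)
        return eval_pmm_smooth(t, Psi, cfg or SmoothConfig())

    def dpsi(self, t, Psi, cfg: SmoothConfig | None = None):
        if self.f is not None:
            if self.df is not None:
                return self.df(t, Psi)
            return _numeric_dpsi(self.f, t, Psi)
        if self.model_id == 1:
            return _smm_dpsi(t, Psi)
        if self.model_id == 2:
            return _pmm_abrupt_dpsi(t, Psi)
        cfg = cfg or SmoothConfig()
        return _numeric_dpsi(lambda tt, pp: eval_pmm_smooth(tt, pp, cfg), t, Psi)

    def clip_psi(self, Psi):
        """Keep per-subject parameters inside the model's domain."""
        if self.model_id == 1:
            Psi = Psi.copy()
            Psi[..., 2] = np.maximum(Psi[..., 2], _MIN_MIDPOINT)
            Psi[..., 3] = np.maximum(Psi[..., 3], 1e-3)
        return Psi


def _mask(pairs):
    m = np.zeros((4, 4), bool)
    for k in range(4):
        m[k, k] = True
    for i, j in pairs:
        m[i, j] = m[j, i] = True
    return m


MODELS = {
    1: ModelDef(
        model_id=1,
        name="sigmoidal mixed model (SMM)",
        param_names=("last.level", "first.level", "midpoint", "hill.slope"),
        random_mask=(True, True, False, False),
        cov_allowed=_mask([(0, 1)]),
        positive_time=True,
    ),
    2: ModelDef(
        model_id=2,
        name="piecewise mixed model, abrupt change (PMM-abrupt)",
        param_names=("last.level", "slope1", "slope2", "changepoint"),
        random_mask=(True, True, True, True),
        cov_allowed=_mask([(1, 2)]),
        positive_time=False,
    ),
    3: ModelDef(
        model_id=3,
        name="piecewise mixed model, smooth transition (PMM-smooth)",
        param_names=("last.level", "slope1", "slope2", "changepoint"),
        random_mask=(True, True, True, True),
        cov_allowed=_mask([(1, 2)]),
        positive_time=False,
        smooth=True,
    ),
}
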