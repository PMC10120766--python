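"""Trajectories, group contrasts, plots and the text summary."""

import re

import numpy as np
import pandas as pd
import pytest

import matplotlib

matplotlib.use("Agg")

from trajmix import (
    ConfigurationError,
    InitialValues,
    ParameterLink,
    SmoothConfig,
    TrajectoryRequest,
    eval_smm,
    group_contrast,
    marginal_trajectory,
    render_summary,
    spaghetti_plot,
)
from trajmix.saem import FitResult

from conftest import make_long


def dummy_fit(beta=(), cov_values=None, model_id=1, alpha=(-1.0, 0.4, 4.0, 1.7),
              ses=None, packed=None):
    """Hand-assembled FitResult for reporting tests (no SAEM run needed)."""
    beta_maps = tuple({name: coef for name, coef in beta} for _ in range(4))
    B = np.zeros((4, 4))
    B[0, 0] = B[1, 1] = 1.0
    est = ParameterLink(
        alpha=np.asarray(alpha, float),
        beta=beta_maps,
        random_mask=(True, True, False, False) if model_id == 1 else (True,) * 4,
        B=B if model_id == 1 else np.diag([1.0, 0.1, 0.1, 1.0]),
        sigma=0.3,
    )
    names = ["alpha.p1", "alpha.p2", "alpha.p3", "alpha.p4",
             "omega2.first", "omega2.second", "sigma2"]
    vals = list(alpha) + [1.0, 1.0, 0.09]
    if packed:
        names, vals = zip(*packed)
        names, vals = list(names), list(vals)
    covariates = pd.DataFrame(cov_values or {}, index=range(
        len(next(iter(cov_values.values()))) if cov_values else 0))
    return FitResult(
        model_id=model_id,
        model_name="test model",
        param_names=("p1", "p2", "p3", "p4"),
        estimates=est,
        ses=ses or {n: None for n in names},
        cv_pct={n: None for n in names},
        pvalues={},
        loglik=-100.0, loglik_se=0.1, aic=214.0, bic=230.0,
        n_free_parameters=7,
        converged=True, max_rel_change=1e-4,
        trace=np.asarray([vals]), trace_names=tuple(names),
        runtime_s=1.23, n_subjects=50, n_obs=400,
        time_range=(-12.0, 0.0), time_shift=0.0,
        smooth=SmoothConfig(2.0) if model_id == 3 else None,
        initials=InitialValues(np.asarray(alpha, float), ("user",) * 4),
        eta=pd.DataFrame(), psi=pd.DataFrame(),
        covariates=covariates,
    )


class TestMarginalTrajectory:
    def test_equals_structural_curve_without_covariates(self):
        f = dummy_fit()
        grid = np.linspace(-12, 0, 25)
        table = marginal_trajectory(f, TrajectoryRequest(time_grid=grid))
        expect = eval_smm(-grid, f.estimates.alpha)
        assert np.allclose(table["predicted"].to_numpy(), expect)

    def test_half_decline_identity_at_midpoint(self):
        f = dummy_fit()
        table = marginal_trajectory(
            f, TrajectoryRequest(time_grid=np.array([-f.estimates.alpha[2]]))
        )
        levels = f.estimates.alpha[:2]
        assert table["predicted"].iloc[0] == pytest.approx(levels.mean())

    def test_profile_must_cover_model_covariates(self):
        f = dummy_fit(beta=[("x", 0.5)], cov_values={"x": [1.0, 2.0]})
        f.covariates = f.covariates.iloc[:0]  # empty: no profile derivable
        with pytest.raises(ConfigurationError):
            marginal_trajectory(f, TrajectoryRequest(time_grid=np.array([0.0])))


class TestGroupContrast:
    def grid(self):
        return TrajectoryRequest(time_grid=np.array([-5.0, 0.0]), group_var="x")

    def test_continuous_covariate_type7_percentiles(self):
        f = dummy_fit(beta=[("x", 0.5)],
                      cov_values={"x": np.arange(1.0, 101.0)})
        table = group_contrast(f, self.grid())
        labels = list(dict.fromkeys(table["group"]))
        assert "10.9" in labels[0] and "90.1" in labels[1]

    def test_percentile_override(self):
        f = dummy_fit(beta=[("x", 0.5)], cov_values={"x": np.arange(1.0, 101.0)})
        req = TrajectoryRequest(time_grid=np.array([0.0]), group_var="x",
                                group_percentiles=(0.25, 0.75))
        table = group_contrast(f, req)
        labels = list(dict.fromkeys(table["group"]))
        assert "25.75" in labels[0] and "75.25" in labels[1]

    def test_binary_covariate_uses_levels_not_percentiles(self):
        f = dummy_fit(beta=[("x", 0.5)], cov_values={"x": [0.0, 1.0] * 30})
        table = group_contrast(f, self.grid())
        labels = sorted(set(table["group"]))
        assert labels == ["x=0", "x=1"]

    def test_zero_effect_trajectories_coincide(self):
        f = dummy_fit(beta=[("x", 0.0)], cov_values={"x": np.arange(1.0, 101.0)})
        table = group_contrast(f, self.grid())
        a, b = [g["predicted"].to_numpy() for _, g in table.groupby("group")]
        assert np.allclose(a, b)

    def test_unknown_group_variable(self):
        f = dummy_fit()
        with pytest.raises(ConfigurationError):
            group_contrast(f, self.grid())

    def test_bad_percentile_pair_rejected(self):
        with pytest.raises(ConfigurationError):
            TrajectoryRequest(group_percentiles=(0.9, 0.1))


class TestSpaghetti:
    def data(self, n=50):
        rows = [(i, -float(j), 0.1 * j) for i in range(n) for j in range(5)]
        return make_long(rows)

    def test_small_cohort_draws_everyone(self):
        fig, ids = spaghetti_plot(self.data(50), n_shown=70, seed=1)
        assert len(ids) == 50

    def test_seeded_sampling_is_deterministic(self):
        data = self.data(100)
        _, a = spaghetti_plot(data, n_shown=70, seed=5)
        _, b = spaghetti_plot(data, n_shown=70, seed=5)
        assert a == b and len(a) == 70

    def test_default_labels_are_raw_column_names(self):
        fig, _ = spaghetti_plot(self.data(5))
        ax = fig.axes[0]
        assert ax.get_xlabel() == "time" and ax.get_ylabel() == "outcome"

    def test_label_override(self):
        fig, _ = spaghetti_plot(self.data(5), xlabel="Years before death")
        assert fig.axes[0].get_xlabel() == "Years before death"


class TestSummary:
    def test_variance_table_header(self):
        text = render_summary(dummy_fit())
        assert "Variance of random effects" in text
        assert re.search(r"Parameter\s+Estimate\s+SE\s+CV\(%\)", text)

    def test_cv_rendering_to_one_decimal(self):
        packed = [("alpha.p1", -1.0), ("alpha.p2", 0.4), ("alpha.p3", 4.0),
                  ("alpha.p4", 1.7), ("omega2.first", 0.146), ("sigma2", 0.09)]
        f = dummy_fit(packed=packed,
                      ses={n: None for n, _ in packed} | {"omega2.first": 0.0071})
        f.cv_pct = dict.fromkeys(f.ses) | {"omega2.first": 100 * 0.0071 / 0.146}
        text = render_summary(f)
        line = next(l for l in text.splitlines() if "omega2.first" in l)
        assert "4.9" in line

    def test_timing_line_format(self):
        text = render_summary(dummy_fit())
        assert re.search(r"^The program took \d+\.\d{2} seconds$",
                         text.splitlines()[-1])
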