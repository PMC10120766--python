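"""Closed-form identities of the three structural mean functions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trajmix import (
    DomainError,
    ConfigurationError,
    ParameterLink,
    SmoothConfig,
    StructuralParams,
    eval_pmm_abrupt,
    eval_pmm_smooth,
    eval_smm,
    link_parameters,
    solve_transition_poly,
)

SMM_P = [-1.03, 0.37, 4.0, 1.69]
PMM_P = [-1.21, -0.03, -0.32, -3.0]


class TestSigmoid:
    def test_intercept_and_halfway(self):
        assert eval_smm(0.0, SMM_P) == pytest.approx(SMM_P[0])  # last level
        half = eval_smm(SMM_P[2], SMM_P)
        assert half == pytest.approx((SMM_P[0] + SMM_P[1]) / 2)

    def test_tends_to_initial_level(self):
        assert eval_smm(1e8, SMM_P) == pytest.approx(SMM_P[1], abs=1e-4)

    def test_generative_value(self):
        # direct evaluation: 2^1.69 ~ 3.2267
        assert eval_smm(8.0, SMM_P) == pytest.approx(0.0388, abs=1e-3)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            eval_smm(1.0, [-1.0, 0.4, -4.0, 1.7])
        with pytest.raises(DomainError):
            eval_smm(-1.0, SMM_P)

    @given(
        last=st.floats(-3, 0), init=st.floats(0.01, 3),
        mid=st.floats(0.5, 20), hill=st.floats(0.2, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_decline_toward_time_zero(self, last, init, mid, hill):
        """With a positive Hill slope and last < initial, the curve declines
        monotonically as time-before-zero shrinks."""
        s = np.linspace(0, 30, 400)
        f = eval_smm(s, [last, init, mid, hill])
        assert np.all(np.diff(f) >= -1e-12)


class TestPiecewiseAbrupt:
    def test_intercept_at_time_zero(self):
        assert eval_pmm_abrupt(0.0, PMM_P) == pytest.approx(PMM_P[0])

    def test_continuity_at_changepoint(self):
        cp = PMM_P[3]
        left = eval_pmm_abrupt(cp - 1e-12, PMM_P)
        right = eval_pmm_abrupt(cp, PMM_P)
        assert left == pytest.approx(right, abs=1e-9)

    def test_hand_computed_values(self):
        assert eval_pmm_abrupt(-5.0, PMM_P) == pytest.approx(-0.19, abs=1e-12)
        assert eval_pmm_abrupt(-1.0, PMM_P) == pytest.approx(-0.89, abs=1e-12)


def hermite_transition(p, v, t):
    """Independent oracle: cubic Hermite form of the transition window."""
    p1, s1, s2, cp = p
    lam = p1 + (s2 - s1) * (cp + v / 2)
    y0 = lam + s1 * cp
    y1 = p1 + s2 * (cp + v)
    u = (t - cp) / v
    h00 = 2 * u**3 - 3 * u**2 + 1
    h10 = u**3 - 2 * u**2 + u
    h01 = -2 * u**3 + 3 * u**2
    h11 = u**3 - u**2
    return h00 * y0 + h10 * v * s1 + h01 * y1 + h11 * v * s2


class TestTransitionPolynomial:
    def test_against_hermite_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = [rng.normal(), rng.normal(), rng.normal(), rng.uniform(-8, -1)]
            v = rng.uniform(0.3, 4.0)
            coeffs, _ = solve_transition_poly(p, SmoothConfig(v))
            t = np.linspace(p[3], p[3] + v, 33)
            mine = coeffs[0] + coeffs[1] * t + coeffs[2] * t**2 + coeffs[3] * t**3
            assert np.allclose(mine, hermite_transition(p, v, t), atol=1e-8)

    def test_edge_derivatives(self):
        p = PMM_P
        v = 2.0
        coeffs, _ = solve_transition_poly(p, SmoothConfig(v))

        def dg(t):
            return coeffs[1] + 2 * coeffs[2] * t + 3 * coeffs[3] * t**2

        assert dg(p[3]) == pytest.approx(p[1], abs=1e-10)
        assert dg(p[3] + v) == pytest.approx(p[2], abs=1e-10)

    def test_equal_slopes_degenerate_to_line(self):
        p = [-1.0, -0.2, -0.2, -3.0]
        coeffs, _ = solve_transition_poly(p, SmoothConfig(2.0))
        assert abs(coeffs[2]) < 1e-10 and abs(coeffs[3]) < 1e-10

    def test_requires_positive_window(self):
        with pytest.raises(DomainError):
            solve_transition_poly(PMM_P, SmoothConfig(0.0))


class TestPiecewiseSmooth:
    def test_zero_window_reduces_to_abrupt(self):
        t = np.linspace(-12, 0, 601)
        sm = eval_pmm_smooth(t, PMM_P, SmoothConfig(0.0))
        ab = eval_pmm_abrupt(t, PMM_P)
        assert np.array_equal(sm, ab)

    def test_c1_across_window_boundaries(self):
        v = 2.0
        cfg = SmoothConfig(v)
        h = 1e-4

        def f(t):
            return eval_pmm_smooth(t, PMM_P, cfg)

        for edge in (PMM_P[3], PMM_P[3] + v):
            # value continuity across the boundary
            assert abs(f(edge - 1e-9) - f(edge + 1e-9)) < 1e-8
            # first-derivative continuity: central differences on each side
            dl = (f(edge - h) - f(edge - 3 * h)) / (2 * h)
            dr = (f(edge + 3 * h) - f(edge + h)) / (2 * h)
            assert abs(dl - dr) < 1e-3

    def test_extended_lines_intersect_at_window_midpoint(self):
        """The lambda constraint makes the two extended straight lines meet
        at the middle of the transition window; the transition curve itself
        clears the corner by (slope2 - slope1) * v / 8."""
        p1, s1, s2, cp = PMM_P
        v = 2.0
        lam = p1 + (s2 - s1) * (cp + v / 2)
        early = lam + s1 * (cp + v / 2)
        late = p1 + s2 * (cp + v / 2)
        assert early == pytest.approx(late, abs=1e-12)
        got = eval_pmm_smooth(cp + v / 2, PMM_P, SmoothConfig(v))
        # independent value: Hermite-form oracle at the midpoint
        assert got == pytest.approx(hermite_transition(PMM_P, v, cp + v / 2), abs=1e-10)
        assert got - early == pytest.approx((s2 - s1) * v / 8, abs=1e-10)

    def test_uniform_limit_as_window_shrinks(self):
        t = np.linspace(-12, 0, 500)
        tiny = eval_pmm_smooth(t, PMM_P, SmoothConfig(1e-6))
        zero = eval_pmm_smooth(t, PMM_P, SmoothConfig(0.0))
        assert np.max(np.abs(tiny - zero)) < 1e-4


class TestVectorisation:
    @pytest.mark.parametrize(
        "fn,params,grid",
        [
            (eval_smm, SMM_P, np.linspace(0, 20, 23)),
            (eval_pmm_abrupt, PMM_P, np.linspace(-10, 0, 23)),
            (lambda t, p: eval_pmm_smooth(t, p, SmoothConfig(2.0)), PMM_P,
             np.linspace(-10, 0, 23)),
        ],
        ids=["smm", "pmm_abrupt", "pmm_smooth"],
    )
    def test_batch_equals_pointwise(self, fn, params, grid):
        batch = fn(grid, params)
        point = np.array([fn(float(tj), params) for tj in grid])
        assert np.array_equal(batch, point)


class TestLinkParameters:
    def link(self):
        B = np.zeros((4, 4))
        B[0, 0] = B[1, 1] = 1.0
        return ParameterLink(
            alpha=[1.0, 2.0, 4.0, 1.5],
            beta=({}, {}, {"x": 0.2}, {}),
            random_mask=(True, True, False, False),
            B=B,
            sigma=0.3,
        )

    def test_null_case_returns_alpha(self):
        link = self.link()
        p = link_parameters(link, {"x": 0.0}, np.zeros(2))
        assert np.allclose(p.as_array(), [1.0, 2.0, 4.0, 1.5])

    def test_single_covariate_term(self):
        p = link_parameters(self.link(), {"x": 1.0}, np.zeros(2))
        assert p.par3 == pytest.approx(4.2)

    def test_eta_on_marginal_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            link_parameters(self.link(), {"x": 0.0}, np.array([0.0, 0.0, 0.5, 0.0]))

    def test_compact_eta_accepted(self):
        p = link_parameters(self.link(), {"x": 0.0}, np.array([0.5, -0.5]))
        assert p.par1 == pytest.approx(1.5) and p.par2 == pytest.approx(1.5)
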