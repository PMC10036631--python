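"""Model evaluation, closed-form areas/Ginis, quadrature oracles and the
theoretical Lorenz-curve conditions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lorenzfit as lf
from lorenzfit.models import quadrature_area

proposed_params = st.builds(
    lf.ProposedParams,
    delta=st.floats(0.0, 0.95),
    rho=st.floats(0.0, 1.0),
    omega=st.floats(0.0, 1.0),
    P=st.floats(1.0, 50.0),
)

s_params = st.builds(
    lambda lam, q, a1, a2: lf.SParams(
        lam=lam, eta=(q * (1.0 - lam)) / max(a2, 1e-9), a1=a1, a2=a2
    ),
    lam=st.floats(0.0, 1.0),
    q=st.floats(0.0, 1.0),
    a1=st.floats(0.0, 20.0),
    a2=st.floats(0.01, 20.0),
)


class TestProposedModel:
    @given(params=proposed_params)
    def test_boundary_conditions(self, params):
        assert lf.proposed_lorenz(0.0, params) == pytest.approx(0.0, abs=1e-12)
        assert lf.proposed_lorenz(1.0, params) == pytest.approx(1.0, abs=1e-12)

    def test_pure_linear_component_value(self):
        # slope 2/(P+1) through the shifted origin
        p = lf.ProposedParams(delta=0.0, rho=0.0, omega=0.0, P=2.96)
        assert lf.proposed_lorenz(0.99, p) == pytest.approx(0.5)

    def test_zero_below_horizontal_segment(self):
        p = lf.ProposedParams(delta=0.5, rho=1.0, omega=0.5, P=2.0)
        assert lf.proposed_lorenz(0.3, p) == 0.0

    def test_x_outside_unit_interval_rejected(self):
        p = lf.ProposedParams(delta=0.0, rho=1.0, omega=0.0, P=2.0)
        with pytest.raises(ValueError):
            lf.proposed_lorenz(1.5, p)
        with pytest.raises(ValueError):
            lf.proposed_lorenz(-0.1, p)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(delta=1.0, rho=0.5, omega=0.5, P=2.0),
            dict(delta=-0.1, rho=0.5, omega=0.5, P=2.0),
            dict(delta=0.0, rho=1.5, omega=0.5, P=2.0),
            dict(delta=0.0, rho=0.5, omega=-0.2, P=2.0),
            dict(delta=0.0, rho=0.5, omega=0.5, P=0.5),
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            lf.ProposedParams(**bad)

    @pytest.mark.parametrize(
        "delta,P,expected",
        [(0.0, 1.0, 0.5), (0.0, 2.96, 1 / 3.96), (0.9, 13.42, 0.1 / 14.42)],
    )
    def test_closed_form_area(self, delta, P, expected):
        p = lf.ProposedParams(delta=delta, rho=1.0, omega=0.5, P=P)
        assert lf.proposed_area(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "delta,P,gini3dp",
        [
            (0.0, 1.0, 0.0),
            (0.00, 15.34, 0.878),  # solar-flare-intensity parameterization
            (0.58, 11.62, 0.933),  # inter-state-war parameterization
            (0.90, 13.42, 0.986),  # metabolic-degree parameterization
            (0.00, 2.01, 0.336),  # CEO-compensation parameterization
            (0.00, 13.56, 0.863),  # tennis-salary parameterization
        ],
    )
    def test_closed_form_gini_published_parameterizations(self, delta, P, gini3dp):
        p = lf.ProposedParams(delta=delta, rho=1.0, omega=0.5, P=P)
        assert round(lf.gini_proposed(p), 3) == pytest.approx(gini3dp, abs=1e-9)

    @given(params=proposed_params)
    def test_quadrature_matches_closed_form_area(self, params):
        assert quadrature_area("proposed", params) == pytest.approx(
            lf.proposed_area(params), abs=1e-7
        )

    @given(params=proposed_params)
    def test_gini_in_unit_interval_and_independent_of_weights(self, params):
        g = lf.gini_proposed(params)
        assert 0.0 <= g <= 1.0
        for rho in (0.0, 0.3, 1.0):
            for omega in (0.0, 0.7, 1.0):
                alt = lf.ProposedParams(
                    delta=params.delta, rho=rho, omega=omega, P=params.P
                )
                assert lf.gini_proposed(alt) == g

    def test_gini_zero_iff_egalitarian(self):
        assert lf.gini_proposed(lf.ProposedParams(0.0, 1.0, 0.0, 1.0)) == 0.0
        assert lf.gini_proposed(lf.ProposedParams(0.1, 1.0, 0.0, 1.0)) > 0.0
        assert lf.gini_proposed(lf.ProposedParams(0.0, 1.0, 0.0, 1.01)) > 0.0


class TestSCSModel:
    @given(x=st.floats(0.0, 1.0))
    def test_reduces_to_diagonal(self, x):
        p = lf.SCSParams(gamma=0.0, alpha=1.0, beta=1.0)
        assert lf.scs_lorenz(x, p) == pytest.approx(x, abs=1e-12)

    def test_hand_evaluated_point(self):
        p = lf.SCSParams(gamma=0.0, alpha=0.31, beta=1.0)
        assert lf.scs_lorenz(0.5, p) == pytest.approx(1 - 0.5**0.31, abs=1e-12)

    @given(
        gamma=st.floats(0.0, 5.0), alpha=st.floats(0.05, 1.0), beta=st.floats(1.0, 20.0)
    )
    def test_boundaries_hold_for_any_params(self, gamma, alpha, beta):
        p = lf.SCSParams(gamma=gamma, alpha=alpha, beta=beta)
        assert lf.scs_lorenz(0.0, p) == 0.0
        assert lf.scs_lorenz(1.0, p) == 1.0

    def test_gini_diagonal_is_zero(self):
        assert lf.gini_scs(lf.SCSParams(0.0, 1.0, 1.0)) == pytest.approx(0.0, abs=1e-9)

    def test_gini_parabola_closed_form(self):
        # y = x^2 integrates to 1/3
        assert lf.gini_scs(lf.SCSParams(1.0, 1.0, 1.0)) == pytest.approx(1 / 3, abs=1e-9)

    def test_gini_hypothetical_parameterization(self):
        assert round(lf.gini_scs(lf.SCSParams(0.0, 0.31, 1.0)), 3) == 0.527

    @given(alpha=st.floats(0.05, 1.0))
    def test_beta1_gamma0_closed_form(self, alpha):
        # integral of 1-(1-x)^alpha is 1 - 1/(alpha+1)
        p = lf.SCSParams(gamma=0.0, alpha=alpha, beta=1.0)
        expected = 1.0 - 2.0 * (1.0 - 1.0 / (alpha + 1.0))
        assert lf.gini_scs(p) == pytest.approx(expected, abs=1e-8)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            lf.SCSParams(gamma=-1.0, alpha=0.5, beta=1.0)
        with pytest.raises(ValueError):
            lf.SCSParams(gamma=0.0, alpha=0.0, beta=1.0)
        with pytest.raises(ValueError):
            lf.SCSParams(gamma=0.0, alpha=0.5, beta=0.5)


class TestSModel:
    @given(x=st.floats(0.0, 1.0))
    def test_reduces_to_diagonal(self, x):
        p = lf.SParams(lam=0.0, eta=0.0, a1=1.0, a2=1.0)
        assert lf.s_lorenz(x, p) == pytest.approx(x, abs=1e-12)

    @pytest.mark.parametrize(
        "lam,x,expected", [(1.0, 0.5, 0.25), (0.5, 0.5, 0.375)]
    )
    def test_power_curve_points(self, lam, x, expected):
        p = lf.SParams(lam=lam, eta=0.0, a1=1.0, a2=1.0)
        assert lf.s_lorenz(x, p) == pytest.approx(expected, abs=1e-12)

    def test_gini_closed_form_examples(self):
        assert lf.gini_s(lf.SParams(0.0, 0.0, 1.0, 1.0)) == 0.0
        assert lf.gini_s(lf.SParams(1.0, 0.0, 2.0, 1.0)) == pytest.approx(0.5)

    @given(params=s_params)
    def test_gini_matches_quadrature(self, params):
        g_quad = 1.0 - 2.0 * quadrature_area("s", params)
        assert lf.gini_s(params) == pytest.approx(g_quad, abs=1e-8)

    def test_constraint_violation_rejected(self):
        with pytest.raises(ValueError):
            lf.SParams(lam=0.9, eta=1.0, a1=1.0, a2=0.5)  # eta*a2 + lam > 1
        with pytest.raises(ValueError):
            lf.SParams(lam=-0.1, eta=0.0, a1=1.0, a2=1.0)


class TestLorenzConditions:
    def test_smooth_convex_case_passes(self):
        rep = lf.check_lorenz_conditions(
            "proposed", lf.ProposedParams(0.0, 1.0, 0.5, 2.0)
        )
        assert rep.all_ok and rep.jump_at_one == pytest.approx(0.0, abs=1e-12)

    def test_linear_component_jump_flagged_not_failed(self):
        rep = lf.check_lorenz_conditions(
            "proposed", lf.ProposedParams(0.0, 0.0, 0.0, 2.96)
        )
        assert rep.all_ok
        # left limit 2/(P+1) < 1 implies a mass atom at the top rank
        assert rep.jump_at_one == pytest.approx(1.0 - 2.0 / 3.96, abs=1e-9)

    def test_egalitarian_case_noted(self):
        rep = lf.check_lorenz_conditions(
            "proposed", lf.ProposedParams(0.0, 1.0, 0.0, 1.0)
        )
        assert rep.all_ok
        assert any("egalitarian" in n for n in rep.notes)

    @given(params=proposed_params)
    def test_monotone_and_convex_over_parameter_box(self, params):
        rep = lf.check_lorenz_conditions("proposed", params, grid_size=1000)
        assert rep.all_ok

    @given(
        gamma=st.floats(0.0, 3.0), alpha=st.floats(0.1, 1.0), beta=st.floats(1.0, 10.0)
    )
    def test_scs_monotone_on_dense_grid(self, gamma, alpha, beta):
        rep = lf.check_lorenz_conditions(
            "scs", lf.SCSParams(gamma, alpha, beta), grid_size=1000
        )
        assert rep.boundary_zero_ok and rep.boundary_one_ok and rep.monotone_ok

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            lf.check_lorenz_conditions(
                "proposed", lf.ProposedParams(0.0, 1.0, 0.0, 2.0), grid_size=5
            )


@given(params=proposed_params)
def test_first_and_second_differences_on_dense_grid(params):
    """Monotonicity everywhere; convexity of the convex portion."""
    x = np.linspace(0.0, 1.0, 1001)
    y = lf.proposed_lorenz(x, params)
    assert np.all(np.diff(y) >= -1e-12)
    inner = (x[1:-1] > params.delta + 1e-9) & (x[1:-1] < 1.0 - 2e-3)
    assert np.all(np.diff(y, 2)[inner] >= -1e-10)
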