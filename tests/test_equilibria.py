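"""Closed-form equilibria, the p/q criterion, and feasibility windows."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import langdyn as ld
from langdyn.equilibria import Classification, EquilibriumLabel
from langdyn.exceptions import (
    BoundaryCaseError,
    DegenerateDenominatorError,
    ValidationError,
)
from langdyn.sampling import draw_jacobian, draw_model

EXPECTED_COUNTS = {
    "hybrid_lv": 4,
    "basic_rd": 4,
    "common_capacity_rd": 5,
    "ecology_society": 4,
}


def _by_label(equilibria, label):
    return [eq for eq in equilibria if eq.label is label]


class TestClosedFormEquilibria:
    @pytest.mark.parametrize("variant,count", EXPECTED_COUNTS.items())
    def test_candidate_counts(self, variant, count, rng):
        eqs = ld.closed_form_equilibria(draw_model(variant, rng))
        assert len(eqs) == count
        assert eqs[0].label is EquilibriumLabel.ORIGIN
        assert eqs[0].coords == (0.0, 0.0)

    def test_hybrid_interior_printed_formula(self):
        m = ld.make_model("hybrid_lv", a1=0.08, a2=0.01, c=0.005, K1=1, K2=1)
        interior = _by_label(ld.closed_form_equilibria(m),
                             EquilibriumLabel.INTERIOR)[0]
        assert interior.coords[0] == pytest.approx(1.0303030303, abs=1e-9)
        assert interior.coords[1] == pytest.approx(0.4848484848, abs=1e-9)
        assert interior.feasible  # K1 = 1 < a2/c = 2
        assert ld.numeric_equilibrium_residual(m, interior.coords) <= 1e-12

    def test_bidirectional_interior_is_exact_rational(self, exp2_model):
        interior = _by_label(ld.closed_form_equilibria(exp2_model),
                             EquilibriumLabel.INTERIOR)[0]
        assert interior.coords[0] == pytest.approx(12 / 7, rel=1e-14)
        assert interior.coords[1] == pytest.approx(25 / 7, rel=1e-14)
        assert interior.feasible

    def test_complex_discriminant_flagged_infeasible(self):
        m = ld.make_model("common_capacity_rd", a1=0.1, a2=0.1, c=0.01,
                          K=1.0, d1=0, d2=0)  # c^2 K^2 = 1e-4 < 4 a1 a2
        eqs = ld.closed_form_equilibria(m)
        interiors = [eq for eq in eqs if eq.discriminant_complex]
        assert len(interiors) == 2
        assert all(not eq.feasible for eq in interiors)
        assert all(math.isnan(eq.coords[0]) for eq in interiors)

    def test_degenerate_denominator_raises(self):
        # choose K1 so that D = E + c1*(c2*K2 - beta*a2)*K1 vanishes exactly
        a1, a2, al, be, c1, c2, K2 = 0.02, 0.01, 0.6, 0.5, 0.016, 0.02, 1.0
        E = -a1 * a2 + al * be * a1 * a2 - c2 * K2 * al * a1
        K1 = -E / (c1 * (c2 * K2 - be * a2))
        m = ld.make_model("ecology_society", a1=a1, a2=a2, K1=K1, K2=K2,
                          c1=c1, c2=c2, alpha=al, beta=be, d1=0.001, d2=0.001)
        with pytest.raises(DegenerateDenominatorError):
            ld.closed_form_equilibria(m)

    @pytest.mark.parametrize("variant", list(EXPECTED_COUNTS))
    def test_residuals_vanish_across_random_draws(self, variant, rng):
        """Every finite closed-form candidate is a root to 1e-12*max(a1,a2)."""
        checked = 0
        attempts = 0
        while checked < 200 and attempts < 2000:
            attempts += 1
            m = draw_model(variant, rng)
            eqs = ld.closed_form_equilibria(m)
            finite = [eq for eq in eqs if np.isfinite(eq.coords).all()]
            # conditioning preconditions: an exact root evaluated at huge
            # coordinates (near-degenerate interior denominator) or next to
            # a shared-capacity singularity cannot meet an absolute residual
            # bound in float64
            if any(np.abs(eq.coords).max() > 10 for eq in finite):
                continue
            if variant == "common_capacity_rd" and any(
                min(abs(m.K - eq.coords[0]), abs(m.K - eq.coords[1]))
                < 1e-3 * m.K
                for eq in finite
                if eq.label not in (EquilibriumLabel.ONLY_LANG1,
                                    EquilibriumLabel.ONLY_LANG2)
            ):
                continue
            bound = 1e-12 * max(m.a1, m.a2)
            for eq in finite:
                assert ld.numeric_equilibrium_residual(m, eq.coords) <= bound
            checked += 1
        assert checked == 200


class TestPQStability:
    def test_positive_growth_origin_is_unstable(self):
        rep = ld.pq_stability(np.array([[0.08, 0.0], [0.0, 0.01]]))
        assert rep.p == pytest.approx(-0.09)
        assert rep.classification is Classification.UNSTABLE

    def test_negative_diagonal_is_stable(self):
        rep = ld.pq_stability(np.array([[-1.0, 0.0], [0.0, -2.0]]))
        assert rep.p == 3.0 and rep.q == 2.0
        assert rep.classification is Classification.STABLE

    def test_zero_trace_positive_det_is_non_hyperbolic(self):
        rep = ld.pq_stability(np.array([[0.0, 1.0], [-1.0, 0.0]]))
        assert rep.classification is Classification.NON_HYPERBOLIC

    def test_nonfinite_matrix_rejected(self):
        with pytest.raises(ValidationError):
            ld.pq_stability(np.array([[np.nan, 0.0], [0.0, -1.0]]))

    def test_common_capacity_interior_trace_vanishes(self):
        """The shared-capacity interior roots always have p = 0 exactly."""
        m = ld.make_model("common_capacity_rd", a1=0.01, a2=0.02, c=0.04,
                          K=1.0, d1=0, d2=0)
        for eq in ld.classify_equilibria(m):
            if eq.label in (EquilibriumLabel.INTERIOR_PLUS,
                            EquilibriumLabel.INTERIOR_MINUS):
                assert abs(eq.report.p) <= eq.report.tol
                assert eq.report.classification is not Classification.STABLE

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=200, deadline=None)
    def test_pq_rule_is_planar_routh_hurwitz(self, seed):
        """p/q and eigenvalue classifications agree off the boundary."""
        jac = draw_jacobian(np.random.default_rng(seed))
        margin = 1e-9 * np.abs(jac).max()
        pq = ld.pq_stability(jac)
        if min(abs(pq.p), abs(pq.q)) <= margin:
            return  # boundary: sign is not numerically decidable
        assert pq.classification is ld.eigen_stability(jac).classification


class TestClassifyEquilibria:
    def test_hybrid_coexistence_is_the_unique_stable_state(self, rng):
        """With K1 < a2/c the interior root is the only stable equilibrium."""
        found = 0
        while found < 50:
            m = draw_model("hybrid_lv", rng)
            if m.K1 >= m.a2 / m.c:
                continue
            found += 1
            stable = [eq for eq in ld.classify_equilibria(m)
                      if eq.report.classification is Classification.STABLE]
            assert len(stable) == 1
            assert stable[0].label is EquilibriumLabel.INTERIOR
            assert stable[0].feasible

    def test_common_capacity_takeover_state_stable_iff_K_large(self, rng):
        for _ in range(50):
            m = draw_model("common_capacity_rd", rng)
            if abs(m.K - m.a2 / m.c) < 1e-6:
                continue
            (lang1,) = _by_label(ld.classify_equilibria(m),
                                 EquilibriumLabel.ONLY_LANG1)
            expected = (Classification.STABLE if m.K > m.a2 / m.c
                        else Classification.UNSTABLE)
            assert lang1.report.classification is expected

    def test_single_language_thresholds_of_bidirectional_model(self, rng):
        """(0,K2) stable iff K1 < alpha*a1*K2/(a1+c1*K2), and symmetrically."""
        for _ in range(200):
            m = draw_model("ecology_society", rng)
            eqs = ld.classify_equilibria(m)
            (lang2,) = _by_label(eqs, EquilibriumLabel.ONLY_LANG2)
            (lang1,) = _by_label(eqs, EquilibriumLabel.ONLY_LANG1)
            thr2 = m.alpha * m.a1 * m.K2 / (m.a1 + m.c1 * m.K2)
            thr1 = m.beta * m.a2 * m.K1 / (m.a2 + m.c2 * m.K1)
            if abs(m.K1 - thr2) > 1e-9:
                assert (lang2.report.classification is Classification.STABLE) \
                    == (m.K1 < thr2)
            if abs(m.K2 - thr1) > 1e-9:
                assert (lang1.report.classification is Classification.STABLE) \
                    == (m.K2 < thr1)

    def test_experiment_presets_have_stable_coexistence(
        self, exp1_model, exp2_model
    ):
        for m, coords in ((exp1_model, (0.7929515419, 2.0704845815)),
                          (exp2_model, (12 / 7, 25 / 7))):
            (interior,) = _by_label(ld.classify_equilibria(m),
                                    EquilibriumLabel.INTERIOR)
            assert interior.coords == pytest.approx(coords, rel=1e-9)
            assert interior.report.classification is Classification.STABLE
            # cross-check with the eigenvalue oracle
            jac = ld.reaction_jacobian(m, interior.coords)
            assert ld.eigen_stability(jac).classification is Classification.STABLE

    def test_paper_verdict_marks_center_like_cases(self):
        m = ld.make_model("common_capacity_rd", a1=0.02, a2=0.01, c=0.04,
                          K=1.0, d1=0, d2=0)  # a1 > a2: minus root has q > 0
        interiors = [eq for eq in ld.classify_equilibria(m)
                     if eq.label in (EquilibriumLabel.INTERIOR_PLUS,
                                     EquilibriumLabel.INTERIOR_MINUS)]
        for eq in interiors:
            assert eq.report.classification is not Classification.STABLE
        flagged = [eq for eq in interiors if eq.paper_verdict == "not stable"]
        for eq in flagged:
            assert eq.report.classification is Classification.NON_HYPERBOLIC


class TestInteriorFeasibility:
    def test_hybrid_predicate(self):
        m = ld.make_model("hybrid_lv", a1=0.08, a2=0.01, c=0.005, K1=1, K2=1)
        rep = ld.interior_feasibility(m)
        assert rep.feasible and rep.window == (0.0, 2.0)

    def test_bidirectional_window_matches_printed_bounds(self, exp2_model):
        rep = ld.interior_feasibility(exp2_model)
        assert rep.details["c2K2_minus_beta_a2"] == pytest.approx(0.015)
        assert rep.details["D"] == pytest.approx(-0.00014)
        assert rep.window[0] == pytest.approx(1 / 3, rel=1e-12)
        assert rep.window[1] == pytest.approx(19 / 12, rel=1e-12)
        assert rep.feasible  # K1 = 1 inside the window
        # the simplified K1=K2=1 reduction fails here although the full
        # inequality holds; it is a diagnostic only
        assert rep.details["simplified_alpha_gt_c1_over_a1"] is False

    def test_common_capacity_boundary_sum_equals_K(self):
        a1, a2 = 0.01, 0.02
        c = 0.04
        m = ld.make_model("common_capacity_rd", a1=a1, a2=a2, c=c,
                          K=(a1 + a2) / c, d1=0, d2=0)
        rep = ld.interior_feasibility(m)
        assert rep.details["interior_minus_sum"] == pytest.approx(m.K, rel=1e-12)

    def test_common_capacity_window_interior_violates_capacity(self, rng):
        """For 2*sqrt(a1 a2)/c < K < (a1+a2)/c with a2 > a1, u1*+u2* >= K."""
        for _ in range(50):
            a1 = rng.uniform(0.005, 0.1)
            a2 = a1 * rng.uniform(1.5, 4.0)
            c = rng.uniform(0.01, 0.2)
            lo = 2 * math.sqrt(a1 * a2) / c
            hi = (a1 + a2) / c
            K = rng.uniform(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo))
            m = ld.make_model("common_capacity_rd", a1=a1, a2=a2, c=c, K=K,
                              d1=0, d2=0)
            rep = ld.interior_feasibility(m)
            assert rep.details["interior_minus_sum"] >= m.K * (1 - 1e-12)
            assert not rep.feasible

    def test_sign_boundary_raises(self):
        # c2*K2 == beta*a2 exactly
        m = ld.make_model("ecology_society", a1=0.02, a2=0.01, K1=1, K2=1,
                          c1=0.016, c2=0.005, alpha=0.6, beta=0.5,
                          d1=0.005, d2=0.005)
        with pytest.raises(BoundaryCaseError):
            ld.interior_feasibility(m)

    def test_window_membership_equals_interior_positivity(self, rng):
        """Window verdict == brute-force positivity of the interior root."""
        checked = 0
        while checked < 500:
            m = draw_model("ecology_society", rng)
            s = m.c2 * m.K2 - m.beta * m.a2
            if abs(s) < 1e-6:
                continue
            rep = ld.interior_feasibility(m)
            (interior,) = [eq for eq in ld.closed_form_equilibria(m)
                           if eq.label is EquilibriumLabel.INTERIOR]
            positive = interior.coords[0] > 0 and interior.coords[1] > 0
            if rep.window is not None:
                lo, hi = rep.window
                if min(abs(m.K1 - lo), abs(m.K1 - hi)) < 1e-9:
                    continue  # exactly on a case boundary
            assert rep.feasible == positive
            checked += 1


def test_residual_reports_largest_rate_at_non_equilibrium(exp2_model):
    assert ld.numeric_equilibrium_residual(exp2_model, (0.5, 0.5)) == \
        pytest.approx(0.00625, abs=1e-15)
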