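"""Multi-order characteristic polynomials, sector condition, verdicts."""

import cmath
import math

import numpy as np
import pytest

import fracimmune as fi
from fracimmune import ModelParams, RationalOrder, State

from conftest import random_params


def fd_jacobian(params, point, eps=1e-6):
    """Central finite differences of the rate field (independent oracle)."""
    J = np.empty((2, 2))
    for j in range(2):
        dP = eps if j == 0 else 0.0
        dT = eps if j == 1 else 0.0
        fp = fi.rhs(params, State(point.P + dP, point.T + dT))
        fm = fi.rhs(params, State(point.P - dP, point.T - dT))
        J[:, j] = (np.array(fp) - np.array(fm)) / (2 * eps)
    return J


def det_eval(params, eq, lam):
    """Determinant oracle: det(diag(lam^e1, lam^e2) - J) at a complex point."""
    m = fi.sector_order_m(params.alpha1, params.alpha2)
    e1 = (m // params.alpha1.denominator) * params.alpha1.numerator
    e2 = (m // params.alpha2.denominator) * params.alpha2.numerator
    J = fi.jacobian(params, eq.as_state())
    M = np.array(
        [[lam**e1 - J[0, 0], -J[0, 1]], [-J[1, 0], lam**e2 - J[1, 1]]],
        dtype=complex,
    )
    return M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]


class TestJacobian:
    def test_closed_form_at_origin(self, scenario2):
        p = scenario2.params
        J = fi.jacobian(p, State(0.0, 0.0))
        assert np.allclose(J, [[p.beta_P, 0.0], [0.0, -p.delta]])

    def test_closed_form_at_pathogen_only_point(self, scenario2):
        p = scenario2.params
        J = fi.jacobian(p, State(p.Lambda, 0.0))
        expected = [
            [-p.beta_P, -p.c * p.Lambda / (p.a * p.Lambda + 1)],
            [0.0, p.mu * p.Lambda / (1 + p.nu * p.Lambda) - p.delta],
        ]
        assert np.allclose(J, expected)

    def test_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            p = random_params(rng)
            pt = State(float(rng.uniform(0.05, 5)), float(rng.uniform(0.05, 5)))
            J = fi.jacobian(p, pt)
            assert np.allclose(J, fd_jacobian(p, pt), rtol=1e-5, atol=1e-6)


@pytest.mark.parametrize(
    "a1, a2, m",
    [((4, 5), (3, 5), 5), ((1, 1), (1, 1), 1), ((1, 2), (1, 3), 6)],
)
def test_sector_order_m(a1, a2, m):
    assert fi.sector_order_m(RationalOrder(*a1), RationalOrder(*a2)) == m


class TestCharacteristicPolynomial:
    def test_scenario2_printed_equation(self, scenario2):
        e2 = fi.equilibria(scenario2.params)[2]
        poly = fi.characteristic_polynomial(scenario2.params, e2)
        assert poly.degree == 7 and poly.m == 5
        assert set(poly.coefficients) == {7, 3, 0}
        assert poly.coefficients[7] == 1.0
        assert poly.coefficients[3] == pytest.approx(-1.40, abs=5e-5)
        assert poly.coefficients[0] == pytest.approx(1.1692, abs=5e-5)
        assert poly.A1 == pytest.approx(0.95) and poly.A2 == pytest.approx(2 / 3)

    def test_scenario3_printed_equation(self, scenario3):
        e2 = fi.equilibria(scenario3.params)[2]
        poly = fi.characteristic_polynomial(scenario3.params, e2)
        assert poly.coefficients[3] == pytest.approx(-0.48, abs=5e-5)
        assert poly.coefficients[0] == pytest.approx(1.1077, abs=5e-5)
        assert poly.A1 == pytest.approx(0.90) and poly.A2 == pytest.approx(1 / 3)

    def test_nonexistent_interior_point_rejected(self, scenario1):
        e2 = fi.equilibria(scenario1.params)[2]
        with pytest.raises(ValueError):
            fi.characteristic_polynomial(scenario1.params, e2)

    def test_matches_determinant_oracle(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 200:
            p = random_params(rng)
            for eq in fi.equilibria(p):
                if eq.label == "E2" and not eq.exists_biologically:
                    continue
                poly = fi.characteristic_polynomial(p, eq)
                lam = complex(rng.normal(), rng.normal())
                expected = det_eval(p, eq, lam)
                scale = max(abs(expected), max(
                    abs(c) for c in poly.coefficients.values()))
                assert abs(poly(lam) - expected) < 1e-10 * max(scale, 1.0)
                checked += 1

    def test_roots_satisfy_polynomial(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p = random_params(rng, require_e2=True, max_denominator=6)
            poly = fi.characteristic_polynomial(p, fi.equilibria(p)[2])
            scale = max(abs(c) for c in poly.coefficients.values())
            for r in poly.roots():
                assert abs(poly(r)) / scale < 1e-8

    def test_root_set_closure(self):
        # conjugate pairing; zero root sum when the subleading term is absent
        rng = np.random.default_rng(13)
        for _ in range(50):
            p = random_params(rng, require_e2=True, max_denominator=6)
            poly = fi.characteristic_polynomial(p, fi.equilibria(p)[2])
            roots = poly.roots()
            assert len(roots) == poly.degree
            key = lambda z: (z.real, z.imag)
            paired = sorted(np.round(roots, 8).tolist(), key=key)
            conj = sorted(np.round(np.conj(roots), 8).tolist(), key=key)
            assert paired == conj
            if poly.degree - 1 not in poly.coefficients:
                assert abs(roots.sum()) < 1e-6 * max(1.0, np.abs(roots).max())


class TestClassify:
    def test_pathogen_only_point_scenario1(self, scenario1):
        rep = fi.classify(scenario1.params, fi.equilibria(scenario1.params)[1])
        assert rep.verdict == "LAS" and rep.method == "analytic_E1"
        assert rep.details["threshold_quantity"] == pytest.approx(10.0)

    def test_interior_point_scenario2_unstable(self, scenario2):
        rep = fi.classify(scenario2.params, fi.equilibria(scenario2.params)[2])
        assert rep.verdict == "unstable"
        assert rep.threshold_deg == pytest.approx(18.0)
        assert rep.min_abs_arg_deg == pytest.approx(14.3191, abs=1e-2)

    def test_interior_point_scenario3_stable(self, scenario3):
        rep = fi.classify(scenario3.params, fi.equilibria(scenario3.params)[2])
        assert rep.verdict == "LAS"
        assert rep.min_abs_arg_deg == pytest.approx(22.0255, abs=1e-2)

    def test_scenario2_unique_real_root(self, scenario2):
        rep = fi.classify(scenario2.params, fi.equilibria(scenario2.params)[2])
        real = [r for r in rep.roots if r.imag == 0.0]
        assert len(real) == 1
        assert real[0].real == pytest.approx(-1.2004, abs=1e-3)

    def test_disease_free_point_always_unstable(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = random_params(rng, max_denominator=6)
            rep = fi.classify(p, fi.equilibria(p)[0])
            assert rep.verdict == "unstable" and rep.method == "analytic_E0"

    def test_nonexistent_interior_point_not_applicable(self, scenario1):
        rep = fi.classify(scenario1.params, fi.equilibria(scenario1.params)[2])
        assert rep.verdict == "not_applicable"

    def test_analytic_and_root_paths_agree(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            p = random_params(rng, max_denominator=6)
            for eq in fi.equilibria(p)[:2]:
                analytic = fi.classify(p, eq)
                by_roots = fi.classify(p, eq, force_roots=True)
                if by_roots.verdict == "marginal":
                    continue
                assert analytic.verdict == by_roots.verdict, (
                    f"{eq.label}: {analytic.verdict} vs {by_roots.verdict}"
                )

    def test_pathogen_only_and_interior_mutually_exclusive(self):
        # E1 LAS and a biologically existing E2 can never coincide
        rng = np.random.default_rng(23)
        for _ in range(1000):
            p = random_params(rng, max_denominator=6)
            eqs = fi.equilibria(p)
            e1_verdict = fi.classify(p, eqs[1]).verdict
            if eqs[2].exists_biologically:
                assert e1_verdict == "unstable"
            if e1_verdict == "LAS":
                assert not eqs[2].exists_biologically


class TestEqualOrder:
    def test_rejects_distinct_orders(self, scenario2):
        with pytest.raises(ValueError):
            fi.classify_equal_order(scenario2.params)

    def test_commensurate_route_scenario3_rates(self):
        p = ModelParams(
            beta_P=2.4, Lambda=5, c=4, a=1, mu=3.9, nu=1.9, delta=1,
            alpha1=0.7, alpha2=0.7,
        )
        rep = fi.classify_equal_order(p)
        assert rep.details["trace_term"] == pytest.approx(0.2)
        assert not rep.details["routh_hurwitz_LAS"]
        full = fi.classify(p, fi.equilibria(p)[2])
        assert rep.verdict == full.verdict == "LAS"
        # the transformed roots are the (m*alpha)-th roots of the 2x2
        # eigenvalues, so arguments divide by m*alpha = 10 * 7/10 = 7
        assert rep.min_abs_arg_deg / 7.0 == pytest.approx(
            full.min_abs_arg_deg, rel=1e-9)

    def test_routh_hurwitz_branch_stable_for_every_order(self):
        # small a and Lambda drive A1*(A2+1) below 1 (negative trace term):
        # the Routh-Hurwitz branch then gives LAS for every order
        for alpha in (0.3, 0.6, 0.9, 1.0):
            p = ModelParams(
                beta_P=2.4, Lambda=1, c=4, a=0.5, mu=3.9, nu=1.9, delta=1,
                alpha1=alpha, alpha2=alpha,
            )
            rep = fi.classify_equal_order(p)
            assert rep.details["trace_term"] < 0
            assert rep.details["routh_hurwitz_LAS"]
            assert rep.verdict == "LAS"

    def test_integer_order_matches_eigenvalue_sign_test(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            p = random_params(
                rng, orders=(RationalOrder(1, 1), RationalOrder(1, 1)),
                require_e2=True)
            rep = fi.classify_equal_order(p)
            if rep.verdict == "marginal":
                continue
            eigs = np.linalg.eigvals(
                fi.jacobian(p, fi.equilibria(p)[2].as_state()))
            assert rep.verdict == (
                "LAS" if np.all(eigs.real < 0) else "unstable")

    def test_agrees_with_multiorder_path(self):
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 200:
            den = int(rng.integers(2, 9))
            num = int(rng.integers(1, den + 1))
            alpha = RationalOrder(num, den)
            p = random_params(rng, orders=(alpha, alpha), require_e2=True)
            rep_eq = fi.classify_equal_order(p)
            rep_full = fi.classify(p, fi.equilibria(p)[2])
            if "marginal" in (rep_eq.verdict, rep_full.verdict):
                continue
            assert rep_eq.verdict == rep_full.verdict
            checked += 1

    def test_sector_monotone_in_order(self):
        # roots of the 2x2 problem are order-independent; lowering alpha
        # widens the stable sector, so LAS can only be preserved
        rng = np.random.default_rng(37)
        for _ in range(100):
            den = int(rng.integers(2, 9))
            num = int(rng.integers(2, den + 1))
            alpha = RationalOrder(num, den)
            p = random_params(rng, orders=(alpha, alpha), require_e2=True)
            rep = fi.classify_equal_order(p)
            if rep.verdict != "LAS":
                continue
            smaller = RationalOrder(max(1, num - 1), den)
            p_small = ModelParams(
                beta_P=p.beta_P, Lambda=p.Lambda, c=p.c, a=p.a, mu=p.mu,
                nu=p.nu, delta=p.delta, alpha1=smaller, alpha2=smaller)
            assert fi.classify_equal_order(p_small).verdict == "LAS"


class TestAngleEquation:
    @pytest.mark.parametrize("name", ["scenario2", "scenario3"])
    def test_root_angles_satisfy_angle_equation(self, name, request):
        cfg = request.getfixturevalue(name)
        residuals = fi.angle_equation_check(cfg.params)
        evaluated = [r for r in residuals if not r.skipped]
        assert evaluated, "all angles were flagged singular"
        for r in evaluated:
            assert abs(r.residual) < 1e-6

    def test_non_root_angle_fails_equation(self, scenario2):
        (res,) = fi.angle_equation_check(scenario2.params, thetas_deg=[20.0])
        assert res.skipped or abs(res.residual) > 1e-3

    def test_singular_angles_flagged(self, scenario2):
        # sin(m(a1+a2)*theta) = 0 at theta = 180/7 deg
        (res,) = fi.angle_equation_check(
            scenario2.params, thetas_deg=[180.0 / 7.0])
        assert res.skipped and "singular" in res.reason

    def test_requires_existing_interior_point(self, scenario1):
        with pytest.raises(ValueError):
            fi.angle_equation_check(scenario1.params)
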