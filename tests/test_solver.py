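"""Constraint solver, prevalence and recurrence-risk predictors."""
import itertools
import math

import numpy as np
import pytest

import mssusmod as m
from mssusmod.parameters import RelativeClass as R

C_STAR = 0.45 / 0.76


def enumerate_prevalence(params):
    """Brute-force oracle: sum over all 2^(x+1) susceptible-state vectors."""
    total = 0.0
    F = params.F
    for states in itertools.product((0, 1), repeat=params.x + 1):
        hla, rest = states[0], states[1:]
        w = params.h if hla else 1.0 - params.h
        for s in rest:
            w *= F if s else 1.0 - F
        if sum(states) >= params.n:
            total += w * (params.Pt1_star if hla else params.Pt0_star)
    return total


class TestHlaNegativeFraction:
    def test_direct_arithmetic(self):
        assert m.hla_negative_fraction(5, 5, 1) == pytest.approx(1 / 6, abs=1e-12)

    def test_empty_product(self):
        assert m.hla_negative_fraction(3, 0, 2) == 1.0

    def test_consistency_with_worked_root(self):
        assert m.hla_negative_fraction(15.87, 4, 2) == pytest.approx(0.592, abs=1e-3)

    def test_monotone_increasing_in_x_decreasing_in_r(self):
        xs = np.arange(10, 40)
        vals = m.hla_negative_fraction(xs, 5, 2.0)
        assert np.all(np.diff(vals) > 0)
        rs = [0.25, 0.5, 1, 2, 4, 8]
        vals_r = [m.hla_negative_fraction(20, 5, r) for r in rs]
        assert all(a > b for a, b in zip(vals_r, vals_r[1:]))

    def test_zero_at_lower_edge_and_domain_error(self):
        assert m.hla_negative_fraction(4, 5, 1.0) == 0.0
        with pytest.raises(ValueError):
            m.hla_negative_fraction(3, 5, 1.0)


class TestSolveX:
    def test_worked_quadratic_example(self):
        sol = m.solve_x(4, 2, C_STAR)
        assert round(sol.x_continuous, 1) == 15.9

    def test_trivial_root(self):
        assert m.solve_x(1, 1, 0.5).x_continuous == pytest.approx(1.0, abs=1e-8)

    def test_integer_band_telescoped_case(self):
        sol = m.solve_x(5, 1, C_STAR, tol=0.05)
        assert (sol.x_low, sol.x_high) == (10, 12)

    def test_empty_band_is_reported_not_raised(self):
        sol = m.solve_x(5, 16, 0.999, tol=0.0005)
        assert not sol.feasible
        assert sol.x_low is None and sol.x_high is None
        with pytest.raises(ValueError):
            sol.endpoints


class TestPrevalence:
    def test_toy_closed_form(self):
        p = m.ModelParameters.with_composition(
            n=1, r=2, x=2, composition=(1, 0, 0), Pt0_star=1.0, Pt1_star=1.0)
        assert m.prevalence(p) == pytest.approx(0.41146, abs=5e-6)

    def test_zero_penetrance(self):
        p = m.ModelParameters.with_composition(
            n=3, r=2, x=10, composition=(0, 1, 0), Pt0_star=0.0, Pt1_star=0.0)
        assert m.prevalence(p) == 0.0

    @pytest.mark.parametrize("n,r,x", [(1, 2, 2), (2, 1, 4), (3, 2, 6),
                                       (5, 4, 8), (6, 0.5, 12)])
    def test_matches_exhaustive_enumeration(self, n, r, x):
        p = m.ModelParameters.with_composition(n=n, r=r, x=x, composition=(0.2, 0.8, 0))
        assert m.prevalence(p) == pytest.approx(enumerate_prevalence(p), abs=1e-12)

    def test_nonincreasing_in_n(self):
        prevs = [m.prevalence(m.ModelParameters.with_composition(
            n=n, r=2, x=30, composition=(0, 1, 0))) for n in range(1, 15)]
        assert all(a >= b for a, b in zip(prevs, prevs[1:]))

    def test_table_cell_r2_n13(self):
        # printed range 0.16 - 0.28% at the printed x endpoints 53 and 57
        lo = m.prevalence(m.ModelParameters.with_composition(n=13, r=2, x=53,
                                                             composition=(0, 1, 0)))
        hi = m.prevalence(m.ModelParameters.with_composition(n=13, r=2, x=57,
                                                             composition=(0, 1, 0)))
        assert round(100 * lo, 2) == 0.16
        assert round(100 * hi, 2) == 0.28


class TestLimitPrevalence:
    def test_floor_at_n5_and_n10(self):
        assert round(100 * m.limit_prevalence(5, 0.24, C_STAR, 0.134), 2) == 1.27
        assert round(100 * m.limit_prevalence(10, 0.24, C_STAR, 0.134), 2) == 0.29

    def test_zero_penetrance(self):
        assert m.limit_prevalence(5, 0.24, C_STAR, 0.0) == 0.0

    @pytest.mark.parametrize("n", [5, 10, 15])
    def test_agrees_with_large_r_evaluation(self, n):
        r = 1e6
        sol = m.solve_x(n, r, C_STAR, x_max=4)  # integer scan irrelevant here
        x = int(round(sol.x_continuous))
        p = m.ModelParameters.with_composition(n=n, r=r, x=x, composition=(0, 1, 0))
        finite = m.prevalence(p)
        lim = m.limit_prevalence(n, 0.24, C_STAR, 0.134)
        assert abs(finite - lim) / lim < 1e-3


class TestRecurrence:
    def toy(self, **kw):
        base = dict(n=1, r=2, x=2, composition=(1, 0, 0), Pt0_star=1.0, Pt1_star=1.0)
        base.update(kw)
        return m.ModelParameters.with_composition(**base)

    def test_toy_sibling_direct_evaluation(self):
        p = self.toy()
        a_h = p.a_h
        p_h = 0.5 * (1 + 2 * a_h - a_h ** 2)
        expected = 1 - (1 - p_h) * (1 - 0.12) ** 2
        assert m.recurrence_risk(p, R.SIBLING, True) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.7056, abs=1e-3)

    def test_zero_penetrance(self):
        p = self.toy(Pt0_star=0.0, Pt1_star=0.0)
        assert m.recurrence_risk(p, R.SIBLING, True) == 0.0

    def test_dominant_sibling_equals_parent_child(self):
        # identical transmission formulas for purely dominant loci
        for n, r, x in [(3, 2, 10), (5, 4, 40), (13, 2, 55)]:
            p = m.ModelParameters.with_composition(n=n, r=r, x=x, composition=(1, 0, 0))
            for hla in (True, False):
                assert m.recurrence_risk(p, R.SIBLING, hla) == \
                    m.recurrence_risk(p, R.PARENT_CHILD, hla)

    def test_recessive_sibling_exceeds_parent_child(self):
        # 0.25 (1+a)^2 > a for a < 1
        for n, r, x in [(3, 2, 10), (13, 2, 55), (13, 4, 100)]:
            p = m.ModelParameters.with_composition(n=n, r=r, x=x, composition=(0, 1, 0))
            assert m.expected_recurrence(p, R.SIBLING) > \
                m.expected_recurrence(p, R.PARENT_CHILD)

    def test_degree_ordering_of_recurrence(self):
        p = m.ModelParameters.with_composition(n=13, r=2, x=55, composition=(0.2, 0.8, 0))
        first = m.expected_recurrence(p, R.SIBLING)
        second = m.expected_recurrence(p, R.AUNT_UNCLE)
        third = m.expected_recurrence(p, R.FIRST_COUSIN)
        assert first >= second >= third

    def test_dz_twin_uses_unadjusted_penetrance(self):
        p = m.ModelParameters.with_composition(n=3, r=2, x=10, composition=(0, 1, 0))
        sib = m.recurrence_risk(p, R.SIBLING, True)
        dz = m.recurrence_risk(p, R.DZ_TWIN, True)
        assert dz == pytest.approx(sib * p.dz_sib_ratio, rel=1e-12)

    def test_mz_twin_risk_is_penetrance(self):
        p = m.ModelParameters.with_composition(n=3, r=2, x=10, composition=(0, 1, 0))
        assert m.recurrence_risk(p, R.MZ_TWIN, True) == pytest.approx(p.Pt1)

    def test_family_information_raises_risk(self):
        for r in (0.25, 1, 4, 16):
            for n in (5, 10, 13, 18):
                sol = m.solve_x(n, r, C_STAR)
                if not sol.feasible:
                    continue
                p = m.ModelParameters.with_composition(
                    n=n, r=r, x=sol.x_low, composition=(0.2, 0.8, 0))
                assert m.expected_recurrence(p, R.SIBLING) >= m.prevalence(p)

    def test_expected_recurrence_mixture(self):
        p = m.ModelParameters.with_composition(n=3, r=2, x=10, composition=(1, 0, 0), C=0.0)
        assert m.expected_recurrence(p, R.SIBLING) == \
            m.recurrence_risk(p, R.SIBLING, True)

    def test_infeasible_partition_raises(self):
        p = m.ModelParameters.with_composition(n=5, r=1, x=4, composition=(0, 1, 0))
        with pytest.raises(ValueError):
            m.recurrence_risk(p, R.SIBLING, False)


class TestTableSpotValues:
    def test_sibling_80_recessive_optimum_column(self):
        # printed 3.5 - 4.2% at the printed x endpoints 100 and 107
        vals = []
        for x in (100, 107):
            p = m.ModelParameters.with_composition(n=13, r=4, x=x,
                                                   composition=(0.2, 0.8, 0))
            vals.append(m.expected_recurrence(p, R.SIBLING))
        assert vals[0] == pytest.approx(0.035, abs=0.002)
        assert vals[1] == pytest.approx(0.042, abs=0.002)

    def test_sibling_100_recessive_column(self):
        # printed 3.7 - 4.3% at x = 58..61
        lo = m.expected_recurrence(m.ModelParameters.with_composition(
            n=14, r=2, x=58, composition=(0, 1, 0)), R.SIBLING)
        hi = m.expected_recurrence(m.ModelParameters.with_composition(
            n=14, r=2, x=61, composition=(0, 1, 0)), R.SIBLING)
        assert round(100 * lo, 1) == 3.7
        assert round(100 * hi, 1) == 4.3
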