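"""Exact 2x2 inference against closed forms, enumeration and scipy oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ttnburden.exact import (
    ExactConfig,
    UndefinedOddsRatioError,
    cmle_or,
    cross_product_or,
    enrichment_test,
    fisher_exact_p,
    midp_ci,
    midp_p,
    noncentral_hypergeom_pmf,
    support_pmf,
    woolf_ci,
)
from ttnburden.model import ContingencyTable2x2

T = ContingencyTable2x2

tables = (
    st.tuples(*[st.integers(0, 25)] * 4)
    .filter(lambda c: c[0] + c[1] > 0 and c[2] + c[3] > 0)
    .map(lambda c: T(*c))
)


def exact_pmf_fraction(k, n1, n2, m, psi_num, psi_den):
    """Brute-force rational enumeration of the noncentral mass (psi rational)."""
    lo, hi = max(0, m - n2), min(n1, m)
    psi = Fraction(psi_num, psi_den)
    weights = {
        j: Fraction(math.comb(n1, j) * math.comb(n2, m - j)) * psi**j
        for j in range(lo, hi + 1)
    }
    return weights[k] / sum(weights.values())


class TestNoncentralPmf:
    def test_central_closed_form(self):
        assert noncentral_hypergeom_pmf(1, 2, 2, 2, 1.0) == pytest.approx(2 / 3, abs=1e-14)

    def test_reduces_to_central_hypergeometric(self):
        ks, pmf = support_pmf(12, 30, 20, 1.0)
        expected = stats.hypergeom.pmf(ks, 42, 12, 20)
        np.testing.assert_allclose(pmf, expected, atol=1e-13)

    @pytest.mark.parametrize("psi_num,psi_den", [(2, 1), (1, 3), (7, 2)])
    def test_matches_rational_enumeration(self, psi_num, psi_den):
        n1, n2, m = 6, 9, 7
        for k in range(max(0, m - n2), min(n1, m) + 1):
            oracle = float(exact_pmf_fraction(k, n1, n2, m, psi_num, psi_den))
            assert noncentral_hypergeom_pmf(k, n1, n2, m, psi_num / psi_den) == pytest.approx(
                oracle, abs=1e-12
            )

    @given(
        n1=st.integers(1, 40), n2=st.integers(1, 40), m=st.integers(0, 80),
        psi=st.floats(0.01, 100),
    )
    def test_normalises_over_support(self, n1, n2, m, psi):
        if m > n1 + n2:
            m = n1 + n2
        _, pmf = support_pmf(n1, n2, m, psi)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_infeasible_k_has_zero_mass(self):
        assert noncentral_hypergeom_pmf(5, 3, 3, 4, 1.0) == 0.0

    def test_rejects_nonpositive_psi(self):
        with pytest.raises(ValueError):
            support_pmf(3, 3, 3, 0.0)

    def test_huge_margins_stay_normalised(self):
        # panel-scale cells (ExAC-sized denominators) must not overflow;
        # log-gamma accumulation at these magnitudes costs a few ulp beyond
        # the small-margin 1e-12 bound
        _, pmf = support_pmf(70, 106140, 11823, 1.0)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-10)


class TestCrossProductOr:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((12, 23, 37, 194), 2328 / 851),
            ((12, 58, 1895, 11111), 1.2131016286052225),
            ((1, 1, 1, 1), 1.0),
        ],
    )
    def test_finite_values(self, cells, expected):
        assert cross_product_or(T(*cells)) == pytest.approx(expected, rel=1e-12)

    def test_zero_denominator_is_infinite(self):
        assert math.isinf(cross_product_or(T(12, 58, 0, 5008)))

    def test_zero_numerator_is_zero(self):
        assert cross_product_or(T(0, 58, 10, 5008)) == 0.0

    def test_zero_over_zero_is_undefined(self):
        with pytest.raises(UndefinedOddsRatioError):
            cross_product_or(T(0, 10, 0, 10))


class TestCmle:
    def test_symmetric_table(self, cfg):
        assert cmle_or(T(1, 1, 1, 1), cfg) == pytest.approx(1.0, abs=1e-6)

    def test_boundary_tables(self, cfg):
        assert math.isinf(cmle_or(T(5, 0, 0, 5), cfg))
        assert cmle_or(T(0, 5, 5, 0), cfg) == 0.0

    @pytest.mark.parametrize("cells", [(3, 7, 2, 11), (5, 2, 4, 9), (1, 9, 3, 4)])
    def test_agrees_with_grid_search(self, cells, cfg):
        """The CMLE maximises the conditional likelihood at the observed count."""
        t = T(*cells)
        grid = np.exp(np.linspace(np.log(1e-4), np.log(1e4), 200_001))
        lik = [noncentral_hypergeom_pmf(t.a, t.n1, t.n2, t.m, p) for p in grid]
        psi_grid = grid[int(np.argmax(lik))]
        assert cmle_or(t, cfg) == pytest.approx(psi_grid, rel=1e-3)
        assert cmle_or(t, cfg) == pytest.approx(psi_grid, abs=1e-2)

    def test_shrinks_relative_to_cross_product(self, cfg):
        # the conditional MLE is pulled toward 1 relative to (a d)/(b c)
        t = T(12, 23, 37, 194)
        assert 1.0 < cmle_or(t, cfg) < cross_product_or(t)


class TestPValues:
    def test_degenerate_table_p_one(self, cfg):
        assert fisher_exact_p(T(0, 7, 0, 9), cfg) == pytest.approx(1.0)

    @given(t=tables)
    def test_one_sided_matches_scipy_fisher(self, t):
        mine = fisher_exact_p(t, ExactConfig(sidedness="one_sided_greater"))
        _, oracle = stats.fisher_exact(
            [[t.a, t.b], [t.c, t.d]], alternative="greater"
        )
        assert mine == pytest.approx(oracle, abs=1e-11)

    @given(t=tables)
    def test_midp_dominated_by_fisher(self, t):
        for sided in ("one_sided_greater", "one_sided_less", "two_sided_doubling"):
            c = ExactConfig(sidedness=sided)
            assert midp_p(t, c) <= fisher_exact_p(t, c) + 1e-14

    def test_midp_strictly_below_fisher_on_study_table(self, cfg):
        t = T(12, 23, 37, 194)
        assert midp_p(t, cfg) < fisher_exact_p(t, cfg)

    def test_proportional_table_is_null_centred(self, cfg):
        assert midp_p(T(5, 5, 5, 5), cfg) > 0.5

    def test_minlike_rule_available(self):
        c = ExactConfig(sidedness="two_sided_minlike")
        t = T(12, 23, 37, 194)
        # minimum-likelihood two-sided p agrees with scipy's two-sided Fisher
        # when the observed mass counts fully
        _, oracle = stats.fisher_exact([[t.a, t.b], [t.c, t.d]])
        assert fisher_exact_p(t, c) == pytest.approx(oracle, abs=1e-11)
        assert midp_p(t, c) < fisher_exact_p(t, c)


class TestMidpCi:
    def test_study_carrier_table(self, cfg):
        lo, hi = midp_ci(T(12, 23, 37, 194), cfg)
        assert lo == pytest.approx(1.21, abs=0.01)
        assert hi == pytest.approx(5.94, abs=0.01)

    def test_rare_stratum_table(self, cfg):
        lo, hi = midp_ci(T(9, 61, 820, 12186), cfg)
        assert lo == pytest.approx(1.022, abs=0.005)
        assert hi == pytest.approx(4.278, abs=0.005)

    def test_inversion_consistency(self, cfg):
        """Plugging a bound back as psi must return tail probability alpha/2."""
        from ttnburden.exact import _tails

        for cells in [(12, 23, 37, 194), (9, 61, 820, 12186), (4, 6, 3, 9)]:
            t = T(*cells)
            lo, hi = midp_ci(t, cfg)
            assert _tails(t, lo, mid=True)[0] == pytest.approx(
                0.025, abs=10 * cfg.root_tolerance
            )
            assert _tails(t, hi, mid=True)[1] == pytest.approx(
                0.025, abs=10 * cfg.root_tolerance
            )

    def test_agrees_with_dense_grid_oracle(self, cfg):
        """Independent oracle: scan a dense psi grid with scipy's noncentral
        distribution for the tail-crossing points."""
        t = T(4, 6, 3, 9)
        grid = np.exp(np.linspace(np.log(1e-3), np.log(1e3), 600_001))
        sf = stats.nchypergeom_fisher.sf(t.a - 1, t.n1 + t.n2, t.n1, t.m, grid)
        pm = stats.nchypergeom_fisher.pmf(t.a, t.n1 + t.n2, t.n1, t.m, grid)
        upper_tail = sf - 0.5 * pm
        lower_tail = 1 - sf + 0.5 * pm
        lo_oracle = grid[int(np.searchsorted(upper_tail, 0.025))]
        hi_oracle = grid[len(grid) - 1 - int(np.searchsorted(lower_tail[::-1], 0.025))]
        lo, hi = midp_ci(t, cfg)
        assert lo == pytest.approx(lo_oracle, abs=1e-3)
        assert hi == pytest.approx(hi_oracle, abs=1e-3)

    def test_zero_control_cell_gives_open_upper_bound(self, cfg):
        lo, hi = midp_ci(T(9, 61, 0, 5008), cfg)
        assert lo > 1.0
        assert math.isinf(hi)

    def test_contained_in_fisher_exact_ci(self, cfg):
        """The mid-p interval sits inside the conservative Fisher exact interval."""
        from ttnburden.exact import _bisect, _tails

        for cells in [(12, 23, 37, 194), (5, 5, 3, 12), (2, 8, 9, 4)]:
            t = T(*cells)
            m_lo, m_hi = midp_ci(t, cfg)
            f_lo = math.exp(_bisect(
                lambda lp: _tails(t, math.exp(lp), mid=False)[0] - 0.025, cfg, True))
            f_hi = math.exp(_bisect(
                lambda lp: _tails(t, math.exp(lp), mid=False)[1] - 0.025, cfg, False))
            assert f_lo <= m_lo and m_hi <= f_hi


class TestWoolfCi:
    def test_closed_form(self, cfg):
        t = T(12, 23, 37, 194)
        se = math.sqrt(1 / 12 + 1 / 23 + 1 / 37 + 1 / 194)
        z = stats.norm.ppf(0.975)
        lo, hi = woolf_ci(t, cfg)
        point = cross_product_or(t)
        assert lo == pytest.approx(point * math.exp(-z * se), rel=1e-12)
        assert hi == pytest.approx(point * math.exp(z * se), rel=1e-12)

    def test_symmetric_about_one_on_log_scale(self, cfg):
        lo, hi = woolf_ci(T(1, 1, 1, 1), cfg)
        assert lo * hi == pytest.approx(1.0, rel=1e-10)

    def test_widens_with_level(self):
        t = T(6, 4, 3, 7)
        lo90, hi90 = woolf_ci(t, ExactConfig(level=0.90))
        lo99, hi99 = woolf_ci(t, ExactConfig(level=0.99))
        assert lo99 < lo90 and hi90 < hi99

    def test_zero_cell_directs_to_midp(self, cfg):
        with pytest.raises(ValueError, match="midp_ci"):
            woolf_ci(T(0, 5, 3, 7), cfg)


class TestEnrichmentBundle:
    def test_study_tables(self, cfg):
        r1 = enrichment_test(T(12, 23, 37, 194), cfg)
        assert r1.p_midp == pytest.approx(0.016, abs=0.001)
        assert r1.or_display == "2.736"
        r2 = enrichment_test(T(12, 23, 6, 39), cfg)
        assert r2.p_midp == pytest.approx(0.032, abs=0.001)

    def test_null_table(self, cfg):
        r = enrichment_test(T(1, 1, 1, 1), cfg)
        assert r.or_cross_product == 1.0
        assert r.p_midp > 0.5
        assert r.ci[0] < 1.0 < r.ci[1]
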