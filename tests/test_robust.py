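"""MAX3, MIN2, GMS and GME: selection rules, invariances, bootstrap behaviour,
Monte-Carlo oracles for the selection-adjusted p-values, and null calibration."""

import math

import numpy as np
import pytest
from hypothesis import given
from scipy import stats

from robustgwas import (
    GenotypeCounts,
    catt,
    estimate_correlations,
    gme_pvalue,
    gme_stat,
    gms_pvalue,
    gms_select,
    hwdtt,
    max3_pvalue,
    max3_stat,
    min2_pvalue,
    min2_stat,
    pearson_chi2,
)
from robustgwas.robust import (
    _max3_box,
    _min2_pvalue_batch,
    _selection_survival_batch,
)
from robustgwas.simulate import _StageStats, _gms_selection

from .test_contingency import polymorphic_tables


class TestMax3:
    def test_null_table_gives_zero(self, null_table):
        assert max3_stat(null_table).statistic == pytest.approx(0.0, abs=1e-12)

    @given(polymorphic_tables())
    def test_dominates_additive_component(self, table):
        assert max3_stat(table).statistic >= abs(catt(table, 0.5).statistic) - 1e-12

    @given(polymorphic_tables())
    def test_allele_relabel_invariance(self, table):
        assert max3_stat(table.relabelled()).statistic == pytest.approx(
            max3_stat(table).statistic, abs=1e-10
        )

    def test_bootstrap_pvalue_bounds_and_self_consistency(self, balanced_table):
        b = 20_000
        p_a = max3_pvalue(balanced_table, b=b, seed=1).p_value
        p_b = max3_pvalue(balanced_table, b=b, seed=2).p_value
        assert 1.0 / (b + 1) <= p_a <= 1.0
        se = math.sqrt(p_a * (1 - p_a) / b)
        assert abs(p_a - p_b) < 3 * math.sqrt(2) * se

    def test_bonferroni_bracketing(self):
        # under the null each |Z_x| shares the tail of the maximising component,
        # so p_best <= p_MAX3 <= 3 p_best (+ MC error)
        rng = np.random.default_rng(3)
        for _ in range(5):
            v = rng.integers(5, 60, size=6)
            table = GenotypeCounts(*(int(x) for x in v))
            if table.is_degenerate or np.any(table.n_i == 0):
                continue
            res = max3_pvalue(table, b=20_000, seed=5)
            p_best = 2 * stats.norm.sf(res.statistic)
            se = math.sqrt(max(res.p_value * (1 - res.p_value), 1e-9) / 20_000)
            assert res.p_value >= p_best - 3 * se
            assert res.p_value <= 3 * p_best + 3 * se

    def test_asymptotic_mode_agrees_with_bootstrap(self, balanced_table):
        p_boot = max3_pvalue(balanced_table, b=200_000, seed=4).p_value
        p_asym = max3_pvalue(balanced_table, mode="asymptotic").p_value
        se = math.sqrt(p_boot * (1 - p_boot) / 200_000)
        assert abs(p_boot - p_asym) < 4 * se


class TestMin2:
    def test_null_table(self, null_table):
        res = min2_stat(null_table)
        assert res.statistic == pytest.approx(1.0)
        assert res.component == "additive"  # tie goes to the additive part

    @given(polymorphic_tables())
    def test_minimum_and_relabel_invariance(self, table):
        res = min2_stat(table)
        assert res.statistic <= catt(table, 0.5).p_value + 1e-12
        assert res.statistic <= pearson_chi2(table).p_value + 1e-12
        assert min2_stat(table.relabelled()).statistic == pytest.approx(
            res.statistic, abs=1e-10
        )

    def test_adjustment_brackets_and_monotone(self):
        grid = [1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.2, 0.5, 0.9, 1.0]
        prev = 0.0
        for m in grid:
            p = min2_pvalue(m)
            assert m - 1e-12 <= p <= 2 * m + 1e-12, m
            assert p > prev
            prev = p
        assert min2_pvalue(1.0) == pytest.approx(1.0)

    def test_batch_matches_scalar(self):
        grid = np.array([1e-6, 1e-4, 1e-2, 0.04])
        batch = _min2_pvalue_batch(grid)
        for m, pb in zip(grid, batch):
            assert pb == pytest.approx(min2_pvalue(m), rel=5e-7)

    def test_against_monte_carlo_oracle(self):
        # the asymptotic null: additive trend z is one 1-df component of the
        # 2-df Pearson statistic
        rng = np.random.default_rng(8)
        z1 = rng.standard_normal(1_000_000)
        z2 = rng.standard_normal(1_000_000)
        p_half = stats.chi2.sf(z1**2, 1)
        p_chi = stats.chi2.sf(z1**2 + z2**2, 2)
        mn = np.minimum(p_half, p_chi)
        for m in (0.05, 0.01, 1e-3):
            mc = np.mean(mn <= m)
            se = math.sqrt(mc * (1 - mc) / len(mn))
            assert abs(min2_pvalue(m) - mc) < 3 * se, m

    def test_domain_errors(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                min2_pvalue(bad)


class TestGmsSelection:
    @given(polymorphic_tables())
    def test_rule_matches_independent_reconstruction(self, table):
        """gms_select implements: Z_H > c -> recessive-coded trend, < -c ->
        dominant-coded, else additive; roles exchanged and statistics negated
        when the additive trend points at allele A."""
        res = gms_select(table, 0.05)
        z = {x: catt(table, x).statistic for x in (0.0, 0.5, 1.0)}
        z_h = hwdtt(table).z_h
        c = stats.norm.isf(0.05)
        if z[0.5] > 0:
            expect = z[0.0] if z_h > c else (z[1.0] if z_h < -c else z[0.5])
        else:
            expect = -z[1.0] if z_h > c else (-z[0.0] if z_h < -c else -z[0.5])
        assert res.statistic == pytest.approx(expect, abs=1e-12)
        assert res.c == pytest.approx(c)

    @given(polymorphic_tables())
    def test_allele_relabel_leaves_statistic_unchanged(self, table):
        a = gms_select(table, 0.05).statistic
        b = gms_select(table.relabelled(), 0.05).statistic
        assert a == pytest.approx(b, abs=1e-10)

    @given(polymorphic_tables())
    def test_within_band_gme_equals_gms(self, table):
        g1 = gms_select(table, 0.05)
        g2 = gme_stat(table, 0.05)
        if g1.zh_region == "within":
            assert g2.statistic == pytest.approx(g1.statistic, abs=1e-12)

    def test_starred_components_have_unit_null_variance(self, balanced_table):
        # Var(Z_x + Z_1/2) = 2 (1 + rho): verify the standardisation empirically
        corr = estimate_correlations(balanced_table)
        rng = np.random.default_rng(9)
        z = rng.multivariate_normal(np.zeros(4), corr.matrix(), size=200_000)
        for x, rho in ((0, corr.rho_0_half), (2, corr.rho_1_half)):
            star = (z[:, x] + z[:, 1]) / math.sqrt(2 * (1 + rho))
            assert np.std(star) == pytest.approx(1.0, abs=0.01)


class TestSelectionAdjustedPvalues:
    @pytest.fixture(scope="class")
    @staticmethod
    def corr():
        return estimate_correlations(GenotypeCounts(10, 10, 20, 20, 10, 10))

    def test_monotone_decreasing(self, corr):
        for pfun in (gms_pvalue, gme_pvalue):
            vals = [pfun(t, corr, alpha_h=0.05) for t in (0.5, 1.5, 2.5, 3.5)]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_batch_matches_adaptive_quadrature(self, corr):
        for starred in (False, True):
            c = float(stats.norm.isf(0.05))
            ts = np.array([1.0, 2.0, 3.0, 4.5])
            batch = _selection_survival_batch(ts, corr, c, starred=starred)
            pfun = gme_pvalue if starred else gms_pvalue
            for t, pb in zip(ts, batch):
                assert pb == pytest.approx(pfun(float(t), corr), abs=2e-6)

    def test_against_monte_carlo_oracle(self, corr):
        """Draw the 4-variate normal null, apply the selection rule, and
        compare the empirical survival of the oriented statistic with the
        quadrature at several thresholds (GMS and GME)."""
        rng = np.random.default_rng(10)
        n = 1_000_000
        z = rng.multivariate_normal(np.zeros(4), corr.matrix(), size=n)
        z0, zhalf, z1, zh = z.T
        c = float(stats.norm.isf(0.05))
        pos = zhalf > 0
        above, below = zh > c, zh < -c
        plain = np.where(
            pos,
            np.where(above, z0, np.where(below, z1, zhalf)),
            -np.where(above, z1, np.where(below, z0, zhalf)),
        )
        s0 = (z0 + zhalf) / math.sqrt(2 * (1 + corr.rho_0_half))
        s1 = (z1 + zhalf) / math.sqrt(2 * (1 + corr.rho_1_half))
        starred = np.where(
            pos,
            np.where(above, s0, np.where(below, s1, zhalf)),
            -np.where(above, s1, np.where(below, s0, zhalf)),
        )
        for sel, pfun in ((plain, gms_pvalue), (starred, gme_pvalue)):
            for t in (1.5, 2.5, 3.5):
                mc = np.mean(sel > t)
                se = math.sqrt(mc * (1 - mc) / n)
                assert abs(pfun(t, corr) - mc) < 3 * se, (pfun.__name__, t)

    def test_non_psd_correlations_rejected(self, corr):
        from dataclasses import replace

        bad = replace(corr, rho_0_half=-0.99, rho_1_half=0.99, rho_0_1=0.99)
        with pytest.raises(ValueError):
            gms_pvalue(2.0, bad, alpha_h=0.05)


class TestNullCalibration:
    def test_gms_gme_max3_reject_five_percent_under_null(self):
        """End-to-end: p-values of the robust tests on multinomial null tables
        reject at ~0.05 (single-stage calibration, 20000 tables)."""
        rng = np.random.default_rng(12)
        g = np.array([0.49, 0.42, 0.09])
        n_rep = 20_000
        cases = rng.multinomial(750, g, size=n_rep).astype(float)
        ctrls = rng.multinomial(750, g, size=n_rep).astype(float)
        s = _StageStats(cases, ctrls)
        c = float(stats.norm.isf(0.05))
        se = math.sqrt(0.05 * 0.95 / n_rep)
        idx, pos = _gms_selection(s, c)
        for starred in (False, True):
            stack = s.z_star_stack if starred else s.z_stack
            picked = np.take_along_axis(stack, idx[..., None], -1)[..., 0]
            t = np.where(pos, picked, -picked)
            p = _selection_survival_batch(t, s.corr, c, starred=starred)
            rate = np.mean(p < 0.05)
            assert abs(rate - 0.05) < 3 * se, ("GME" if starred else "GMS", rate)
        t_max3 = np.abs(s.z_stack).max(axis=-1)
        p = 1.0 - _max3_box(t_max3, s.corr)
        rate = np.mean(p < 0.05)
        assert abs(rate - 0.05) < 3 * se, ("MAX3", rate)
        m = np.minimum(s.chi2[2], 2 * stats.norm.sf(np.abs(s.z(0.5))))
        rate = np.mean(_min2_pvalue_batch(np.clip(m, 1e-300, 1 - 1e-12)) < 0.05)
        assert abs(rate - 0.05) < 3 * se, ("MIN2", rate)
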