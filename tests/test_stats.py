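"""Statistics layer: descriptives, t tests, ANOVA variants, pooling, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from guidedev.errors import ConfigError
from guidedev.stats import (
    describe,
    factorial_anova,
    one_way_anova,
    pooled_mean,
    sample_size_two_group_t,
    tukey_kramer,
    two_sample_t,
)


class TestDescribe:
    def test_constant_sample(self):
        s = describe([1, 1, 1])
        assert (s.mean, s.sd, s.n) == (1.0, 0.0, 3)

    def test_symmetric_quartiles(self):
        s = describe([0, 1, 2, 3, 4])
        assert (s.q1, s.median, s.q3) == (1.0, 2.0, 3.0)
        assert (s.min, s.max) == (0.0, 4.0)

    def test_matches_two_pass_oracle(self, rng):
        x = rng.normal(size=500)
        s = describe(x)
        mean = sum(float(v) for v in x) / len(x)
        sd = (sum((float(v) - mean) ** 2 for v in x) / (len(x) - 1)) ** 0.5
        assert s.mean == pytest.approx(mean, abs=1e-12)
        assert s.sd == pytest.approx(sd, abs=1e-12)
        assert s.q1 <= s.median <= s.q3

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            describe([])


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_equal_means_convention(self):
        res = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_summary_mode_equals_raw_mode(self, rng):
        a, b = rng.normal(size=15), rng.normal(0.5, 1.2, size=20)
        for variant in ("pooled", "welch"):
            raw = two_sample_t(a, b, variant=variant)
            summ = two_sample_t(
                (a.mean(), a.std(ddof=1), len(a)),
                (b.mean(), b.std(ddof=1), len(b)),
                variant=variant,
            )
            assert summ.statistic == pytest.approx(raw.statistic, abs=1e-12)
            assert summ.p_value == pytest.approx(raw.p_value, abs=1e-12)

    def test_published_registration_contrast(self):
        """Pooled t from the study's registration-group summary statistics
        (1.24 ± 0.68 mm, n=21 vs 0.92 ± 0.49 mm, n=35) reproduces the
        printed p = 0.0464 within summary-rounding tolerance."""
        res = two_sample_t((1.24, 0.68, 21), (0.92, 0.49, 35), variant="pooled")
        assert res.p_value == pytest.approx(0.0464, abs=0.003)

    def test_matches_permutation_oracle(self, rng):
        a, b = rng.normal(size=8), rng.normal(0.8, 1.0, size=9)
        res = two_sample_t(a, b, variant="pooled")
        combined = np.concatenate([a, b])
        n_perm = 20_000
        obs = abs(a.mean() - b.mean())
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(combined)
            count += abs(perm[:8].mean() - perm[8:].mean()) >= obs - 1e-12
        p_perm = count / n_perm
        # permutation and t p-values agree within Monte-Carlo error for
        # moderate samples from a normal population
        assert res.p_value == pytest.approx(p_perm, abs=4 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.02)

    def test_degenerate_n_rejected(self):
        with pytest.raises(ConfigError):
            two_sample_t([1.0], [1.0, 2.0])


class TestOneWayAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(size=12), rng.normal(0.3, 1.0, size=15)
        F = one_way_anova([a, b]).term("between")["F"]
        t = two_sample_t(a, b, variant="pooled").statistic
        assert F == pytest.approx(t**2, abs=1e-10)

    def test_identical_groups_give_zero_f(self):
        g = [1.0, 2.0, 3.0]
        table = one_way_anova([g, g, g])
        assert table.term("between")["F"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(m, 1.0, size=n) for m, n in ((0, 10), (0.5, 14), (1.0, 8))]
        table = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert table.term("between")["F"] == pytest.approx(ref.statistic, abs=1e-10)
        assert table.term("between")["p"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_residual_df(self, rng):
        groups = [rng.normal(size=5), rng.normal(size=7)]
        table = one_way_anova(groups)
        assert table.residual["df"] == 10


class TestTukeyKramer:
    def test_no_flags_for_identical_groups(self):
        g = [1.0, 2.0, 3.0, 2.0]
        out = tukey_kramer([g, g, g])
        assert not out.significant.any()
        assert (out.p > 0.99).all()

    def test_matches_statsmodels_tukeyhsd(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = [rng.normal(m, 1.0, size=n) for m, n in ((0, 9), (0.7, 13), (1.8, 6))]
        ours = tukey_kramer(groups, labels=["a", "b", "c"])
        data = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c"], [9, 13, 6])
        ref = pairwise_tukeyhsd(data, labels)
        assert np.allclose(ours.p.to_numpy(), ref.pvalues, atol=1e-6)

    def test_guide_support_flag_pattern(self, rng):
        """Three groups simulated from the study's guide-support summaries
        (mucosa 0.62±0.33 n=28, bilateral 0.65±0.36 n=20, distal extension
        1.03±0.61 n=8): over seeded replicates, the distal-extension pairs
        are flagged more often than the mucosa-vs-bilateral pair."""
        flags = np.zeros(3)
        reps = 300
        for _ in range(reps):
            g1 = rng.normal(0.62, 0.33, 28)
            g2 = rng.normal(0.65, 0.36, 20)
            g3 = rng.normal(1.03, 0.61, 8)
            out = tukey_kramer([g1, g2, g3], labels=["mucosa", "bilateral", "distal"])
            flags += out.significant.to_numpy()
        muc_bil, muc_dist, bil_dist = flags
        assert muc_dist > muc_bil and bil_dist > muc_bil

    def test_small_group_rejected(self):
        with pytest.raises(ConfigError):
            tukey_kramer([[1.0, 2.0], [3.0]])


class TestFactorialAnova:
    @staticmethod
    def _balanced_table(rng, effect=0.0):
        rows = []
        for a in "xy":
            for b in "uv":
                for c in "pq":
                    for _ in range(4):
                        y = rng.normal() + (effect if a == "x" else 0.0)
                        rows.append({"y": y, "A": a, "B": b, "D": c})
        return pd.DataFrame(rows)

    def test_balanced_type3_equals_sequential(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        table = self._balanced_table(rng, effect=0.8)
        ours = factorial_anova(table, "y", ["A", "B", "D"])
        seq = sm.stats.anova_lm(
            smf.ols("y ~ C(A, Sum) * C(B, Sum) * C(D, Sum)", table).fit(), typ=1
        )
        for term, seq_name in (("A", "C(A, Sum)"), ("B", "C(B, Sum)"), ("D", "C(D, Sum)")):
            assert ours.term(term)["sum_sq"] == pytest.approx(
                seq.loc[seq_name, "sum_sq"], abs=1e-8
            )

    def test_single_factor_reduces_to_one_way(self, rng):
        table = pd.DataFrame({
            "y": rng.normal(size=30),
            "g": np.repeat(["a", "b", "c"], 10),
        })
        ours = factorial_anova(table, "y", ["g"], include_interactions=False)
        groups = [table.loc[table.g == lev, "y"].to_numpy() for lev in ("a", "b", "c")]
        ref = one_way_anova(groups)
        assert ours.term("g")["F"] == pytest.approx(ref.term("between")["F"], abs=1e-9)

    def test_null_p_values_uniform(self, rng):
        """Term p-values on balanced null designs are uniform (KS check)."""
        pvals = {"A": [], "B": [], "D": []}
        for _ in range(300):
            table = self._balanced_table(rng)
            aov = factorial_anova(table, "y", ["A", "B", "D"])
            for term in pvals:
                pvals[term].append(aov.term(term)["p"])
        for term, ps in pvals.items():
            assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_cell_interaction_dropped_with_warning(self, rng):
        table = self._balanced_table(rng)
        table = table[~((table.A == "x") & (table.B == "u"))]
        with pytest.warns(UserWarning, match="empty cells"):
            aov = factorial_anova(table, "y", ["A", "B", "D"])
        assert not any(":" in t and "A" in t and "B" in t for t in aov.terms.term)

    def test_single_level_factor_named_in_error(self, rng):
        table = pd.DataFrame({"y": rng.normal(size=10), "A": ["x"] * 10})
        with pytest.raises(ConfigError, match="'A'"):
            factorial_anova(table, "y", ["A"])


class TestPooledMean:
    def test_single_group_is_identity(self):
        assert pooled_mean([(0.73, 12)]) == 0.73

    def test_published_total_row(self):
        assert pooled_mean([(0.97, 56), (1.84, 18)], round_2dp=True) == 1.18

    def test_published_registration_margin(self):
        assert pooled_mean([(1.24, 21), (0.92, 35)], round_2dp=True) == 1.04

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            pooled_mean([])


class TestSampleSize:
    def test_matches_exact_power_grid(self):
        """n per group from the analytic search equals the smallest n whose
        exact noncentral-t power reaches the target (brute-force oracle)."""
        for d in (0.5, 0.8, 1.0):
            n = sample_size_two_group_t(d, power=0.8, alpha=0.05)

            def power_at(m, d=d):
                df = 2 * m - 2
                tcrit = sps.t.ppf(0.975, df)
                nc = d * np.sqrt(m / 2)
                return sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)

            assert power_at(n) >= 0.8
            assert power_at(n - 1) < 0.8

    def test_agrees_with_statsmodels_power(self):
        from statsmodels.stats.power import TTestIndPower

        n = sample_size_two_group_t(0.5, power=0.8, alpha=0.05)
        ref = TTestIndPower().solve_power(effect_size=0.5, power=0.8, alpha=0.05)
        assert abs(n - ref) <= 1.0

    def test_vanishing_power_gives_minimum_n(self):
        assert sample_size_two_group_t(1.0, power=1e-6, alpha=0.05) == 2

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ConfigError):
            sample_size_two_group_t(-1.0, 0.8, 0.05)
        with pytest.raises(ConfigError):
            sample_size_two_group_t(0.5, 1.5, 0.05)
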