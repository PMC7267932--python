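"""Repeated-measures ANOVA, Duncan post-hoc, modulator tests, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flowparse import bold_sim, glm, regional_stats as rs
from flowparse.regional_stats import (
    ANOVA_CONDITIONS,
    RegionResponseTable,
    classify_profile,
    duncan_critical_value,
    duncan_posthoc,
    flow_parsing_index,
    modulator_ttests,
    pearson_corr,
    rm_anova_oneway,
)

CONDS = list(ANOVA_CONDITIONS)


def random_table(rng, n, loc=None):
    vals = rng.standard_normal((n, 4))
    if loc is not None:
        vals = vals + np.asarray(loc)
    return pd.DataFrame(vals, columns=CONDS)


class TestRmAnova:
    @pytest.mark.parametrize("n, df2", [(15, 42), (14, 39)])
    def test_degrees_of_freedom(self, n, df2):
        rng = np.random.default_rng(0)
        res = rm_anova_oneway(random_table(rng, n))
        assert (res.df1, res.df2) == (3, df2)

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("n", [2, 5, 12, 30])
    def test_df_formula_grid(self, k, n):
        rng = np.random.default_rng(k * 100 + n)
        cols = [f"c{i}" for i in range(k)]
        table = pd.DataFrame(rng.standard_normal((n, k)), columns=cols)
        res = rm_anova_oneway(table, restrict_motion=False)
        assert res.df1 == k - 1
        assert res.df2 == (k - 1) * (n - 1)

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        table = random_table(rng, 12, loc=[0.0, 0.3, 0.5, 0.8])
        res = rm_anova_oneway(table)
        long = table.reset_index().melt(
            id_vars="index", var_name="cond", value_name="y"
        )
        oracle = pingouin.rm_anova(
            data=long, dv="y", within="cond", subject="index"
        )
        pcol = "p_unc" if "p_unc" in oracle.columns else "p-unc"
        assert res.F == pytest.approx(float(oracle["F"].iloc[0]), rel=1e-6)
        assert res.p_value == pytest.approx(float(oracle[pcol].iloc[0]), rel=1e-6)

    def test_identical_values_degenerate(self):
        table = pd.DataFrame(np.ones((6, 4)), columns=CONDS)
        res = rm_anova_oneway(table)
        assert res.F == 0.0 and res.p_value == 1.0

    def test_f_equals_squared_paired_t_for_two_conditions(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        res = rm_anova_oneway(x, restrict_motion=False)
        t = stats.ttest_rel(x["a"], x["b"])
        assert res.F == pytest.approx(t.statistic**2)
        assert res.p_value == pytest.approx(t.pvalue)

    def test_type_one_error_rate_at_nominal_level(self):
        rng = np.random.default_rng(12345)
        n_sim, alpha = 2000, 0.05
        rejections = sum(
            rm_anova_oneway(random_table(rng, 14)).p_value < alpha
            for _ in range(n_sim)
        )
        assert 0.035 <= rejections / n_sim <= 0.065

    def test_static_excluded_from_regional_analysis(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((10, 5))
        table = RegionResponseTable(
            pd.DataFrame(vals, columns=CONDS + ["Static"]), region="V6"
        )
        res = rm_anova_oneway(table)
        assert res.df1 == 3  # four motion conditions only

    def test_missing_cells_rejected(self):
        table = pd.DataFrame(np.ones((5, 4)), columns=CONDS)
        table.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_oneway(table)


class TestDuncan:
    def test_clear_separation(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, 12) * 0.01
        table["Disjoint"] += 10.0
        ph = duncan_posthoc(table)
        sig = ph.significant_pairs()
        assert frozenset(("Disjoint", "Joint")) in sig
        assert frozenset(("Disjoint", "Onboard")) in sig
        assert frozenset(("Disjoint", "Offboard")) in sig
        assert frozenset(("Joint", "Onboard")) not in sig

    def test_step_down_protection(self):
        """A pair inside a homogeneous span is never called significant."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            table = random_table(rng, 8)
            ph = duncan_posthoc(table)
            d = ph.decisions
            full_span = d[d["span"] == 4]
            if not full_span["significant"].iloc[0]:
                assert not d["significant"].any()

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            table = random_table(rng, 10, loc=[0, 0.3, 0.6, 1.0])
            strict = duncan_posthoc(table, alpha=0.01).significant_pairs()
            loose = duncan_posthoc(table, alpha=0.05).significant_pairs()
            assert strict <= loose

    def test_two_groups_reduce_to_lsd(self):
        """With two conditions Duncan's protection level is alpha, so the
        decision matches an unprotected paired-model LSD test."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            table = pd.DataFrame(
                rng.standard_normal((9, 2)) + [0.0, 0.6], columns=["a", "b"]
            )
            anova = rm_anova_oneway(table, restrict_motion=False)
            ph = duncan_posthoc(table, alpha=0.05, anova=anova)
            # LSD: |diff| > t_{1-alpha/2, df2} * sqrt(2 MS_res / n)
            lsd = stats.t.ppf(0.975, anova.df2) * np.sqrt(
                2 * anova.ms_residual / anova.n_units
            )
            diff = abs(table["a"].mean() - table["b"].mean())
            assert ph.decisions["significant"].iloc[0] == (diff > lsd)

    def test_studentized_range_quantile_against_monte_carlo(self):
        """q(.95, 3, 42) validated against simulated range/SD draws."""
        q = stats.studentized_range.ppf(0.95, 3, 42)
        rng = np.random.default_rng(99)
        n_draws = 200_000
        z = rng.standard_normal((n_draws, 3))
        s = np.sqrt(rng.chisquare(42, n_draws) / 42)
        stat = (z.max(axis=1) - z.min(axis=1)) / s
        mc = np.quantile(stat, 0.95)
        assert q == pytest.approx(mc, rel=0.01)

    def test_critical_value_uses_protection_level(self):
        # span 2 at alpha equals the plain studentized-range quantile;
        # span 3 uses level 1-(1-alpha)^2
        c2 = duncan_critical_value(0.05, 2, 40, 1.0, 10)
        q2 = stats.studentized_range.ppf(0.95, 2, 40) * np.sqrt(0.1)
        assert c2 == pytest.approx(q2)
        c3 = duncan_critical_value(0.05, 3, 40, 1.0, 10)
        q3 = stats.studentized_range.ppf(
            (1 - 0.05) ** 2, 3, 40
        ) * np.sqrt(0.1)
        assert c3 == pytest.approx(q3)


class TestModulatorTTests:
    def make_loadings(self, values_by_cell, n=14):
        rows = []
        for (region, modulator), vals in values_by_cell.items():
            for v in vals:
                rows.append({"region": region, "modulator": modulator, "value": v})
        return pd.DataFrame(rows)

    def test_zero_loadings_nonsignificant(self):
        table = self.make_loadings({("V6", "SoM"): [0.0] * 14})
        out = modulator_ttests(table, n_regions=12)
        assert out["t"].iloc[0] == 0.0
        assert not out["significant"].iloc[0]

    def test_constant_nonzero_degenerate(self):
        table = self.make_loadings({("MT", "QoM"): [0.7] * 14})
        out = modulator_ttests(table, n_regions=12)
        assert np.isinf(out["t"].iloc[0])
        assert out["significant"].iloc[0] and out["degenerate"].iloc[0]

    def test_power_matches_noncentral_t(self):
        """Empirical Bonferroni-corrected power for N(0.5, 1) loadings,
        n = 14 subjects, 12 regions, vs the closed-form noncentral-t."""
        n, n_regions, alpha = 14, 12, 0.05
        thr = alpha / n_regions
        t_crit = stats.t.ppf(1 - thr / 2, n - 1)
        ncp = 0.5 * np.sqrt(n)
        power = 1 - stats.nct.cdf(t_crit, n - 1, ncp) + stats.nct.cdf(
            -t_crit, n - 1, ncp
        )
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 4000
        for _ in range(n_sim):
            v = rng.normal(0.5, 1.0, n)
            t, p = stats.ttest_1samp(v, 0.0)
            hits += p < thr
        assert abs(hits / n_sim - power) < 0.05

    def test_bonferroni_threshold_applied(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.8, 1.0, 14)
        table = self.make_loadings({("A", "SoM"): list(vals)})
        t, p = stats.ttest_1samp(vals, 0.0)
        few = modulator_ttests(table, n_regions=1)
        many = modulator_ttests(table, n_regions=1000)
        assert few["significant"].iloc[0] == (p < 0.05)
        assert many["significant"].iloc[0] == (p < 0.05 / 1000)

    def test_single_subject_rejected(self):
        table = self.make_loadings({("A", "QoM"): [1.0]})
        with pytest.raises(ValueError, match="2 subjects"):
            modulator_ttests(table, n_regions=1)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(5.0)
        r, p = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        r, _ = pearson_corr(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, _ = pearson_corr(x, y)
        oracle = np.sum((x - x.mean()) * (y - y.mean())) / (
            np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
        )
        assert r == pytest.approx(oracle)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_corr(np.ones(5), np.arange(5.0))


class TestFlowParsing:
    def test_identical_conditions_give_zero_index(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(12)
        table = pd.DataFrame(
            {"Joint": base, "Onboard": base, "Offboard": base, "Disjoint": base}
        )
        res = flow_parsing_index(table)
        assert res.index == 0.0 and not res.flow_parsing

    def test_programmed_difference_detected(self):
        """Joint - Onboard = 0.3 PSC with 0.2 subject SD, n = 14: the
        region should be flagged in at least 90% of replicates."""
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            onboard = rng.normal(0.5, 0.2, 14)
            joint = onboard + rng.normal(0.3, 0.2, 14)
            table = pd.DataFrame({"Joint": joint, "Onboard": onboard})
            hits += flow_parsing_index(table).flow_parsing
        assert hits >= 90

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {"Joint": rng.standard_normal(10), "Onboard": rng.standard_normal(10)}
        )
        swapped = table.rename(columns={"Joint": "Onboard", "Onboard": "Joint"})
        assert flow_parsing_index(table).index == pytest.approx(
            -flow_parsing_index(swapped).index
        )

    def test_missing_condition_rejected(self):
        with pytest.raises(KeyError):
            flow_parsing_index(pd.DataFrame({"Joint": [1.0, 2.0]}))


class TestClassifyProfile:
    def build(self, means, n=14, sd=0.1, seed=0):
        rng = np.random.default_rng(seed)
        data = {
            c: rng.normal(m, sd, n) for c, m in zip(CONDS, means)
        }
        return pd.DataFrame(data)

    def test_object_preferring_with_flow_parsing(self):
        # MT-like: Offboard > Onboard, Joint > Onboard
        table = self.build([1.0, 0.3, 0.9, 0.8])
        prof = classify_profile(table)
        assert prof.label == "object_preferring"
        assert prof.flow_parsing

    def test_self_preferring_without_flow_parsing(self):
        # CSv-like: Onboard > Offboard, Joint == Onboard
        table = self.build([0.2, 1.0, 1.0, 0.8])
        prof = classify_profile(table)
        assert prof.label == "self_preferring"
        assert not prof.flow_parsing

    def test_complex_preferring(self):
        table = self.build([0.5, 0.5, 0.6, 1.2])
        prof = classify_profile(table)
        assert prof.label == "complex_preferring"

    def test_flat_table_unclassified(self):
        table = pd.DataFrame(np.full((14, 4), 0.5), columns=CONDS)
        prof = classify_profile(table)
        assert prof.label == "unclassified"
        assert not prof.flow_parsing

    def test_recovers_programmed_profile_from_bold_simulation(
        self, identifiable_design_matrix
    ):
        """End to end: simulate subjects with a programmed self-motion
        preference (Onboard 0.5 PSC above Offboard), fit each subject's
        GLM, classify the region from recovered PSC values."""
        x = identifiable_design_matrix
        idx = {c: x.names.index(c) for c in CONDS}
        group = np.zeros(14)
        group[idx["Onboard"]] = 0.7
        group[idx["Offboard"]] = 0.2
        group[idx["Joint"]] = 0.7
        group[idx["Disjoint"]] = 0.5
        rng = np.random.default_rng(21)
        hits = 0
        n_reps = 20
        for rep in range(n_reps):
            subj_betas = bold_sim.draw_subject_betas(group, 10, 0.1, rng)
            psc = {c: [] for c in CONDS}
            for s, betas in enumerate(subj_betas):
                spec = bold_sim.SimSpec(
                    betas=betas, rho=0.3, noise_sd=0.5,
                    seed=int(rng.integers(2**31 - 1)),
                )
                y, _ = bold_sim.simulate_roi_timeseries(x, spec)
                fit = glm.fit_glm_ar1(y, x)
                for c in CONDS:
                    psc[c].append(glm.percent_signal_change(fit, c)[0])
            table = pd.DataFrame(psc)
            prof = classify_profile(table)
            hits += prof.label == "self_preferring"
        assert hits >= int(0.95 * n_reps)


class TestRegionReport:
    def test_report_structure(self):
        rng = np.random.default_rng(5)
        table = RegionResponseTable(
            pd.DataFrame(
                rng.standard_normal((14, 4)) + [0.2, 0.8, 0.9, 0.6],
                columns=CONDS,
            ),
            region="pCi",
        )
        report = rs.region_report(table)
        assert report["region"] == "pCi"
        assert report["anova"]["df"] == [3, 39]
        assert set(report) >= {"posthoc", "profile", "flow_parsing"}
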