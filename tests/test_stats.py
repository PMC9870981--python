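"""ANOVA / Dunnett from summary statistics and the survival layer."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gcxquant import (
    GroupSummary,
    anova_from_summary,
    dunnett_critical_value,
    dunnett_sf,
    dunnett_sf_mc,
    dunnett_vs_control,
    km_curve,
    logrank_test,
    significance_flag,
    summarize_groups,
)
from gcxquant.exceptions import StatsError
from gcxquant.tables import ENDPOINT_SUMMARIES


def summaries_of(endpoint):
    return [
        GroupSummary(g, n, m, s, endpoint)
        for g, (m, s, n) in ENDPOINT_SUMMARIES[endpoint].items()
    ]


def exact_moment_sample(mean, sd, n, rng):
    """Raw sample whose mean and sample SD match the summary exactly."""
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestAnova:
    def test_two_group_closed_form(self):
        res = anova_from_summary(
            [GroupSummary("a", 3, 0.0, 1.0), GroupSummary("b", 3, 2.0, 1.0)]
        )
        assert res.F == pytest.approx(6.0)
        assert res.df_between == 1 and res.df_within == 4
        assert res.mse == pytest.approx(1.0)
        assert res.p == pytest.approx(0.070484, abs=1e-5)

    def test_equal_means_give_zero_f(self):
        res = anova_from_summary(
            [GroupSummary("a", 4, 1.0, 0.5), GroupSummary("b", 6, 1.0, 0.7)]
        )
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_summary_anova_equals_raw_anova(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            k = rng.integers(2, 6)
            raws = [rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3),
                               size=rng.integers(3, 12)) for _ in range(k)]
            summaries = [
                GroupSummary(f"g{i}", len(x), float(x.mean()), float(x.std(ddof=1)))
                for i, x in enumerate(raws)
            ]
            f_raw, _ = sps.f_oneway(*raws)
            assert anova_from_summary(summaries).F == pytest.approx(f_raw, abs=1e-10)

    def test_all_groups_constant_and_equal_raises(self):
        with pytest.raises(StatsError):
            anova_from_summary(
                [GroupSummary("a", 3, 1.0, 0.0), GroupSummary("b", 3, 1.0, 0.0)]
            )


class TestDunnett:
    def test_single_treatment_reduces_to_t_test(self):
        summ = [GroupSummary("C", 7, 0.0, 1.0), GroupSummary("T", 5, 1.2, 1.1)]
        (comp,) = dunnett_vs_control(summ, "C")
        assert comp.p_adjusted == pytest.approx(comp.p_unadjusted, abs=2e-5)
        assert comp.p_unadjusted == pytest.approx(
            2 * sps.t.sf(abs(comp.t), 10), rel=1e-9
        )

    def test_adjusted_p_monotone_and_above_unadjusted(self):
        lam = [math.sqrt(8 / 17)] * 3
        ps = [dunnett_sf(q, lam, 30) for q in (1.0, 1.5, 2.0, 2.5, 3.0)]
        assert all(b < a for a, b in zip(ps, ps[1:]))
        for q in (1.0, 2.0, 3.0):
            assert dunnett_sf(q, lam, 30) >= 2 * sps.t.sf(q, 30) - 1e-12

    def test_large_df_single_comparison_approaches_z_test(self):
        lam = [math.sqrt(0.5)]
        assert dunnett_sf(2.0, lam, 10_000) == pytest.approx(
            2 * sps.norm.sf(2.0), abs=1e-3
        )

    def test_matches_monte_carlo_oracle(self):
        lam = [math.sqrt(n / (n + 9)) for n in (7, 5, 6, 6, 8)]
        det = dunnett_sf(2.5, lam, 35)
        mc = dunnett_sf_mc(2.5, lam, 35, n_draws=400_000, seed=3)
        assert det == pytest.approx(mc, abs=0.002)

    def test_matches_scipy_on_exact_moment_data(self):
        rng = np.random.default_rng(7)
        groups = {
            g: exact_moment_sample(m, s, n, rng)
            for g, (m, s, n) in ENDPOINT_SUMMARIES["syndecan1"].items()
        }
        treat_names = [g for g in groups if g != "C"]
        scipy_res = sps.dunnett(
            *[groups[g] for g in treat_names], control=groups["C"],
            random_state=np.random.default_rng(0),
        )
        ours = dunnett_vs_control(summaries_of("syndecan1"), "C")
        for comp, p_scipy in zip(ours, scipy_res.pvalue):
            assert comp.p_adjusted == pytest.approx(p_scipy, abs=2e-3)

    def test_syndecan1_nsns_flagged_highly_significant(self):
        # published table: NS-NS 7.70 +- 5.71 vs control 2.54 +- 0.69, '**'
        comps = {c.group: c for c in dunnett_vs_control(summaries_of("syndecan1"), "C")}
        assert comps["NS-NS"].p_adjusted <= 0.01
        assert comps["NS-NS"].flag == "**"
        for g in ("NS-ALB", "NS-HES", "HES-NS"):
            assert comps[g].p_adjusted > 0.05

    def test_matches_r_multcomp_reference(self):
        # independent oracle: aov + glht(Dunnett) on exact-moment raw data
        rng = np.random.default_rng(21)
        rows = []
        for g, (m, s, n) in ENDPOINT_SUMMARIES["lactate"].items():
            for v in exact_moment_sample(m, s, n, rng):
                rows.append(f'"{g}",{float(v):.12g}')
        script = (
            'suppressMessages(library(multcomp));'
            'd <- read.csv("stdin", header=FALSE, col.names=c("g","y"));'
            'd$g <- relevel(factor(d$g), ref="C");'
            'fit <- aov(y ~ g, data=d);'
            'p <- summary(glht(fit, linfct=mcp(g="Dunnett")))$test$pvalues;'
            'cat(sprintf("%.6f", p), sep="\\n")'
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", "-e", script],
            input="\n".join(rows), capture_output=True, text=True, check=True,
        )
        r_named = [float(x) for x in proc.stdout.split()]
        ours = {c.group: c.p_adjusted for c in dunnett_vs_control(summaries_of("lactate"), "C")}
        # glht orders levels alphabetically after releveling to C
        r_groups = sorted(g for g in ENDPOINT_SUMMARIES["lactate"] if g != "C")
        for g, p_r in zip(r_groups, r_named):
            assert ours[g] == pytest.approx(p_r, abs=2e-3)

    def test_critical_value_inverts_tail_probability(self):
        lam = [math.sqrt(0.5)] * 4
        q = dunnett_critical_value(0.05, lam, 40)
        assert dunnett_sf(q, lam, 40) == pytest.approx(0.05, abs=1e-6)

    def test_missing_control_raises(self):
        with pytest.raises(StatsError):
            dunnett_vs_control([GroupSummary("a", 3, 0.0, 1.0),
                                GroupSummary("b", 3, 1.0, 1.0)], control="C")

    def test_one_sided_smaller_than_two_sided(self):
        summ = summaries_of("syndecan1")
        two = {c.group: c.p_adjusted for c in dunnett_vs_control(summ, "C")}
        one = {c.group: c.p_adjusted for c in dunnett_vs_control(summ, "C", two_sided=False)}
        assert one["NS-NS"] < two["NS-NS"]


def test_significance_flags():
    assert significance_flag(0.005) == "**"
    assert significance_flag(0.03) == "*"
    assert significance_flag(0.2) == ""


def test_summarize_groups_round_trip():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({
        "group": ["a"] * 5 + ["b"] * 7,
        "value": rng.normal(size=12),
    })
    for s in summarize_groups(df):
        vals = df[df.group == s.group].value
        assert s.mean == pytest.approx(vals.mean())
        assert s.sd == pytest.approx(vals.std(ddof=1))


class TestSurvival:
    def test_no_events_survival_stays_at_one(self):
        df = pd.DataFrame({"group": ["A"] * 4, "time_days": [7.0] * 4, "event": [0] * 4})
        km = km_curve(df, "A")
        assert km(7.0) == pytest.approx(1.0)

    def test_two_deaths_product_limit(self):
        df = pd.DataFrame({"group": ["A", "A"], "time_days": [1.0, 2.0], "event": [1, 1]})
        km = km_curve(df, "A")
        assert km(1.0) == pytest.approx(0.5)
        assert km(2.0) == pytest.approx(0.0)

    def test_censoring_shrinks_risk_set(self):
        # death day 1, censored day 2, death day 3: S(1) = 2/3, S(3) = 0
        # (the day-3 risk set is the single remaining subject)
        df = pd.DataFrame({"group": ["A"] * 3, "time_days": [1.0, 2.0, 3.0],
                           "event": [1, 0, 1]})
        km = km_curve(df, "A")
        assert km(1.0) == pytest.approx(2 / 3)
        assert km(2.5) == pytest.approx(2 / 3)
        assert km(3.0) == pytest.approx(0.0)

    def test_km_is_nonincreasing_step_function_from_one(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "group": ["A"] * 30,
            "time_days": np.minimum(rng.exponential(4, 30), 7.0),
            "event": rng.integers(0, 2, 30),
        })
        df.loc[df.time_days >= 7.0, "event"] = 0
        km = km_curve(df, "A")
        assert km.survival[0] == pytest.approx(1.0)
        assert all(b <= a + 1e-12 for a, b in zip(km.survival, km.survival[1:]))

    def test_logrank_identical_groups_is_null(self):
        df = pd.DataFrame({
            "group": ["A", "A", "B", "B"],
            "time_days": [1.0, 2.0, 1.0, 2.0],
            "event": [1, 1, 1, 1],
        })
        chi2, df_lr, p = logrank_test(df)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df_lr == 1
        assert p == pytest.approx(1.0)

    def test_logrank_matches_hand_tally(self):
        # deaths at 1, 2 in A vs two censored at 7 in B:
        # U = (1 - 2/4) + (1 - 1/3) = 7/6, V = 1/4 + 2/9 = 17/36,
        # chi-square = U^2 / V = 49/17
        df = pd.DataFrame({
            "group": ["A", "A", "B", "B"],
            "time_days": [1.0, 2.0, 7.0, 7.0],
            "event": [1, 1, 0, 0],
        })
        chi2, _, _ = logrank_test(df)
        assert chi2 == pytest.approx(49 / 17, rel=1e-9)

    def test_no_events_anywhere_raises(self):
        df = pd.DataFrame({"group": ["A", "B"], "time_days": [7.0, 7.0], "event": [0, 0]})
        with pytest.raises(StatsError):
            logrank_test(df)

    def test_empty_group_raises(self):
        df = pd.DataFrame({"group": ["A"], "time_days": [1.0], "event": [1]})
        with pytest.raises(StatsError):
            km_curve(df, "B")
        with pytest.raises(StatsError):
            logrank_test(df)
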