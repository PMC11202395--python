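"""Normality gating, group comparisons, post-hoc adjustment and labeling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from astrocrosstalk.calibration import adjusted_monotone
from astrocrosstalk.stats import (
    compare_groups,
    dunn_test,
    normality_gate,
    rm_anova_mea,
    stars,
)


class TestStars:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.03, "*"),
            (0.004, "**"),
            (0.0005, "***"),
            (0.2, "n.s."),
            (0.05, "n.s."),   # boundary is strict
            (0.01, "*"),
            (0.001, "**"),
            (0.0, "***"),
            (1.0, "n.s."),
        ],
    )
    def test_legend_mapping(self, p, label):
        assert stars(p) == label

    @pytest.mark.parametrize("bad", [-0.1, 1.1, np.nan])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValueError):
            stars(bad)


class TestNormalityGate:
    def test_normal_groups_route_parametric_about_95pct(self):
        rng = np.random.default_rng(11)
        hits = sum(
            normality_gate({"a": rng.normal(size=20), "b": rng.normal(size=20)}).route
            == "parametric"
            for _ in range(400)
        )
        # two independent Shapiro tests at alpha 0.05 -> ~0.95^2 = 0.90
        assert 0.82 <= hits / 400 <= 0.97

    def test_exponential_group_routes_nonparametric(self):
        rng = np.random.default_rng(12)
        hits = sum(
            normality_gate(
                {"a": rng.normal(size=50), "b": rng.exponential(size=50)}
            ).route
            == "nonparametric"
            for _ in range(100)
        )
        assert hits / 100 > 0.95

    def test_tiny_groups_forced_nonparametric_with_warning(self):
        with pytest.warns(UserWarning, match="normality"):
            gate = normality_gate({"a": [1.0, 2.0], "b": [1.0, 3.0]})
        assert gate.route == "nonparametric"


class TestCompareGroups:
    def test_identical_groups_nothing_significant(self):
        data = {"a": [5.0, 5.1, 4.9, 5.0], "b": [5.0, 4.9, 5.1, 5.0], "c": [5.1, 5.0, 4.9, 5.0]}
        res = compare_groups(data, posthoc="tukey", route="parametric")
        assert res.p_value > 0.05
        assert (res.posthoc["p_adjusted"] > 0.05).all()

    def test_shifted_group_flagged_by_dunnett(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(50):
            data = {
                "ctrl": rng.normal(0, 1, 20),
                "same": rng.normal(0, 1, 20),
                "shifted": rng.normal(3, 1, 20),
            }
            res = compare_groups(data, posthoc="dunnett", control="ctrl", route="parametric")
            tab = res.posthoc.set_index("comparison")
            hits += tab.loc["shifted vs ctrl", "p_adjusted"] < 0.001
        assert hits / 50 > 0.99

    def test_two_group_nonparametric_routes_to_mannwhitney(self):
        rng = np.random.default_rng(14)
        res = compare_groups(
            {"a": rng.exponential(size=30), "b": rng.exponential(size=30)},
            route="nonparametric",
        )
        assert res.test == "Mann-Whitney U"

    def test_nonparametric_multigroup_routes_to_kruskal_dunn(self):
        rng = np.random.default_rng(15)
        data = {g: rng.exponential(size=15) for g in "abc"}
        res = compare_groups(data, route="nonparametric")
        assert res.test == "Kruskal-Wallis"
        assert len(res.posthoc) == 3  # all pairs

    def test_unknown_control_rejected(self):
        data = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 4.0], "c": [2.0, 3.0, 4.0]}
        with pytest.raises(ValueError):
            compare_groups(data, posthoc="dunnett", control="zzz", route="parametric")

    @pytest.mark.parametrize("posthoc", ["dunnett", "tukey", "holm_sidak"])
    def test_adjusted_p_never_below_unadjusted(self, posthoc):
        rng = np.random.default_rng(16)
        for _ in range(20):
            data = {g: rng.normal(size=10) for g in "abcd"}
            res = compare_groups(data, posthoc=posthoc, control="a", route="parametric")
            tab = res.posthoc
            assert (tab["p_adjusted"] >= tab["p_unadjusted"] - 1e-12).all()


class TestDunn:
    def test_adjusted_monotone(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            data = {g: rng.exponential(size=12) for g in "abcd"}
            tab = dunn_test(data)
            assert (tab["p_adjusted"] >= tab["p_unadjusted"] - 1e-12).all()

    def test_detects_large_shift(self):
        rng = np.random.default_rng(18)
        data = {"ctrl": rng.normal(0, 1, 25), "hi": rng.normal(4, 1, 25), "same": rng.normal(0, 1, 25)}
        tab = dunn_test(data, control="ctrl").set_index("comparison")
        assert tab.loc["ctrl vs hi", "p_adjusted"] < 0.001
        assert tab.loc["ctrl vs same", "p_adjusted"] > 0.05

    def test_z_statistic_matches_direct_formula_without_ties(self):
        # two groups, no ties: Dunn z equals the standardized rank-sum
        a = np.array([1.1, 2.3, 3.1, 4.7])
        b = np.array([5.2, 6.4, 7.8, 8.9])
        tab = dunn_test({"a": a, "b": b})
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        z_direct = (ranks[:4].mean() - ranks[4:].mean()) / np.sqrt(
            len(pooled) * (len(pooled) + 1) / 12 * (1 / 4 + 1 / 4)
        )
        assert tab.loc[0, "statistic"] == pytest.approx(z_direct)


class TestAdjustedMonotone:
    def test_holm_sidak_bounds(self):
        p = np.array([0.001, 0.02, 0.4, 0.9])
        adj = adjusted_monotone(p)
        assert (adj >= p).all() and (adj <= 1).all()


def _rm_frame(effect=0.0, n=10, seed=0, arms=("ctrl", "trt"), tps=("baseline", "4h", "24h")):
    rng = np.random.default_rng(seed)
    rows = []
    for arm in arms:
        for s in range(n):
            for tp in tps:
                val = 1.0 if tp == "baseline" else 1 + 0.1 * rng.normal() + (
                    effect if arm != "ctrl" and tp != "baseline" else 0
                )
                rows.append(
                    {"subject": f"{arm}{s}", "treatment": arm, "timepoint": tp, "value": val}
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_strong_effect_flagged_at_late_timepoints(self):
        res = rm_anova_mea(_rm_frame(effect=2.0), control_treatment="ctrl")
        tab = res.posthoc.set_index("timepoint")
        assert res.p_value < 0.001
        assert (tab.loc[["4h", "24h"], "p_adjusted"] < 0.05).all()
        assert (tab.loc["baseline", "p_adjusted"] == 1.0).all()

    def test_null_usually_not_significant(self):
        hits = sum(
            rm_anova_mea(_rm_frame(effect=0.0, seed=s), control_treatment="ctrl").p_value < 0.05
            for s in range(40)
        )
        assert hits <= 6  # ~5% expected

    def test_incomplete_subject_excluded_listwise(self):
        d = _rm_frame(effect=1.0)
        d = d[~((d["subject"] == "trt0") & (d["timepoint"] == "24h"))]
        res = rm_anova_mea(d, control_treatment="ctrl")
        assert res.tables["n_subjects"] == 19
        assert res.tables["n_excluded"] == 1

    def test_single_timepoint_rejected(self):
        d = _rm_frame()
        with pytest.raises(ValueError, match="timepoint"):
            rm_anova_mea(d[d["timepoint"] == "4h"], control_treatment="ctrl")

    def test_unknown_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            rm_anova_mea(_rm_frame(), control_treatment="nope")
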