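"""The group-comparison ladder used throughout the analyses.

The decision structure mirrors common practice in in-vitro neuroscience:

1. every group is checked for normality (Shapiro-Wilk at alpha 0.05);
2. if all groups pass: t-test (two groups) or one-way ANOVA followed by
   Dunnett's, Tukey's or Holm-Sidak post-hoc comparisons;
3. otherwise: Mann-Whitney U (two groups) or Kruskal-Wallis followed by
   Dunn's test;
4. MEA fold-change time-courses use a two-way repeated-measures design
   (time within electrodes, treatment between electrodes) with
   Greenhouse-Geisser correction and Dunnett-style per-timepoint contrasts
   versus the control arm;
5. p-values map to significance labels: ``***`` < 0.001, ``**`` < 0.01,
   ``*`` < 0.05, else ``n.s.``.

Dunn's test is implemented here (rank-sum z statistics with tie correction,
Bonferroni-adjusted); the remaining machinery comes from scipy, statsmodels
and pingouin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NormalityGate",
    "TestResult",
    "normality_gate",
    "compare_groups",
    "rm_anova_mea",
    "dunn_test",
    "stars",
]

ALPHA = 0.05


@dataclass(frozen=True)
class NormalityGate:
    """Outcome of the per-group Shapiro-Wilk normality check."""

    route: str  # "parametric" | "nonparametric"
    shapiro_p: Mapping[str, float]
    alpha: float = ALPHA


@dataclass(frozen=True)
class TestResult:
    """One statistical comparison: omnibus statistic plus post-hoc table."""

    test: str
    statistic: float
    df: tuple
    p_value: float
    posthoc: pd.DataFrame | None = None
    tables: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return stars(self.p_value)

    def summary(self) -> str:
        lines = [
            f"{self.test}: statistic={self.statistic:.4g}, df={self.df}, "
            f"p={self.p_value:.4g} ({self.stars})"
        ]
        if self.posthoc is not None and len(self.posthoc):
            lines.append(self.posthoc.to_string(index=False))
        return "\n".join(lines)


def stars(p: float) -> str:
    """Significance label: ``***`` p<0.001, ``**`` p<0.01, ``*`` p<0.05, else n.s."""
    if not np.isfinite(p) or not 0 <= p <= 1:
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def _as_groups(data: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    groups = {k: np.asarray(v, dtype=float) for k, v in data.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 observations")
    return groups


def normality_gate(data: Mapping[str, Sequence[float]], alpha: float = ALPHA) -> NormalityGate:
    """Route to a parametric or nonparametric comparison.

    Shapiro-Wilk per group; parametric iff every group passes at ``alpha``.
    Groups too small for the test (< 3 observations) force the
    nonparametric route with a warning.
    """
    groups = _as_groups(data)
    pvals: dict[str, float] = {}
    for name, values in groups.items():
        if values.size < 3:
            warnings.warn(
                f"group {name!r} has < 3 observations; normality untestable, "
                "routing nonparametric",
                stacklevel=2,
            )
            return NormalityGate("nonparametric", pvals, alpha)
        pvals[name] = float(sps.shapiro(values).pvalue)
    route = "parametric" if all(p > alpha for p in pvals.values()) else "nonparametric"
    return NormalityGate(route, pvals, alpha)


def dunn_test(
    data: Mapping[str, Sequence[float]],
    control: str | None = None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's rank-based post-hoc test after Kruskal-Wallis.

    z statistics on mean ranks with the tie correction
    ``sum(t^3 - t) / (12 (N - 1))``; two-sided normal p-values adjusted for
    multiplicity.  With ``control`` set, only many-to-one comparisons are
    made; otherwise all pairs.
    """
    groups = _as_groups(data)
    names = list(groups)
    if control is not None and control not in groups:
        raise ValueError(f"unknown control group {control!r}")
    pooled = np.concatenate([groups[n] for n in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes, idx = {}, {}, 0
    for n in names:
        k = groups[n].size
        mean_ranks[n] = ranks[idx : idx + k].mean()
        sizes[n] = k
        idx += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    if control is not None:
        pairs = [(control, n) for n in names if n != control]
    else:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"comparison": f"{a} vs {b}", "statistic": z, "p_unadjusted": p})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.minimum(
        multipletests(table["p_unadjusted"], method=adjust)[1], 1.0
    )
    table["p_adjusted"] = np.maximum(table["p_adjusted"], table["p_unadjusted"])
    table["stars"] = table["p_adjusted"].map(stars)
    return table


def _pooled_t_p(groups: dict[str, np.ndarray], a: str, b: str) -> float:
    """Unadjusted p for the pooled-variance contrast used by Dunnett/Tukey.

    Uses the ANOVA error variance (pooled over *all* groups, df = N - k), so
    the multiplicity-adjusted p-value of the same statistic is never smaller.
    """
    arrays = list(groups.values())
    n_total = sum(g.size for g in arrays)
    k = len(arrays)
    s2 = sum((g.size - 1) * g.var(ddof=1) for g in arrays) / (n_total - k)
    t = (groups[a].mean() - groups[b].mean()) / np.sqrt(
        s2 * (1.0 / groups[a].size + 1.0 / groups[b].size)
    )
    return float(2.0 * sps.t.sf(abs(t), n_total - k))


def _parametric_posthoc(
    groups: dict[str, np.ndarray], posthoc: str, control: str | None
) -> pd.DataFrame:
    names = list(groups)
    rows = []
    if posthoc == "dunnett":
        if control is None or control not in groups:
            raise ValueError("Dunnett's test requires a valid control group")
        others = [n for n in names if n != control]
        # fixed rng: Dunnett p-values come from randomized multivariate-t
        # integration and must be reproducible run to run
        res = sps.dunnett(*[groups[n] for n in others], control=groups[control],
                          rng=np.random.default_rng(0))
        for name, stat, p in zip(others, np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)):
            rows.append(
                {"comparison": f"{name} vs {control}", "statistic": float(stat),
                 "p_unadjusted": _pooled_t_p(groups, name, control), "p_adjusted": float(p)}
            )
    elif posthoc == "tukey":
        res = sps.tukey_hsd(*[groups[n] for n in names])
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                b = names[j]
                rows.append(
                    {"comparison": f"{a} vs {b}", "statistic": float(res.statistic[i, j]),
                     "p_unadjusted": _pooled_t_p(groups, a, b),
                     "p_adjusted": float(res.pvalue[i, j])}
                )
    elif posthoc == "holm_sidak":
        pairs = [(a, names[j]) for i, a in enumerate(names) for j in range(i + 1, len(names))]
        stats_p = [sps.ttest_ind(groups[a], groups[b]) for a, b in pairs]
        p_adj = multipletests([r.pvalue for r in stats_p], method="holm-sidak")[1]
        for (a, b), r, pa in zip(pairs, stats_p, p_adj):
            rows.append(
                {"comparison": f"{a} vs {b}", "statistic": float(r.statistic),
                 "p_unadjusted": float(r.pvalue), "p_adjusted": float(max(pa, r.pvalue))}
            )
    else:
        raise ValueError(f"unknown parametric post-hoc {posthoc!r}")
    table = pd.DataFrame(rows)
    # multiplicity adjustment can only make a comparison harder to call
    table["p_adjusted"] = np.maximum(table["p_adjusted"], table["p_unadjusted"])
    table["stars"] = table["p_adjusted"].map(stars)
    return table


def compare_groups(
    data: Mapping[str, Sequence[float]],
    posthoc: str = "dunnett",
    control: str | None = None,
    route: str | None = None,
    alpha: float = ALPHA,
) -> TestResult:
    """Omnibus comparison of >= 2 groups with multiplicity-adjusted post-hocs.

    The route (parametric vs nonparametric) is decided by
    :func:`normality_gate` unless given explicitly.  Parametric: t-test
    (2 groups) or one-way ANOVA with the requested post-hoc
    (``dunnett`` | ``tukey`` | ``holm_sidak``).  Nonparametric:
    Mann-Whitney U (2 groups) or Kruskal-Wallis followed by Dunn's test.
    """
    groups = _as_groups(data)
    if route is None:
        route = normality_gate(data, alpha).route
    arrays = list(groups.values())
    if route == "parametric":
        if len(groups) == 2:
            res = sps.ttest_ind(*arrays)
            return TestResult("t-test", float(res.statistic),
                              (arrays[0].size + arrays[1].size - 2,), float(res.pvalue))
        f, p = sps.f_oneway(*arrays)
        df = (len(groups) - 1, sum(a.size for a in arrays) - len(groups))
        table = _parametric_posthoc(groups, posthoc, control)
        return TestResult("one-way ANOVA", float(f), df, float(p), posthoc=table)
    if route == "nonparametric":
        if len(groups) == 2:
            res = sps.mannwhitneyu(*arrays, alternative="two-sided")
            return TestResult("Mann-Whitney U", float(res.statistic), (), float(res.pvalue))
        h, p = sps.kruskal(*arrays)
        table = dunn_test(data, control=control if posthoc == "dunn" else control)
        return TestResult("Kruskal-Wallis", float(h), (len(groups) - 1,), float(p),
                          posthoc=table)
    raise ValueError(f"unknown route {route!r}")


def rm_anova_mea(
    data: pd.DataFrame,
    control_treatment: str,
    dv: str = "value",
    within: str = "timepoint",
    between: str = "treatment",
    subject: str = "subject",
) -> TestResult:
    """Two-way repeated-measures analysis of MEA fold-change time-courses.

    ``data`` is tidy with one row per (electrode, timepoint).  Electrodes are
    the repeated-measures subjects: time is the within factor, treatment arm
    the between factor (each electrode sits in one arm), so the model is a
    mixed ANOVA with Greenhouse-Geisser correction applied to
    within-involved effects when sphericity is rejected.  Post-hoc:
    Dunnett's many-to-one contrasts of each arm against
    ``control_treatment`` at every timepoint.

    Electrodes with an incomplete timepoint series are excluded listwise.
    """
    import pingouin as pg

    for col in (dv, within, between, subject):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    timepoints = list(dict.fromkeys(data[within]))
    if len(timepoints) < 2:
        raise ValueError("need >= 2 timepoints; use compare_groups for one")
    if control_treatment not in set(data[between]):
        raise ValueError(f"unknown control treatment {control_treatment!r}")

    counts = data.groupby(subject)[within].nunique()
    complete = counts[counts == len(timepoints)].index
    d = data[data[subject].isin(complete)].copy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=d, dv=dv, within=within, subject=subject, between=between,
            correction=True,
        )
    aov = aov.set_index("Source")

    def _get(row: pd.Series, *names: str, default: float = np.nan) -> float:
        for n in names:
            if n in row.index and pd.notna(row[n]):
                return float(row[n])
        return default

    def _p(source: str) -> float:
        row = aov.loc[source]
        p_gg = _get(row, "p_GG_corr", "p-GG-corr")
        spher = row.get("sphericity", True)
        sphericity_ok = bool(spher) if pd.notna(spher) else True
        if not sphericity_ok and np.isfinite(p_gg):
            return p_gg
        return _get(row, "p_unc", "p-unc")

    inter = "Interaction"
    p_treatment = _p(between)
    rows = []
    for tp in timepoints:
        sub = d[d[within] == tp]
        arms = {g: sub.loc[sub[between] == g, dv].to_numpy() for g in dict.fromkeys(sub[between])}
        others = [g for g in arms if g != control_treatment]
        if not others or any(arms[g].size < 2 for g in arms):
            continue
        pooled = np.concatenate(list(arms.values()))
        if np.ptp(pooled) == 0:
            # degenerate timepoint (e.g. baseline folds identically 1)
            for g in others:
                rows.append({"timepoint": tp, "comparison": f"{g} vs {control_treatment}",
                             "statistic": 0.0, "p_adjusted": 1.0, "stars": "n.s."})
            continue
        res = sps.dunnett(*[arms[g] for g in others], control=arms[control_treatment],
                          rng=np.random.default_rng(0))
        for g, stat, p in zip(others, np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)):
            rows.append(
                {"timepoint": tp, "comparison": f"{g} vs {control_treatment}",
                 "statistic": float(stat), "p_adjusted": float(p), "stars": stars(float(p))}
            )
    posthoc = pd.DataFrame(rows)
    trt = aov.loc[between]
    return TestResult(
        "mixed RM-ANOVA",
        float(trt["F"]),
        (float(trt["DF1"]), float(trt["DF2"])),
        p_treatment,
        posthoc=posthoc,
        tables={
            "anova": aov.reset_index(),
            "p_interaction": _p(inter) if inter in aov.index else np.nan,
            "n_subjects": int(len(complete)),
            "n_excluded": int(counts.size - len(complete)),
        },
    )
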