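"""Monte Carlo calibration of the statistical routes.

Every test route offered by :mod:`astrocrosstalk.stats` can be driven under
its own null hypothesis (all groups i.i.d. normal, or a null repeated-
measures design) to measure the empirical type-I error at nominal alpha.
For post-hoc routes the measured quantity is the family-wise error rate:
the probability that any adjusted comparison is declared significant.

Omnibus tests are vectorized across replicates where scipy supports it;
the post-hoc and repeated-measures routes loop over replicates and call
the package's own implementation, so the calibration exercises exactly the
code path users run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .stats import dunn_test, rm_anova_mea, _parametric_posthoc

__all__ = ["type_one_error", "ROUTES"]

ROUTES = (
    "anova",
    "kruskal",
    "mannwhitney",
    "ttest",
    "dunnett",
    "tukey",
    "holm_sidak",
    "dunn",
    "rm_anova",
)


def _null_groups(rng: np.random.Generator, n_groups: int, n: int) -> dict[str, np.ndarray]:
    return {f"g{i}": rng.normal(size=n) for i in range(n_groups)}


def type_one_error(
    route: str,
    n_reps: int = 10_000,
    seed: int = 0,
    n_per_group: int = 10,
    n_groups: int = 3,
    alpha: float = 0.05,
    n_timepoints: int = 5,
) -> float:
    """Empirical type-I (or family-wise) error of one route under its null.

    All observations are drawn i.i.d. standard normal.  For omnibus routes
    the rate is ``P(p < alpha)``; for post-hoc routes it is the family-wise
    rate ``P(min adjusted p < alpha)``; for ``rm_anova`` it is the rate of
    a significant between-arm (treatment) effect.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, ROUTES.index(route)]))

    if route in ("anova", "kruskal"):
        x = rng.normal(size=(n_groups, n_reps, n_per_group))
        fn = sps.f_oneway if route == "anova" else sps.kruskal
        p = fn(*list(x), axis=-1).pvalue
        return float(np.mean(p < alpha))

    if route in ("mannwhitney", "ttest"):
        a = rng.normal(size=(n_reps, n_per_group))
        b = rng.normal(size=(n_reps, n_per_group))
        if route == "ttest":
            p = sps.ttest_ind(a, b, axis=-1).pvalue
        else:
            p = sps.mannwhitneyu(a, b, axis=-1, alternative="two-sided").pvalue
        return float(np.mean(p < alpha))

    if route in ("dunnett", "tukey", "holm_sidak"):
        hits = 0
        for _ in range(n_reps):
            groups = _null_groups(rng, n_groups, n_per_group)
            table = _parametric_posthoc(groups, route, control="g0")
            hits += bool((table["p_adjusted"] < alpha).any())
        return hits / n_reps

    if route == "dunn":
        hits = 0
        for _ in range(n_reps):
            groups = _null_groups(rng, n_groups, n_per_group)
            table = dunn_test(groups, control="g0")
            hits += bool((table["p_adjusted"] < alpha).any())
        return hits / n_reps

    if route == "rm_anova":
        arms = [f"arm{i}" for i in range(n_groups)]
        tps = [f"t{i}" for i in range(n_timepoints)]
        base = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n_groups * n_per_group), n_timepoints),
                "treatment": np.repeat(arms, n_per_group * n_timepoints),
                "timepoint": np.tile(tps, n_groups * n_per_group),
            }
        )
        hits = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_reps):
                d = base.copy()
                d["value"] = rng.normal(size=len(d))
                res = rm_anova_mea(d, control_treatment="arm0")
                hits += res.p_value < alpha
        return hits / n_reps

    raise ValueError(f"unknown route {route!r}; choose from {ROUTES}")


def adjusted_monotone(p_unadjusted: np.ndarray, method: str = "holm-sidak") -> np.ndarray:
    """Adjusted p-values for a set of raw p-values (never below the raw ones)."""
    adj = multipletests(np.asarray(p_unadjusted, dtype=float), method=method)[1]
    return np.maximum(adj, p_unadjusted)
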