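"""Relative qPCR quantification: dCt against a housekeeping gene and 2^(-ddCt).

Technical replicates are averaged per (sample, gene) after a simple QC rule
(a replicate more than 0.5 cycles from its triplet median is dropped), each
sample's target Ct is normalized to the housekeeping gene (dCt), referenced
to the control group's mean dCt (ddCt), and reported as fold change
2^(-ddCt).  Amplification efficiency is fixed at 2, the textbook model.

Referencing ddCt to the control group's *arithmetic mean* dCt makes the
geometric mean of control-sample folds exactly 1, matching the convention
of normalizing controls to 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "aggregate_replicates",
    "delta_ct",
    "fold_change",
    "analyze_ct_table",
    "OUTLIER_CYCLES",
]

#: replicate rejected if further than this many cycles from the triplet median
OUTLIER_CYCLES = 0.5


def aggregate_replicates(
    ct: pd.DataFrame, outlier_cycles: float = OUTLIER_CYCLES, min_replicates: int = 2
) -> pd.DataFrame:
    """Mean Ct per (sample, gene) after dropping outlier replicates.

    ``ct`` is tidy with columns ``sample_id, group, gene, replicate, ct``;
    non-finite Ct values (failed amplification) are treated as missing.
    A replicate more than ``outlier_cycles`` from the median of its
    (sample, gene) set is dropped; sets left with fewer than
    ``min_replicates`` valid values are marked missing (NaN mean).

    Returns columns ``sample_id, group, gene, ct_mean, n_used, flagged``.
    """
    required = {"sample_id", "group", "gene", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")

    def _agg(g: pd.DataFrame) -> pd.Series:
        vals = g["ct"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        kept = vals[np.abs(vals - np.median(vals)) <= outlier_cycles] if vals.size else vals
        flagged = kept.size < vals.size
        if kept.size < min_replicates:
            return pd.Series({"ct_mean": np.nan, "n_used": int(kept.size), "flagged": True})
        return pd.Series({"ct_mean": kept.mean(), "n_used": int(kept.size), "flagged": flagged})

    out = (
        ct.groupby(["sample_id", "group", "gene"], sort=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n_used"] = out["n_used"].astype(int)
    out["flagged"] = out["flagged"].astype(bool)
    return out


def delta_ct(target_ct: float, housekeeping_ct: float) -> float:
    """dCt = Ct(target) - Ct(housekeeping) for one sample."""
    return target_ct - housekeeping_ct


def fold_change(sample_delta_ct: float, control_mean_delta_ct: float) -> float:
    """2^(-ddCt) with ddCt = dCt(sample) - mean dCt(control group)."""
    return float(2.0 ** -(sample_delta_ct - control_mean_delta_ct))


def analyze_ct_table(
    ct: pd.DataFrame,
    housekeeping: str = "RPL13a",
    control_group: str = "control",
    outlier_cycles: float = OUTLIER_CYCLES,
) -> pd.DataFrame:
    """Full ddCt analysis of a tidy Ct table.

    Returns one row per (sample, target gene) with columns
    ``sample_id, group, gene, delta_ct, delta_delta_ct, fold``.  Samples
    without a valid housekeeping mean, and (sample, gene) pairs marked
    missing by replicate QC, are dropped with their flags preserved in the
    aggregation step.
    """
    agg = aggregate_replicates(ct, outlier_cycles=outlier_cycles)
    if housekeeping not in set(agg["gene"]):
        raise ValueError(f"housekeeping gene {housekeeping!r} absent from table")
    hk = (
        agg[agg["gene"] == housekeeping]
        .set_index("sample_id")["ct_mean"]
        .rename("hk_ct")
    )
    targets = agg[agg["gene"] != housekeeping].copy()
    targets["hk_ct"] = targets["sample_id"].map(hk)
    targets = targets.dropna(subset=["ct_mean", "hk_ct"])
    targets["delta_ct"] = targets["ct_mean"] - targets["hk_ct"]

    if control_group not in set(targets["group"]):
        raise ValueError(f"control group {control_group!r} has no usable samples")
    ref = (
        targets[targets["group"] == control_group]
        .groupby("gene")["delta_ct"]
        .mean()
    )
    missing_ref = set(targets["gene"]) - set(ref.index)
    if missing_ref:
        raise ValueError(f"no control-group dCt for genes {sorted(missing_ref)}")
    targets["delta_delta_ct"] = targets["delta_ct"] - targets["gene"].map(ref)
    targets["fold"] = 2.0 ** -targets["delta_delta_ct"]
    return targets[
        ["sample_id", "group", "gene", "delta_ct", "delta_delta_ct", "fold"]
    ].reset_index(drop=True)
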