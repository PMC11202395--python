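"""Max-interval burst detection and per-electrode network-activity metrics.

Bursts are detected from spike timestamps with the classical max-interval
rules: a candidate burst opens at the first spike of a pair whose ISI is at
most ``max_isi_start`` (20 ms), extends while subsequent ISIs stay at or
below ``max_isi_end`` (10 ms), and closes at the last spike before a longer
ISI.  Candidates separated by less than ``min_ibi`` (10 ms) are merged, and
candidates with fewer than ``min_spikes`` (4) spikes or shorter than
``min_duration`` (20 ms) are discarded.

Note the printed parameter pair inverts the usual max-interval ordering
(start-ISI 20 ms > end-ISI 10 ms, where typically end >= start); the numbers
are implemented as given and both are parameters.  With these defaults the
merge step is provably vacuous: any inter-candidate gap is an ISI that
exceeded ``max_isi_end`` = ``min_ibi``, so it can never be < ``min_ibi``.

Activity is summarized per electrode as spike rate (Hz) and burst rate
(bursts/min) over 5-minute windows, then expressed as fold change relative
to the electrode's own baseline window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mea import SpikeTrain

__all__ = [
    "BurstParams",
    "Burst",
    "BurstSet",
    "NetworkQualification",
    "detect_bursts",
    "spike_rate",
    "burst_rate",
    "burst_features",
    "normalize_to_baseline",
    "qualify_network",
]


@dataclass(frozen=True)
class BurstParams:
    """Max-interval burst criteria (seconds / counts)."""

    max_isi_start: float = 0.020
    max_isi_end: float = 0.010
    min_ibi: float = 0.010
    min_duration: float = 0.020
    min_spikes: int = 4

    def __post_init__(self):
        for name in ("max_isi_start", "max_isi_end", "min_ibi", "min_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be >= 2")


@dataclass(frozen=True)
class Burst:
    """One burst: first-spike time, last-spike time, spike count."""

    start: float
    end: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def intra_rate(self) -> float:
        """Spikes per second within the burst (undefined for zero duration)."""
        return self.n_spikes / self.duration if self.duration > 0 else np.nan


BurstSet = tuple[Burst, ...]


@dataclass(frozen=True)
class NetworkQualification:
    """Outcome of the >=10-active-electrodes maturity criterion."""

    active_electrodes: tuple[str, ...]
    qualified: bool
    min_active: int
    synchrony_index: float


def detect_bursts(train: SpikeTrain | np.ndarray, params: BurstParams = BurstParams()) -> BurstSet:
    """Detect bursts in a sorted spike train with the max-interval criteria.

    Returns ordered, non-overlapping bursts.  ISI comparisons are inclusive:
    an ISI exactly equal to ``max_isi_start`` opens a burst and one exactly
    equal to ``max_isi_end`` continues it.
    """
    t = train.times if isinstance(train, SpikeTrain) else np.asarray(train, dtype=float)
    n = t.size
    candidates: list[tuple[int, int]] = []  # inclusive spike-index ranges
    i = 0
    while i < n - 1:
        if t[i + 1] - t[i] <= params.max_isi_start:
            j = i + 1
            while j < n - 1 and t[j + 1] - t[j] <= params.max_isi_end:
                j += 1
            candidates.append((i, j))
            i = j + 1
        else:
            i += 1
    # Merge candidates separated by less than min_ibi (vacuous when
    # min_ibi <= max_isi_end, kept for general parameter values).
    merged: list[tuple[int, int]] = []
    for lo, hi in candidates:
        if merged and t[lo] - t[merged[-1][1]] < params.min_ibi:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    out = []
    for lo, hi in merged:
        n_spk = hi - lo + 1
        dur = t[hi] - t[lo]
        if n_spk >= params.min_spikes and dur >= params.min_duration:
            out.append(Burst(float(t[lo]), float(t[hi]), n_spk))
    return tuple(out)


def spike_rate(train: SpikeTrain | np.ndarray, window: float = 300.0) -> float:
    """Mean spike rate (Hz): spikes with ``0 <= t < window`` divided by window."""
    if window <= 0:
        raise ValueError("window must be positive")
    t = train.times if isinstance(train, SpikeTrain) else np.asarray(train, dtype=float)
    return float(np.count_nonzero((t >= 0) & (t < window))) / window


def burst_rate(bursts: Iterable[Burst], window: float = 300.0) -> float:
    """Burst rate in bursts per minute: bursts starting in the window / window."""
    if window <= 0:
        raise ValueError("window must be positive")
    n = sum(1 for b in bursts if 0 <= b.start < window)
    return n / window * 60.0


def burst_features(bursts: Iterable[Burst]) -> pd.DataFrame:
    """Per-burst duration (s), spike count and intra-burst rate (Hz).

    The frame carries one row per burst; ``frame.mean()`` gives the summary
    means.  An empty burst set yields an empty frame (means are then NaN).
    """
    rows = [
        {"duration_s": b.duration, "n_spikes": b.n_spikes, "intra_rate_hz": b.intra_rate}
        for b in bursts
    ]
    return pd.DataFrame(rows, columns=["duration_s", "n_spikes", "intra_rate_hz"])


def normalize_to_baseline(
    metrics: pd.DataFrame,
    baseline: str = "baseline",
    value_columns: Sequence[str] = ("spike_rate_hz", "burst_rate_per_min"),
) -> pd.DataFrame:
    """Express per-electrode metrics as fold change over the baseline timepoint.

    ``metrics`` is tidy with columns ``electrode``, ``timepoint`` and the
    value columns.  For each value column a ``fold_<column>`` column is
    added: metric / metric(baseline) per electrode.  Electrodes whose
    baseline value is zero get NaN folds for that metric (flagged, excluded
    from downstream aggregation) rather than infinities.
    """
    if baseline not in set(metrics["timepoint"]):
        raise ValueError(f"baseline timepoint {baseline!r} missing from metrics")
    out = metrics.copy()
    base = metrics[metrics["timepoint"] == baseline].set_index("electrode")
    for col in value_columns:
        if col not in metrics.columns:
            continue
        b = out["electrode"].map(base[col])
        if (b == 0).all():
            raise ValueError(f"baseline {col} is zero on every electrode")
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = out[col] / b
        fold[b == 0] = np.nan
        out[f"fold_{col}"] = fold
    return out


def _overlaps(b: Burst, others: Sequence[Burst]) -> bool:
    return any(b.start <= o.end and o.start <= b.end for o in others)


def qualify_network(
    trains: Mapping[str, SpikeTrain],
    params: BurstParams = BurstParams(),
    min_active: int = 10,
    synchrony_threshold: float = 0.5,
    window: float = 300.0,
) -> NetworkQualification:
    """Check the culture-maturity criterion: bursting, synchronous electrodes.

    An electrode is *active* if it shows at least one burst in the window and
    at least ``synchrony_threshold`` of its bursts temporally overlap a burst
    on some other electrode.  The network qualifies when at least
    ``min_active`` electrodes are active.  ``synchrony_index`` is the mean
    overlapping-burst fraction over bursting electrodes.
    """
    if not trains:
        raise ValueError("at least one electrode required")
    burst_map = {eid: detect_bursts(tr, params) for eid, tr in trains.items()}
    active = []
    fractions = []
    for eid, bursts in burst_map.items():
        bursts = tuple(b for b in bursts if 0 <= b.start < window)
        if not bursts:
            continue
        others = [b for oid, bs in burst_map.items() if oid != eid for b in bs]
        frac = sum(_overlaps(b, others) for b in bursts) / len(bursts)
        fractions.append(frac)
        if frac >= synchrony_threshold:
            active.append(eid)
    sync = float(np.mean(fractions)) if fractions else 0.0
    return NetworkQualification(
        active_electrodes=tuple(active),
        qualified=len(active) >= min_active,
        min_active=min_active,
        synchrony_index=sync,
    )
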