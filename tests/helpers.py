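"""Independent brute-force oracles used to cross-check the implementations.

These deliberately avoid the package's code paths: the burst oracle is a
plain state machine over ISIs with explicit interval merging, and the Otsu
oracle is an exhaustive loop over all 256 candidate splits.
"""

from __future__ import annotations

import numpy as np


def brute_force_bursts(
    times: np.ndarray,
    max_isi_start: float = 0.020,
    max_isi_end: float = 0.010,
    min_ibi: float = 0.010,
    min_duration: float = 0.020,
    min_spikes: int = 4,
) -> list[tuple[float, float, int]]:
    """Enumerate bursts by explicit rule application; returns (start, end, n)."""
    t = list(map(float, times))
    n = len(t)
    # Phase 1: candidate runs.
    runs = []
    k = 0
    while k + 1 < n:
        isi = t[k + 1] - t[k]
        if isi <= max_isi_start:
            members = [k, k + 1]
            while members[-1] + 1 < n and t[members[-1] + 1] - t[members[-1]] <= max_isi_end:
                members.append(members[-1] + 1)
            runs.append(members)
            k = members[-1] + 1
        else:
            k += 1
    # Phase 2: merge runs separated by gaps below min_ibi.
    merged = []
    for run in runs:
        if merged and t[run[0]] - t[merged[-1][-1]] < min_ibi:
            merged[-1] = merged[-1] + run
        else:
            merged.append(run)
    # Phase 3: count/duration filters.
    out = []
    for run in merged:
        start, end = t[run[0]], t[run[-1]]
        if len(run) >= min_spikes and (end - start) >= min_duration:
            out.append((start, end, len(run)))
    return out


def random_spike_train(rng: np.random.Generator, max_spikes: int = 200) -> np.ndarray:
    """Random sorted train mixing ISI scales around the burst criteria."""
    n = int(rng.integers(0, max_spikes + 1))
    if n == 0:
        return np.empty(0)
    # ISIs drawn across scales spanning 1 ms .. 1 s so every rule boundary
    # (5/10/20 ms) is exercised, including exact boundary hits.
    choices = rng.integers(0, 4, size=n)
    isis = np.where(
        choices == 0,
        rng.uniform(0.001, 0.008, size=n),
        np.where(
            choices == 1,
            rng.uniform(0.008, 0.025, size=n),
            np.where(choices == 2, rng.choice([0.010, 0.020], size=n), rng.uniform(0.025, 1.0, size=n)),
        ),
    )
    return np.cumsum(isis)


def brute_force_otsu_bin(channel: np.ndarray) -> int:
    """Exhaustive 256-bin Otsu split; returns the chosen bin index."""
    x = np.asarray(channel, dtype=float).ravel()
    lo, hi = x.min(), x.max()
    scaled = np.clip(((x - lo) * 255.0 / (hi - lo)).astype(int), 0, 255)
    hist = [int(np.sum(scaled == b)) for b in range(256)]
    centers = list(range(256))
    best_k, best_var = 0, -1.0
    total = sum(hist)
    for k in range(255):
        w0 = sum(hist[: k + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            var = 0.0
        else:
            mu0 = sum(h * c for h, c in zip(hist[: k + 1], centers[: k + 1])) / w0
            mu1 = sum(h * c for h, c in zip(hist[k + 1 :], centers[k + 1 :])) / w1
            var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    return best_k


def otsu_bin_of_threshold(channel: np.ndarray, threshold: float) -> int:
    """Map a threshold on the intensity scale back to its 256-bin index."""
    x = np.asarray(channel, dtype=float)
    lo, hi = x.min(), x.max()
    return int(round((threshold - lo) * 255.0 / (hi - lo) - 0.5))
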