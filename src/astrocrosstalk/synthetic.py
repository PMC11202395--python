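"""Ground-truth simulators for every input of the analysis pipeline.

Because the experimental raw data (MEA voltage traces, fluorescence images,
Ct tables, live/dead counts) are not deposited anywhere reusable, every
downstream stage is exercised on synthetic inputs with known ground truth:

* bursty spike trains on ~60 electrodes, with a treatment acting as a pure
  multiplicative factor on firing and burst rates across the timepoints
  {baseline, acute, 1h, 4h, 24h};
* biphasic extracellular spike waveforms embedded in white Gaussian noise;
* blob-like two-channel (+ nuclei) cell images with group-dependent marker
  intensity;
* Ct tables with technical-triplicate noise around configured fold changes;
* binomial live/dead counts.

Spike trains are a two-state renewal process: tonic firing is Poisson at
``base_rate``; burst events arrive as a second Poisson process and each
emits a fixed number of spikes at a fixed intra-burst ISI.  This is not a
biophysical neuron model — it is exactly rich enough to exercise the
max-interval burst detector and the rate/fold analysis with known truth.

All generators are deterministic given their config (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import FluorescenceImage, ViabilityCount
from .mea import Recording

__all__ = [
    "MeaSimConfig",
    "GroundTruth",
    "ImageSimConfig",
    "CtSimConfig",
    "simulate_recording",
    "simulate_ground_truth",
    "iter_simulated_channels",
    "spike_waveform",
    "simulate_images",
    "simulate_ct_table",
    "simulate_viability",
]

TIMEPOINTS = ("baseline", "acute", "1h", "4h", "24h")


@dataclass(frozen=True)
class MeaSimConfig:
    """Configuration of the MEA recording simulator.

    Rates are per electrode.  ``burst_params`` is (burst events per minute,
    spikes per burst, intra-burst ISI in seconds); defaults are plausible
    for mature (DIV 15-30) cortical cultures and are configuration, not a
    claim about any particular dataset.  ``treatment_fold`` scales tonic and
    burst-event rates multiplicatively per timepoint.
    """

    n_electrodes: int = 60
    sampling_rate: float = 25_000.0
    duration: float = 300.0
    base_rate: float = 2.0
    burst_params: tuple[float, float, float] = (10.0, 6.0, 0.005)
    treatment_fold: Mapping[str, float] = field(
        default_factory=lambda: {tp: 1.0 for tp in TIMEPOINTS}
    )
    spike_amplitude: float = 60.0
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_electrodes < 1:
            raise ValueError("need at least one electrode")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        if self.base_rate < 0 or self.burst_params[0] < 0:
            raise ValueError("rates must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if any(f < 0 for f in self.treatment_fold.values()):
            raise ValueError("treatment folds must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Known truth of one simulated recording window."""

    spike_times: dict[str, np.ndarray]
    burst_intervals: dict[str, list[tuple[float, float]]]
    true_fold: Mapping[str, float]
    timepoint: str


def spike_waveform(sampling_rate: float, amplitude: float) -> tuple[np.ndarray, int]:
    """Biphasic extracellular spike template and its trough index.

    Double-exponential lobes: a sharp negative deflection (~0.3 ms) followed
    by a slower positive rebound; total support 2 ms.  The template is
    scaled so its minimum equals ``-amplitude`` (negative-peak convention).
    """
    t = np.arange(0, 0.002, 1.0 / sampling_rate)
    neg = np.exp(-t / 1.2e-4) - np.exp(-t / 4.0e-5)
    neg /= np.abs(neg).max()
    d = 3.0e-4
    tp = np.clip(t - d, 0, None)
    pos = (np.exp(-tp / 4.0e-4) - np.exp(-tp / 1.0e-4)) * (t >= d)
    peak = np.abs(pos).max()
    if peak > 0:
        pos /= peak
    w = -neg + 0.35 * pos
    w *= amplitude / np.abs(w.min())
    return w, int(np.argmin(w))


def _channel_seed(config: MeaSimConfig, timepoint: str, electrode: int) -> np.random.Generator:
    tp_index = list(config.treatment_fold).index(timepoint)
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), tp_index, electrode])
    )


def _simulate_train(
    config: MeaSimConfig, fold: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Spike times (on the sample grid) and burst intervals for one electrode."""
    T, fs = config.duration, config.sampling_rate
    burst_per_min, spikes_per_burst, intra_isi = config.burst_params
    n_tonic = rng.poisson(config.base_rate * fold * T)
    tonic = rng.uniform(0, T, size=n_tonic)
    n_events = rng.poisson(burst_per_min / 60.0 * fold * T)
    burst_len = (int(spikes_per_burst) - 1) * intra_isi
    starts = rng.uniform(0, max(T - burst_len, 0), size=n_events)
    starts.sort()
    burst_spikes = (
        starts[:, None] + np.arange(int(spikes_per_burst)) * intra_isi
    ).ravel() if n_events else np.empty(0)
    times = np.concatenate([tonic, burst_spikes])
    samples = np.unique(np.round(times * fs).astype(np.int64))
    samples = samples[(samples >= 0) & (samples < int(round(T * fs)))]
    intervals = [(s, s + burst_len) for s in starts]
    return samples / fs, intervals


def simulate_ground_truth(
    config: MeaSimConfig, timepoint: str
) -> GroundTruth:
    """Ground-truth spike trains for one timepoint, without waveform synthesis.

    Useful when only spike-level analysis is under study (burst detection,
    rates, fold changes, statistics): identical trains to those embedded in
    the full voltage simulation, at a fraction of the cost.
    """
    if timepoint not in config.treatment_fold:
        raise ValueError(
            f"unknown timepoint {timepoint!r}; configured: {list(config.treatment_fold)}"
        )
    fold = config.treatment_fold[timepoint]
    spike_times: dict[str, np.ndarray] = {}
    intervals: dict[str, list[tuple[float, float]]] = {}
    for e in range(config.n_electrodes):
        eid = f"E{e:02d}"
        rng = _channel_seed(config, timepoint, e)
        spike_times[eid], intervals[eid] = _simulate_train(config, fold, rng)
    return GroundTruth(spike_times, intervals, dict(config.treatment_fold), timepoint)


def _synthesize_trace(
    config: MeaSimConfig, times: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = int(round(config.duration * config.sampling_rate))
    trace = (
        rng.normal(0.0, config.noise_sigma, size=n)
        if config.noise_sigma > 0
        else np.zeros(n)
    )
    w, trough = spike_waveform(config.sampling_rate, config.spike_amplitude)
    centers = np.round(times * config.sampling_rate).astype(np.int64)
    for c in centers:  # overlapping waveforms superpose additively
        lo = c - trough
        hi = lo + w.size
        wlo, whi = max(-lo, 0), w.size - max(hi - n, 0)
        trace[max(lo, 0) : min(hi, n)] += w[wlo:whi]
    return trace


def iter_simulated_channels(
    config: MeaSimConfig, timepoint: str
) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
    """Yield ``(electrode_id, trace, true_spike_times)`` one channel at a time.

    Memory-lean path for long recordings: a 60-electrode, 5-minute window at
    25 kHz never has to exist in memory at once.
    """
    truth = simulate_ground_truth(config, timepoint)
    for e in range(config.n_electrodes):
        eid = f"E{e:02d}"
        rng = _channel_seed(config, timepoint, e)
        _simulate_train(config, config.treatment_fold[timepoint], rng)  # advance to noise draws
        trace = _synthesize_trace(config, truth.spike_times[eid], rng)
        yield eid, trace, truth.spike_times[eid]


def simulate_recording(
    config: MeaSimConfig, timepoint: str
) -> tuple[Recording, GroundTruth]:
    """Simulate a full multichannel voltage recording for one timepoint.

    Each electrode's spike train is drawn from the two-state renewal process
    (all rates scaled by ``treatment_fold[timepoint]``), every spike is
    embedded as a biphasic waveform whose trough lands on the spike's sample,
    and white Gaussian noise of ``noise_sigma`` is added.
    """
    truth = simulate_ground_truth(config, timepoint)
    n = int(round(config.duration * config.sampling_rate))
    samples = np.empty((config.n_electrodes, n), dtype=np.float32)
    ids = []
    for i, (eid, trace, _) in enumerate(iter_simulated_channels(config, timepoint)):
        samples[i] = trace
        ids.append(eid)
    rec = Recording(
        samples,
        config.sampling_rate,
        tuple(ids),
        meta={"timepoint": timepoint, "true_fold": config.treatment_fold[timepoint]},
    )
    return rec, truth


# --------------------------------------------------------------------------
# fluorescence images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSimConfig:
    """Blob-image simulator configuration.

    ``mask_intensity`` is (in-cell mean, background mean) for the masking
    channel; ``target_intensity`` maps each experimental group to
    (in-cell mean, in-cell SD) for the quantified channel.  One nucleus is
    placed at each cell centre.
    """

    image_size: tuple[int, int] = (256, 256)
    n_cells: int = 25
    cell_radius: tuple[float, float] = (8.0, 14.0)
    mask_intensity: tuple[float, float] = (200.0, 10.0)
    target_intensity: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (50.0, 5.0)}
    )
    target_background: float = 10.0
    nucleus_radius: float = 3.5
    noise_sigma: float = 2.0
    max_intensity: float = 65535.0
    seed: int = 0
    placement_retries: int = 2000

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        vals = [*self.mask_intensity, self.target_background] + [
            v for pair in self.target_intensity.values() for v in pair
        ]
        if any(v < 0 or v > self.max_intensity for v in vals):
            raise ValueError("intensities must lie in [0, max_intensity]")


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def simulate_images(
    config: ImageSimConfig, group: str
) -> tuple[FluorescenceImage, np.ndarray]:
    """Simulate one field of view for ``group``; returns (image, truth_mask).

    Cells are non-overlapping discs (rejection-sampled within a retry
    budget); the truth mask is the noiseless cell-pixel set.
    """
    if group not in config.target_intensity:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), sorted(config.target_intensity).index(group)])
    )
    h, wdt = config.image_size
    cells: list[tuple[float, float, float]] = []
    tries = 0
    while len(cells) < config.n_cells:
        if tries >= config.placement_retries:
            raise RuntimeError(
                f"could not place {config.n_cells} non-overlapping cells in "
                f"{config.image_size} within {config.placement_retries} tries"
            )
        tries += 1
        r = rng.uniform(*config.cell_radius)
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, wdt - r)
        if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr) ** 2 for y, x, rr in cells):
            cells.append((cy, cx, r))

    truth_mask = np.zeros((h, wdt), dtype=bool)
    for cy, cx, r in cells:
        truth_mask |= _disc((h, wdt), (cy, cx), r)

    cell_mean, bg_mean = config.mask_intensity
    mask_ch = np.full((h, wdt), bg_mean)
    mask_ch[truth_mask] = cell_mean

    t_mean, t_sd = config.target_intensity[group]
    target_ch = np.full((h, wdt), config.target_background)
    n_in = int(truth_mask.sum())
    if n_in:
        draw = rng.normal(t_mean, t_sd, size=n_in) if t_sd > 0 else np.full(n_in, t_mean)
        target_ch[truth_mask] = draw

    nuclei_ch = np.full((h, wdt), bg_mean)
    for cy, cx, _ in cells:
        nuclei_ch[_disc((h, wdt), (cy, cx), config.nucleus_radius)] = cell_mean

    if config.noise_sigma > 0:
        mask_ch = mask_ch + rng.normal(0, config.noise_sigma, size=(h, wdt))
        target_ch = target_ch + rng.normal(0, config.noise_sigma, size=(h, wdt))
        nuclei_ch = nuclei_ch + rng.normal(0, config.noise_sigma, size=(h, wdt))
    clip = lambda a: np.clip(a, 0, config.max_intensity)
    img = FluorescenceImage(
        clip(mask_ch), clip(target_ch), clip(nuclei_ch),
        meta={"group": group, "n_cells": len(cells)},
    )
    return img, truth_mask


# --------------------------------------------------------------------------
# qPCR Ct tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CtSimConfig:
    """Ct-table simulator configuration.

    ``true_fold`` maps (gene, group) to the fold change versus the control
    group (missing entries mean fold 1).  ``control_delta_ct`` is the
    control group's target-minus-housekeeping dCt (cycles); target Ct for a
    sample is ``housekeeping_ct + control_delta_ct - log2(fold) + noise``,
    so a noise-free table reproduces the configured folds exactly under the
    2^(-ddCt) analysis.
    """

    genes: Sequence[str] = ("S100A10", "iNOS", "RPL13a")
    housekeeping: str = "RPL13a"
    samples: Sequence[tuple[str, str]] = (
        ("s1", "control"), ("s2", "control"), ("s3", "control"),
        ("s4", "treated"), ("s5", "treated"), ("s6", "treated"),
    )
    control_group: str = "control"
    true_fold: Mapping[tuple[str, str], float] = field(default_factory=dict)
    housekeeping_ct: float = 20.0
    control_delta_ct: float = 3.0
    replicate_sd: float = 0.15
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.housekeeping not in self.genes:
            raise ValueError(f"housekeeping gene {self.housekeeping!r} not in genes")
        if any(f <= 0 for f in self.true_fold.values()):
            raise ValueError("true folds must be > 0")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")


def simulate_ct_table(config: CtSimConfig) -> pd.DataFrame:
    """Simulate a technical-replicate Ct table as a tidy DataFrame.

    Columns: ``sample_id, group, gene, replicate, ct``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed)]))
    rows = []
    for sample_id, group in config.samples:
        for gene in config.genes:
            if gene == config.housekeeping:
                level = config.housekeeping_ct
            else:
                fold = config.true_fold.get((gene, group), 1.0)
                level = config.housekeeping_ct + config.control_delta_ct - np.log2(fold)
            for rep in range(1, config.n_replicates + 1):
                noise = rng.normal(0, config.replicate_sd) if config.replicate_sd > 0 else 0.0
                rows.append(
                    {"sample_id": sample_id, "group": group, "gene": gene,
                     "replicate": rep, "ct": level + noise}
                )
    return pd.DataFrame(rows)


def simulate_viability(n_cells: int, death_prob: float, seed: int = 0) -> ViabilityCount:
    """Binomial live/dead counts: PI-positive ~ Binomial(n_cells, death_prob)."""
    if not 0 <= death_prob <= 1:
        raise ValueError("death_prob must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    dead = int(rng.binomial(n_cells, death_prob))
    return ViabilityCount(total=n_cells, dead=dead)
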