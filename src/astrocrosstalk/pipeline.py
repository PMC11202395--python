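"""End-to-end experiment orchestration: simulate -> detect -> quantify -> test.

A single :class:`ExperimentConfig` drives a full in-silico MEA experiment
shaped like a conditioned-media crossover design: several treatment arms
(e.g. Ctrl, CM Co, CM Telmisartan, CM PD123319), five recording windows
(baseline, acute, 1h, 4h, 24h), per-electrode spike and burst rates,
baseline-normalized fold changes, and a repeated-measures comparison of
each arm against the control arm with significance stars.

Two execution paths share all analysis code:

* :func:`run_experiment` — the full path: voltage traces are synthesized,
  filtered, spike-detected and burst-analyzed, and all tables, a report and
  a fold-change plot are written to the output directory (every file
  carries the config hash for provenance);
* :func:`train_level_experiment` — a fast path that analyzes the
  simulator's ground-truth spike trains directly, for Monte Carlo studies
  of the rate/fold/statistics stages where waveform synthesis and detection
  are not under study.

A real-data variant skips simulation: feed spike-time CSVs through
:func:`analyze_trains` with your own labels.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as atio
from .bursts import BurstParams, burst_rate, detect_bursts, normalize_to_baseline, spike_rate
from .mea import (
    FilterSpec,
    SpikeDetectParams,
    SpikeTrain,
    detect_spikes,
    estimate_noise,
    filter_channel,
)
from .stats import TestResult, rm_anova_mea
from .synthetic import TIMEPOINTS, MeaSimConfig, iter_simulated_channels, simulate_ground_truth

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "train_level_experiment",
    "analyze_trains",
    "config_hash",
]

log = logging.getLogger("astrocrosstalk")

STAGE_VERSION = "0.1.0"


@dataclass(frozen=True)
class ExperimentConfig:
    """One simulated experiment: arms x timepoints with analysis parameters.

    ``arms`` maps each arm label to its timepoint->fold treatment effect;
    every arm must cover every timepoint and the arm set must include
    ``control_arm``.  ``mea`` is the per-arm simulator template (its
    ``treatment_fold`` and ``seed`` are overridden per arm).
    """

    arms: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "Ctrl": {tp: 1.0 for tp in TIMEPOINTS},
            "CM Co": {tp: 1.0 for tp in TIMEPOINTS},
            "CM Telmisartan": {"baseline": 1.0, "acute": 1.0, "1h": 1.5, "4h": 3.0, "24h": 3.0},
            "CM PD123319": {tp: 1.0 for tp in TIMEPOINTS},
        }
    )
    timepoints: tuple[str, ...] = TIMEPOINTS
    control_arm: str = "CM Co"
    mea: MeaSimConfig = field(default_factory=lambda: MeaSimConfig(n_electrodes=10))
    filter_spec: FilterSpec | None = None
    detect_params: SpikeDetectParams = field(default_factory=SpikeDetectParams)
    burst_params: BurstParams = field(default_factory=BurstParams)
    seed: int = 0

    def __post_init__(self):
        if "baseline" not in self.timepoints:
            raise ValueError("timepoints must include 'baseline'")
        if self.control_arm not in self.arms:
            raise ValueError(f"control arm {self.control_arm!r} missing from arms")
        for arm, folds in self.arms.items():
            missing = set(self.timepoints) - set(folds)
            if missing:
                raise ValueError(f"arm {arm!r} missing folds for {sorted(missing)}")
        if self.filter_spec is None:
            object.__setattr__(
                self, "filter_spec", FilterSpec(sampling_rate=self.mea.sampling_rate)
            )

    def arm_sim_config(self, arm: str) -> MeaSimConfig:
        """Simulator config for one arm, with a seed derived from the master seed."""
        arm_index = list(self.arms).index(arm)
        derived = int(
            np.random.SeedSequence([int(self.seed), arm_index]).generate_state(1)[0]
            % (2**31)
        )
        return MeaSimConfig(
            n_electrodes=self.mea.n_electrodes,
            sampling_rate=self.mea.sampling_rate,
            duration=self.mea.duration,
            base_rate=self.mea.base_rate,
            burst_params=self.mea.burst_params,
            treatment_fold={tp: self.arms[arm][tp] for tp in self.timepoints},
            spike_amplitude=self.mea.spike_amplitude,
            noise_sigma=self.mea.noise_sigma,
            seed=derived,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arms"] = {k: dict(v) for k, v in self.arms.items()}
        d["mea"] = asdict(self.mea)
        d["mea"]["treatment_fold"] = dict(self.mea.treatment_fold)
        d["filter_spec"] = asdict(self.filter_spec)
        d["detect_params"] = asdict(self.detect_params)
        d["burst_params"] = asdict(self.burst_params)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        if "mea" in d and not isinstance(d["mea"], MeaSimConfig):
            m = dict(d["mea"])
            if "burst_params" in m:
                m["burst_params"] = tuple(m["burst_params"])
            d["mea"] = MeaSimConfig(**m)
        if "filter_spec" in d and d["filter_spec"] is not None and not isinstance(
            d["filter_spec"], FilterSpec
        ):
            d["filter_spec"] = FilterSpec(**d["filter_spec"])
        if "detect_params" in d and not isinstance(d["detect_params"], SpikeDetectParams):
            d["detect_params"] = SpikeDetectParams(**d["detect_params"])
        if "burst_params" in d and not isinstance(d["burst_params"], BurstParams):
            d["burst_params"] = BurstParams(**d["burst_params"])
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: ExperimentConfig) -> str:
    """Short stable hash of the full configuration, for output provenance."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ExperimentReport:
    """Bundle returned by :func:`run_experiment`."""

    metrics: pd.DataFrame           # electrode x timepoint rates and folds, per arm
    spike_result: TestResult        # RM comparison of spike-rate folds
    burst_result: TestResult | None # RM comparison of burst-rate folds
    config_digest: str
    output_dir: Path | None = None

    def summary(self) -> str:
        lines = [f"experiment {self.config_digest}"]
        lines.append("spike-rate folds: " + self.spike_result.summary())
        if self.burst_result is not None:
            lines.append("burst-rate folds: " + self.burst_result.summary())
        return "\n".join(lines)


def analyze_trains(
    trains: Mapping[str, Mapping[str, SpikeTrain]],
    arm_of: Mapping[str, str],
    burst_params: BurstParams = BurstParams(),
    window: float | None = None,
) -> pd.DataFrame:
    """Per-electrode rates and baseline folds from spike trains.

    ``trains`` maps timepoint -> {subject id -> SpikeTrain} (subject ids
    unique across arms); ``arm_of`` maps subject id -> arm label.  Returns
    a tidy frame with columns ``arm, electrode, timepoint, spike_rate_hz,
    burst_rate_per_min, fold_spike_rate_hz, fold_burst_rate_per_min``.
    """
    rows = []
    for tp, per_el in trains.items():
        for sid, train in per_el.items():
            w = window if window is not None else train.duration
            bursts = detect_bursts(train, burst_params)
            rows.append(
                {
                    "arm": arm_of[sid],
                    "electrode": sid,
                    "timepoint": tp,
                    "spike_rate_hz": spike_rate(train, w),
                    "burst_rate_per_min": burst_rate(bursts, w),
                    "n_bursts": sum(1 for b in bursts if 0 <= b.start < w),
                }
            )
    metrics = pd.DataFrame(rows)
    parts = []
    for arm, sub in metrics.groupby("arm", sort=False):
        parts.append(normalize_to_baseline(sub))
    out = pd.concat(parts, ignore_index=True)
    n_zero = int(out["fold_spike_rate_hz"].isna().sum())
    if n_zero:
        log.info("excluded %d electrode-timepoints with zero baseline", n_zero)
    return out


def _rm_on_fold(metrics: pd.DataFrame, fold_col: str, control_arm: str) -> TestResult | None:
    d = metrics.rename(columns={fold_col: "value", "arm": "treatment", "electrode": "subject"})
    d = d.dropna(subset=["value"])[["value", "treatment", "timepoint", "subject"]]
    if d.empty or d["treatment"].nunique() < 2:
        return None
    return rm_anova_mea(d, control_treatment=control_arm)


def train_level_experiment(
    config: ExperimentConfig, analyze_bursts: bool = True
) -> tuple[pd.DataFrame, TestResult, TestResult | None]:
    """Run the rate/fold/statistics stages on ground-truth spike trains.

    Skips waveform synthesis and spike detection — exact for studying the
    burst, fold and statistical stages, and orders of magnitude faster.
    Returns ``(metrics, spike_rate_result, burst_rate_result)``.
    """
    trains: dict[str, dict[str, SpikeTrain]] = {tp: {} for tp in config.timepoints}
    arm_of: dict[str, str] = {}
    for arm in config.arms:
        sim = config.arm_sim_config(arm)
        for tp in config.timepoints:
            truth = simulate_ground_truth(sim, tp)
            for eid, t in truth.spike_times.items():
                sid = f"{arm}/{eid}"
                arm_of[sid] = arm
                trains[tp][sid] = SpikeTrain(sid, t, sim.duration)
    metrics = analyze_trains(trains, arm_of, config.burst_params, window=config.mea.duration)
    spike_res = _rm_on_fold(metrics, "fold_spike_rate_hz", config.control_arm)
    burst_res = _rm_on_fold(metrics, "fold_burst_rate_per_min", config.control_arm) if analyze_bursts else None
    return metrics, spike_res, burst_res


def _plot_timecourse(metrics: pd.DataFrame, fold_col: str, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tps = list(dict.fromkeys(metrics["timepoint"]))
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    for arm, sub in metrics.groupby("arm", sort=False):
        g = sub.groupby("timepoint")[fold_col]
        mean = g.mean().reindex(tps)
        sem = g.sem().reindex(tps)
        ax.errorbar(range(len(tps)), mean, yerr=sem, marker="o", capsize=3, label=arm)
    ax.set_xticks(range(len(tps)), tps)
    ax.set_ylabel("fold change vs baseline")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_experiment(
    config: ExperimentConfig, output_dir: str | Path | None = None
) -> ExperimentReport:
    """Full end-to-end run: synthesize voltages, detect spikes and bursts,
    build the fold-change time-course and test arms against control.

    With ``output_dir`` set, writes per-(arm, timepoint) spike and burst
    CSVs, the metrics table, the statistical report and fold-change plots;
    every table carries the config hash and stage version in its header.
    Channels are processed one at a time so long high-rate recordings never
    have to fit in memory.
    """
    digest = config_hash(config)
    outdir = Path(output_dir) if output_dir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": digest, "stage_version": STAGE_VERSION}

    trains: dict[str, dict[str, SpikeTrain]] = {tp: {} for tp in config.timepoints}
    arm_of: dict[str, str] = {}
    for arm in config.arms:
        sim = config.arm_sim_config(arm)
        for tp in config.timepoints:
            n_spikes_total = 0
            for eid, trace, _truth in iter_simulated_channels(sim, tp):
                filtered = filter_channel(trace, config.filter_spec)
                noise = estimate_noise(filtered, config.detect_params.noise_estimator)
                train = detect_spikes(
                    filtered, noise, config.detect_params,
                    sampling_rate=sim.sampling_rate, electrode_id=eid,
                )
                sid = f"{arm}/{eid}"
                arm_of[sid] = arm
                trains[tp][sid] = SpikeTrain(sid, train.times, train.duration)
                n_spikes_total += len(train)
            log.info("arm=%s tp=%s: %d spikes on %d electrodes",
                     arm, tp, n_spikes_total, sim.n_electrodes)
            if outdir is not None:
                tag = f"{arm.replace(' ', '_')}_{tp}"
                atio.write_spike_trains(
                    {sid: trains[tp][sid] for sid in trains[tp] if arm_of[sid] == arm},
                    outdir / f"spikes_{tag}.csv",
                )

    metrics = analyze_trains(trains, arm_of, config.burst_params, window=config.mea.duration)
    spike_res = _rm_on_fold(metrics, "fold_spike_rate_hz", config.control_arm)
    burst_res = _rm_on_fold(metrics, "fold_burst_rate_per_min", config.control_arm)

    if outdir is not None:
        burst_rows = []
        for tp, per_el in trains.items():
            for sid, train in per_el.items():
                for b in detect_bursts(train, config.burst_params):
                    burst_rows.append(
                        {"arm": arm_of[sid], "electrode": sid, "timepoint": tp,
                         "start_s": b.start, "end_s": b.end, "n_spikes": b.n_spikes}
                    )
        atio.write_table(pd.DataFrame(burst_rows), outdir / "bursts.csv", provenance)
        atio.write_table(metrics, outdir / "metrics.csv", provenance)
        report_lines = [f"# config_hash={digest} stage_version={STAGE_VERSION}"]
        if spike_res is not None:
            report_lines += ["", "Spike-rate folds vs baseline", spike_res.summary()]
            atio.write_table(spike_res.posthoc, outdir / "posthoc_spike.csv", provenance)
        if burst_res is not None:
            report_lines += ["", "Burst-rate folds vs baseline", burst_res.summary()]
            atio.write_table(burst_res.posthoc, outdir / "posthoc_burst.csv", provenance)
        (outdir / "report.txt").write_text("\n".join(report_lines) + "\n")
        _plot_timecourse(metrics, "fold_spike_rate_hz", outdir / "fold_spike_rate.png",
                         "Spike rate vs baseline")
        _plot_timecourse(metrics, "fold_burst_rate_per_min", outdir / "fold_burst_rate.png",
                         "Burst rate vs baseline")

    return ExperimentReport(metrics, spike_res, burst_res, digest, outdir)
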