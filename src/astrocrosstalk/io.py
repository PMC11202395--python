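"""File formats: raw binary recordings with JSON sidecars, spike/burst CSVs,
16-bit TIFF images, and provenance-stamped tables.

Recordings are stored as little-endian float32, time-major interleaved
(sample 0 of every channel, then sample 1, ...), next to a JSON sidecar
holding ``sampling_rate``, ``n_channels``, ``electrode_ids`` and free-form
``labels``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import FluorescenceImage
from .mea import Recording, SpikeTrain

__all__ = [
    "write_recording",
    "read_recording",
    "write_spike_trains",
    "read_spike_trains",
    "write_image",
    "read_image",
    "write_table",
    "read_table",
]


def write_recording(rec: Recording, bin_path: str | Path, sidecar_path: str | Path | None = None) -> Path:
    """Write a recording as raw interleaved float32 plus a JSON sidecar."""
    bin_path = Path(bin_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else bin_path.with_suffix(".json")
    interleaved = np.ascontiguousarray(rec.samples.T, dtype="<f4")
    interleaved.tofile(bin_path)
    sidecar = {
        "sampling_rate": rec.sampling_rate,
        "n_channels": rec.n_channels,
        "electrode_ids": list(rec.electrode_ids),
        "labels": rec.meta,
        "dtype": "<f4",
        "order": "time_major_interleaved",
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    return bin_path


def read_recording(bin_path: str | Path, sidecar_path: str | Path | None = None) -> Recording:
    """Read a raw binary recording using its JSON sidecar."""
    bin_path = Path(bin_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else bin_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    raw = np.fromfile(bin_path, dtype="<f4")
    n_ch = int(meta["n_channels"])
    if raw.size % n_ch:
        raise ValueError(f"{bin_path} length is not a multiple of {n_ch} channels")
    samples = raw.reshape(-1, n_ch).T
    return Recording(
        samples,
        float(meta["sampling_rate"]),
        tuple(meta["electrode_ids"]),
        dict(meta.get("labels", {})),
    )


def write_spike_trains(trains: dict[str, SpikeTrain], path: str | Path) -> Path:
    """Write spike trains as tidy CSV with columns ``electrode_id, time_s``."""
    rows = [
        {"electrode_id": eid, "time_s": t}
        for eid, train in trains.items()
        for t in train.times
    ]
    df = pd.DataFrame(rows, columns=["electrode_id", "time_s"])
    df.to_csv(path, index=False)
    return Path(path)


def read_spike_trains(path: str | Path, duration: float) -> dict[str, SpikeTrain]:
    """Read spike trains from a tidy ``electrode_id, time_s`` CSV."""
    df = pd.read_csv(path)
    out = {}
    for eid, sub in df.groupby("electrode_id", sort=True):
        out[str(eid)] = SpikeTrain(str(eid), np.sort(sub["time_s"].to_numpy()), duration)
    return out


def _to_uint16(channel: np.ndarray) -> np.ndarray:
    return np.clip(np.round(channel), 0, 65535).astype(np.uint16)


def write_image(image: FluorescenceImage, path: str | Path) -> Path:
    """Write the channel stack (mask, target[, nuclei]) as a 16-bit TIFF."""
    channels = [image.mask_channel, image.target_channel]
    if image.nuclei_channel is not None:
        channels.append(image.nuclei_channel)
    tifffile.imwrite(path, np.stack([_to_uint16(c) for c in channels]))
    return Path(path)


def read_image(path: str | Path) -> FluorescenceImage:
    """Read a 2- or 3-channel TIFF written by :func:`write_image`."""
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] not in (2, 3):
        raise ValueError("expected a (2-3, H, W) channel stack")
    nuclei = stack[2] if stack.shape[0] == 3 else None
    return FluorescenceImage(stack[0], stack[1], nuclei)


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> Path:
    """Write a CSV, optionally prefixed with ``# key=value`` provenance lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, skipping provenance lines."""
    return pd.read_csv(path, comment="#")
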