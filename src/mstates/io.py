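"""Readers and writers for every artifact the pipeline touches.

Plain-text formats throughout: tab-separated matrices for recordings, map
sets, segmentations and metric/statistics tables, and a ``name x y z``
sidecar for montages. EDF recordings are read through :mod:`mne`; a minimal
16-bit EDF writer is provided for interchange (no installed library exports
EDF).
"""

from __future__ import annotations

import datetime as _dt
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ChannelMismatchError,
    MicrostateMapSet,
    Montage,
    Recording,
    Segmentation,
)

METRIC_COLUMNS = [
    "subject_id", "group", "state",
    "gev_pct", "duration_ms", "coverage_pct", "occurrence_per_s",
]


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

def read_montage(path: str | Path) -> Montage:
    """Read a ``name x y z`` montage sidecar; positions renormalized to unit radius."""
    names, rows = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"montage line must be 'name x y z', got: {line!r}")
        names.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    pos = np.asarray(rows, dtype=float)
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("montage position at origin cannot be normalized")
    return Montage(channel_names=names, positions=pos / norms)


def write_montage(montage: Montage, path: str | Path) -> None:
    lines = ["# name x y z"]
    for name, (x, y, z) in zip(montage.channel_names, montage.positions):
        lines.append(f"{name} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, format: str = "matrix",
                   montage_path: str | Path | None = None,
                   montage: Montage | None = None) -> Recording:
    """Read a recording from ``matrix`` (TSV + montage sidecar) or ``edf``.

    Channel order downstream is the montage's order; data rows are reordered
    to match at load. Units are coerced to µV (EDF honors the physical
    dimension field; mV/V are scaled, other dimensions rejected).
    """
    if montage is None:
        if montage_path is None:
            raise ValueError("a montage (path or object) is required")
        montage = read_montage(montage_path)
    if format == "matrix":
        return _read_matrix(Path(path), montage)
    if format == "edf":
        return _read_edf(Path(path), montage)
    raise ValueError(f"unknown recording format: {format!r}")


def _read_matrix(path: Path, montage: Montage) -> Recording:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    names = list(df.index)
    data = df.to_numpy(dtype=float)
    rate = float(df.columns[0].split("=")[1]) if "=" in df.columns[0] else None
    if rate is None:
        raise ValueError("matrix header must carry 'sfreq=<Hz>' in its first column")
    if set(names) != set(montage.channel_names):
        extra = sorted(set(names) - set(montage.channel_names))
        missing = sorted(set(montage.channel_names) - set(names))
        raise ChannelMismatchError(
            f"matrix has {len(names)} channels, montage {montage.n_channels}; "
            f"extra={extra} missing={missing}"
        )
    order = [names.index(n) for n in montage.channel_names]
    return Recording(data=data[order], sampling_rate=rate,
                     channel_names=list(montage.channel_names), montage=montage,
                     history=[f"read_recording(matrix, {path.name})"])


def write_recording(recording: Recording, path: str | Path,
                    format: str = "matrix") -> None:
    if format == "matrix":
        cols = [f"sfreq={recording.sampling_rate:g}"] + [
            f"s{i}" for i in range(1, recording.n_samples)
        ]
        df = pd.DataFrame(recording.data, index=recording.channel_names, columns=cols)
        df.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "edf":
        write_edf(recording, path)
    else:
        raise ValueError(f"unknown recording format: {format!r}")


def _read_edf(path: Path, montage: Montage) -> Recording:
    import mne  # deferred: slow import, EDF only

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = list(raw.ch_names)
    missing = sorted(set(names) - set(montage.channel_names))
    if missing:
        raise ChannelMismatchError(f"EDF channels absent from montage: {missing}")
    absent = sorted(set(montage.channel_names) - set(names))
    if absent:
        raise ChannelMismatchError(f"montage channels absent from EDF: {absent}")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    order = [names.index(n) for n in montage.channel_names]
    return Recording(data=data_uv[order], sampling_rate=float(raw.info["sfreq"]),
                     channel_names=list(montage.channel_names), montage=montage,
                     history=[f"read_recording(edf, {path.name})"])


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a minimal EDF file (one data record spanning the recording).

    16-bit quantization; physical dimension is µV. Intended for interchange
    and round-trip testing, not for clinical annotation use.
    """
    data = recording.data
    n_ch, n_samp = data.shape
    phys_min = float(min(data.min(), -1.0))
    phys_max = float(max(data.max(), 1.0))
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min) * scale + dig_min).astype("<i2")

    record_dur = n_samp / recording.sampling_rate
    now = _dt.datetime(2000, 1, 1)

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate X X X X", 80),
        f(now.strftime("%d.%m.%y"), 8), f(now.strftime("%H.%M.%S"), 8),
        f(str(256 * (n_ch + 1)), 8), f("", 44), f("1", 8),
        f(f"{record_dur:.6f}"[:8], 8), f(str(n_ch), 4),
    ])
    header += b"".join(f(n, 16) for n in recording.channel_names)
    header += b"".join(f("EEG", 80) for _ in range(n_ch))
    header += b"".join(f("uV", 8) for _ in range(n_ch))
    header += b"".join(f(f"{phys_min:.10g}"[:8], 8) for _ in range(n_ch))
    header += b"".join(f(f"{phys_max:.10g}"[:8], 8) for _ in range(n_ch))
    header += b"".join(f(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(f(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(f("", 80) for _ in range(n_ch))
    header += b"".join(f(str(n_samp), 8) for _ in range(n_ch))
    header += b"".join(f("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(struct.pack(f"<{n_ch * n_samp}h", *digital.ravel().tolist()))


# ---------------------------------------------------------------------------
# Microstate map sets
# ---------------------------------------------------------------------------

def write_mapset(mapset: MicrostateMapSet, path: str | Path) -> None:
    df = pd.DataFrame(mapset.maps, index=mapset.labels, columns=mapset.channel_names)
    with open(path, "w") as fh:
        fh.write(f"# level={mapset.level}"
                 + (f" fit_gev={mapset.fit_gev:.12g}" if mapset.fit_gev is not None else "")
                 + "\n")
        df.to_csv(fh, sep="\t", float_format="%.17g", index_label="map")


def read_mapset(path: str | Path) -> MicrostateMapSet:
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("#"):
        raise ValueError("map set file must start with a '# level=...' header")
    meta = dict(kv.split("=") for kv in text[0][1:].split())
    df = pd.read_csv(Path(path), sep="\t", comment="#", index_col=0,
                     float_precision="round_trip")
    if df.shape[0] < 1:
        raise ValueError("empty map set")
    return MicrostateMapSet(
        maps=df.to_numpy(dtype=float), channel_names=list(df.columns),
        level=meta.get("level", "subject"), labels=[str(i) for i in df.index],
        fit_gev=float(meta["fit_gev"]) if "fit_gev" in meta else None,
    )


# ---------------------------------------------------------------------------
# Segmentations, metrics, statistics
# ---------------------------------------------------------------------------

def write_segmentation(seg: Segmentation, path: str | Path) -> None:
    df = pd.DataFrame({"frame": np.arange(seg.n_frames), "label": seg.labels})
    if seg.corr is not None:
        df["corr"] = seg.corr
    if seg.gfp is not None:
        df["gfp"] = seg.gfp
    with open(path, "w") as fh:
        fh.write(f"# sfreq={seg.sampling_rate:g}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_segmentation(path: str | Path) -> Segmentation:
    first = Path(path).read_text().split("\n", 1)[0]
    if not first.startswith("# sfreq="):
        raise ValueError("segmentation file must start with '# sfreq=<Hz>'")
    rate = float(first.split("=")[1])
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return Segmentation(
        labels=df["label"].to_numpy(int), sampling_rate=rate,
        corr=df["corr"].to_numpy(float) if "corr" in df else None,
        gfp=df["gfp"].to_numpy(float) if "gfp" in df else None,
    )


def write_metrics(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy per-(subject, state) metrics table as TSV."""
    missing = [c for c in METRIC_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metrics table lacks columns: {missing}")
    table.loc[:, METRIC_COLUMNS].to_csv(path, sep="\t", index=False,
                                        float_format="%.17g")


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
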