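"""Reading/writing multi-channel driving recordings and marker-channel parsing.

A recording is a directory with a ``manifest.json`` naming per-channel files
(two-column CSV ``time_s,value``) and either a ``periods.csv`` table
(``kind,start_s,end_s``) or a MARKER channel from which the stress periods are
derived.  The marker dialect is a piecewise-constant series of stress-level
codes: 0 = low (rest), 1 = medium (highway driving), 2 = high (city driving).
Times are 0-based seconds; periods are half-open intervals ``[start_s, end_s)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

SIGNAL_CHANNELS = ("FGSR", "HGSR", "HR")
CHANNEL_NAMES = SIGNAL_CHANNELS + ("MARKER",)

#: marker level code -> period kind
MARKER_CODES = {0: "rest", 1: "highway", 2: "city"}
#: period kind -> stress level (fixed by the driving protocol)
KIND_TO_LEVEL = {"rest": "low", "highway": "medium", "city": "high"}
KIND_TO_CODE = {v: k for k, v in MARKER_CODES.items()}

MANIFEST_NAME = "manifest.json"
PERIODS_NAME = "periods.csv"


@dataclass
class Channel:
    """A uniformly sampled signal at its native rate.

    GSR channels are in microsiemens-like units, HR in beats per minute, the
    marker channel in level codes {0, 1, 2}.
    """

    name: str
    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.name not in CHANNEL_NAMES:
            raise DataError(f"unknown channel name {self.name!r}; expected one of {CHANNEL_NAMES}")
        if self.values.ndim != 1 or self.values.size == 0:
            raise DataError(f"channel {self.name}: values must be a non-empty 1-D sequence")
        if not (self.fs > 0):
            raise DataError(f"channel {self.name}: sampling rate must be positive, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs


@dataclass(frozen=True)
class StressPeriod:
    """One protocol period: rest, highway or city driving, over [start_s, end_s)."""

    kind: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.kind not in KIND_TO_LEVEL:
            raise DataError(f"unknown period kind {self.kind!r}")
        if not self.end_s > self.start_s:
            raise DataError(f"period {self.kind}: end_s must exceed start_s "
                            f"({self.start_s} .. {self.end_s})")

    @property
    def level(self) -> str:
        return KIND_TO_LEVEL[self.kind]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Recording:
    """One subject session: named channels plus ordered stress periods.

    ``meta`` carries generator-side bookkeeping (e.g. the synthetic event log)
    and is not persisted by :func:`write_recording`.
    """

    id: str
    channels: dict[str, Channel]
    periods: list[StressPeriod]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.periods, self.periods[1:]):
            if nxt.start_s < prev.end_s - 1e-9:
                raise DataError(
                    f"recording {self.id}: periods overlap or are out of order "
                    f"({prev.kind}[{prev.start_s},{prev.end_s}) vs {nxt.kind}[{nxt.start_s},{nxt.end_s}))")

    @property
    def missing_channels(self) -> list[str]:
        """Signal channels the session lacks (cf. the excluded-recording bookkeeping)."""
        return [n for n in SIGNAL_CHANNELS if n not in self.channels]

    @property
    def duration_s(self) -> float:
        return max(ch.duration_s for ch in self.channels.values())


def parse_marker(marker: Channel, total_duration_s: float) -> list[StressPeriod]:
    """Split a piecewise-constant marker channel into stress periods.

    Contiguous runs of an identical level code become one period each; the
    resulting periods tile ``[0, total_duration_s)``.
    """
    vals = np.asarray(marker.values)
    if vals.size == 0:
        raise DataError("empty marker channel")
    codes = vals.astype(int)
    if not np.allclose(vals, codes) or not np.isin(codes, list(MARKER_CODES)).all():
        bad = sorted(set(np.unique(vals)) - set(MARKER_CODES))
        raise DataError(f"marker values outside code set {sorted(MARKER_CODES)}: {bad}")

    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(codes)]))
    periods = []
    for s, e in zip(starts, ends):
        start_s = s / marker.fs
        end_s = total_duration_s if e == len(codes) else e / marker.fs
        periods.append(StressPeriod(MARKER_CODES[codes[s]], start_s, end_s))
    return periods


def render_marker(periods: Iterable[StressPeriod], fs: float) -> Channel:
    """Inverse of :func:`parse_marker`: encode a period tiling as a marker channel."""
    periods = list(periods)
    total = periods[-1].end_s
    n = int(round(total * fs))
    t = np.arange(n) / fs
    codes = np.empty(n, dtype=float)
    for p in periods:
        codes[(t >= p.start_s - 1e-12) & (t < p.end_s - 1e-12)] = KIND_TO_CODE[p.kind]
    return Channel("MARKER", codes, fs)


def _read_channel_file(path: Path, name: str) -> Channel:
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns time_s,value")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if len(t) == 0:
        raise DataError(f"{path}: zero-length channel file")
    if len(t) >= 2:
        dt = np.diff(t)
        if (dt <= 0).any():
            raise DataError(f"{path}: non-monotone timestamps")
        # native rate inferred from the stamps (SRAD GSR drifts between 33-35 Hz)
        fs = (len(t) - 1) / (t[-1] - t[0])
    else:
        raise DataError(f"{path}: need at least 2 samples to infer the sampling rate")
    return Channel(name, v, fs)


def read_recording(path: str | Path) -> Recording:
    """Read a recording directory written by :func:`write_recording`."""
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.is_file():
        raise FormatError(f"missing {MANIFEST_NAME} in {path}")
    manifest = json.loads(manifest_path.read_text())
    rec_id = manifest.get("id", path.name)
    channels: dict[str, Channel] = {}
    for name, fname in manifest.get("channels", {}).items():
        channels[name] = _read_channel_file(path / fname, name)
    if not channels:
        raise FormatError(f"{manifest_path}: no channels listed")

    periods_path = path / PERIODS_NAME
    if periods_path.is_file():
        df = pd.read_csv(periods_path)
        periods = [StressPeriod(r.kind, float(r.start_s), float(r.end_s))
                   for r in df.itertuples()]
    elif "MARKER" in channels:
        marker = channels["MARKER"]
        total = max(ch.duration_s for ch in channels.values() if ch.name != "MARKER")
        periods = parse_marker(marker, total)
    else:
        raise FormatError(f"{path}: neither {PERIODS_NAME} nor a MARKER channel present")
    return Recording(rec_id, channels, periods)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording directory readable by :func:`read_recording`.

    Values are stored with 12 significant digits (lossless well past the 1e-9
    round-trip contract).
    """
    if not rec.periods and "MARKER" not in rec.channels:
        raise DataError(f"recording {rec.id}: no periods and no MARKER channel; refusing "
                        "to write an unannotated recording")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {"id": rec.id, "channels": {}}
    for name, ch in rec.channels.items():
        fname = f"{name.lower()}.csv"
        manifest["channels"][name] = fname
        df = pd.DataFrame({"time_s": ch.times, "value": ch.values})
        df.to_csv(path / fname, index=False, float_format="%.12g")
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    if rec.periods:
        rows = [{"kind": p.kind, "start_s": p.start_s, "end_s": p.end_s} for p in rec.periods]
        pd.DataFrame(rows).to_csv(path / PERIODS_NAME, index=False, float_format="%.12g")
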