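"""Raw channels -> labeled 16 Hz segments.

Fixed stage order: resample -> median filter -> z-normalize -> window -> label.
Windows overlapping a period boundary are discarded, as are windows inside
highway (medium-stress) periods: the classification task contrasts low-stress
rest against high-stress city driving only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal

from .errors import ConfigError, DataError, DegenerateInputError
from .records_io import Channel, Recording, StressPeriod

LABEL_RELAXED = 0
LABEL_STRESSED = 1

#: period kind -> binary label; highway periods carry no label and are dropped
KIND_TO_LABEL = {"rest": LABEL_RELAXED, "city": LABEL_STRESSED}
LABEL_NAMES = {LABEL_RELAXED: "relaxed", LABEL_STRESSED: "stressed"}


@dataclass(frozen=True)
class PreprocessConfig:
    target_fs: float = 16.0
    median_kernel: int = 5
    window_s: float = 30.0
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ConfigError(f"median_kernel must be odd and >= 1, got {self.median_kernel}")
        if not (0 <= self.overlap_fraction < 1):
            raise ConfigError("overlap_fraction must lie in [0, 1)")
        n = self.window_s * self.target_fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigError(f"window_s * target_fs must be an integer, got {n}")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.target_fs))

    @property
    def step_samples(self) -> int:
        return int(round(self.window_samples * (1 - self.overlap_fraction)))


@dataclass(frozen=True)
class Segment:
    """A fixed-length labeled window of one channel at the target rate."""

    values: np.ndarray
    channel: str
    label: int
    recording_id: str
    start_s: float

    @property
    def label_name(self) -> str:
        return LABEL_NAMES[self.label]


def resample(ch: Channel, target_fs: float = 16.0) -> Channel:
    """Resample a channel onto a uniform grid at ``target_fs``.

    Downsampling applies a zero-phase Butterworth anti-alias filter before
    linear interpolation; upsampling interpolates directly (GSR and HR vary
    slowly relative to 16 Hz).  Output length is round(duration * target_fs).
    """
    if len(ch.values) < 2:
        raise DataError(f"channel {ch.name}: need >= 2 samples to resample")
    n_out = int(round(ch.duration_s * target_fs))
    if abs(ch.fs - target_fs) < 1e-9 and n_out == len(ch.values):
        return Channel(ch.name, ch.values.copy(), target_fs)
    x = ch.values
    if ch.fs > target_fs * (1 + 1e-9):
        # anti-alias at the new Nyquist rate
        wn = (target_fs / 2) / (ch.fs / 2)
        sos = scipy.signal.butter(4, min(wn, 0.99), output="sos")
        padlen = min(len(x) - 1, 3 * 8)
        x = scipy.signal.sosfiltfilt(sos, x, padlen=padlen)
    t_out = np.arange(n_out) / target_fs
    vals = np.interp(t_out, ch.times, x)
    return Channel(ch.name, vals, target_fs)


def median_filter(ch: Channel, kernel: int = 5) -> Channel:
    """Running-median despiking with reflected edges; length and rate preserved."""
    if kernel % 2 == 0 or kernel < 1:
        raise ConfigError(f"median kernel must be odd and >= 1, got {kernel}")
    if kernel > len(ch.values):
        raise ConfigError(f"median kernel {kernel} exceeds channel length {len(ch.values)}")
    vals = scipy.ndimage.median_filter(ch.values, size=kernel, mode="reflect")
    return Channel(ch.name, vals, ch.fs)


def znorm(ch: Channel) -> Channel:
    """Standardize to zero mean and unit population standard deviation."""
    mu = ch.values.mean()
    sd = ch.values.std()  # population (n) denominator
    if sd <= 1e-12:
        raise DegenerateInputError(f"channel {ch.name}: constant signal cannot be z-normalized")
    return Channel(ch.name, (ch.values - mu) / sd, ch.fs)


def segment(ch: Channel, cfg: PreprocessConfig) -> list[tuple[float, np.ndarray]]:
    """Cut a channel into ``(start_s, values)`` windows with the configured overlap.

    Trailing partial windows are dropped; a channel shorter than one window
    yields an empty list.
    """
    if abs(ch.fs - cfg.target_fs) > 1e-6:
        raise DataError(f"channel {ch.name}: expected fs={cfg.target_fs}, got {ch.fs}; "
                        "resample first")
    win, step = cfg.window_samples, cfg.step_samples
    out = []
    start = 0
    while start + win <= len(ch.values):
        out.append((start / cfg.target_fs, ch.values[start:start + win]))
        start += step
    return out


def label_segments(
    windows: list[tuple[float, np.ndarray]],
    periods: list[StressPeriod],
    channel: str,
    recording_id: str,
    window_s: float,
) -> list[Segment]:
    """Assign relaxed/stressed labels; discard boundary-straddling and highway windows.

    A window is labeled only when it lies fully inside a single rest or city
    period; any window containing a period transition is excluded from analysis.
    """
    out = []
    for start_s, values in windows:
        end_s = start_s + window_s
        for p in periods:
            if p.start_s - 1e-9 <= start_s and end_s <= p.end_s + 1e-9:
                if p.kind in KIND_TO_LABEL:
                    out.append(Segment(values, channel, KIND_TO_LABEL[p.kind],
                                       recording_id, start_s))
                break
    return out


def preprocess_channel(ch: Channel, cfg: PreprocessConfig) -> Channel:
    """resample -> median filter -> znorm, the fixed front half of the pipeline."""
    ch = resample(ch, cfg.target_fs)
    ch = median_filter(ch, cfg.median_kernel)
    return znorm(ch)


def preprocess_recording(rec: Recording, cfg: PreprocessConfig) -> dict[str, list[Segment]]:
    """Labeled segments per signal channel for one recording."""
    out: dict[str, list[Segment]] = {}
    for name, ch in rec.channels.items():
        if name == "MARKER":
            continue
        clean = preprocess_channel(ch, cfg)
        wins = segment(clean, cfg)
        out[name] = label_segments(wins, rec.periods, name, rec.id, cfg.window_s)
    return out


def undersample(samples: list, seed: int) -> list:
    """Random majority-class undersampling to equal class counts.

    Works on any items with a ``label`` attribute; retained items are an
    order-preserving subset, deterministic given ``seed``.
    """
    labels = np.array([s.label for s in samples])
    n_pos = int((labels == LABEL_STRESSED).sum())
    n_neg = int((labels == LABEL_RELAXED).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("undersample requires both classes present")
    k = min(n_pos, n_neg)
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for lab in (LABEL_RELAXED, LABEL_STRESSED):
        idx = np.flatnonzero(labels == lab)
        keep.update(rng.choice(idx, size=k, replace=False).tolist())
    return [s for i, s in enumerate(samples) if i in keep]
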