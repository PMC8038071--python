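"""Synthetic driving-protocol recordings with stress-dependent physiology.

Emulates the structure of real-driving stress sessions: a seven-period route
(rest, city, highway, city, highway, city, rest), GSR channels sampled near
33 Hz and an HR channel near 1 Hz, plus a marker channel encoding the route.

Signal model
------------
* GSR (foot and hand): tonic level = subject baseline + slow random walk +
  state-dependent shift, with skin conductance responses (SCRs) superposed at
  state-dependent Poisson rates.  Each SCR is a difference of exponentials
  (rise 0.75 s, decay 2.0 s) with log-normal amplitude — standard electrodermal
  phenomenology.  Foot and hand channels share rates but draw independent
  event streams, emulating their observed complementarity.  Gaussian sensor
  noise and sparse large spike artifacts are added.
* HR: state-dependent baseline (rest 75, highway 82, city 92 bpm — ordering
  and rough scale of real city-vs-rest contrasts), sinusoidal respiratory
  modulation (0.25 Hz, 3 bpm), and AR(1) noise whose scale grows with stress.
* ``stress_contrast`` linearly scales every state-dependent difference away
  from the rest value: 1 reproduces the defaults, 0 removes separability
  entirely (all states statistically identical to rest).

This is a calibrated stand-in, not a physiologically validated EDA/HRV model;
it exists so that every pipeline stage is testable without external data.
All randomness derives from the single root seed.  The per-channel SCR event
log and noiseless components are attached to ``Recording.meta`` so tests can
audit the construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .records_io import KIND_TO_LEVEL, Channel, Recording, StressPeriod, render_marker

DEFAULT_ROUTE: tuple[tuple[str, float], ...] = (
    ("rest", 900.0), ("city", 300.0), ("highway", 420.0), ("city", 300.0),
    ("highway", 420.0), ("city", 300.0), ("rest", 900.0),
)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    route: tuple[tuple[str, float], ...] = DEFAULT_ROUTE
    gsr_fs: float = 33.0
    hr_fs: float = 1.0
    marker_fs: float = 1.0
    # skin conductance responses: events/s per state, log-normal amplitude (uS)
    scr_rate: dict = field(default_factory=lambda: {"rest": 0.05, "highway": 0.15, "city": 0.30})
    scr_amp_mu: float = math.log(0.7)
    scr_amp_sigma: float = 0.5
    scr_rise_s: float = 0.75
    scr_decay_s: float = 2.0
    # tonic GSR level (uS)
    gsr_tonic_mus: float = 5.0
    gsr_tonic_shift: dict = field(default_factory=lambda: {"rest": 0.0, "highway": 1.0, "city": 2.5})
    gsr_walk_sd: float = 0.02  # uS per sqrt(second)
    gsr_noise_sd: float = 0.05
    # heart rate (bpm)
    hr_mean_bpm: dict = field(default_factory=lambda: {"rest": 75.0, "highway": 82.0, "city": 92.0})
    hr_rsa_hz: float = 0.25
    hr_rsa_amp_bpm: float = 3.0
    hr_noise_sd: dict = field(default_factory=lambda: {"rest": 1.0, "highway": 2.0, "city": 3.5})
    hr_ar_phi: float = 0.9
    # artifacts
    spike_rate: float = 0.02  # impulses/s
    spike_amp_mus: float = 5.0
    stress_contrast: float = 1.0

    def __post_init__(self) -> None:
        for kind, dur in self.route:
            if kind not in KIND_TO_LEVEL:
                raise ConfigError(f"invalid route kind {kind!r}")
            if dur <= 0:
                raise ConfigError(f"route durations must be positive, got {dur}")
        for name in ("gsr_fs", "hr_fs", "marker_fs", "scr_rise_s", "scr_decay_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @property
    def total_duration_s(self) -> float:
        return sum(d for _, d in self.route)

    @property
    def periods(self) -> list[StressPeriod]:
        out, t = [], 0.0
        for kind, dur in self.route:
            out.append(StressPeriod(kind, t, t + dur))
            t += dur
        return out

    def state_value(self, table: dict, kind: str) -> float:
        """Rest value plus contrast-scaled state difference."""
        return table["rest"] + self.stress_contrast * (table[kind] - table["rest"])


def _scr_kernel(cfg: SimConfig, fs: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials SCR shape, truncated at 8 decay times."""
    t = np.arange(0.0, 8.0 * cfg.scr_decay_s, 1.0 / fs)
    h = np.exp(-t / cfg.scr_decay_s) - np.exp(-t / cfg.scr_rise_s)
    return h / h.max()


def _gen_gsr(cfg: SimConfig, rng: np.random.Generator, tonic_offset: float):
    n = int(round(cfg.total_duration_s * cfg.gsr_fs))
    t = np.arange(n) / cfg.gsr_fs
    tonic = np.full(n, cfg.gsr_tonic_mus + tonic_offset)
    tonic += np.cumsum(rng.normal(0.0, cfg.gsr_walk_sd / math.sqrt(cfg.gsr_fs), n))
    for p in cfg.periods:
        shift = cfg.state_value(cfg.gsr_tonic_shift, p.kind)
        tonic[(t >= p.start_s) & (t < p.end_s)] += shift

    kernel = _scr_kernel(cfg, cfg.gsr_fs)
    phasic = np.zeros(n)
    events: list[tuple[float, float]] = []
    for p in cfg.periods:
        rate = cfg.state_value(cfg.scr_rate, p.kind)
        count = rng.poisson(rate * p.duration_s)
        times = np.sort(rng.uniform(p.start_s, p.end_s, count))
        amps = rng.lognormal(cfg.scr_amp_mu, cfg.scr_amp_sigma, count)
        for t0, a in zip(times, amps):
            i0 = int(round(t0 * cfg.gsr_fs))
            seg = phasic[i0:i0 + len(kernel)]
            seg += a * kernel[:len(seg)]
            events.append((float(t0), float(a)))

    clean = tonic + phasic
    noisy = clean + rng.normal(0.0, cfg.gsr_noise_sd, n)
    n_spikes = rng.poisson(cfg.spike_rate * cfg.total_duration_s)
    idx = rng.integers(0, n, n_spikes)
    noisy[idx] += rng.choice([-1.0, 1.0], n_spikes) * \
        rng.uniform(0.5, 1.0, n_spikes) * cfg.spike_amp_mus
    return noisy, clean, events


def _gen_hr(cfg: SimConfig, rng: np.random.Generator, hr_offset: float):
    n = int(round(cfg.total_duration_s * cfg.hr_fs))
    t = np.arange(n) / cfg.hr_fs
    base = np.full(n, hr_offset)
    sd = np.empty(n)
    for p in cfg.periods:
        inside = (t >= p.start_s) & (t < p.end_s)
        base[inside] += cfg.state_value(cfg.hr_mean_bpm, p.kind)
        sd[inside] = cfg.state_value(cfg.hr_noise_sd, p.kind)
    clean = base + cfg.hr_rsa_amp_bpm * np.sin(2 * math.pi * cfg.hr_rsa_hz * t)
    # AR(1) with state-dependent stationary sd
    phi = cfg.hr_ar_phi
    innov = rng.normal(0.0, 1.0, n) * sd * math.sqrt(1 - phi * phi)
    ar = np.empty(n)
    prev = rng.normal(0.0, sd[0]) if n else 0.0
    for i in range(n):
        prev = phi * prev + innov[i]
        ar[i] = prev
    return clean + ar, clean


def generate_recording(cfg: SimConfig, rec_id: str, hr_offset: float = 0.0,
                       fgsr_offset: float = 0.0, hgsr_offset: float = 0.0) -> Recording:
    """One synthetic session; bit-identical for identical arguments."""
    root = np.random.SeedSequence(cfg.seed)
    rng_f, rng_h, rng_hr = (np.random.default_rng(s) for s in root.spawn(3))
    fgsr, fgsr_clean, fgsr_events = _gen_gsr(cfg, rng_f, fgsr_offset)
    hgsr, hgsr_clean, hgsr_events = _gen_gsr(cfg, rng_h, hgsr_offset)
    hr, hr_clean = _gen_hr(cfg, rng_hr, hr_offset)
    channels = {
        "FGSR": Channel("FGSR", fgsr, cfg.gsr_fs),
        "HGSR": Channel("HGSR", hgsr, cfg.gsr_fs),
        "HR": Channel("HR", hr, cfg.hr_fs),
        "MARKER": render_marker(cfg.periods, cfg.marker_fs),
    }
    meta = {"events": {"FGSR": fgsr_events, "HGSR": hgsr_events},
            "clean": {"FGSR": fgsr_clean, "HGSR": hgsr_clean, "HR": hr_clean}}
    return Recording(rec_id, channels, cfg.periods, meta=meta)


def make_dataset(n_recordings: int, cfg: SimConfig) -> list[Recording]:
    """``n_recordings`` sessions with distinct derived seeds and subject offsets.

    Per-recording baseline offsets emulate the wide between-subject spread of
    real sessions (tonic GSR level and resting HR differ by several units
    across subjects).
    """
    if n_recordings < 1:
        raise ConfigError("need at least one recording")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xD5)))
    recs = []
    for i in range(n_recordings):
        child_seed = int(rng.integers(0, 2**31 - 1))
        hr_off = float(rng.normal(0.0, 6.0))
        f_off = float(rng.normal(0.0, 1.5))
        h_off = float(rng.normal(0.0, 1.5))
        rec_cfg = replace(cfg, seed=child_seed)
        recs.append(generate_recording(rec_cfg, f"sim{i + 1:02d}", hr_off, f_off, h_off))
    return recs
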