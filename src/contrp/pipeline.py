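"""End-to-end glue: recordings -> labeled segment triples -> Cont-RP samples.

Also provides the npz archive format used by the CLI to pass samples between
stages (image stacks per modality plus labels, recording ids, start times and
an embedded JSON metadata block).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import DataError
from .model import SampleTriple
from .preprocess import PreprocessConfig, preprocess_recording
from .recurrence import EmbeddingConfig, cont_rp, rp_to_image
from .records_io import SIGNAL_CHANNELS, Recording


def build_sample_triples(recordings: list[Recording], pre_cfg: PreprocessConfig,
                         emb_cfg: EmbeddingConfig) -> list[SampleTriple]:
    """Run preprocess + Cont-RP over recordings and align the three modalities.

    A sample exists for every window start at which all three channels produced
    a labeled segment (starts are aligned exactly: all channels share the 16 Hz
    grid and the window step).
    """
    samples: list[SampleTriple] = []
    for rec in recordings:
        missing = rec.missing_channels
        if missing:
            raise DataError(f"recording {rec.id} lacks channels {missing}")
        per_channel = preprocess_recording(rec, pre_cfg)
        by_start = {
            name: {round(seg.start_s, 6): seg for seg in per_channel[name]}
            for name in SIGNAL_CHANNELS
        }
        common = sorted(set.intersection(*(set(d) for d in by_start.values())))
        for start in common:
            segs = {name: by_start[name][start] for name in SIGNAL_CHANNELS}
            labels = {s.label for s in segs.values()}
            assert len(labels) == 1  # same periods -> same label on a shared grid
            images = {name: rp_to_image(cont_rp(segs[name].values, emb_cfg),
                                        rescale=emb_cfg.rescale)
                      for name in SIGNAL_CHANNELS}
            samples.append(SampleTriple(images["FGSR"], images["HGSR"], images["HR"],
                                        labels.pop(), rec.id, start_s=start))
    return samples


def save_samples(path: str | Path, samples: list[SampleTriple], meta: dict | None = None) -> None:
    """Persist aligned RP-image samples to one npz archive."""
    if not samples:
        raise DataError("refusing to save an empty sample archive")
    payload = {
        "fgsr": np.stack([s.rp_fgsr for s in samples]),
        "hgsr": np.stack([s.rp_hgsr for s in samples]),
        "hr": np.stack([s.rp_hr for s in samples]),
        "labels": np.array([s.label for s in samples]),
        "recording_ids": np.array([s.recording_id for s in samples]),
        "start_s": np.array([s.start_s for s in samples]),
        "meta_json": np.array(json.dumps(meta or {})),
    }
    np.savez_compressed(path, **payload)


def load_samples(path: str | Path) -> tuple[list[SampleTriple], dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta_json"]))
        samples = [
            SampleTriple(z["fgsr"][i], z["hgsr"][i], z["hr"][i],
                         int(z["labels"][i]), str(z["recording_ids"][i]),
                         float(z["start_s"][i]))
            for i in range(len(z["labels"]))
        ]
    return samples, meta
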