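"""Readers and writers for the pipeline's on-disk formats.

Everything travels as plain CSV (declared headers, UTF-8) except
cone-catch image stacks, which are stored as one ``.npy`` array of shape
(H, W, n_channels + 2) — chromatic planes, then luminance, then mask —
with a YAML sidecar naming the channels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .color import ConeCatchImage
from .diversity import TimedSequence, Token

EVENT_LOG_COLUMNS = ["species", "individual", "clip", "behavior", "kind",
                     "start_s", "end_s"]


def read_event_log(path) -> pd.DataFrame:
    """Behavioral event-log CSV with required header columns
    species,individual,clip,behavior,kind,start_s,end_s (an optional
    clip_duration_s column is honored)."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event log {path} missing columns {missing}")
    return df


def write_event_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_notes(path) -> pd.DataFrame:
    """Note-table CSV; feature columns are discovered from the header."""
    df = pd.read_csv(path)
    required = ["species", "individual", "clip", "onset_s", "duration_s",
                "fm", "nonharmonic", "impulsive", "stochastic"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"note table {path} missing columns {missing}")
    return df


def write_cone_catch_stack(img: ConeCatchImage, path, channel_names=None) -> None:
    """Planar stack: chromatic planes, luminance plane, mask plane."""
    path = Path(path)
    stack = np.dstack([img.catches, img.luminance[:, :, None],
                       img.mask.astype(float)[:, :, None]])
    np.save(path, stack)
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(img.n_channels)]
    sidecar = path.with_suffix(".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {"channels": list(channel_names), "luminance_plane": img.n_channels,
             "mask_plane": img.n_channels + 1},
            fh,
        )


def read_cone_catch_stack(path) -> ConeCatchImage:
    path = Path(path)
    stack = np.load(path.with_suffix(".npy"))
    n = stack.shape[2] - 2
    return ConeCatchImage(stack[:, :, :n], stack[:, :, n], stack[:, :, n + 1] > 0.5)
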