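"""Readers and writers for the pipeline's on-disk formats.

Recordings are little-endian float32 binaries, sample-major interleaved
across channels, with a JSON sidecar naming the sampling rate, channel
count, units and duration.  Tables are plain CSV; images are 16-bit
grayscale TIFF and masks 8-bit (0/255) TIFF.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from imequant.ephys import RecordingBlock

__all__ = [
    "write_recording",
    "read_recording",
    "write_table",
    "read_table",
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
]

SIDECAR_FIELDS = ["fs_hz", "n_channels", "units", "duration_s"]


def write_recording(block: RecordingBlock, bin_path, sidecar_path) -> None:
    """Write samples as interleaved little-endian float32 plus a JSON sidecar."""
    data = np.ascontiguousarray(block.samples.T, dtype="<f4")  # sample-major
    Path(bin_path).write_bytes(data.tobytes())
    sidecar = {
        "fs_hz": block.fs,
        "n_channels": block.n_channels,
        "units": "uV",
        "duration_s": block.n_samples / block.fs,
        "filtered": block.filtered,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_recording(bin_path, sidecar_path) -> RecordingBlock:
    """Read a recording written by :func:`write_recording`."""
    meta = json.loads(Path(sidecar_path).read_text())
    for fld in SIDECAR_FIELDS:
        if fld not in meta:
            raise ValueError(f"sidecar {sidecar_path} is missing required field {fld!r}")
    raw = np.frombuffer(Path(bin_path).read_bytes(), dtype="<f4")
    n_channels = int(meta["n_channels"])
    if raw.size % n_channels:
        raise ValueError(
            f"binary length {raw.size} is not a multiple of n_channels={n_channels}"
        )
    samples = raw.reshape(-1, n_channels).T
    return RecordingBlock(
        samples=samples.copy(),
        fs=float(meta["fs_hz"]),
        filtered=bool(meta.get("filtered", True)),
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV; extra columns are kept with a warning, missing ones raise."""
    df = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        extra = [c for c in df.columns if c not in required]
        if extra:
            warnings.warn(f"{path}: extra columns {extra} preserved", stacklevel=2)
    return df


def write_image(image: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0
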