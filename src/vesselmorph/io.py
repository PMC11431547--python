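"""Readers and writers for the on-disk formats used by the pipeline.

Frame stacks travel as multi-page grayscale TIFF (one file per detection
channel), derived images as single-page float TIFF with a JSON parameter
sidecar, segmentations as JSON, edit journals as YAML, and cohorts as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "read_stack",
    "write_stack",
    "read_image",
    "write_image",
    "read_json",
    "write_json",
    "read_yaml",
    "write_yaml",
    "read_cohort",
    "write_cohort",
]


def read_stack(path, channel_label: str, pixel_scale: float, frame_rate: float = 30.0):
    """Load a multi-page TIFF as a :class:`~vesselmorph.preprocess.FrameStack`."""
    from .preprocess import FrameStack

    pixels = tifffile.imread(str(path))
    if pixels.ndim == 2:
        pixels = pixels[None]
    return FrameStack(
        pixels=np.asarray(pixels, dtype=np.float64),
        channel_label=channel_label,
        pixel_scale=float(pixel_scale),
        frame_rate=float(frame_rate),
    )


def write_stack(path, stack) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(stack.pixels, dtype=np.float32))


def read_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=np.float64)


def write_image(path, image: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(obj), fh, sort_keys=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort(path, table: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
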