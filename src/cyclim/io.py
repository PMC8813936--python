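"""TIFF / CSV / YAML input-output with explicit metadata contracts.

Exposure stacks are multi-page TIFFs carrying a JSON payload in the
ImageDescription tag with the per-page exposure times and the channel,
cycle and tile ids.  A stack without exposure metadata is a hard error —
silent default exposures would corrupt every HDR fusion downstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibrationSet, CrosstalkMatrix, NoiseModel
from .errors import MetadataError
from .synthetic import ExposureStack

__all__ = [
    "write_exposure_stack",
    "read_exposure_stack",
    "write_image",
    "read_image",
    "write_label_mask",
    "read_label_mask",
    "save_calibration",
    "load_calibration",
    "write_object_table",
    "read_object_table",
]


def write_exposure_stack(path, stack: ExposureStack) -> None:
    meta = {
        "cyclim": {
            "kind": "exposure_stack",
            "exposure_ms": list(stack.exposure_ms),
            "channel": stack.channel,
            "cycle": stack.cycle,
            "tile": stack.tile,
        }
    }
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack",
                     description=json.dumps(meta))


def read_exposure_stack(path) -> ExposureStack:
    with tifffile.TiffFile(path) as tif:
        frames = tif.asarray()
        description = tif.pages[0].description
    try:
        meta = json.loads(description)["cyclim"]
        exposures = meta["exposure_ms"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise MetadataError(
            f"{path}: missing cyclim exposure metadata in ImageDescription"
        ) from exc
    if frames.ndim == 2:
        frames = frames[None]
    return ExposureStack(frames=frames.astype(float),
                         exposure_ms=tuple(float(e) for e in exposures),
                         channel=meta.get("channel", ""),
                         cycle=int(meta.get("cycle", 0)),
                         tile=int(meta.get("tile", 0)))


def write_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_label_mask(path, labels: np.ndarray) -> None:
    """Label image as 16-bit TIFF (0 = background)."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise MetadataError("more than 65535 labels; 16-bit label TIFF overflow")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_label_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def save_calibration(path, calibration: CalibrationSet) -> None:
    """Calibration as YAML with flatfields in sibling TIFF files."""
    path = Path(path)
    doc: dict = {
        "readout_offset": (calibration.readout_offset
                           if np.isscalar(calibration.readout_offset)
                           else str(path.with_suffix(".offset.tif").name)),
        "noise": {
            "read_offset": calibration.noise.read_offset,
            "read_sigma": calibration.noise.read_sigma,
            "gain": calibration.noise.gain,
            "saturation_level": calibration.noise.saturation_level,
            "hot_rate": calibration.noise.hot_rate,
            "cold_rate": calibration.noise.cold_rate,
            "sensor_seed": calibration.noise.sensor_seed,
        },
        "flatfield": {},
    }
    if not np.isscalar(calibration.readout_offset):
        write_image(path.with_suffix(".offset.tif"), calibration.readout_offset)
    for channel, ff in calibration.flatfield.items():
        ff_name = f"{path.stem}.flatfield.{channel}.tif"
        write_image(path.parent / ff_name, ff)
        doc["flatfield"][channel] = ff_name
    if calibration.crosstalk is not None:
        doc["crosstalk"] = {
            "channels": list(calibration.crosstalk.channels),
            "matrix": calibration.crosstalk.matrix.tolist(),
            "max_condition": calibration.crosstalk.max_condition,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_calibration(path) -> CalibrationSet:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    offset = doc.get("readout_offset", 0.0)
    if isinstance(offset, str):
        offset = read_image(path.parent / offset)
    flatfield = {ch: read_image(path.parent / name)
                 for ch, name in doc.get("flatfield", {}).items()}
    crosstalk = None
    if "crosstalk" in doc:
        ct = doc["crosstalk"]
        crosstalk = CrosstalkMatrix(np.asarray(ct["matrix"], dtype=float),
                                    list(ct["channels"]),
                                    max_condition=ct.get("max_condition", 1e6))
    noise = NoiseModel(**doc.get("noise", {}))
    return CalibrationSet(flatfield=flatfield, readout_offset=offset,
                          crosstalk=crosstalk, noise=noise)


def write_object_table(path, table: pd.DataFrame) -> None:
    """Object table as UTF-8 comma-separated CSV with a mandatory header."""
    table.to_csv(path, index=False)


def read_object_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
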