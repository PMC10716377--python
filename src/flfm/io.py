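"""TIFF / YAML / JSON I/O helpers.

All volumes, PSF stacks and light-field images travel as 32-bit float
TIFF (multi-page for anything with a leading depth or view axis), with a
small YAML/JSON sidecar for physical metadata.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml


def write_tiff(path: str | Path, data: np.ndarray) -> Path:
    """Write an array as float32 TIFF; leading axes become pages."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(data, dtype=np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")
    return path


def read_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float32)


def write_yaml(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256_of_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_of_array(arr: np.ndarray) -> str:
    a = np.ascontiguousarray(arr)
    return hashlib.sha256(a.tobytes() + str(a.shape).encode()).hexdigest()
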