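"""Raster, CSV, config and manifest I/O.

Rasters round-trip through 8/16-bit PNG with an explicit ``value_range``
mapping (the integer codes are linear in the declared range); 1D signals
and all curves go through plain CSV with "." decimal points regardless of
locale.  Every CLI run writes a JSON manifest (config + seed + package
version) sufficient to reproduce it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .core import Raster

__all__ = [
    "write_raster_png",
    "read_raster_png",
    "write_signal_csv",
    "read_signal_csv",
    "write_curve_csv",
    "read_curve_csv",
    "load_config",
    "save_config",
    "write_manifest",
]


def write_raster_png(raster: Raster, path, bits: int = 16) -> None:
    """Encode a raster as grayscale PNG, linearly mapping value_range."""
    import imageio.v3 as iio

    lo, hi = raster.value_range
    if hi <= lo:
        raise ValueError("value_range must be increasing")
    scale = (2 ** bits - 1) / (hi - lo)
    codes = np.clip(np.round((raster.values - lo) * scale), 0, 2 ** bits - 1)
    arr = codes.astype(np.uint16 if bits == 16 else np.uint8)
    if arr.ndim == 1:
        arr = arr[None, :]
    iio.imwrite(str(path), arr)
    sidecar = {
        "value_range": list(raster.value_range),
        "pixels_per_degree": raster.pixels_per_degree,
        "bits": bits,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_raster_png(path) -> Raster:
    """Decode a PNG written by :func:`write_raster_png` (uses its sidecar)."""
    import imageio.v3 as iio

    meta = json.loads(Path(str(path) + ".json").read_text())
    lo, hi = meta["value_range"]
    bits = meta["bits"]
    arr = np.asarray(iio.imread(str(path)), dtype=float)
    values = lo + arr * (hi - lo) / (2 ** bits - 1)
    return Raster(values, value_range=(lo, hi),
                  pixels_per_degree=meta["pixels_per_degree"])


def write_signal_csv(raster: Raster, path) -> None:
    if raster.values.ndim != 1:
        raise ValueError("CSV signals are 1D")
    write_curve_csv({"index": np.arange(raster.values.size),
                     "value": raster.values}, path)


def read_signal_csv(path, value_range=(0.0, 1.0)) -> Raster:
    cols = read_curve_csv(path)
    return Raster(cols["value"], value_range=value_range)


def write_curve_csv(columns: Mapping[str, Sequence], path) -> None:
    """Write named numeric columns as CSV (header + rows, '.' decimals)."""
    df = pd.DataFrame({k: np.asarray(v) for k, v in columns.items()})
    df.to_csv(path, index=False, float_format="%.17g")


def read_curve_csv(path) -> Dict[str, np.ndarray]:
    """Inverse of :func:`write_curve_csv`; raises on malformed rows."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    return {str(k): df[k].to_numpy() for k in df.columns}


def save_config(config: Union[Mapping, object], path) -> None:
    data = asdict(config) if is_dataclass(config) else dict(config)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_config(path, allowed_keys: Optional[Sequence[str]] = None) -> Dict:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    if allowed_keys is not None:
        unknown = set(data) - set(allowed_keys)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return data


def write_manifest(out_dir, experiment: str, config: Mapping, seed: Optional[int]) -> Path:
    from . import __version__

    manifest = {
        "experiment": experiment,
        "config": {k: _jsonable(v) for k, v in dict(config).items()},
        "seed": seed,
        "version": __version__,
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, tuple):
        return list(v)
    return v
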