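"""File formats and provenance helpers.

Fields travel as multi-page TIFF (page 0 = 405-nm channel, page 1 = 488-nm),
label grids as integer TIFF, tabular outputs as CSV with '#'-prefixed
provenance header lines (config hash, package version, seed), audit and fit
summaries as JSON, and run configuration as YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .segmentation import ImageField


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def provenance_lines(provenance: dict) -> list[str]:
    prov = {"package_version": __version__, **provenance}
    return [f"# {k}={v}" for k, v in sorted(prov.items())]


def write_csv(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """CSV with provenance comment lines; readable back via ``read_csv``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(provenance or {}):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path, provenance: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"provenance": {"package_version": __version__, **(provenance or {})}, **obj}
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_field_tiff(path, field: ImageField) -> None:
    """Two-page float32 TIFF: 405-nm channel first, then 488-nm."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([field.channel_405, field.channel_488]).astype(np.float32)
    tifffile.imwrite(path, stack, metadata={"pixel_size_um": field.pixel_size})


def read_field_tiff(path, pixel_size: float, heart_id="", treatment="", session_id="") -> ImageField:
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"{path}: expected a 2-page field TIFF")
    return ImageField(
        channel_405=np.asarray(stack[0], dtype=float),
        channel_488=np.asarray(stack[1], dtype=float),
        pixel_size=pixel_size,
        heart_id=heart_id,
        treatment=treatment,
        session_id=session_id,
    )


def write_labels_tiff(path, cell_labels: np.ndarray, nucleus_labels: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([cell_labels, nucleus_labels]).astype(np.int32)
    tifffile.imwrite(path, stack)


def read_labels_tiff(path) -> tuple[np.ndarray, np.ndarray]:
    stack = tifffile.imread(path)
    return np.asarray(stack[0]), np.asarray(stack[1])


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
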