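"""Readers and writers with explicit axis and unit conventions.

* Stacks: plain multi-page TIFF, page order t-major then channel then z;
  voxel sizes, frame interval and channel names are stored as JSON in the
  image-description tag.  Axes are always normalized to ``(t, c, z, y, x)``.
* Label volumes: single-timepoint multi-page TIFF (z pages).
* Tables: UTF-8 CSV with '.' decimal; times in seconds, lengths in µm,
  volumes in µm³.  Non-finite values are written as empty fields and read
  back as missing.
* Configs: YAML mappings; unknown keys are rejected, out-of-range values
  raise a validation error naming the key.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .stack import LabelVolume, Stack4D
from .synthetic.config import (ConfigError, SimConfig, SolutionProtocol,
                               TransportParams, config_from_mapping)

log = logging.getLogger(__name__)

DEFAULT_VOXEL_SIZE = (10.0, 2.0, 2.0)

#: documented table schemas (column name -> brief meaning/unit)
TRACK_TABLE_COLUMNS = (
    "track_id", "frame", "time_s", "x_um", "y_um", "z_um", "volume_um3",
    "region", "vx_um_s", "vy_um_s", "vz_um_s", "speed_um_s", "accel_um_s2",
)
CELL_TABLE_COLUMNS = (
    "label", "frame", "time_s", "track_id", "volume_um3", "surface_um2",
    "x_um", "y_um", "z_um", "voxel_count", "nucleus_count",
)
TISSUE_TABLE_COLUMNS = (
    "frame", "time_s", "volume_um3", "surface_um2", "radius_um", "dv_v0",
)
_SCHEMAS = {
    "track": TRACK_TABLE_COLUMNS,
    "cell": CELL_TABLE_COLUMNS,
    "tissue": TISSUE_TABLE_COLUMNS,
}


class FormatError(ValueError):
    """A file does not match its documented layout."""


# ---------------------------------------------------------------------------
# stacks

def write_stack(stack: Stack4D, path) -> None:
    """Write a Stack4D as a plain multi-page TIFF (t, then c, then z)."""
    t, c, z, y, x = stack.data.shape
    meta = {
        "axes": "TCZYX",
        "stack_shape": [t, c, z, y, x],
        "voxel_size_um": list(stack.voxel_size),
        "frame_interval_s": stack.frame_interval,
        "channel_names": list(stack.channel_names),
        "seed": stack.seed,
    }
    pages = stack.data.reshape(t * c * z, y, x)
    tifffile.imwrite(path, pages, description=json.dumps(meta),
                     photometric="minisblack", shaped=False)


def read_stack(path, *, shape_hint: tuple[int, int] | None = None) -> Stack4D:
    """Read a multi-page TIFF into a Stack4D.

    Layout metadata is taken from the JSON image description written by
    :func:`write_stack`.  Without it, ``shape_hint`` = (n_channels, n_z)
    describes the page layout; a plain stack is then read as a single
    frame/channel if no hint is given, with documented default voxel
    sizes and a logged warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description if tif.pages else ""
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"{path.name}: expected uniform 2D pages, got shape {pages.shape}")

    meta = None
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = None
    if meta and "stack_shape" in meta:
        t, c, z, y, x = meta["stack_shape"]
        if t * c * z != pages.shape[0]:
            raise FormatError(
                f"{path.name}: {pages.shape[0]} pages inconsistent with "
                f"declared t*c*z = {t * c * z}")
        if (y, x) != pages.shape[1:]:
            raise FormatError(f"{path.name}: page shape {pages.shape[1:]} "
                              f"does not match declared ({y}, {x})")
        data = pages.reshape(t, c, z, y, x)
        return Stack4D(data=data,
                       voxel_size=tuple(meta.get("voxel_size_um", DEFAULT_VOXEL_SIZE)),
                       frame_interval=float(meta.get("frame_interval_s", 1.0)),
                       channel_names=tuple(meta.get("channel_names", ())),
                       seed=meta.get("seed"))

    if shape_hint is not None:
        c, z = shape_hint
        if pages.shape[0] % (c * z):
            raise FormatError(
                f"{path.name}: {pages.shape[0]} pages not divisible by c*z = {c * z}")
        t = pages.shape[0] // (c * z)
        data = pages.reshape(t, c, z, *pages.shape[1:])
    else:
        data = pages[None, None]
    log.warning("%s: no voxel-size metadata; assuming %s µm and 1 s frames",
                path.name, DEFAULT_VOXEL_SIZE)
    return Stack4D(data=data, voxel_size=DEFAULT_VOXEL_SIZE, frame_interval=1.0)


def write_labels(labels: LabelVolume, path) -> None:
    meta = {"axes": "ZYX", "voxel_size_um": list(labels.voxel_size)}
    tifffile.imwrite(path, labels.labels.astype(np.int32),
                     description=json.dumps(meta),
                     photometric="minisblack", shaped=False)


def read_labels(path) -> LabelVolume:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description if tif.pages else ""
    if arr.ndim == 2:
        arr = arr[None]
    voxel = DEFAULT_VOXEL_SIZE
    try:
        voxel = tuple(json.loads(desc)["voxel_size_um"])
    except (json.JSONDecodeError, KeyError, TypeError):
        log.warning("%s: no voxel-size metadata; assuming %s µm", path, voxel)
    return LabelVolume(arr, voxel)


# ---------------------------------------------------------------------------
# tables

def _schema_for(table: pd.DataFrame) -> str:
    cols = tuple(table.columns)
    for name, schema in _SCHEMAS.items():
        if set(cols) <= set(schema) and {"frame"} <= set(cols):
            # a table belongs to the schema containing all its columns
            if name == "track" and "track_id" in cols and "label" not in cols:
                return name
            if name == "cell" and "label" in cols:
                return name
            if name == "tissue" and "dv_v0" in cols:
                return name
    raise FormatError(f"columns {sorted(cols)} match no documented table schema")


def write_table(table: pd.DataFrame, path) -> None:
    """Write a documented table as CSV (header must match a schema)."""
    schema = _SCHEMAS[_schema_for(table)]
    ordered = [c for c in schema if c in table.columns]
    table[ordered].to_csv(path, index=False, encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    _schema_for(df)
    return df


# ---------------------------------------------------------------------------
# configs

_SECTION_TYPES = {
    "simulation": SimConfig,
    "protocol": SolutionProtocol,
    "transport": TransportParams,
}


def read_config(path) -> dict:
    """Read a YAML config with ``simulation:``/``protocol:``/``transport:``
    sections into validated dataclasses (missing sections get defaults).

    Unknown sections or keys raise :class:`ConfigError`; out-of-range
    values raise with the offending key and bound.  The materialized
    configuration is echoed to the log.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_SECTION_TYPES)
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}; "
                          f"known: {sorted(_SECTION_TYPES)}")
    out = {}
    for name, cls in _SECTION_TYPES.items():
        section = raw.get(name, {}) or {}
        out[name] = config_from_mapping(cls, section)
    log.info("materialized config: %s", out)
    return out


def write_config(config: dict, path) -> None:
    """Echo a config dict of dataclasses back to YAML."""
    from dataclasses import asdict

    enc = {}
    for name, obj in config.items():
        d = asdict(obj)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = [list(e) if isinstance(e, tuple) else e for e in v]
        enc[name] = d
    Path(path).write_text(yaml.safe_dump(enc, sort_keys=False))
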