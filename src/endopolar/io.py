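"""Reading and writing calibrated stacks and result tables.

Stacks are exchanged as OME-TIFF; on read, whatever axis order the file
declares is normalized to the package-wide ``(C, T, Z, Y, X)`` layout
and the physical calibration (pixel size in µm, z-step in µm, frame
interval in min) is recovered from the OME metadata.  Plain TIFFs
without calibration are accepted only when the missing metadata is
supplied as overrides.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .scene import ImageScene

__all__ = ["read_stack", "write_scene", "write_results", "read_polyline"]

_AXES = "CTZYX"


def write_scene(scene: ImageScene, path: str | Path) -> None:
    """Write a scene as OME-TIFF with its physical calibration."""
    path = Path(path)
    data = scene.data
    metadata = {
        "axes": _AXES,
        "PhysicalSizeX": scene.pixel_size,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": scene.pixel_size,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": scene.z_step,
        "PhysicalSizeZUnit": "µm",
        "TimeIncrement": scene.frame_interval,
        "TimeIncrementUnit": "min",
        "Channel": {"Name": list(scene.channel_names)},
    }
    tifffile.imwrite(path, data.astype(np.float32), ome=True,
                     metadata=metadata)


def read_stack(path: str | Path,
               pixel_size: Optional[float] = None,
               z_step: Optional[float] = None,
               frame_interval: Optional[float] = None,
               channel_names: Optional[tuple[str, ...]] = None) -> ImageScene:
    """Read a TIFF/OME-TIFF into an :class:`ImageScene`.

    Axes are normalized to (C, T, Z, Y, X); missing axes get size 1.
    Physical metadata is taken from the OME header when present;
    keyword overrides win.  A file without a recoverable pixel size and
    no override raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper().replace("S", "C").replace("Q", "Z")
        ome = {}
        if tif.ome_metadata:
            try:
                d = tifffile.xml2dict(tif.ome_metadata)
                pixels = d["OME"]["Image"]
                if isinstance(pixels, list):
                    pixels = pixels[0]
                ome = pixels["Pixels"]
            except (KeyError, TypeError):
                ome = {}

    if data.ndim != len(axes):
        raise ValueError(f"cannot interpret axes {axes!r} for shape {data.shape}")
    unknown = set(axes) - set(_AXES)
    if unknown:
        raise ValueError(f"ambiguous axes {sorted(unknown)} in {path.name}; "
                         "re-export as OME-TIFF or pass overrides")
    # move present axes into canonical order, add the missing ones
    order = [axes.index(a) for a in _AXES if a in axes]
    data = np.transpose(data, order)
    for i, a in enumerate(_AXES):
        if a not in axes:
            data = np.expand_dims(data, i)

    if pixel_size is None:
        pixel_size = ome.get("PhysicalSizeX")
    if pixel_size is None:
        raise ValueError(f"{path.name}: pixel size not present in metadata; "
                         "pass pixel_size explicitly")
    if z_step is None:
        z_step = ome.get("PhysicalSizeZ", 1.0)
    if frame_interval is None:
        frame_interval = ome.get("TimeIncrement", 1.0)
    if channel_names is None:
        ch = ome.get("Channel")
        if ch is not None:
            if isinstance(ch, dict):
                ch = [ch]
            names = [c.get("Name") for c in ch]
            if all(isinstance(n, str) for n in names) and len(names) == data.shape[0]:
                channel_names = tuple(names)
    return ImageScene(np.clip(np.asarray(data, dtype=float), 0, None),
                      pixel_size=float(pixel_size),
                      z_step=float(z_step),
                      frame_interval=float(frame_interval),
                      channel_names=channel_names or ())


def write_results(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as CSV (header row, full float precision)."""
    if records is None or len(records) == 0:
        raise ValueError("refusing to write an empty result table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False, float_format="%.17g")
    return path


def read_polyline(path: str | Path) -> np.ndarray:
    """Read a polyline vertex list from CSV with columns y,x (pixels)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "y" not in cols or "x" not in cols:
        raise ValueError("polyline CSV needs 'y' and 'x' columns")
    return df[[cols["y"], cols["x"]]].to_numpy(dtype=float)
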