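"""Reading and writing image stacks, ROIs and configuration.

Stacks are plain multi-page TIFFs accompanied by a JSON sidecar
(``<stem>.json``) that declares the dimension order, channel labels and
acquisition metadata, so a stack written here round-trips bitwise. On read,
an explicit layout spec (e.g. ``"TCYX"``, ``"CYX"``, ``"YX"``) resolves any
file whose sidecar is missing; an ambiguous file without a spec is an error.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .image import CellImage

__all__ = [
    "read_stack",
    "write_stack",
    "read_roi",
    "write_roi",
    "load_config",
    "save_config",
]

_VALID_LAYOUTS = {"TCYX", "CTYX", "TYX", "CYX", "YX"}


def _to_tcyx(arr: np.ndarray, layout: str) -> np.ndarray:
    layout = layout.upper()
    if layout not in _VALID_LAYOUTS:
        raise ValueError(f"layout must be one of {sorted(_VALID_LAYOUTS)}")
    if arr.ndim != len(layout):
        raise ValueError(
            f"layout {layout} implies {len(layout)} dims; file has {arr.ndim}"
        )
    if layout == "YX":
        return arr[None, None]
    if layout == "TYX":
        return arr[:, None]
    if layout == "CYX":
        return arr[None]
    if layout == "CTYX":
        return arr.transpose(1, 0, 2, 3)
    return arr


def read_stack(
    path: str | Path,
    layout: str | None = None,
    channels: tuple[str, ...] | None = None,
    roi: np.ndarray | None = None,
) -> CellImage:
    """Read a multi-page TIFF into a (frames, channels, H, W) CellImage.

    The JSON sidecar written by :func:`write_stack` supplies layout and
    channel labels automatically; otherwise ``layout`` must disambiguate any
    3-D or 4-D file. Integer data is widened to float64 without value change.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = path.with_suffix(".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        layout = layout or meta.get("layout")
        if channels is None and "channels" in meta:
            channels = tuple(meta["channels"])
    arr = tifffile.imread(path)
    if layout is None:
        if arr.ndim == 2:
            layout = "YX"
        else:
            raise ValueError(
                f"{path} has {arr.ndim} dims and no sidecar; pass an explicit "
                "layout spec such as 'TCYX' or 'CYX'"
            )
    data = _to_tcyx(arr, layout)
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(data.shape[1]))
    return CellImage(
        data=data,
        channels=channels,
        roi=roi,
        frame_interval=float(meta.get("frame_interval", 1.0)),
        meta=meta,
    )


def write_stack(stack: CellImage, path: str | Path) -> Path:
    """Write a CellImage as a multi-page TIFF (page order = frame-major,
    i.e. page t*C + c) plus a JSON sidecar declaring layout ``TCYX``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    sidecar = {
        "layout": "TCYX",
        "shape": list(stack.data.shape),
        "dtype": str(stack.data.dtype),
        "channels": list(stack.channels),
        "frame_interval": stack.frame_interval,
    }
    sidecar.update(
        {k: v for k, v in stack.meta.items() if isinstance(v, (int, float, str))}
    )
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_roi(path: str | Path) -> np.ndarray:
    """Read a boolean ROI mask from a grayscale TIFF (nonzero = inside)."""
    return np.asarray(tifffile.imread(Path(path))) > 0


def write_roi(roi: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(roi, bool) * np.uint8(255)))
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) pipeline/scene configuration into a dict."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def save_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path
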