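"""File readers/writers: PNG/TIFF images, 0/255 PNG masks, (x, y) contour
CSVs, JSON reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError
from .geometry import Contour

__all__ = [
    "read_image",
    "read_mask",
    "write_mask",
    "write_image",
    "read_contour_csv",
    "write_contour_csv",
    "write_json_report",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read an image file; RGB images come back (H, W, 3), grayscale (H, W)."""
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA", "P"):
            return np.asarray(im.convert("RGB"))
        return np.asarray(im.convert("L"))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG (any nonzero pixel is foreground)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image)).save(path)


def read_contour_csv(path: str | Path) -> Contour:
    """Read an ordered contour from a 2-column (x, y) CSV with header."""
    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise FormatError("contour CSV must have 'x' and 'y' columns")
    return Contour(df[["x", "y"]].to_numpy(dtype=np.int64))


def write_contour_csv(path: str | Path, contour: Contour) -> None:
    pd.DataFrame({"x": contour.x, "y": contour.y}).to_csv(path, index=False)


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_json_report(path: str | Path, report) -> None:
    Path(path).write_text(json.dumps(_jsonify(report), indent=2) + "\n")
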