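"""Standard-format I/O: 16-bit grayscale TIFFs, CSV tables, JSON provenance.

Float images in [0, 1] are written as 16-bit TIFF and read back to floats;
label and class maps are written as integer TIFFs.  Tables are CSV with a
fixed column order and a fixed float format so that reruns are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import tifffile

from .classify import Scribbles
from .specs import Micrograph

__all__ = [
    "write_image",
    "read_image",
    "write_labels",
    "read_labels",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
    "read_scribbles_csv",
    "write_scribbles_csv",
    "write_scene",
]

FLOAT_FORMAT = "%.6g"


def write_image(path, img, pixel_scale: float | None = None) -> None:
    """Write a float image in [0, 1] as 16-bit grayscale TIFF."""
    data = np.asarray(getattr(img, "data", img), dtype=np.float64)
    u16 = np.clip(np.round(data * 65535.0), 0, 65535).astype(np.uint16)
    meta = {}
    scale = pixel_scale or getattr(img, "pixel_scale", None)
    if scale:
        meta["pixel_scale_px_per_um"] = scale
    tifffile.imwrite(str(path), u16, metadata=meta)


def read_image(path, pixel_scale: float = 1.0, modality: str = "brightfield_dic") -> Micrograph:
    """Read a grayscale TIFF (single- or multi-plane) to floats in [0, 1]."""
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    return Micrograph(arr, pixel_scale, modality)


def write_labels(path, labels: np.ndarray) -> None:
    lab = np.asarray(labels)
    if lab.max(initial=0) <= np.iinfo(np.uint16).max:
        lab = lab.astype(np.uint16)
    else:
        lab = lab.astype(np.int32)
    tifffile.imwrite(str(path), lab)


def read_labels(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)))


def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(str(path), index=False, float_format=FLOAT_FORMAT, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(str(path))


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_scribbles_csv(path, scribbles: Scribbles) -> None:
    """Scribbles as CSV rows of (x, y, class) pixel coordinates."""
    rows = []
    for cls, regs in scribbles.regions.items():
        for r, c in regs:
            for rr, cc in zip(np.asarray(r), np.asarray(c)):
                rows.append({"x": int(cc), "y": int(rr), "class": cls})
    pd.DataFrame(rows, columns=["x", "y", "class"]).to_csv(str(path), index=False)


def read_scribbles_csv(path, image_shape: Tuple[int, int]) -> Scribbles:
    frame = pd.read_csv(str(path))
    regions: Dict[str, List[Tuple[np.ndarray, np.ndarray]]] = {}
    for cls, grp in frame.groupby("class"):
        regions[str(cls)] = [(grp["y"].to_numpy(int), grp["x"].to_numpy(int))]
    return Scribbles(regions=regions, image_shape=image_shape, source=str(path))


def write_scene(scene, out_dir) -> Path:
    """Write a synthetic scene (images, truth tables, config echo) to a
    run directory named by its seed."""
    from .specs import spec_to_dict

    out = Path(out_dir) / f"scene_seed{scene.scene_spec.seed}"
    out.mkdir(parents=True, exist_ok=True)
    write_image(out / "dic.tif", scene.dic_image)
    write_image(out / "fluorescence.tif", scene.fluo_image)
    write_labels(out / "label_map.tif", scene.label_map)
    write_labels(out / "class_map.tif", scene.class_map)
    write_table(out / "particle_truth.csv", scene.particle_table)
    write_table(out / "fiber_truth.csv", scene.fiber_table)
    write_json(
        out / "scene.json",
        {
            "scene_spec": spec_to_dict(scene.scene_spec),
            "filter_spec": spec_to_dict(scene.filter_spec),
            "acq_dic": spec_to_dict(scene.acq_dic),
            "acq_fluo": spec_to_dict(scene.acq_fluo),
        },
    )
    return out
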