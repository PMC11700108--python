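"""File I/O: cohort CSVs, images, masks with JSON sidecars, manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from fruitmass.segmentation import LabeledMask
from fruitmass.synthetic import COHORT_COLUMNS


def write_cohort(records: pd.DataFrame, path, config_hash: Optional[str] = None) -> None:
    """Write a cohort CSV (header length_mm,diameter_mm,weight_g).

    An optional provenance hash is embedded as a leading ``#`` comment line.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        records.to_csv(fh, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_image(image: np.ndarray, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, image)


def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    return img[..., :3]


def write_manifest(manifest: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=_json_default))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def write_mask(mask: LabeledMask, path, seed: Optional[int] = None) -> None:
    """Write a 0/255 PNG mask plus a JSON sidecar with provenance."""
    path = Path(path)
    write_image((mask.mask.astype(np.uint8) * 255), path)
    sidecar = {"steps_applied": mask.steps_applied}
    if seed is not None:
        sidecar["seed"] = seed
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_mask(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img > 127


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
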