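"""File formats and manifests for the two-stage pipeline.

Images and hard masks travel as 8-bit PNG; soft labels and superpixel maps
as 16-bit single-channel PNG (probabilities scaled to [0, 65535], lossless
to ~1.5e-5), with run parameters recorded in JSON sidecars/manifests so a
run's provenance is inspectable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import FormatError, MissingInputError
from .softlabel import SoftLabel
from .superpixel import SlicParams, SuperpixelMap

__all__ = [
    "read_image", "read_mask", "write_image", "write_mask",
    "write_soft_label", "read_soft_label",
    "write_superpixel_map", "read_superpixel_map",
    "resize_pair", "Manifest", "WORKING_SIZE",
]

#: Default working size (width, height) for the label-generation stage.
WORKING_SIZE = (500, 375)


def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[2] < 3:
        raise FormatError(f"{path}: expected an RGB image, got {img.shape}")
    return np.ascontiguousarray(img[..., :3])


def read_mask(path) -> np.ndarray:
    m = iio.imread(path)
    if m.ndim == 3:
        m = m[..., 0]
    return (m > (m.max() / 2 if m.max() > 1 else 0)).astype(np.uint8)


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def write_soft_label(path, soft: SoftLabel) -> None:
    """16-bit PNG, p scaled to [0, 65535]."""
    q = np.round(np.clip(soft.p, 0.0, 1.0) * 65535.0).astype(np.uint16)
    iio.imwrite(path, q)


def read_soft_label(path) -> np.ndarray:
    q = iio.imread(path)
    return q.astype(float) / 65535.0


def write_superpixel_map(path, spmap: SuperpixelMap) -> None:
    """16-bit PNG of region ids plus a JSON sidecar with params/counts."""
    if spmap.n_regions > 65535:
        raise FormatError("more than 65535 regions cannot be PNG-serialized")
    iio.imwrite(path, spmap.labels.astype(np.uint16))
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({
        "n_regions": spmap.n_regions,
        "grid_interval": spmap.grid_interval,
        "params": asdict(spmap.params),
    }, indent=2))


def read_superpixel_map(path) -> SuperpixelMap:
    labels = iio.imread(path).astype(np.int32)
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise MissingInputError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    return SuperpixelMap(labels=labels, n_regions=meta["n_regions"],
                         grid_interval=meta["grid_interval"],
                         params=SlicParams(**meta["params"]))


def resize_pair(image: np.ndarray, mask: np.ndarray,
                size=WORKING_SIZE) -> tuple[np.ndarray, np.ndarray]:
    """Resize to the (width, height) working size: bilinear for the image,
    nearest for the mask so it stays binary."""
    w, h = size
    img = _sk_resize(image, (h, w), order=1, preserve_range=True,
                     anti_aliasing=True).astype(np.uint8)
    m = _sk_resize(mask.astype(float), (h, w), order=0,
                   preserve_range=True, anti_aliasing=False)
    return img, (m > 0.5).astype(np.uint8)


@dataclass
class Manifest:
    """Per-run record of artifact paths and the parameters that made them."""

    params: dict = field(default_factory=dict)
    items: list = field(default_factory=list)  # dicts of per-item paths
    partial: bool = False

    def add_item(self, **paths) -> None:
        self.items.append({k: str(v) for k, v in paths.items()})

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"params": self.params, "partial": self.partial,
             "items": self.items}, indent=2))

    @classmethod
    def load(cls, path) -> "Manifest":
        p = Path(path)
        if not p.exists():
            raise MissingInputError(f"manifest not found: {p}")
        data = json.loads(p.read_text())
        m = cls(params=data.get("params", {}), items=data.get("items", []),
                partial=data.get("partial", False))
        for item in m.items:
            for v in item.values():
                if not Path(v).exists():
                    raise MissingInputError(f"manifest references missing {v}")
        return m
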