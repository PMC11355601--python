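"""Dataset reading: directories of PNG/JPEG images with a labels CSV.

The on-disk contract is the one :func:`dermadapt.synthetic.write_corpus`
produces and real corpora can be massaged into: a root directory, a CSV with
header ``path,class,domain`` (``domain`` optional), paths relative to the
root.  Images are decoded with Pillow, resized bilinearly to the configured
square size and scaled to [0, 1], channels-first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["DatasetManifest", "ImageDataset", "load_dataset"]


@dataclass(frozen=True)
class DatasetManifest:
    """Where a dataset lives and how to decode it."""

    root: Path
    labels_csv: str = "labels.csv"
    image_size: int = 64
    split: str = "all"

    def __post_init__(self):
        if self.split not in ("train", "test", "all"):
            raise ValueError(f"unknown split '{self.split}'")


@dataclass
class ImageDataset:
    """Decoded images (n, 3, s, s) in [0, 1] plus label arrays."""

    images: np.ndarray
    class_labels: np.ndarray
    domain_labels: np.ndarray | None
    paths: list[str]

    def __len__(self):
        return self.images.shape[0]


def load_dataset(manifest: DatasetManifest) -> ImageDataset:
    """Read every image referenced by the manifest's CSV.

    Raises on missing files, undecodable images and labels outside {0, 1};
    iteration order is the CSV row order (deterministic).
    """
    root = Path(manifest.root)
    csv_path = root / manifest.labels_csv
    if not csv_path.exists():
        raise FileNotFoundError(f"labels CSV not found: {csv_path}")
    table = pd.read_csv(csv_path)
    if "path" not in table.columns or "class" not in table.columns:
        raise ValueError("labels CSV must have 'path' and 'class' columns")
    if not table["class"].isin((0, 1)).all():
        bad = table.loc[~table["class"].isin((0, 1)), "class"].iloc[0]
        raise ValueError(f"class label outside {{0, 1}}: {bad!r}")
    if "domain" in table.columns and not table["domain"].isin((0, 1)).all():
        raise ValueError("domain labels must be 0 (source) or 1 (target)")

    s = manifest.image_size
    images = np.empty((len(table), 3, s, s), dtype=np.float32)
    for i, rel in enumerate(table["path"]):
        path = root / rel
        if not path.exists():
            raise FileNotFoundError(f"image listed in CSV is missing: {path}")
        with Image.open(path) as im:
            im = im.convert("RGB")
            if im.size != (s, s):
                im = im.resize((s, s), Image.BILINEAR)
            images[i] = np.asarray(im, dtype=np.float32).transpose(2, 0, 1)
    images /= 255.0
    domains = (table["domain"].to_numpy(np.int64)
               if "domain" in table.columns else None)
    return ImageDataset(images=images,
                        class_labels=table["class"].to_numpy(np.int64),
                        domain_labels=domains,
                        paths=list(table["path"]))
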