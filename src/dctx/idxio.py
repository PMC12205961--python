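"""IDX dataset serialization (the MNIST container convention) plus a
JSON sidecar carrying ambiguity annotations and generation parameters,
and a JSON triplet index."""

from __future__ import annotations

import json
import struct
from pathlib import Path
from typing import Sequence

import numpy as np

from .ambiguous import AmbiguousTriplet
from .glyphs import IMG_SIZE, LabeledImage

IDX_IMAGES_MAGIC = 0x00000803
IDX_LABELS_MAGIC = 0x00000801

__all__ = [
    "write_idx_images", "read_idx_images",
    "write_idx_labels", "read_idx_labels",
    "save_dataset", "load_idx_dataset",
    "save_triplet_index", "load_triplet_index",
]


class IdxFormatError(ValueError):
    """Malformed IDX container (bad magic, truncation, count mismatch)."""


def write_idx_images(path, images: np.ndarray) -> None:
    """Write (N, 28, 28) images; float inputs in [0,1] are quantized to
    uint8 (value = round(pixel * 255))."""
    images = np.asarray(images)
    if images.ndim != 3:
        raise ValueError("expected (N, rows, cols) images")
    if images.dtype != np.uint8:
        images = np.round(np.clip(images, 0.0, 1.0) * 255).astype(np.uint8)
    n, rows, cols = images.shape
    with open(path, "wb") as fh:
        fh.write(struct.pack(">IIII", IDX_IMAGES_MAGIC, n, rows, cols))
        fh.write(images.tobytes())


def read_idx_images(path) -> np.ndarray:
    """Read an IDX image file; returns (N, rows, cols) floats in [0,1]."""
    raw = Path(path).read_bytes()
    if len(raw) < 16:
        raise IdxFormatError(f"{path}: truncated header")
    magic, n, rows, cols = struct.unpack(">IIII", raw[:16])
    if magic != IDX_IMAGES_MAGIC:
        raise IdxFormatError(f"{path}: bad magic {magic:#010x} for images")
    expected = 16 + n * rows * cols
    if len(raw) != expected:
        raise IdxFormatError(f"{path}: expected {expected} bytes, got {len(raw)}")
    data = np.frombuffer(raw, dtype=np.uint8, offset=16)
    return data.reshape(n, rows, cols).astype(np.float64) / 255.0


def write_idx_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    with open(path, "wb") as fh:
        fh.write(struct.pack(">II", IDX_LABELS_MAGIC, len(labels)))
        fh.write(labels.astype(np.uint8).tobytes())


def read_idx_labels(path) -> np.ndarray:
    raw = Path(path).read_bytes()
    if len(raw) < 8:
        raise IdxFormatError(f"{path}: truncated header")
    magic, n = struct.unpack(">II", raw[:8])
    if magic != IDX_LABELS_MAGIC:
        raise IdxFormatError(f"{path}: bad magic {magic:#010x} for labels")
    if len(raw) != 8 + n:
        raise IdxFormatError(f"{path}: expected {8 + n} bytes, got {len(raw)}")
    return np.frombuffer(raw, dtype=np.uint8, offset=8).astype(np.int64)


def save_dataset(images_path, labels_path, sidecar_path,
                 images: Sequence[LabeledImage],
                 params: dict | None = None) -> None:
    """IDX pair plus a JSON sidecar with per-image ambiguity annotations."""
    pix = np.stack([im.pixels for im in images])
    labels = np.array([im.label for im in images])
    write_idx_images(images_path, pix)
    write_idx_labels(labels_path, labels)
    sidecar = {
        "params": params or {},
        "ambiguity": [
            None if im.ambiguity is None
            else {"class_a": int(im.ambiguity[0]),
                  "class_b": int(im.ambiguity[1]),
                  "mix": float(im.ambiguity[2])}
            for im in images
        ],
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def load_idx_dataset(images_path, labels_path,
                     sidecar_path=None) -> list[LabeledImage]:
    """Load an IDX pair into labelled images in [0,1]; attach ambiguity
    annotations from the sidecar when present."""
    pix = read_idx_images(images_path)
    labels = read_idx_labels(labels_path)
    if len(pix) != len(labels):
        raise IdxFormatError(
            f"image/label count mismatch: {len(pix)} vs {len(labels)}")
    if pix.shape[1:] != (IMG_SIZE, IMG_SIZE):
        raise IdxFormatError(f"expected {IMG_SIZE}x{IMG_SIZE} images, "
                             f"got {pix.shape[1:]}")
    ambig = [None] * len(pix)
    if sidecar_path is not None:
        side = json.loads(Path(sidecar_path).read_text())
        ann = side.get("ambiguity", [])
        if len(ann) != len(pix):
            raise IdxFormatError("sidecar annotation count mismatch")
        ambig = [None if a is None
                 else (int(a["class_a"]), int(a["class_b"]), float(a["mix"]))
                 for a in ann]
    return [LabeledImage(pixels=pix[i], label=int(labels[i]),
                         ambiguity=ambig[i]) for i in range(len(pix))]


def save_triplet_index(path, triplets: Sequence[AmbiguousTriplet],
                       unambiguous: Sequence[LabeledImage],
                       ambiguous: Sequence[LabeledImage]) -> None:
    """Store triplets as index records into the two saved datasets."""
    un_pos = {id(im): i for i, im in enumerate(unambiguous)}
    amb_pos = {id(im): i for i, im in enumerate(ambiguous)}
    records = []
    for t in triplets:
        records.append({
            "x0_idx": un_pos[id(t.x0)], "x1_idx": un_pos[id(t.x1)],
            "ambig_idx": amb_pos[id(t.x_ambig)],
            "y0": int(t.y0), "y1": int(t.y1), "alpha": float(t.alpha),
        })
    Path(path).write_text(json.dumps(records, indent=1))


def load_triplet_index(path, unambiguous: Sequence[LabeledImage],
                       ambiguous: Sequence[LabeledImage]
                       ) -> list[AmbiguousTriplet]:
    records = json.loads(Path(path).read_text())
    return [AmbiguousTriplet(x0=unambiguous[r["x0_idx"]],
                             x1=unambiguous[r["x1_idx"]],
                             x_ambig=ambiguous[r["ambig_idx"]])
            for r in records]
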