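"""COCO panoptic format reader/writer (JSON + per-pixel segment-id PNGs).

Segment ids are packed into 24-bit RGB id-map PNGs using the common COCO
panoptic dialect ``id = R + 256*G + 256**2*B``.  Images are written as 8-bit
grayscale PNGs.  Coordinates are 0-based row-major; bounding boxes follow the
COCO ``[x, y, width, height]`` convention.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from PIL import Image

from .phantom import PanopticSample, PhantomConfig, generate_phantom
from .vocab import DEFAULT_VOCABULARY, Vocabulary

__all__ = [
    "PanopticFormatError", "encode_id_map", "decode_id_map",
    "write_panoptic", "read_panoptic", "generate_dataset",
]


class PanopticFormatError(ValueError):
    """Raised when a panoptic JSON/id-map pair is inconsistent."""


def encode_id_map(ids: np.ndarray) -> np.ndarray:
    """(H, W) integer ids -> (H, W, 3) uint8 RGB, id = R + 256*G + 256^2*B."""
    ids = np.asarray(ids)
    if ids.min() < 0 or ids.max() >= 256 ** 3:
        raise ValueError("segment ids must fit in 24 bits and be non-negative")
    rgb = np.zeros((*ids.shape, 3), dtype=np.uint8)
    rgb[..., 0] = ids % 256
    rgb[..., 1] = (ids // 256) % 256
    rgb[..., 2] = ids // (256 ** 2)
    return rgb


def decode_id_map(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=np.int64)
    return rgb[..., 0] + 256 * rgb[..., 1] + (256 ** 2) * rgb[..., 2]


def _bbox(mask: np.ndarray) -> list[int]:
    ys, xs = np.nonzero(mask)
    return [int(xs.min()), int(ys.min()),
            int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1)]


def write_panoptic(samples: list[PanopticSample], out_dir: str | Path,
                   vocab: Vocabulary = DEFAULT_VOCABULARY,
                   stem: str = "phantom") -> dict:
    """Write samples as COCO panoptic (images/, panoptic/, panoptic.json).

    Returns a manifest dict listing per-image paths and segment counts; the
    manifest is also stored as ``manifest.json`` next to the annotation file.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "panoptic").mkdir(parents=True, exist_ok=True)

    images_json, annotations = [], []
    manifest_entries = []
    for idx, sample in enumerate(samples):
        image_id = sample.image_id if sample.image_id else idx + 1
        name = f"{stem}_{idx:04d}.png"
        img8 = np.round(sample.image * 255.0).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(out_dir / "images" / name)

        ids = sample.id_map()
        Image.fromarray(encode_id_map(ids), mode="RGB").save(
            out_dir / "panoptic" / name)

        segments_info = []
        for seg_idx, (mask, cid) in enumerate(zip(sample.masks, sample.classes)):
            segments_info.append({
                "id": seg_idx + 1,
                "category_id": int(cid),
                "area": int(mask.sum()),
                "bbox": _bbox(mask),
                "iscrowd": 0,
            })
        images_json.append({"id": image_id, "file_name": name,
                            "height": sample.height, "width": sample.width})
        annotations.append({"image_id": image_id, "file_name": name,
                            "segments_info": segments_info})
        manifest_entries.append({"image_id": image_id, "image": f"images/{name}",
                                 "id_map": f"panoptic/{name}",
                                 "k": sample.k})

    payload = {"images": images_json, "annotations": annotations,
               "categories": vocab.coco_categories()}
    json_path = out_dir / "panoptic.json"
    json_path.write_text(json.dumps(payload, indent=1))

    manifest = {"annotation_file": "panoptic.json", "images": manifest_entries,
                "n_images": len(samples),
                "total_segments": int(sum(e["k"] for e in manifest_entries))}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_panoptic(json_path: str | Path,
                  idmap_dir: str | Path | None = None,
                  images_dir: str | Path | None = None
                  ) -> tuple[list[PanopticSample], Vocabulary]:
    """Read a COCO panoptic annotation file back into samples.

    ``idmap_dir`` defaults to ``<json dir>/panoptic`` and ``images_dir`` to
    ``<json dir>/images``.  Raises :class:`PanopticFormatError` when the
    id-map contains a segment id absent from the JSON.
    """
    json_path = Path(json_path)
    root = json_path.parent
    idmap_dir = Path(idmap_dir) if idmap_dir is not None else root / "panoptic"
    images_dir = Path(images_dir) if images_dir is not None else root / "images"

    payload = json.loads(json_path.read_text())
    cats = sorted(payload["categories"], key=lambda c: c["id"])
    things = tuple(c["name"] for c in cats if c["isthing"])
    stuffs = tuple(c["name"] for c in cats if not c["isthing"])
    vocab = Vocabulary(things=things, stuffs=stuffs)
    expected_ids = [c["id"] for c in cats]
    if expected_ids != list(range(1, len(cats) + 1)):
        raise PanopticFormatError(
            f"category ids must be contiguous from 1, got {expected_ids}")

    images_by_id = {img["id"]: img for img in payload["images"]}
    samples = []
    for ann in payload["annotations"]:
        info = images_by_id.get(ann["image_id"])
        if info is None:
            raise PanopticFormatError(
                f"annotation references unknown image id {ann['image_id']}")
        ids = decode_id_map(np.asarray(
            Image.open(idmap_dir / ann["file_name"]).convert("RGB")))
        if ids.shape != (info["height"], info["width"]):
            raise PanopticFormatError(
                f"id-map shape {ids.shape} does not match image "
                f"{(info['height'], info['width'])} for {ann['file_name']}")
        declared = {int(s["id"]) for s in ann["segments_info"]}
        present = {int(v) for v in np.unique(ids) if v != 0}
        orphans = sorted(present - declared)
        if orphans:
            raise PanopticFormatError(
                f"id-map {ann['file_name']} contains segment ids absent from "
                f"the JSON: {orphans}")
        masks, classes = [], []
        for seg in ann["segments_info"]:
            masks.append((ids == seg["id"]).astype(np.uint8))
            classes.append(int(seg["category_id"]))
        img_path = images_dir / ann["file_name"]
        if img_path.exists():
            image = np.asarray(Image.open(img_path).convert("L"),
                               dtype=np.float32) / 255.0
        else:
            image = np.zeros((info["height"], info["width"]), dtype=np.float32)
        samples.append(PanopticSample(
            image=image,
            masks=np.stack(masks) if masks else
            np.zeros((0, info["height"], info["width"]), dtype=np.uint8),
            classes=np.array(classes, dtype=np.int64),
            image_id=int(ann["image_id"])))
    return samples, vocab


def generate_dataset(config: PhantomConfig, n_images: int,
                     out_dir: str | Path,
                     vocab: Vocabulary = DEFAULT_VOCABULARY) -> dict:
    """Generate ``n_images`` phantoms and write them as a COCO panoptic set.

    Per-image seeds are derived deterministically from ``config.seed``, so
    the whole dataset is byte-identical across runs.
    """
    if n_images < 1:
        raise ValueError(f"n_images must be >= 1, got {n_images}")
    config.validate()
    seeds = np.random.SeedSequence(config.seed).generate_state(n_images)
    samples = []
    for i, s in enumerate(seeds):
        cfg_i = dataclasses.replace(config, seed=int(s % (2 ** 31)))
        samples.append(generate_phantom(cfg_i, vocab=vocab, image_id=i + 1))
    return write_panoptic(samples, out_dir, vocab=vocab)
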