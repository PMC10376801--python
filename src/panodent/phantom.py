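"""Synthetic panoramic-radiograph phantom with panoptic ground truth.

The generator emulates the structure of panoramic dental X-rays at desk
scale: up to 32 tooth instances arranged along two mirrored arches, a single
background-tissue "stuff" region covering everything else, optional bright
restoration blobs and appliance wires, low contrast, blur and noise.  The
ground truth is a set of pairwise-disjoint binary masks whose union tiles
the image, one mask per tooth plus one for the background.

Everything is driven by a single integer seed: the same configuration
produces bit-identical images and masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .vocab import DEFAULT_VOCABULARY, Vocabulary

__all__ = ["PhantomConfig", "PanopticSample", "generate_phantom",
           "PhantomConfigError"]


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration field is invalid."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic radiograph generator.

    Sizes are in pixels, intensities on the [0, 1] image scale.
    """

    image_height: int = 256
    image_width: int = 512
    n_teeth: int = 32
    arch_curvature: float = 1.0
    tooth_size_range: tuple[float, float] = (48.0, 72.0)
    restoration_prob: float = 0.6
    appliance_prob: float = 0.25
    noise_sigma: float = 0.03
    blur_sigma: float = 1.0
    contrast_range: tuple[float, float] = (0.55, 0.9)
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 64:
            raise PhantomConfigError(f"image_height must be >= 64, got {self.image_height}")
        if self.image_width < 64:
            raise PhantomConfigError(f"image_width must be >= 64, got {self.image_width}")
        if not 0 <= self.n_teeth <= 32:
            raise PhantomConfigError(f"n_teeth must be in [0, 32], got {self.n_teeth}")
        if self.arch_curvature < 0:
            raise PhantomConfigError(f"arch_curvature must be >= 0, got {self.arch_curvature}")
        lo, hi = self.tooth_size_range
        if not (0 < lo <= hi):
            raise PhantomConfigError(f"tooth_size_range must be 0 < lo <= hi, got {self.tooth_size_range}")
        for name in ("restoration_prob", "appliance_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PhantomConfigError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sigma < 0:
            raise PhantomConfigError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.blur_sigma < 0:
            raise PhantomConfigError(f"blur_sigma must be >= 0, got {self.blur_sigma}")
        clo, chi = self.contrast_range
        if not (0 < clo <= chi <= 1.0):
            raise PhantomConfigError(f"contrast_range must satisfy 0 < lo <= hi <= 1, got {self.contrast_range}")


@dataclass
class PanopticSample:
    """One image with its panoptic ground truth.

    ``masks`` are K pairwise-disjoint binary arrays; together with the void
    region they tile the image (the phantom never produces void pixels:
    background tissue covers everything that is not a tooth).
    """

    image: np.ndarray            # (H, W) float32 in [0, 1]
    masks: np.ndarray            # (K, H, W) uint8, values in {0, 1}
    classes: np.ndarray          # (K,) int64 category ids
    image_id: int = 0

    def __post_init__(self):
        if len(self.masks) != len(self.classes):
            raise ValueError("masks and classes must have equal length")
        if self.masks.ndim != 3 or self.masks.shape[1:] != self.image.shape:
            raise ValueError("mask shape inconsistent with image")

    @property
    def k(self) -> int:
        return len(self.masks)

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    def thing_indices(self, vocab: Vocabulary = DEFAULT_VOCABULARY) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.classes)
                         if vocab.is_thing(int(c))], dtype=np.int64)

    def semantic_map(self, vocab: Vocabulary = DEFAULT_VOCABULARY) -> np.ndarray:
        """(H, W) int64 map of semantic class indices; -1 where void."""
        sem = np.full(self.image.shape, -1, dtype=np.int64)
        for mask, cid in zip(self.masks, self.classes):
            sem[mask.astype(bool)] = vocab.semantic_index(int(cid))
        return sem

    def id_map(self) -> np.ndarray:
        """(H, W) int32 of 1-based segment ids (0 = void)."""
        ids = np.zeros(self.image.shape, dtype=np.int32)
        for i, mask in enumerate(self.masks):
            ids[mask.astype(bool)] = i + 1
        return ids


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _superellipse_mask(h: int, w: int, cx: float, cy: float, a: float, b: float,
                       angle: float, power: float, notch: float,
                       root_sign: float) -> np.ndarray:
    """Rasterize a rotated superellipse, optionally with a root notch.

    ``root_sign`` gives the direction (in local +y) of the tooth root; a
    positive ``notch`` carves a triangular indentation from the root tip,
    which splits the root into two lobes the way molar roots look.
    """
    pad = int(np.ceil(max(a, b))) + 2
    y0 = max(0, int(cy) - pad)
    y1 = min(h, int(cy) + pad + 1)
    x0 = max(0, int(cx) - pad)
    x1 = min(w, int(cx) + pad + 1)
    if y0 >= y1 or x0 >= x1:
        return np.zeros((h, w), dtype=bool)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs - cx
    dy = ys - cy
    ca, sa = np.cos(angle), np.sin(angle)
    xl = ca * dx + sa * dy
    yl = -sa * dx + ca * dy
    inside = (np.abs(xl / a) ** power + np.abs(yl / b) ** power) <= 1.0
    if notch > 0:
        toward_root = yl * root_sign
        depth = notch * b
        tip = toward_root - (b - depth)      # > 0 within the root tip band
        with np.errstate(invalid="ignore", divide="ignore"):
            half_width = 0.35 * a * np.clip(tip / max(depth, 1e-6), 0.0, 1.0)
        inside &= ~((tip > 0) & (np.abs(xl) < half_width))
    out = np.zeros((h, w), dtype=bool)
    out[y0:y1, x0:x1] = inside
    return out


def _low_freq_field(rng: np.random.Generator, h: int, w: int,
                    cells: tuple[int, int] = (6, 10)) -> np.ndarray:
    coarse = rng.normal(size=cells)
    return zoom(coarse, (h / cells[0], w / cells[1]), order=3, mode="nearest",
                grid_mode=True)[:h, :w]


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------

def generate_phantom(config: PhantomConfig,
                     vocab: Vocabulary = DEFAULT_VOCABULARY,
                     image_id: int = 0) -> PanopticSample:
    """Generate one synthetic panoramic radiograph with ground truth.

    Teeth are placed along two mirrored arches (upper and lower), later
    teeth clipped against earlier ones so masks stay disjoint; the final
    segment is the background-tissue stuff region covering every remaining
    pixel, so K = surviving teeth + 1.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    h, w = config.image_height, config.image_width

    n_upper = (config.n_teeth + 1) // 2
    n_lower = config.n_teeth - n_upper
    span = 0.78 * w
    gap = 0.055 * h
    occupancy = np.zeros((h, w), dtype=bool)
    tooth_masks: list[np.ndarray] = []
    tooth_class_ids: list[int] = []

    tooth_counter = 0
    for arch_sign, n_arch in ((-1.0, n_upper), (+1.0, n_lower)):
        if n_arch == 0:
            continue
        spacing = span / n_arch
        for i in range(n_arch):
            u = -1.0 + (i + 0.5) * 2.0 / n_arch
            size = rng.uniform(*config.tooth_size_range)
            power = rng.uniform(2.0, 3.0)
            jitter_x = rng.normal(0.0, 0.02) * spacing
            jitter_y = rng.normal(0.0, 0.015) * h
            notch = rng.uniform(0.25, 0.45) if rng.random() < 0.5 else 0.0
            b = size / 2.0
            a = 0.5 * min(0.62 * size, 1.15 * spacing)
            drop = config.arch_curvature * 0.12 * h * u * u
            cx = w / 2.0 + u * span / 2.0 + jitter_x
            cy = (h / 2.0 + arch_sign * (gap / 2.0 + b + drop) + jitter_y)
            angle = arch_sign * u * 0.28           # teeth fan outward
            mask = _superellipse_mask(h, w, cx, cy, a, b, angle, power,
                                      notch, root_sign=arch_sign * -1.0)
            mask &= ~occupancy                     # clip against earlier teeth
            if not mask.any():
                continue
            occupancy |= mask
            tooth_masks.append(mask)
            if vocab.n_things >= 32:
                tooth_counter += 1
                tooth_class_ids.append(tooth_counter)
            else:
                tooth_class_ids.append(vocab.thing_ids()[0])

    background = ~occupancy
    masks = np.stack(tooth_masks + [background]).astype(np.uint8) \
        if tooth_masks else background[None].astype(np.uint8)
    classes = np.array(tooth_class_ids + [vocab.stuff_ids()[0]], dtype=np.int64)

    # ---------------------------------------------------------- appearance
    img = 0.30 + 0.06 * _low_freq_field(rng, h, w)
    yy = np.arange(h, dtype=np.float64)[:, None]
    img += 0.08 * np.exp(-(((yy - 0.5 * h) / (0.28 * h)) ** 2))  # jaw bone band

    for mask in tooth_masks:
        img[mask] = rng.uniform(0.60, 0.74)

    if tooth_masks and rng.random() < config.restoration_prob:
        n_rest = int(rng.integers(1, max(2, len(tooth_masks) // 4 + 1)))
        chosen = rng.choice(len(tooth_masks), size=min(n_rest, len(tooth_masks)),
                            replace=False)
        for ti in chosen:
            ys_t, xs_t = np.nonzero(tooth_masks[ti])
            cy_t, cx_t = ys_t.mean(), xs_t.mean()
            r = 0.35 * np.sqrt(len(ys_t) / np.pi)
            blob = (ys_t - cy_t) ** 2 + (xs_t - cx_t) ** 2 <= r * r
            img[ys_t[blob], xs_t[blob]] = 0.97

    if rng.random() < config.appliance_prob:
        xs_w = np.arange(w, dtype=np.float64)
        u = (xs_w - w / 2.0) / (span / 2.0)
        wire_y = h / 2.0 + config.arch_curvature * 0.12 * h * u * u
        half = 0.9 * span / 2.0
        for x in range(w):
            if abs(xs_w[x] - w / 2.0) > half:
                continue
            y = int(round(wire_y[x]))
            if 1 <= y < h - 1:
                img[y - 1:y + 2, x] = 0.92

    contrast = rng.uniform(*config.contrast_range)
    img = 0.5 + (img - 0.5) * contrast
    if config.blur_sigma > 0:
        img = gaussian_filter(img, config.blur_sigma)
    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    return PanopticSample(image=img, masks=masks, classes=classes,
                          image_id=image_id)
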