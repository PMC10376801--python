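"""Dual-path mask transformer for panoptic tooth segmentation.

The network has two streams: a *pixel path* (a small residual CNN producing
feature maps at output strides 4, 8 and 16) and a *memory path* of N learned
object queries, each of which comes to represent one candidate segment.  The
two streams communicate inside dual-path transformer blocks through four
attention flows:

* memory-to-pixel (M2P) and memory-to-memory (M2M), computed jointly as one
  attention over the concatenation of memory and pixel tokens;
* pixel-to-memory (P2M) feedback attention;
* pixel-to-pixel (P2P) self-attention, factorized axially: a height-axis
  pass followed by a width-axis pass.

A stacked hourglass-style decoder traverses the stride schedule L times,
merging scales by bilinear resizing and summation; the dual-path blocks sit
at the stride-16 visits.  Two heads read the result: a 2-layer fully
connected class head mapping each query to a distribution over the real
classes plus the "no object" class ⌀, and a mask head that multiplies a
projected memory feature f (N×D) with the normalized stride-4 pixel feature
g (D×H/4×W/4), followed by a per-pixel softmax over the N slots so that slot
scores form non-overlapping soft masks.  Auxiliary heads emit semantic
logits and a per-pixel unit-norm embedding map used by the auxiliary losses.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import (
    Conv2d,
    FeedForward,
    LayerNorm,
    Linear,
    Module,
    MultiheadAttention,
    ResidualConvBlock,
    Tensor,
    bilinear_resize,
    concat,
    l2_normalize,
    sinusoidal_position_encoding,
)

__all__ = ["ModelConfig", "MemoryState", "PixelState", "ModelOutput",
           "DualPathBlock", "MaskTransformer", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised for structurally invalid model configurations or inputs."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``n_slots`` must exceed the largest number of ground-truth segments the
    model will be asked to match (at most 32 teeth per radiograph, hence the
    default of 40).  ``n_classes`` counts real thing classes; the ⌀ class is
    added internally.  ``n_stuff`` extends the semantic head only.
    """

    n_slots: int = 40
    feature_dim: int = 64
    n_classes: int = 1
    n_stuff: int = 1
    decoder_strides: tuple[int, ...] = (4, 8, 16)
    n_decoder_stacks: int = 2
    n_attention_heads: int = 4
    backbone_channels: tuple[int, int, int, int] = (16, 32, 48, 64)
    n_transformer_blocks: int = 1
    embed_dim: int = 16
    ffn_ratio: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_slots < 1:
            raise ConfigurationError(f"n_slots must be >= 1, got {self.n_slots}")
        if 4 not in self.decoder_strides:
            raise ConfigurationError("decoder output stride 4 must be present")
        if sorted(self.decoder_strides) != list(self.decoder_strides):
            raise ConfigurationError("decoder_strides must be sorted ascending")
        if any(s not in (4, 8, 16) for s in self.decoder_strides):
            raise ConfigurationError("decoder strides must be among (4, 8, 16)")
        if self.n_decoder_stacks < 1:
            raise ConfigurationError(
                f"n_decoder_stacks must be >= 1, got {self.n_decoder_stacks}")
        if self.feature_dim % self.n_attention_heads != 0:
            raise ConfigurationError("feature_dim must divide by attention heads")
        if self.feature_dim % 4 != 0:
            raise ConfigurationError("feature_dim must be a multiple of 4")
        if self.n_classes < 1 or self.n_stuff < 1:
            raise ConfigurationError("need at least one thing and one stuff class")
        if len(self.backbone_channels) != 4:
            raise ConfigurationError("backbone_channels needs 4 entries")

    @property
    def n_semantic(self) -> int:
        return self.n_classes + self.n_stuff


@dataclass
class MemoryState:
    """The global memory: one feature row per object query."""
    queries: Tensor  # (N, D)


@dataclass
class PixelState:
    """CNN-path feature maps keyed by output stride."""
    features: dict[int, Tensor]  # stride -> (D, H/stride, W/stride)


@dataclass
class ModelOutput:
    """Raw network predictions for one image (stride-4 resolution maps)."""

    mask_logits: Tensor        # (N, H4, W4)
    mask_scores: Tensor        # (N, H4, W4); per-pixel softmax over slots
    class_logits: Tensor       # (N, C+1); last column is ⌀
    class_probs: Tensor        # (N, C+1)
    semantic_logits: Tensor    # (C+n_stuff, H4, W4)
    embedding_map: Tensor      # (embed_dim, H4, W4), unit per-pixel norm
    image_hw: tuple[int, int]  # original input size

    @property
    def n_slots(self) -> int:
        return self.mask_scores.shape[0]

    @property
    def grid_hw(self) -> tuple[int, int]:
        return self.mask_scores.shape[1:]


class DualPathBlock(Module):
    """One dual-path transformer block (all four attention flows).

    Pre-norm residual layout: every attention and feed-forward sub-layer is
    wrapped as ``x + sublayer(LN(x))``, so zeroing the attention output
    projections (and the second FFN projections, which are zero-initialized
    anyway) makes the block an exact identity on both paths.  Fixed 2-D
    sinusoidal position codes are added to the *inputs* of the attention
    sub-layers only, never to the residual streams.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 ffn_ratio: int = 2):
        self.dim = dim
        self.ln_mem = LayerNorm(dim)
        self.ln_pix_kv = LayerNorm(dim)
        self.mem_attn = MultiheadAttention(dim, n_heads, rng)   # M2M + M2P fused
        self.ln_mem_ffn = LayerNorm(dim)
        self.mem_ffn = FeedForward(dim, ffn_ratio * dim, rng)
        self.ln_p2m_q = LayerNorm(dim)
        self.ln_p2m_kv = LayerNorm(dim)
        self.p2m_attn = MultiheadAttention(dim, n_heads, rng)   # P2M feedback
        self.ln_axial_h = LayerNorm(dim)
        self.axial_h = MultiheadAttention(dim, n_heads, rng)    # P2P, height axis
        self.ln_axial_w = LayerNorm(dim)
        self.axial_w = MultiheadAttention(dim, n_heads, rng)    # P2P, width axis
        self.ln_pix_ffn = LayerNorm(dim)
        self.pix_ffn = FeedForward(dim, ffn_ratio * dim, rng)

    def __call__(self, pixel: Tensor, memory: Tensor) -> tuple[Tensor, Tensor]:
        d, h, w = pixel.shape
        if h < 2 or w < 2:
            raise ConfigurationError(
                f"axial attention needs spatial dims >= 2, got {h}x{w}")
        pe = Tensor(sinusoidal_position_encoding(d, h, w).transpose(1, 2, 0))
        x = pixel.transpose(1, 2, 0)                     # (h, w, D)

        # -- memory update: one attention over {memory ∪ pixel tokens}
        tokens = (x + pe).reshape(h * w, d)
        mem_q = self.ln_mem(memory)
        kv = concat([mem_q, self.ln_pix_kv(tokens)], axis=0)
        memory = memory + self.mem_attn(mem_q, kv)
        memory = memory + self.mem_ffn(self.ln_mem_ffn(memory))

        # -- pixel reads memory back (P2M feedback)
        q = self.ln_p2m_q((x + pe).reshape(h * w, d))
        p2m = self.p2m_attn(q, self.ln_p2m_kv(memory)).reshape(h, w, d)
        x = x + p2m

        # -- P2P axial self-attention: height pass, then width pass
        cols = self.ln_axial_h(x + pe).transpose(1, 0, 2)   # (w, h, D) batches
        x = x + self.axial_h(cols).transpose(1, 0, 2)
        rows = self.ln_axial_w(x + pe)                      # (h, w, D) batches
        x = x + self.axial_w(rows)

        x = x + self.pix_ffn(self.ln_pix_ffn(x))
        return x.transpose(2, 0, 1), memory


class MaskTransformer(Module):
    """The full dual-path network: backbone, decoder and output heads."""

    MAX_STRIDE = 16

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        c2, c4, c8, c16 = config.backbone_channels
        d = config.feature_dim

        # ---- pixel-path CNN: strides 2, 4, 8, 16
        self.stem = Conv2d(1, c2, 3, rng, stride=2)
        self.stage4 = ResidualConvBlock(c2, c4, rng, stride=2)
        self.stage8 = ResidualConvBlock(c4, c8, rng, stride=2)
        self.stage16 = ResidualConvBlock(c8, c16, rng, stride=2)
        self.proj = {s: Conv2d(c, d, 1, rng, padding=0)
                     for s, c in ((4, c4), (8, c8), (16, c16))}

        # ---- memory path: learned object queries
        self.queries = Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(d),
                       size=(config.n_slots, d)).astype(np.float32),
            requires_grad=True)

        # ---- decoder: dual-path blocks at stride-16 visits, conv elsewhere
        self.dp_blocks = [
            [DualPathBlock(d, config.n_attention_heads, rng, config.ffn_ratio)
             for _ in range(config.n_transformer_blocks)]
            for _ in range(config.n_decoder_stacks)]
        self.stage_convs = [
            {s: ResidualConvBlock(d, d, rng)
             for s in config.decoder_strides if s != self.MAX_STRIDE}
            for _ in range(config.n_decoder_stacks)]

        # ---- output heads
        nc = config.n_classes + 1                       # + ⌀
        self.class_fc1 = Linear(d, d, rng)
        self.class_fc2 = Linear(d, nc, rng)
        self.mask_fc1 = Linear(d, d, rng)
        self.mask_fc2 = Linear(d, d, rng)
        self.mask_conv1 = Conv2d(d, d, 3, rng)
        self.mask_conv2 = Conv2d(d, d, 3, rng)
        self.logit_scale = Tensor(np.float32(10.0), requires_grad=True)
        self.sem_conv1 = Conv2d(d, d, 3, rng)
        self.sem_conv2 = Conv2d(d, config.n_semantic, 1, rng, padding=0)
        self.embed_conv = Conv2d(d, config.embed_dim, 1, rng, padding=0)

    # ------------------------------------------------------------ components
    def _pad(self, image: np.ndarray) -> np.ndarray:
        h, w = image.shape
        ph = (-h) % self.MAX_STRIDE
        pw = (-w) % self.MAX_STRIDE
        if ph or pw:
            image = np.pad(image, ((0, ph), (0, pw)))
        return image

    def backbone_forward(self, image: np.ndarray | Tensor) -> PixelState:
        """Run the CNN path; returns feature maps at strides 4, 8 and 16.

        Inputs whose sides are not multiples of 16 are zero-padded on the
        bottom/right so every stride divides exactly; stride-4 outputs are
        cropped back in :meth:`forward`.
        """
        arr = image.data if isinstance(image, Tensor) else np.asarray(image)
        if arr.ndim != 2:
            raise ConfigurationError(f"expected a (H, W) image, got {arr.shape}")
        arr = self._pad(arr.astype(np.float32))
        x = Tensor(arr[None])                     # (1, H, W)
        s2 = self.stem(x).relu()
        s4 = self.stage4(s2)
        s8 = self.stage8(s4)
        s16 = self.stage16(s8)
        raw = {4: s4, 8: s8, 16: s16}
        return PixelState(features={
            s: self.proj[s](raw[s]) for s in self.config.decoder_strides})

    def stacked_decoder(self, pixel: PixelState, memory: MemoryState
                        ) -> tuple[Tensor, Tensor]:
        """Traverse the stride schedule L times; returns (stride-4 feature,
        final memory).

        Each visit resizes the running feature bilinearly to the target
        stride, sums it with the backbone skip feature, then applies a
        dual-path transformer block (at stride 16) or a residual conv block.
        Intermediate pyramid features are used only for aggregation.
        """
        cfg = self.config
        missing = [s for s in cfg.decoder_strides if s not in pixel.features]
        if missing:
            raise ConfigurationError(f"pixel state lacks strides {missing}")
        schedule = sorted(cfg.decoder_strides, reverse=True)   # coarse -> fine
        mem = memory.queries
        x = pixel.features[schedule[0]]
        for stack in range(cfg.n_decoder_stacks):
            for idx, s in enumerate(schedule):
                skip = pixel.features[s]
                first_visit = stack == 0 and idx == 0
                if not first_visit:
                    x = bilinear_resize(x, skip.shape[1:]) + skip
                if s == self.MAX_STRIDE:
                    for block in self.dp_blocks[stack]:
                        x, mem = block(x, mem)
                else:
                    x = self.stage_convs[stack][s](x)
        return x, mem

    def class_head(self, memory: Tensor) -> tuple[Tensor, Tensor]:
        logits = self.class_fc2(self.class_fc1(memory).relu())
        return logits, logits.softmax(axis=-1)

    def mask_head(self, memory: Tensor, pixel4: Tensor
                  ) -> tuple[Tensor, Tensor]:
        """Multiply memory feature f with normalized pixel feature g.

        Both factors are unit-normalized and the product scaled by a learned
        temperature before the per-pixel softmax over the N slots.
        """
        if memory.shape[1] != pixel4.shape[0]:
            raise ConfigurationError(
                f"memory dim {memory.shape[1]} != pixel dim {pixel4.shape[0]}")
        f = self.mask_fc2(self.mask_fc1(memory).relu())        # (N, D)
        f = l2_normalize(f, axis=1)
        pe = Tensor(sinusoidal_position_encoding(*pixel4.shape))
        g = self.mask_conv2(self.mask_conv1(pixel4 + pe).relu())  # (D, h, w)
        g = l2_normalize(g, axis=0)
        d, h, w = g.shape
        logits = (f @ g.reshape(d, h * w)) * self.logit_scale
        logits = logits.reshape(memory.shape[0], h, w)
        return logits, logits.softmax(axis=0)

    # ----------------------------------------------------------------- main
    def forward(self, image: np.ndarray) -> ModelOutput:
        image = np.asarray(image, dtype=np.float32)
        h, w = image.shape
        pixel = self.backbone_forward(image)
        x4, mem = self.stacked_decoder(pixel, MemoryState(self.queries))
        h4, w4 = -(-h // 4), -(-w // 4)
        if x4.shape[1:] != (h4, w4):
            x4 = x4[:, :h4, :w4]
        class_logits, class_probs = self.class_head(mem)
        mask_logits, mask_scores = self.mask_head(mem, x4)
        semantic_logits = self.sem_conv2(self.sem_conv1(x4).relu())
        embedding = l2_normalize(self.embed_conv(x4), axis=0)
        return ModelOutput(mask_logits=mask_logits, mask_scores=mask_scores,
                           class_logits=class_logits, class_probs=class_probs,
                           semantic_logits=semantic_logits,
                           embedding_map=embedding, image_hw=(h, w))

    __call__ = forward

    def summary(self) -> str:
        """Plain-text architecture summary with per-component parameter counts."""
        cfg = self.config
        rows: list[tuple[str, int]] = []
        for name, value in vars(self).items():
            if name == "config":
                continue
            from .nn.modules import _collect
            n = sum(p.size for p in _collect(value))
            if n:
                rows.append((name, n))
        width = max(len(n) for n, _ in rows)
        lines = [
            f"MaskTransformer: N={cfg.n_slots} slots, D={cfg.feature_dim}, "
            f"L={cfg.n_decoder_stacks} decoder stacks, "
            f"C={cfg.n_classes}+{cfg.n_stuff} classes, "
            f"strides {list(cfg.decoder_strides)}",
            f"{'component':<{width}}  parameters",
        ]
        lines += [f"{n:<{width}}  {c}" for n, c in rows]
        lines.append(f"{'total':<{width}}  {self.n_parameters()}")
        return "\n".join(lines)

    # ----------------------------------------------------------- checkpoints
    def save(self, path: str | Path) -> None:
        """Save parameters plus the config (as embedded JSON) in one file."""
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        cfg = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MaskTransformer":
        try:
            blob = np.load(path)
            cfg_json = bytes(blob["__config__"]).decode()
            cfg_dict = json.loads(cfg_json)
        except Exception as exc:
            raise ConfigurationError(f"unreadable checkpoint {path}: {exc}") from exc
        for key in ("decoder_strides", "backbone_channels"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = cls(ModelConfig(**cfg_dict))
        params = model.parameters()
        for i, p in enumerate(params):
            stored = blob[f"param_{i}"]
            if stored.shape != p.data.shape:
                raise ConfigurationError(
                    f"checkpoint parameter {i} has shape {stored.shape}, "
                    f"expected {p.data.shape}")
            p.data = stored.astype(np.float32)
        return model
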