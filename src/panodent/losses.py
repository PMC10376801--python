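"""PQ-style set-prediction loss with bipartite matching, plus auxiliaries.

The main loss scores each (ground-truth mask, predicted slot) pair with the
similarity ``sim = p̂_j(c_i) · Dice(m_i, m̂_j)`` — recognition quality times
segmentation quality — assigns slots to ground truth by maximum-total-
similarity bipartite matching, and optimizes

* for matched pairs: the dice loss weighted by class correctness plus the
  class cross-entropy weighted by mask correctness (the weight factors are
  detached from the gradient by default, since they act as weights);
* for unmatched slots: cross entropy towards the "no object" class ⌀;
* the two terms balanced by ``alpha``.

Three auxiliary losses assist training: an instance-discrimination
contrastive term on the per-pixel embedding map, a per-pixel mask-ID cross
entropy over the N slots, and a semantic segmentation cross entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import ModelOutput
from .nn import Tensor, as_tensor, bilinear_resize, concat, l2_normalize
from .phantom import PanopticSample
from .vocab import DEFAULT_VOCABULARY, Vocabulary

__all__ = [
    "MatchResult", "LossBreakdown", "LossWeights",
    "dice", "similarity", "similarity_matrix", "match",
    "pq_loss_pos", "pq_loss_neg", "pq_loss",
    "instance_discrimination_loss", "mask_id_cross_entropy", "semantic_loss",
    "downsample_masks",
]

_EPS_DICE = 1e-6
_PROB_FLOOR = 1e-8
_LOG_FLOOR = float(np.log(_PROB_FLOOR))


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def dice(m, m_hat, eps: float = _EPS_DICE) -> Tensor:
    """Soft Dice overlap ``2·Σ(m·m̂) / (Σm + Σm̂ + eps)`` in [0, 1]."""
    m = as_tensor(m)
    m_hat = as_tensor(m_hat)
    if m.shape != m_hat.shape:
        raise ValueError(f"dice shape mismatch: {m.shape} vs {m_hat.shape}")
    inter = (m * m_hat).sum()
    return (2.0 * inter) / (m.sum() + m_hat.sum() + eps)


def similarity(class_index: int, mask, class_probs, mask_score) -> float:
    """``p̂(c) × Dice(m, m̂)``: 1 iff class and mask both match exactly,
    0 when the class probability vanishes or the masks are disjoint."""
    p = np.asarray(class_probs.data if isinstance(class_probs, Tensor)
                   else class_probs, dtype=np.float64)
    if not 0 <= class_index < p.shape[-1] - 1:
        raise ValueError(
            f"class index {class_index} outside vocabulary of {p.shape[-1] - 1} "
            "real classes")
    return float(p[class_index]) * float(dice(mask, mask_score).data)


def downsample_masks(masks: np.ndarray, grid_hw: tuple[int, int]) -> np.ndarray:
    """Area-average binary masks onto the stride-4 grid (soft coverage)."""
    masks = np.asarray(masks, dtype=np.float32)
    k, h, w = masks.shape
    gh, gw = grid_hw
    fh, fw = -(-h // gh), -(-w // gw)
    padded = np.zeros((k, gh * fh, gw * fw), dtype=np.float32)
    padded[:, :h, :w] = masks
    return padded.reshape(k, gh, fh, gw, fw).mean(axis=(2, 4))


def similarity_matrix(class_indices: np.ndarray, masks_ds: np.ndarray,
                      class_probs: np.ndarray, mask_scores: np.ndarray
                      ) -> np.ndarray:
    """K×N similarity matrix between ground truth and prediction slots."""
    k = masks_ds.shape[0]
    n = mask_scores.shape[0]
    gt = masks_ds.reshape(k, -1)
    pr = mask_scores.reshape(n, -1)
    inter = gt @ pr.T
    denom = gt.sum(axis=1)[:, None] + pr.sum(axis=1)[None, :] + _EPS_DICE
    dice_mat = 2.0 * inter / denom
    prob_mat = class_probs[:, class_indices].T        # (K, N)
    return prob_mat * dice_mat


@dataclass
class MatchResult:
    """Optimal one-to-one assignment of ground truth to prediction slots."""

    similarity: np.ndarray   # (K, N)
    assignment: np.ndarray   # (K,) slot index per ground-truth segment
    unmatched: np.ndarray    # (N-K,) slots left without ground truth
    gt_indices: np.ndarray   # (K,) indices into sample.masks (thing segments)
    masks_ds: np.ndarray     # (K, H4, W4) area-averaged ground-truth masks

    @property
    def total_similarity(self) -> float:
        return float(self.similarity[np.arange(len(self.assignment)),
                                     self.assignment].sum())


def match(sample: PanopticSample, output: ModelOutput,
          vocab: Vocabulary = DEFAULT_VOCABULARY) -> MatchResult:
    """Maximum-total-similarity bipartite matching (Hungarian algorithm).

    Only thing-class ground-truth segments take part; ground-truth masks are
    area-averaged to the stride-4 grid before comparison.
    """
    gt_idx = sample.thing_indices(vocab)
    n = output.n_slots
    if len(gt_idx) > n:
        raise ValueError(
            f"{len(gt_idx)} ground-truth segments exceed the {n} prediction "
            "slots; configure the model with a larger n_slots")
    masks_ds = downsample_masks(sample.masks[gt_idx], output.grid_hw)
    cls_idx = np.array([vocab.thing_index(int(sample.classes[i]))
                        for i in gt_idx], dtype=np.int64)
    sim = similarity_matrix(cls_idx, masks_ds, output.class_probs.data,
                            output.mask_scores.data)
    rows, cols = linear_sum_assignment(-sim)
    order = np.argsort(rows)
    assignment = cols[order]
    unmatched = np.setdiff1d(np.arange(n), assignment)
    return MatchResult(similarity=sim, assignment=assignment,
                       unmatched=unmatched, gt_indices=gt_idx,
                       masks_ds=masks_ds)


# --------------------------------------------------------------------------
# PQ-style loss terms
# --------------------------------------------------------------------------

def pq_loss_pos(match_result: MatchResult, sample: PanopticSample,
                output: ModelOutput, vocab: Vocabulary = DEFAULT_VOCABULARY,
                stop_gradient_weights: bool = True,
                full_resolution: bool = False) -> Tensor:
    """Positive term: Σ_i  p̂·(−Dice) + Dice·(−log p̂) over matched pairs.

    The class-probability weight of the dice term and the dice weight of the
    cross-entropy term are treated as constants during differentiation
    (``stop_gradient_weights=False`` lets gradients flow for ablation).
    By default both sides are compared on the stride-4 grid (the ground
    truth area-averaged there); ``full_resolution`` instead upsamples the
    matched slot's score map bilinearly to image resolution and compares it
    against the original binary mask.  A perfect prediction contributes −1
    per matched mask.
    """
    log_probs = output.class_logits.log_softmax(axis=-1)
    h, w = output.image_hw
    total = Tensor(0.0)
    for row, gt_i in enumerate(match_result.gt_indices):
        j = int(match_result.assignment[row])
        c = vocab.thing_index(int(sample.classes[gt_i]))
        if full_resolution:
            up = bilinear_resize(output.mask_scores[j].reshape(
                1, *output.grid_hw), (h, w))
            d = dice(sample.masks[gt_i][None].astype(np.float32), up)
        else:
            d = dice(match_result.masks_ds[row], output.mask_scores[j])
        log_p = log_probs[j, c].clip_min(_LOG_FLOOR)
        p_val = float(np.exp(max(float(log_p.data), _LOG_FLOOR)))
        if stop_gradient_weights:
            p_w: Tensor | float = p_val
            d_w: Tensor | float = float(d.data)
        else:
            p_w = log_p.exp()
            d_w = d
        total = total + p_w * (-d) + d_w * (-log_p)
    return total


def pq_loss_neg(match_result: MatchResult, output: ModelOutput) -> Tensor:
    """Negative term: Σ over unmatched slots of −log p̂(⌀); 0 when K = N."""
    if len(match_result.unmatched) == 0:
        return Tensor(0.0)
    log_probs = output.class_logits.log_softmax(axis=-1)
    total = Tensor(0.0)
    for j in match_result.unmatched:
        total = total + (-log_probs[int(j), -1].clip_min(_LOG_FLOOR))
    return total


@dataclass(frozen=True)
class LossWeights:
    """Relative weights and knobs of the auxiliary losses."""

    instance_discrimination: float = 1.0
    mask_id: float = 1.0
    semantic: float = 1.0
    tau: float = 0.3            # instance-discrimination temperature
    max_pixels: int = 4096      # per-image pixel cap for the contrastive term
    stop_gradient_weights: bool = True
    dice_full_resolution: bool = False


@dataclass
class LossBreakdown:
    """All loss terms for one sample; ``loss`` is the differentiable total."""

    l_pq_pos: float
    l_pq_neg: float
    l_pq: float
    alpha: float
    l_instdisc: float
    l_maskid: float
    l_semantic: float
    total: float
    loss: Tensor               # differentiable total

    def to_dict(self) -> dict[str, float]:
        return {k: round(getattr(self, k), 6)
                for k in ("l_pq_pos", "l_pq_neg", "l_pq", "alpha",
                          "l_instdisc", "l_maskid", "l_semantic", "total")}


def pq_loss(sample: PanopticSample, output: ModelOutput, alpha: float = 0.75,
            weights: LossWeights = LossWeights(),
            vocab: Vocabulary = DEFAULT_VOCABULARY,
            match_result: MatchResult | None = None) -> LossBreakdown:
    """Full training objective: α·L_pos + (1−α)·L_neg + auxiliary terms."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if match_result is None:
        match_result = match(sample, output, vocab)
    pos = pq_loss_pos(match_result, sample, output, vocab,
                      stop_gradient_weights=weights.stop_gradient_weights,
                      full_resolution=weights.dice_full_resolution)
    neg = pq_loss_neg(match_result, output)
    pq = alpha * pos + (1.0 - alpha) * neg
    inst = instance_discrimination_loss(
        sample, output.embedding_map, tau=weights.tau,
        max_pixels=weights.max_pixels, vocab=vocab)
    maskid = mask_id_cross_entropy(match_result, sample, output.mask_logits)
    sem = semantic_loss(sample, output.semantic_logits, vocab=vocab)
    total = (pq + weights.instance_discrimination * inst
             + weights.mask_id * maskid + weights.semantic * sem)
    return LossBreakdown(
        l_pq_pos=float(pos.data), l_pq_neg=float(neg.data),
        l_pq=float(pq.data), alpha=alpha, l_instdisc=float(inst.data),
        l_maskid=float(maskid.data), l_semantic=float(sem.data),
        total=float(total.data), loss=total)


# --------------------------------------------------------------------------
# auxiliary losses
# --------------------------------------------------------------------------

def _subsample(indices: np.ndarray, cap: int) -> np.ndarray:
    """Deterministic, evenly spaced subset of at most ``cap`` indices."""
    if len(indices) <= cap:
        return indices
    sel = np.linspace(0, len(indices) - 1, cap).round().astype(np.int64)
    return indices[np.unique(sel)]


def instance_discrimination_loss(sample: PanopticSample, embedding_map: Tensor,
                                 tau: float = 0.3, max_pixels: int = 4096,
                                 vocab: Vocabulary = DEFAULT_VOCABULARY
                                 ) -> Tensor:
    """Contrastive clustering of pixel embeddings into instances.

    Each in-mask pixel embedding is pulled towards its own instance's mean
    embedding and pushed from the other instances' means via a softmax over
    ``e·μ_k / τ``.  Returns 0 when the sample has no thing instances (or a
    single one, where there are no negatives).
    """
    embedding_map = as_tensor(embedding_map)
    gt_idx = sample.thing_indices(vocab)
    if len(gt_idx) == 0:
        return Tensor(0.0)
    de, gh, gw = embedding_map.shape
    masks_ds = downsample_masks(sample.masks[gt_idx], (gh, gw))
    emb = embedding_map.reshape(de, gh * gw)
    pixel_groups = []
    for k in range(len(gt_idx)):
        flat = np.flatnonzero(masks_ds[k].reshape(-1) > 0.5)
        if len(flat):
            pixel_groups.append(flat)
    if not pixel_groups:
        return Tensor(0.0)
    mus = []
    for flat in pixel_groups:
        mu = emb[:, flat].mean(axis=1).reshape(de, 1)
        mus.append(l2_normalize(mu, axis=0))
    mus_t = concat(mus, axis=1)                        # (De, K)
    total_px = sum(len(g) for g in pixel_groups)
    labels, selected = [], []
    for k, flat in enumerate(pixel_groups):
        cap_k = max(1, int(max_pixels * len(flat) / total_px))
        sel = _subsample(flat, cap_k)
        selected.append(sel)
        labels.extend([k] * len(sel))
    sel_all = np.concatenate(selected)
    labels = np.array(labels, dtype=np.int64)
    e_sel = emb[:, sel_all].transpose(1, 0)            # (M, De)
    logits = (e_sel @ mus_t) * (1.0 / tau)             # (M, K)
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(len(labels)), labels]
    return -picked.mean()


def mask_id_cross_entropy(match_result: MatchResult, sample: PanopticSample,
                          mask_logits: Tensor) -> Tensor:
    """Per-pixel cross entropy of the N-slot distribution against the slot
    matched to the ground-truth segment covering the pixel.

    Pixels covered by no matched thing segment (background / void at the
    stride-4 grid) are excluded; a fully uncovered image contributes 0.
    """
    mask_logits = as_tensor(mask_logits)
    n, gh, gw = mask_logits.shape
    masks_ds = match_result.masks_ds
    if masks_ds.shape[0] == 0:
        return Tensor(0.0)
    coverage = masks_ds.reshape(masks_ds.shape[0], -1)
    best = coverage.argmax(axis=0)
    covered = coverage.max(axis=0) > 0.5
    pix = np.flatnonzero(covered)
    if len(pix) == 0:
        return Tensor(0.0)
    targets = match_result.assignment[best[pix]]
    logp = mask_logits.reshape(n, gh * gw).log_softmax(axis=0)
    picked = logp[targets, pix]
    return -picked.mean()


def semantic_loss(sample: PanopticSample, semantic_logits: Tensor,
                  vocab: Vocabulary = DEFAULT_VOCABULARY) -> Tensor:
    """Mean per-pixel cross entropy over semantic classes (things + stuff).

    The stride-4 ground-truth class of a pixel is the semantic class with
    the largest summed area coverage (ties break towards the lowest class
    index, so the result is independent of segment ordering); void pixels
    (no coverage) are excluded.
    """
    semantic_logits = as_tensor(semantic_logits)
    ns, gh, gw = semantic_logits.shape
    masks_ds = downsample_masks(sample.masks, (gh, gw))
    class_cov = np.zeros((vocab.n_semantic, gh * gw), dtype=np.float32)
    for seg_mask, cid in zip(masks_ds, sample.classes):
        class_cov[vocab.semantic_index(int(cid))] += seg_mask.reshape(-1)
    best = class_cov.argmax(axis=0)
    covered = class_cov.max(axis=0) > 0.0
    pix = np.flatnonzero(covered)
    if len(pix) == 0:
        return Tensor(0.0)
    targets = best[pix]
    logp = semantic_logits.reshape(ns, gh * gw).log_softmax(axis=0)
    picked = logp[targets, pix]
    return -picked.mean()
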