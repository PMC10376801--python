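"""Seeded training loop minimizing the PQ-style loss plus auxiliaries.

Single-process, CPU-first: batches are processed image by image (the model
operates on one radiograph at a time) and gradients accumulate before each
Adam step.  Per-step loss breakdowns are appended to a JSON-lines log; the
checkpoint with the best training-set pixel F1 is kept alongside the final
one.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import confusion, metrics
from .inference import postprocess
from .losses import LossWeights, dice, match, pq_loss
from .model import MaskTransformer, ModelConfig
from .nn import Adam, cosine_lr, no_grad
from .phantom import PanopticSample
from .vocab import DEFAULT_VOCABULARY, Vocabulary

__all__ = ["TrainSettings", "TrainResult", "train", "evaluate_model"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainSettings:
    """Optimization hyper-parameters (desk scale: steps, not epochs)."""

    optimizer: str = "adam"
    learning_rate: float = 3e-4
    steps: int = 500
    batch_size: int = 2
    cosine_decay: bool = True
    alpha: float = 0.75
    loss_weights: LossWeights = field(default_factory=LossWeights)
    class_threshold: float = 0.4
    pixel_threshold: float = 0.4
    eval_every: int = 100
    log_every: int = 10
    early_stop_dice: float | None = None
    early_stop_f1: float | None = None

    def validate(self) -> None:
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.steps < 1 or self.batch_size < 1:
            raise ValueError("steps and batch_size must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")


@dataclass
class TrainResult:
    steps_run: int
    final_loss: float
    initial_loss: float
    mean_matched_dice: float
    pixel_f1: float
    best_f1: float
    checkpoint: Path
    best_checkpoint: Path
    log_path: Path


def evaluate_model(model: MaskTransformer, samples: list[PanopticSample],
                   class_threshold: float = 0.4, pixel_threshold: float = 0.4,
                   vocab: Vocabulary = DEFAULT_VOCABULARY
                   ) -> tuple[float, float]:
    """(mean matched soft Dice, mean pixel F1) over ``samples``.

    Soft Dice follows the usual convention: un-thresholded predicted mask
    scores against the binary ground-truth mask (rasterized at the stride-4
    grid by majority coverage).
    """
    dices, f1s = [], []
    with no_grad():
        for sample in samples:
            output = model.forward(sample.image)
            m = match(sample, output, vocab)
            for row, j in enumerate(m.assignment):
                gt_bin = (m.masks_ds[row] > 0.5).astype(np.float32)
                dices.append(float(dice(gt_bin,
                                        output.mask_scores.data[int(j)]).data))
            pred = postprocess(output, class_threshold=class_threshold,
                               pixel_threshold=pixel_threshold, vocab=vocab)
            f1s.append(metrics(*confusion(pred, sample, vocab)).f1)
    return (float(np.mean(dices)) if dices else 0.0,
            float(np.mean(f1s)) if f1s else 0.0)


def train(model_config: ModelConfig, samples: list[PanopticSample],
          settings: TrainSettings, out_dir: str | Path,
          vocab: Vocabulary = DEFAULT_VOCABULARY,
          seed: int = 0) -> TrainResult:
    """Train on ``samples``; returns final metrics and checkpoint paths.

    The batch order is drawn from ``seed`` and is independent of parameter
    initialization (which ``model_config.seed`` controls), so two runs with
    identical configs are bit-identical.
    """
    settings.validate()
    if not samples:
        raise ValueError("no training samples")
    for i, s in enumerate(samples):
        k_things = len(s.thing_indices(vocab))
        if k_things > model_config.n_slots:
            raise ValueError(
                f"sample {i} has {k_things} thing segments but the model has "
                f"only {model_config.n_slots} slots; increase n_slots")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = MaskTransformer(model_config)
    opt = Adam(model.parameters(), lr=settings.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    log_path = out_dir / "training_log.jsonl"
    best_path = out_dir / "checkpoint_best.npz"
    last_path = out_dir / "checkpoint_last.npz"

    n = len(samples)
    order = rng.permutation(n)
    cursor = 0
    best_f1 = -1.0
    initial_loss = final_loss = float("nan")
    mean_dice = pixel_f1 = 0.0
    steps_run = 0
    t0 = time.time()

    with log_path.open("w") as log:
        for step in range(settings.steps):
            batch_idx = []
            for _ in range(min(settings.batch_size, n)):
                if cursor >= n:
                    order = rng.permutation(n)
                    cursor = 0
                batch_idx.append(int(order[cursor]))
                cursor += 1

            opt.zero_grad()
            records = []
            loss_sum = None
            for bi in batch_idx:
                sample = samples[bi]
                output = model.forward(sample.image)
                breakdown = pq_loss(sample, output, alpha=settings.alpha,
                                    weights=settings.loss_weights, vocab=vocab)
                records.append(breakdown.to_dict())
                loss_sum = breakdown.loss if loss_sum is None \
                    else loss_sum + breakdown.loss
            loss = loss_sum * (1.0 / len(batch_idx))
            loss.backward()
            lr = cosine_lr(settings.learning_rate, step, settings.steps) \
                if settings.cosine_decay else settings.learning_rate
            opt.step(lr=lr)
            steps_run = step + 1

            step_loss = float(loss.data)
            if step == 0:
                initial_loss = step_loss
            final_loss = step_loss
            if step % settings.log_every == 0 or step == settings.steps - 1:
                mean_rec = {k: float(np.mean([r[k] for r in records]))
                            for k in records[0]}
                log.write(json.dumps({"step": step, "lr": lr,
                                      "loss": step_loss, **mean_rec}) + "\n")

            if (step + 1) % settings.eval_every == 0 or step == settings.steps - 1:
                mean_dice, pixel_f1 = evaluate_model(
                    model, samples, settings.class_threshold,
                    settings.pixel_threshold, vocab)
                log.write(json.dumps({"step": step, "eval_matched_dice":
                                      mean_dice, "eval_pixel_f1": pixel_f1})
                          + "\n")
                logger.info("step %d loss %.4f dice %.4f f1 %.4f (%.1fs)",
                            step, step_loss, mean_dice, pixel_f1,
                            time.time() - t0)
                if pixel_f1 > best_f1:
                    best_f1 = pixel_f1
                    model.save(best_path)
                if (settings.early_stop_dice is not None
                        and settings.early_stop_f1 is not None
                        and mean_dice >= settings.early_stop_dice
                        and pixel_f1 >= settings.early_stop_f1):
                    break

    model.save(last_path)
    if best_f1 < 0:
        model.save(best_path)
        best_f1 = pixel_f1
    return TrainResult(steps_run=steps_run, final_loss=final_loss,
                       initial_loss=initial_loss, mean_matched_dice=mean_dice,
                       pixel_f1=pixel_f1, best_f1=best_f1,
                       checkpoint=last_path, best_checkpoint=best_path,
                       log_path=log_path)
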