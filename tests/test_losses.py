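"""Set-prediction loss: similarity algebra, matching optimality, loss terms.

The Hungarian matching is checked against an exhaustive enumeration of all
injective assignments; loss values on constructed predictions are checked
against hand-derived closed forms.
"""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from panodent.losses import (
    LossWeights,
    dice,
    downsample_masks,
    instance_discrimination_loss,
    mask_id_cross_entropy,
    match,
    pq_loss,
    pq_loss_neg,
    pq_loss_pos,
    semantic_loss,
    similarity,
    similarity_matrix,
)
from panodent.model import ModelOutput
from panodent.nn import Adam, Tensor
from panodent.phantom import PanopticSample
from panodent.vocab import DEFAULT_VOCABULARY


def exhaustive_best_assignment(sim: np.ndarray) -> float:
    """Oracle: maximum total similarity over all injective assignments."""
    k, n = sim.shape
    best = -np.inf
    for perm in itertools.permutations(range(n), k):
        best = max(best, sum(sim[i, j] for i, j in enumerate(perm)))
    return best


def make_output(mask_scores, class_probs, image_hw=None) -> ModelOutput:
    """Assemble a ModelOutput from raw arrays (for loss tests)."""
    scores = np.asarray(mask_scores, dtype=np.float32)
    probs = np.asarray(class_probs, dtype=np.float32)
    n, gh, gw = scores.shape
    logits = np.log(np.clip(probs, 1e-30, None))
    mask_logits = np.log(np.clip(scores, 1e-30, None))
    sem = np.zeros((2, gh, gw), dtype=np.float32)
    emb = np.ones((4, gh, gw), dtype=np.float32) * 0.5
    return ModelOutput(
        mask_logits=Tensor(mask_logits), mask_scores=Tensor(scores),
        class_logits=Tensor(logits), class_probs=Tensor(probs),
        semantic_logits=Tensor(sem), embedding_map=Tensor(emb),
        image_hw=image_hw or (gh * 4, gw * 4))


def make_sample(masks, classes) -> PanopticSample:
    masks = np.asarray(masks, dtype=np.uint8)
    return PanopticSample(image=np.zeros(masks.shape[1:], np.float32),
                          masks=masks,
                          classes=np.asarray(classes, dtype=np.int64))


# --------------------------------------------------------------------------
# dice and similarity
# --------------------------------------------------------------------------

class TestDice:
    def test_identity_on_binary_mask(self):
        m = np.zeros((8, 8), np.float32)
        m[2:5, 3:6] = 1.0
        assert float(dice(m, m).data) == pytest.approx(1.0, abs=1e-5)

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((8, 8), np.float32)
        b = np.zeros((8, 8), np.float32)
        a[:2], b[6:] = 1.0, 1.0
        assert float(dice(a, b).data) == pytest.approx(0.0, abs=1e-7)

    def test_half_overlap_hand_count(self):
        """4-pixel squares overlapping in 2 pixels: 2*2/(4+4) = 0.5."""
        a = np.zeros((4, 4), np.float32)
        b = np.zeros((4, 4), np.float32)
        a[1:3, 0:2] = 1.0
        b[1:3, 1:3] = 1.0
        assert float(dice(a, b).data) == pytest.approx(0.5, abs=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_gradient_points_toward_overlap(self):
        m = np.zeros((4, 4), np.float32)
        m[1:3, 1:3] = 1.0
        pred = Tensor(np.full((4, 4), 0.5, np.float32), requires_grad=True)
        (-dice(m, pred)).backward()
        # increasing prediction inside the mask decreases the loss
        assert (pred.grad[1:3, 1:3] < 0).all()
        assert (pred.grad[0, :] > 0).all()


class TestSimilarity:
    def test_perfect_class_and_mask_gives_one(self):
        m = np.zeros((4, 4), np.float32)
        m[1:3, 1:3] = 1.0
        assert similarity(0, m, np.array([1.0, 0.0]), m) == \
            pytest.approx(1.0, abs=1e-5)

    def test_disjoint_masks_give_zero_any_class(self):
        a = np.zeros((4, 4), np.float32)
        b = np.zeros((4, 4), np.float32)
        a[0], b[3] = 1.0, 1.0
        assert similarity(0, a, np.array([0.9, 0.1]), b) == 0.0

    def test_product_of_half_probabilities(self):
        a = np.zeros((4, 4), np.float32)
        b = np.zeros((4, 4), np.float32)
        a[1:3, 0:2] = 1.0
        b[1:3, 1:3] = 1.0          # dice 0.5
        assert similarity(0, a, np.array([0.5, 0.5]), b) == \
            pytest.approx(0.25, abs=1e-6)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="class index"):
            similarity(1, np.zeros((2, 2)), np.array([0.5, 0.5]),
                       np.zeros((2, 2)))

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = (rng.random((6, 6)) > 0.5).astype(np.float32)
            b = rng.random((6, 6)).astype(np.float32)
            p = rng.dirichlet(np.ones(3))
            s = similarity(int(rng.integers(2)), a, p, b)
            assert 0.0 <= s <= 1.0


# --------------------------------------------------------------------------
# matching
# --------------------------------------------------------------------------

class TestMatching:
    def test_single_truth_matches_best_slot(self):
        sim = np.array([[0.2, 0.9, 0.1]])
        rows, cols = linear_sum_assignment(-sim)
        assert cols[0] == 1

    @pytest.mark.parametrize("trial", range(40))
    def test_hungarian_equals_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(trial)
        k = int(rng.integers(1, 6))
        n = int(rng.integers(k, 8))
        sim = rng.random((k, n))
        rows, cols = linear_sum_assignment(-sim)
        total = sim[rows, cols].sum()
        assert total == pytest.approx(exhaustive_best_assignment(sim),
                                      abs=1e-12)

    def test_all_zero_similarity_accepts_any_injective_assignment(self):
        sim = np.zeros((3, 5))
        rows, cols = linear_sum_assignment(-sim)
        assert len(set(cols)) == 3
        assert sim[rows, cols].sum() == 0.0

    def test_match_on_constructed_output(self):
        """Two teeth, three slots; slots 2 and 0 carry the right masks."""
        masks = np.zeros((3, 8, 8), np.uint8)
        masks[0, 0:4, 0:4] = 1
        masks[1, 4:8, 4:8] = 1
        masks[2] = 1 - masks[0] - masks[1]
        sample = make_sample(masks, [1, 1, 2])
        scores = np.full((3, 2, 2), 1e-4, np.float32)
        scores[2, 0, 0] = 1.0       # slot 2 covers tooth 0's quadrant
        scores[0, 1, 1] = 1.0       # slot 0 covers tooth 1's quadrant
        probs = np.array([[0.9, 0.1], [0.5, 0.5], [0.8, 0.2]], np.float32)
        out = make_output(scores, probs)
        result = match(sample, out)
        assert list(result.assignment) == [2, 0]
        assert list(result.unmatched) == [1]

    def test_more_truth_than_slots_raises(self):
        masks = np.zeros((4, 8, 8), np.uint8)
        for i in range(4):
            masks[i, 2 * i:2 * i + 2] = 1
        sample = make_sample(masks, [1, 1, 1, 2])
        out = make_output(np.full((2, 2, 2), 0.5), np.full((2, 2), 0.5))
        with pytest.raises(ValueError, match="n_slots"):
            match(sample, out)


# --------------------------------------------------------------------------
# loss terms
# --------------------------------------------------------------------------

def perfect_pair(k=3, grid=4):
    """Sample + output where k slots predict the k teeth exactly."""
    h = w = grid * 4
    masks = np.zeros((k + 1, h, w), np.uint8)
    for i in range(k):
        masks[i, :, i * 4:(i + 1) * 4] = 1
    masks[k] = 1 - masks[:k].sum(axis=0)
    sample = make_sample(masks, [1] * k + [2])
    n = k + 2
    scores = np.full((n, grid, grid * (k + 1) // 1), 0.0, np.float32)
    scores_grid = downsample_masks(masks[:k], (grid, w // 4))
    scores = np.zeros((n, grid, w // 4), np.float32)
    scores[:k] = scores_grid
    scores[k:] = (1.0 - scores_grid.sum(axis=0)) / 2.0
    probs = np.zeros((n, 2), np.float32)
    probs[:k, 0] = 1.0
    probs[k:, 1] = 1.0
    return sample, make_output(scores, probs, image_hw=(h, w))


class TestPQLossTerms:
    def test_perfect_prediction_gives_minus_k(self):
        for k in (1, 2, 4):
            sample, out = perfect_pair(k=k)
            m = match(sample, out)
            val = float(pq_loss_pos(m, sample, out).data)
            assert val == pytest.approx(-k, abs=1e-3)

    def test_vanishing_class_and_dice_contributes_zero(self):
        masks = np.zeros((2, 8, 8), np.uint8)
        masks[0, :, :4] = 1
        masks[1] = 1 - masks[0]
        sample = make_sample(masks, [1, 2])
        scores = np.zeros((2, 2, 2), np.float32)
        scores[1] = 1.0             # no mass on the tooth's slot
        probs = np.array([[0.0, 1.0], [0.0, 1.0]], np.float32)
        out = make_output(scores, probs)
        m = match(sample, out)
        assert float(pq_loss_pos(m, sample, out).data) == \
            pytest.approx(0.0, abs=1e-3)

    def test_two_mask_half_probability_hand_value(self):
        """p = (0.5, 0.5), Dice = (1, 1): loss = -(0.5+0.5) + 2 log 2."""
        sample, out = perfect_pair(k=2)
        probs = np.array([[0.5, 0.5]] * 4, np.float32)
        out2 = make_output(out.mask_scores.data, probs,
                           image_hw=out.image_hw)
        m = match(sample, out2)
        # masks here are exact at stride 4 so Dice = 1 per pair
        expected = -(0.5 + 0.5) + 2 * np.log(2.0)
        assert float(pq_loss_pos(m, sample, out2).data) == \
            pytest.approx(expected, abs=1e-3)

    def test_negative_term_zero_when_empty_predicts_empty(self):
        sample, out = perfect_pair(k=2)
        m = match(sample, out)
        assert float(pq_loss_neg(m, out).data) == pytest.approx(0.0, abs=1e-4)

    def test_negative_term_log2_for_half_empty_probability(self):
        masks = np.zeros((2, 8, 8), np.uint8)
        masks[0, :, :4] = 1
        masks[1] = 1 - masks[0]
        sample = make_sample(masks, [1, 2])
        scores = downsample_masks(masks[:1], (2, 2))
        scores = np.concatenate([scores, 1 - scores])
        probs = np.array([[1.0, 0.0], [0.5, 0.5]], np.float32)
        out = make_output(scores, probs)
        m = match(sample, out)
        assert len(m.unmatched) == 1
        assert float(pq_loss_neg(m, out).data) == \
            pytest.approx(np.log(2.0), abs=1e-4)

    def test_negative_term_empty_sum_when_k_equals_n(self):
        masks = np.zeros((3, 8, 8), np.uint8)
        masks[0, :, :4] = 1
        masks[1, :, 4:] = 1
        masks[2] = 0
        masks[2, 0, 0] = 0          # keep disjoint; background empty is fine
        sample = make_sample(masks[:2], [1, 1])
        scores = downsample_masks(masks[:2], (2, 2))
        out = make_output(scores, np.array([[1.0, 0.0], [1.0, 0.0]]))
        m = match(sample, out)
        assert len(m.unmatched) == 0
        assert float(pq_loss_neg(m, out).data) == 0.0


class TestPQLossComposition:
    @pytest.mark.parametrize("alpha", [0.0, 1.0])
    def test_alpha_extremes_select_single_term(self, alpha):
        sample, out = perfect_pair(k=2)
        probs = out.class_probs.data.copy()
        probs[2:] = [0.5, 0.5]      # unmatched slots imperfect on purpose
        out2 = make_output(out.mask_scores.data, probs, image_hw=out.image_hw)
        bd = pq_loss(sample, out2, alpha=alpha)
        if alpha == 1.0:
            assert bd.l_pq == pytest.approx(bd.l_pq_pos, abs=1e-6)
        else:
            assert bd.l_pq == pytest.approx(bd.l_pq_neg, abs=1e-6)

    def test_alpha_out_of_range_rejected(self):
        sample, out = perfect_pair(k=1)
        with pytest.raises(ValueError, match="alpha"):
            pq_loss(sample, out, alpha=1.5)

    def test_breakdown_identity(self):
        sample, out = perfect_pair(k=2)
        bd = pq_loss(sample, out, alpha=0.6)
        assert bd.l_pq == pytest.approx(
            0.6 * bd.l_pq_pos + 0.4 * bd.l_pq_neg, abs=1e-5)
        assert bd.total == pytest.approx(
            bd.l_pq + bd.l_instdisc + bd.l_maskid + bd.l_semantic, abs=1e-4)

    def test_invariance_under_ground_truth_permutation(self, tiny_model,
                                                       desk_sample):
        out = tiny_model.forward(desk_sample.image)
        base = pq_loss(desk_sample, out).total
        rng = np.random.default_rng(0)
        for _ in range(10):
            perm = rng.permutation(desk_sample.k)
            shuffled = PanopticSample(image=desk_sample.image,
                                      masks=desk_sample.masks[perm],
                                      classes=desk_sample.classes[perm])
            assert pq_loss(shuffled, out).total == \
                pytest.approx(base, rel=1e-4, abs=1e-4)

    def test_invariance_under_slot_relabeling(self, tiny_model, desk_sample):
        out = tiny_model.forward(desk_sample.image)
        base = pq_loss(desk_sample, out).total
        rng = np.random.default_rng(1)
        for _ in range(10):
            perm = rng.permutation(out.n_slots)
            shuffled = ModelOutput(
                mask_logits=Tensor(out.mask_logits.data[perm]),
                mask_scores=Tensor(out.mask_scores.data[perm]),
                class_logits=Tensor(out.class_logits.data[perm]),
                class_probs=Tensor(out.class_probs.data[perm]),
                semantic_logits=out.semantic_logits,
                embedding_map=out.embedding_map,
                image_hw=out.image_hw)
            assert pq_loss(desk_sample, shuffled).total == \
                pytest.approx(base, rel=1e-4, abs=1e-4)

    def test_increasing_matched_dice_never_increases_positive_term(self):
        """Monotonicity: sharpening the matched mask can only lower LPQpos."""
        masks = np.zeros((2, 8, 8), np.uint8)
        masks[0, :, :4] = 1
        masks[1] = 1 - masks[0]
        sample = make_sample(masks, [1, 2])
        probs = np.array([[0.8, 0.2], [0.1, 0.9]], np.float32)
        prev = np.inf
        for level in [0.3, 0.5, 0.7, 0.9, 1.0]:
            scores = np.zeros((2, 2, 2), np.float32)
            scores[0, :, 0] = level
            scores[1] = 1 - scores[0]
            out = make_output(scores, probs)
            m = match(sample, out)
            val = float(pq_loss_pos(m, sample, out).data)
            assert val <= prev + 1e-9
            prev = val


# --------------------------------------------------------------------------
# auxiliary losses
# --------------------------------------------------------------------------

class TestAuxiliaryLosses:
    def _sample_two_teeth(self):
        masks = np.zeros((3, 16, 16), np.uint8)
        masks[0, :, :8] = 1
        masks[1, :, 8:] = 1
        masks[2] = 0
        return make_sample(masks[:2], [1, 1])

    def test_instance_discrimination_uniform_embeddings_give_log_k(self):
        sample = self._sample_two_teeth()
        emb = np.full((4, 4, 4), 0.5, np.float32)
        val = float(instance_discrimination_loss(sample, Tensor(emb),
                                                 tau=1.0).data)
        assert val == pytest.approx(np.log(2.0), abs=1e-5)

    def test_instance_discrimination_separated_embeddings_approach_zero(self):
        sample = self._sample_two_teeth()
        emb = np.zeros((4, 4, 4), np.float32)
        emb[0, :, :2] = 1.0
        emb[1, :, 2:] = 1.0
        val = float(instance_discrimination_loss(sample, Tensor(emb),
                                                 tau=0.05).data)
        assert val < 1e-6

    def test_instance_discrimination_zero_without_things(self):
        masks = np.ones((1, 8, 8), np.uint8)
        sample = make_sample(masks, [2])
        assert float(instance_discrimination_loss(
            sample, Tensor(np.ones((4, 2, 2)))).data) == 0.0

    def test_single_instance_has_no_negatives(self):
        masks = np.zeros((2, 8, 8), np.uint8)
        masks[0, :4] = 1
        masks[1] = 1 - masks[0]
        sample = make_sample(masks, [1, 2])
        val = float(instance_discrimination_loss(
            sample, Tensor(np.random.default_rng(0).random((4, 2, 2)))).data)
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_mask_id_perfect_one_hot_scores_give_zero(self):
        sample, out = perfect_pair(k=2)
        m = match(sample, out)
        val = float(mask_id_cross_entropy(m, sample, out.mask_logits).data)
        assert val == pytest.approx(0.0, abs=1e-3)

    def test_mask_id_uniform_scores_give_log_n(self):
        sample, out = perfect_pair(k=2)
        m = match(sample, out)
        n = out.n_slots
        uniform = Tensor(np.zeros_like(out.mask_logits.data))
        val = float(mask_id_cross_entropy(m, sample, uniform).data)
        assert val == pytest.approx(np.log(n), abs=1e-5)

    def test_semantic_uniform_logits_give_log_classes(self):
        sample, out = perfect_pair(k=2)
        uniform = Tensor(np.zeros_like(out.semantic_logits.data))
        val = float(semantic_loss(sample, uniform).data)
        assert val == pytest.approx(np.log(2.0), abs=1e-5)

    def test_semantic_saturated_correct_logits_approach_zero(self):
        sample, out = perfect_pair(k=1)
        gh, gw = out.grid_hw
        sem_gt = downsample_masks(sample.masks, (gh, gw)).argmax(axis=0)
        cls = np.array([0, 1])[sem_gt]          # tooth=0, background=1
        logits = np.full((2, gh, gw), -50.0, np.float32)
        for c in (0, 1):
            logits[c][cls == c] = 50.0
        val = float(semantic_loss(sample, Tensor(logits)).data)
        assert val == pytest.approx(0.0, abs=1e-5)


class TestGradientSmoke:
    def test_one_adam_step_decreases_total_loss(self, desk_sample):
        from panodent.model import MaskTransformer, ModelConfig
        from conftest import TINY_MODEL
        model = MaskTransformer(ModelConfig(**TINY_MODEL, seed=7))
        opt = Adam(model.parameters(), lr=1e-3)
        out = model.forward(desk_sample.image)
        before = pq_loss(desk_sample, out)
        before.loss.backward()
        opt.step()
        after = pq_loss(desk_sample, model.forward(desk_sample.image))
        assert after.total < before.total
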