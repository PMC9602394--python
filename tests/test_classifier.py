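"""Entity-word detection, span enumeration/representation, joint loss, decoding."""

import math

import numpy as np
import pytest

from nestner.autograd import Tensor
from nestner.classifier import (LossTerms, SpanHeads, decode_entities,
                                entity_word_labels, enumerate_spans, joint_loss,
                                represent_spans, runs_from_mask)
from nestner.corpus import NestedEntity, entities_to_tags

from conftest import FRAGMENT_ENTITIES


def sig(z):
    return 1.0 / (1.0 + math.exp(-z))


class TestEntityWordLabels:
    def test_fragment_labels(self):
        y = entity_word_labels(7, FRAGMENT_ENTITIES)
        np.testing.assert_array_equal(y, [1, 1, 1, 1, 1, 0, 0])

    def test_probability_exactly_half_is_not_an_entity_word(self, rng):
        heads = SpanHeads(4, 2, rng)
        heads.detector.weight.data = np.zeros((4, 1))
        heads.detector.bias.data = np.zeros(1)
        p = heads.detect(Tensor(rng.normal(size=(1, 3, 4)))).numpy()
        np.testing.assert_array_equal(p, 0.5)      # sigmoid(0) exactly
        assert not np.any(p > 0.5)                 # strict threshold: no entity words


class TestEnumerateSpans:
    def test_run_of_five_yields_all_fifteen_subspans(self):
        spans = enumerate_spans(np.array([1, 1, 1, 1, 1, 0, 0]))
        brute = [(i, j) for i in range(5) for j in range(i + 1, 6)]
        assert sorted(spans) == sorted(brute)
        assert len(spans) == 15

    def test_short_run_contributes_only_itself(self):
        assert enumerate_spans(np.array([1, 1, 0, 0])) == [(0, 2)]

    def test_empty_mask_yields_no_candidates(self):
        assert enumerate_spans(np.zeros(6)) == []

    def test_multiple_runs(self):
        spans = enumerate_spans(np.array([1, 0, 1, 1, 1]))
        assert (0, 1) in spans
        assert len(spans) == 1 + 6  # singleton run + n(n+1)/2 for n=3

    def test_candidate_count_monotone_in_mask(self, rng):
        for _ in range(50):
            mask = rng.integers(0, 2, size=10)
            n0 = len(enumerate_spans(mask))
            zeros = np.flatnonzero(mask == 0)
            if zeros.size == 0:
                continue
            mask2 = mask.copy()
            mask2[rng.choice(zeros)] = 1
            assert len(enumerate_spans(mask2)) >= n0

    def test_runs_from_mask(self):
        assert runs_from_mask(np.array([0, 1, 1, 0, 1])) == [(1, 3), (4, 5)]


class TestRepresentSpans:
    def test_single_token_span_repeats_boundary(self, rng):
        H = Tensor(rng.normal(size=(1, 4, 3)))
        out = represent_spans(H, [[(2, 3)]]).numpy()[0]
        v = H.numpy()[0, 2]
        np.testing.assert_allclose(out, np.concatenate([v, v, v]), atol=1e-12)

    def test_identical_tokens_give_repeated_vector(self, rng):
        v = rng.normal(size=3)
        H = Tensor(np.tile(v, (1, 4, 1)))
        out = represent_spans(H, [[(0, 4)]]).numpy()[0]
        np.testing.assert_allclose(out, np.concatenate([v, v, v]), atol=1e-12)

    def test_interior_mean_matches_direct_summation(self, rng):
        Hv = rng.normal(size=(2, 6, 4))
        spans = [[(1, 4), (0, 6)], [(2, 3)]]
        out = represent_spans(Tensor(Hv), spans).numpy()
        k = 0
        for b, sl in enumerate(spans):
            for (i, j) in sl:
                mean = sum(Hv[b, t] for t in range(i, j)) / (j - i)
                np.testing.assert_allclose(out[k, :4], Hv[b, i], atol=1e-12)
                np.testing.assert_allclose(out[k, 4:8], mean, atol=1e-12)
                np.testing.assert_allclose(out[k, 8:], Hv[b, j - 1], atol=1e-12)
                k += 1

    def test_out_of_range_span_rejected(self, rng):
        H = Tensor(rng.normal(size=(1, 4, 3)))
        with pytest.raises(IndexError):
            represent_spans(H, [[(2, 5)]])


class TestClassify:
    def test_probabilities_sum_to_one(self, rng):
        heads = SpanHeads(4, 3, rng)
        probs = heads.classify(Tensor(rng.normal(size=(7, 12)))).numpy()
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-12)
        assert probs.shape == (7, 4)  # 3 types + non-entity

    def test_zero_parameters_give_uniform_probabilities(self, rng):
        heads = SpanHeads(4, 3, rng)
        for p in heads.classifier.parameters():
            p.data = np.zeros_like(p.data)
        probs = heads.classify(Tensor(rng.normal(size=(5, 12)))).numpy()
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)


class TestJointLoss:
    def _token_loss(self, y, p, lam=0.5):
        prob = Tensor(np.array([[float(p)]]))
        return joint_loss(prob, np.array([[float(y)]]), np.ones((1, 1)),
                          None, None, lam)

    def test_perfect_prediction_has_zero_loss(self):
        assert self._token_loss(1, 1 - 1e-15).token_loss.item() == pytest.approx(0.0, abs=1e-9)

    def test_half_probability_costs_ln_two(self):
        assert self._token_loss(1, 0.5).token_loss.item() == pytest.approx(math.log(2), abs=1e-9)

    def test_lambda_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="λ|lambda|weight"):
            self._token_loss(1, 0.5, lam=1.0)

    def test_two_token_one_span_hand_oracle(self):
        # tokens: y = (1, 0), p = (0.9, 0.2); one candidate span with
        # 3 classes, logits chosen so softmax is computable by hand
        p = Tensor(np.array([[0.9, 0.2]]))
        y = np.array([[1.0, 0.0]])
        logits = Tensor(np.array([[0.5, -0.1, 0.3]]))
        labels = np.array([1])
        lam = 0.5
        terms = joint_loss(p, y, np.ones((1, 2)), logits, labels, lam)
        ll = -(math.log(0.9) + math.log(0.8)) / 2
        z = [math.exp(v) for v in (0.5, -0.1, 0.3)]
        lh = -math.log(z[1] / sum(z))
        assert terms.token_loss.item() == pytest.approx(ll, abs=1e-9)
        assert terms.span_loss.item() == pytest.approx(lh, abs=1e-9)
        assert terms.total.item() == pytest.approx(lam * ll + (1 - lam) * lh, abs=1e-9)

    def test_sum_reduction_keeps_raw_sums(self):
        p = Tensor(np.array([[0.5, 0.5]]))
        y = np.array([[1.0, 1.0]])
        terms = joint_loss(p, y, np.ones((1, 2)), None, None, 0.5, reduction="sum")
        assert terms.token_loss.item() == pytest.approx(2 * math.log(2), abs=1e-9)

    def test_lambda_endpoints_control_gradient_flow(self, rng):
        # as λ -> 1 span-classifier gradients vanish; as λ -> 0 detector's do
        W_det = Tensor(rng.normal(size=(4, 1)), requires_grad=True)
        W_cls = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        H = Tensor(rng.normal(size=(2, 4)))

        def run(lam):
            W_det.grad = W_cls.grad = None
            p = (H @ W_det).sigmoid().reshape(1, 2)
            logits = H @ W_cls
            terms = joint_loss(p, np.array([[1.0, 0.0]]), np.ones((1, 2)),
                               logits, np.array([0, 2]), lam)
            terms.total.backward()
            return np.abs(W_det.grad).max(), np.abs(W_cls.grad).max()

        det_hi, cls_hi = run(1 - 1e-9)
        det_lo, cls_lo = run(1e-9)
        assert cls_hi < 1e-8 < det_hi
        assert det_lo < 1e-8 < cls_lo


class TestDecodeEntities:
    def test_non_entity_argmax_is_discarded(self):
        probs = np.array([[0.1, 0.2, 0.7], [0.6, 0.3, 0.1]])
        out = decode_entities([(0, 2), (3, 4)], probs, ["DNA", "RNA"])
        assert out == {NestedEntity(3, 4, "DNA", 1)}

    def test_crossing_spans_resolved_by_probability(self):
        probs = np.array([[0.9, 0.0, 0.1], [0.0, 0.8, 0.2]])
        out = decode_entities([(0, 3), (2, 5)], probs, ["DNA", "RNA"])
        assert out == {NestedEntity(0, 3, "DNA", 1)}  # higher-probability span wins

    def test_duplicate_interval_keeps_single_type(self):
        probs = np.array([[0.9, 0.0, 0.1], [0.0, 0.85, 0.15]])
        out = decode_entities([(1, 3), (1, 3)], probs, ["DNA", "RNA"])
        assert out == {NestedEntity(1, 3, "DNA", 1)}

    def test_nesting_depth_derived_from_containment(self):
        probs = np.array([[0.9, 0.0, 0.1], [0.0, 0.8, 0.2]])
        out = decode_entities([(0, 5), (1, 3)], probs, ["DNA", "RNA"])
        assert out == {NestedEntity(0, 5, "DNA", 2), NestedEntity(1, 3, "RNA", 1)}

    def test_decoded_sets_always_encode_as_layered_bio(self, rng):
        type_names = ["A", "B", "C"]
        for _ in range(100):
            mask = rng.integers(0, 2, size=12)
            spans = enumerate_spans(mask)
            if not spans:
                continue
            probs = rng.dirichlet(np.ones(4), size=len(spans))
            out = decode_entities(spans, probs, type_names, max_depth=4)
            entities_to_tags(out, 12, 4)  # raises if same-depth overlap survived
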