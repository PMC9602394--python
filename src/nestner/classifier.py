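"""Entity-word detection, fine-grained span division and span classification.

Decoding proceeds in three stages.  A binary detector scores every token
with the probability p of lying inside or on the boundary of some entity
(entity word iff p > 0.5, strictly).  Maximal runs of consecutive entity
words become candidate intervals; runs of at least ``min_fine_len`` tokens
are additionally divided into *all* of their contiguous sub-intervals so
that nested inner mentions can be recovered, while shorter runs contribute
only themselves.  Each candidate span ⟨i, j⟩ is represented as
``S(i,j) = [H_i ; mean(H_i..H_j) ; H_j]`` — left boundary, interior average,
right boundary — and classified by a linear+softmax head over the entity
types plus one non-entity class.

Training combines a token-level binary cross-entropy L_l with the span
cross-entropy L_h as ``L = λ·L_l + (1−λ)·L_h``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat
from .corpus import NestedEntity, assign_depths
from .nn import Linear, MLP, Module

__all__ = [
    "entity_word_labels",
    "runs_from_mask",
    "enumerate_spans",
    "represent_spans",
    "SpanHeads",
    "joint_loss",
    "decode_entities",
    "LossTerms",
]


def entity_word_labels(length: int, entities: set[NestedEntity]) -> np.ndarray:
    """Binary gold labels: y_i = 1 iff token i lies in any entity, any depth."""
    y = np.zeros(length, dtype=np.float64)
    for ent in entities:
        y[ent.start:ent.end] = 1.0
    return y


def runs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive 1s, as half-open intervals."""
    runs = []
    start = None
    for i, m in enumerate(list(mask) + [0]):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    return runs


def enumerate_spans(mask: np.ndarray, min_fine_len: int = 3) -> list[tuple[int, int]]:
    """Candidate intervals from an entity-word mask.

    Every maximal run is a candidate; runs of length >= ``min_fine_len``
    additionally contribute all n(n+1)/2 contiguous sub-intervals (the
    fine-grained division that exposes nested inner entities).
    """
    out: list[tuple[int, int]] = []
    for s, e in runs_from_mask(mask):
        if e - s >= min_fine_len:
            for i in range(s, e):
                for j in range(i + 1, e + 1):
                    out.append((i, j))
        else:
            out.append((s, e))
    return out


def represent_spans(H: Tensor, spans_per_sentence: list[list[tuple[int, int]]]) -> Tensor:
    """Stack span representations S(i,j) = [H_i ; mean H_i..j ; H_j].

    ``H`` is the (B, T, D) sentence representation; the interior mean is
    computed from a cumulative sum along the time axis so that an arbitrary
    number of spans costs a single gather.
    Returns a (n_spans_total, 3D) tensor ordered sentence-major.
    """
    B, T, D = H.shape
    flat = H.reshape(B * T, D)
    cs = H.cumsum(axis=1).reshape(B * T, D)
    starts, ends, start_minus1, lengths, has_prev = [], [], [], [], []
    for b, spans in enumerate(spans_per_sentence):
        for (i, j) in spans:
            if not (0 <= i < j <= T):
                raise IndexError(f"span ({i}, {j}) out of range for length {T}")
            starts.append(b * T + i)
            ends.append(b * T + j - 1)
            start_minus1.append(b * T + i - 1 if i > 0 else b * T)
            has_prev.append(1.0 if i > 0 else 0.0)
            lengths.append(j - i)
    if not starts:
        raise ValueError("no spans to represent")
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    left = flat.take_rows(starts)
    right = flat.take_rows(ends)
    upper = cs.take_rows(ends)
    lower = cs.take_rows(np.asarray(start_minus1)) * Tensor(np.asarray(has_prev)[:, None])
    mean = (upper - lower) / Tensor(np.asarray(lengths, dtype=np.float64)[:, None])
    return concat([left, mean, right], axis=-1)


class SpanHeads(Module):
    """Detector (linear→sigmoid) and span classifier (FC layer→softmax layer).

    The classifier passes S(i,j) through a fully connected tanh layer before
    the softmax output layer; boundary decisions ("starts exactly at the run
    boundary", "type changes here") are conjunctions of features that a bare
    linear map cannot express.
    """

    def __init__(self, d_model: int, n_types: int, rng: np.random.Generator,
                 classifier_hidden: int | None = None):
        self.n_types = n_types
        self.detector = Linear(d_model, 1, rng)
        hidden = classifier_hidden if classifier_hidden is not None else d_model
        self.classifier = MLP(3 * d_model, hidden, n_types + 1, rng)  # + non-entity class

    def detect(self, H: Tensor) -> Tensor:
        """Per-token entity-word probability p, shape (B, T)."""
        B, T, D = H.shape
        return self.detector(H.reshape(B * T, D)).sigmoid().reshape(B, T)

    def classify(self, span_repr: Tensor) -> Tensor:
        """Class probabilities over n_types + 1 (last index = non-entity)."""
        return self.classifier(span_repr).softmax(axis=-1)

    def classify_logits(self, span_repr: Tensor) -> Tensor:
        return self.classifier(span_repr)


@dataclass
class LossTerms:
    token_loss: Tensor   # L_l, binary cross-entropy of the detector
    span_loss: Tensor    # L_h, cross-entropy of the span classifier
    weight: float        # λ
    total: Tensor        # λ·L_l + (1−λ)·L_h

    def as_floats(self) -> tuple[float, float, float]:
        return (self.token_loss.item(), self.span_loss.item(), self.total.item())


def joint_loss(p: Tensor, gold_y: np.ndarray, token_mask: np.ndarray,
               span_logits: Tensor | None, span_labels: np.ndarray | None,
               lam: float, reduction: str = "mean") -> LossTerms:
    """Weighted multi-task loss L = λ·L_l + (1−λ)·L_h.

    ``p`` is the (B, T) detector probability, ``gold_y``/``token_mask`` the
    matching binary labels and padding mask; ``span_logits`` are unnormalized
    class scores for the candidate spans, ``span_labels`` integer gold classes
    (n_types = non-entity).  With ``reduction="mean"`` each term is averaged
    over its own support before weighting; ``"sum"`` keeps raw sums.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError(f"loss weight λ must be in (0, 1), got {lam}")
    if reduction not in ("mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    eps = 1e-12
    y = Tensor(gold_y)
    m = Tensor(token_mask)
    p_c = p.clip(eps, 1.0 - eps)
    per_token = -(y * p_c.log() + (1.0 - y) * (1.0 - p_c).log()) * m
    n_tokens = max(float(token_mask.sum()), 1.0)
    token_loss = per_token.sum() / n_tokens if reduction == "mean" else per_token.sum()

    if span_logits is not None and span_labels is not None and span_labels.size > 0:
        logp = span_logits.log_softmax(axis=-1)
        rows = np.arange(span_labels.size)
        picked = logp[rows, np.asarray(span_labels, dtype=np.int64)]
        span_loss = -picked.mean() if reduction == "mean" else -picked.sum()
    else:
        span_loss = Tensor(0.0)

    total = lam * token_loss + (1.0 - lam) * span_loss
    return LossTerms(token_loss=token_loss, span_loss=span_loss, weight=lam, total=total)


def _resolve_conflicts(cands: list[tuple[tuple[int, int], str, float]]
                       ) -> list[tuple[int, int, str]]:
    """Drop crossing or duplicate spans, keeping the higher-probability one.

    Two accepted spans must be nested or disjoint — partial overlap (and a
    second type on an identical interval) cannot be expressed in layered
    BIO.  Ties break toward earlier start, then shorter span.
    """
    order = sorted(cands, key=lambda c: (-c[2], c[0][0], c[0][1] - c[0][0]))
    kept: list[tuple[tuple[int, int], str]] = []
    for (s, e), t, _prob in order:
        ok = True
        for (s2, e2), _ in kept:
            if (s, e) == (s2, e2):
                ok = False
                break
            crossing = s < s2 < e < e2 or s2 < s < e2 < e
            if crossing:
                ok = False
                break
        if ok:
            kept.append(((s, e), t))
    return [(s, e, t) for (s, e), t in kept]


def decode_entities(span_list: list[tuple[int, int]],
                    class_probs: np.ndarray, type_names: list[str],
                    max_depth: int = 4) -> set[NestedEntity]:
    """Turn classified candidate spans into a legal nested-entity set.

    Candidates whose argmax is the non-entity class are discarded; the rest
    are de-conflicted (no crossing, no duplicate interval) and given depths
    by containment, innermost = 1, capped at ``max_depth``.
    """
    n_types = len(type_names)
    cands: list[tuple[tuple[int, int], str, float]] = []
    for (i, j), probs in zip(span_list, class_probs):
        k = int(np.argmax(probs))
        if k == n_types:  # non-entity
            continue
        cands.append(((i, j), type_names[k], float(probs[k])))
    spans = _resolve_conflicts(cands)
    entities = assign_depths(spans)
    return {e for e in entities if e.depth <= max_depth}
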