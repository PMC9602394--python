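"""The dual-stream nested-entity recognizer assembled end to end.

Pipeline per batch: word/char embedding → per-stream sentence BiLSTMs →
low-level gated complementation (CCM/WEM) → per-stream multi-head
self-attention → high-level double complementation → per-token sentence
representation H_i → entity-word detector + fine-grained span classifier.
Every block can be switched off independently for ablation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .autograd import Tensor, concat
from .classifier import (LossTerms, SpanHeads, decode_entities, entity_word_labels,
                         enumerate_spans, joint_loss, represent_spans)
from .complement import HighLevelComplement, LowLevelComplement
from .corpus import NestedEntity, Vocabulary
from .encoder import DualStreamEncoder, batch_to_ids
from .nn import Dropout, Module, MultiHeadSelfAttention

__all__ = ["ModelConfig", "NestedNERModel"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The reference configuration uses 200-dimensional word and character
    embeddings, 200 hidden LSTM units per direction, 8 attention heads,
    dropout 0.5 and λ = 0.5; the small profile keeps training on a single
    CPU fast while preserving every architectural element.
    """

    word_dim: int = 200
    char_raw_dim: int = 50
    char_hidden: int = 100      # e^c dimension = 2 * char_hidden
    hidden: int = 200           # per direction; h^w, h^c are 2 * hidden wide
    n_heads: int = 8
    mlp_hidden: int | None = None
    dropout: float = 0.5
    lam: float = 0.5
    min_fine_len: int = 3
    neg_ratio: float = 3.0
    max_depth: int = 4
    use_ccm: bool = True
    use_wem: bool = True
    use_mhsm: bool = True
    use_hbcl: bool = True
    hbcl_printed_asymmetry: bool = False
    loss_reduction: str = "mean"

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        base = dict(word_dim=32, char_raw_dim=12, char_hidden=8, hidden=16,
                    n_heads=4, dropout=0.2)
        base.update(overrides)
        return cls(**base)

    def ablated(self, **flags) -> "ModelConfig":
        return replace(self, **flags)


class NestedNERModel(Module):
    """End-to-end model over fixed word/char vocabularies and a type set."""

    def __init__(self, cfg: ModelConfig, word_vocab: Vocabulary,
                 char_vocab: Vocabulary, type_names: list[str],
                 seed: int = 0, pretrained: np.ndarray | None = None):
        self.cfg = cfg
        self.word_vocab = word_vocab
        self.char_vocab = char_vocab
        self.type_names = list(type_names)
        rng = np.random.default_rng(seed)
        self.encoder = DualStreamEncoder(
            len(word_vocab), len(char_vocab), word_dim=cfg.word_dim,
            char_raw_dim=cfg.char_raw_dim, char_hidden=cfg.char_hidden,
            hidden=cfg.hidden, rng=rng, pretrained=pretrained)
        d_stream = self.encoder.out_dim
        self.low = LowLevelComplement(d_stream, d_stream, rng,
                                      mlp_hidden=cfg.mlp_hidden,
                                      use_ccm=cfg.use_ccm, use_wem=cfg.use_wem)
        dim_w, dim_c = self.low.out_dim_w, self.low.out_dim_c
        if cfg.use_mhsm:
            self.attn_w = MultiHeadSelfAttention(dim_w, cfg.n_heads, rng)
            self.attn_c = MultiHeadSelfAttention(dim_c, cfg.n_heads, rng)
        if cfg.use_hbcl:
            self.high = HighLevelComplement(dim_w, dim_c, rng,
                                            printed_asymmetry=cfg.hbcl_printed_asymmetry)
            self.d_model = self.high.out_dim
        else:
            self.d_model = dim_w + dim_c
        self.heads = SpanHeads(self.d_model, len(type_names), rng)
        self.dropout = Dropout(cfg.dropout, np.random.default_rng(seed + 1))
        self._neg_rng = np.random.default_rng(seed + 2)

    # ------------------------------------------------------------- plumbing
    def train_mode(self, flag: bool = True) -> None:
        self.dropout.training = flag

    def represent(self, sentences: list[list[str]]) -> tuple[Tensor, np.ndarray, np.ndarray]:
        """Sentence representation H (B, T, D), lengths and padding mask (B, T)."""
        word_ids, lengths, char_ids, char_lengths = batch_to_ids(
            sentences, self.word_vocab, self.char_vocab)
        h_w, h_c = self.encoder(word_ids, lengths, char_ids, char_lengths,
                                dropout=self.dropout)
        hbar_w, hbar_c = self.low(h_w, h_c)
        T = word_ids.shape[1]
        pad_mask = (np.arange(T)[None, :] < lengths[:, None])
        if self.cfg.use_mhsm:
            # residual around attention: keeps per-token identity intact while
            # the attention weights are still diffuse
            hbar_w = hbar_w + self.attn_w(hbar_w, pad_mask)
            hbar_c = hbar_c + self.attn_c(hbar_c, pad_mask)
        if self.cfg.use_hbcl:
            H = self.high(hbar_w, hbar_c)
        else:
            H = concat([hbar_w, hbar_c], axis=-1)
        H = self.dropout(H)
        return H, lengths, pad_mask.astype(np.float64)

    # ------------------------------------------------------------- training
    def _training_candidates(self, lengths: np.ndarray,
                             gold: list[set[NestedEntity]]
                             ) -> tuple[list[list[tuple[int, int]]], np.ndarray]:
        """Candidate spans from the *gold* entity-word mask (teacher forcing).

        Gold spans keep their type label; other candidates are labeled
        non-entity and subsampled to at most ``neg_ratio`` per positive
        (at least one negative is kept when any exists).
        """
        n_types = len(self.type_names)
        type_idx = {t: k for k, t in enumerate(self.type_names)}
        spans_per_sentence: list[list[tuple[int, int]]] = []
        labels: list[int] = []
        for length, ents in zip(lengths, gold):
            y = entity_word_labels(int(length), ents)
            cands = enumerate_spans(y, self.cfg.min_fine_len)
            gold_spans = {e.span: type_idx[e.type] for e in ents}
            pos = [c for c in cands if c in gold_spans]
            neg = [c for c in cands if c not in gold_spans]
            # every gold span inside a run is enumerable; keep all positives
            k = int(min(len(neg), max(self.cfg.neg_ratio * max(len(pos), 1), 1)))
            if len(neg) > k:
                pick = self._neg_rng.choice(len(neg), size=k, replace=False)
                neg = [neg[i] for i in sorted(pick)]
            chosen = pos + neg
            spans_per_sentence.append(chosen)
            labels.extend([gold_spans.get(c, n_types) for c in chosen])
        return spans_per_sentence, np.asarray(labels, dtype=np.int64)

    def loss(self, sentences: list[list[str]], gold: list[set[NestedEntity]]) -> LossTerms:
        H, lengths, pad_mask = self.represent(sentences)
        p = self.heads.detect(H)
        B, T = p.shape
        gold_y = np.zeros((B, T))
        for b, (length, ents) in enumerate(zip(lengths, gold)):
            gold_y[b, :int(length)] = entity_word_labels(int(length), ents)
        spans_per_sentence, labels = self._training_candidates(lengths, gold)
        if labels.size:
            reprs = represent_spans(H, spans_per_sentence)
            logits = self.heads.classify_logits(reprs)
        else:
            logits = None
            labels = None
        return joint_loss(p, gold_y, pad_mask, logits, labels,
                          self.cfg.lam, self.cfg.loss_reduction)

    # ------------------------------------------------------------ inference
    def predict(self, sentences: list[list[str]]) -> list[set[NestedEntity]]:
        """Detect → enumerate → classify → decode a legal nested-entity set."""
        was_training = self.dropout.training
        self.train_mode(False)
        try:
            H, lengths, _ = self.represent(sentences)
            p = self.heads.detect(H).numpy()
            out: list[set[NestedEntity]] = []
            spans_per_sentence: list[list[tuple[int, int]]] = []
            for b, length in enumerate(lengths):
                mask = (p[b, :int(length)] > 0.5).astype(int)  # strict: p = 0.5 is not an entity word
                spans_per_sentence.append(enumerate_spans(mask, self.cfg.min_fine_len))
            if not any(spans_per_sentence):
                return [set() for _ in sentences]
            reprs = represent_spans(H, spans_per_sentence)
            probs = self.heads.classify(reprs).numpy()
            offset = 0
            for b, spans in enumerate(spans_per_sentence):
                chunk = probs[offset:offset + len(spans)]
                offset += len(spans)
                out.append(decode_entities(spans, chunk, self.type_names,
                                           max_depth=self.cfg.max_depth))
            return out
        finally:
            self.train_mode(was_training)

    def detect_mask(self, sentences: list[list[str]]) -> list[np.ndarray]:
        """Binary entity-word masks per sentence (inference mode)."""
        was_training = self.dropout.training
        self.train_mode(False)
        try:
            H, lengths, _ = self.represent(sentences)
            p = self.heads.detect(H).numpy()
            return [(p[b, :int(n)] > 0.5).astype(int) for b, n in enumerate(lengths)]
        finally:
            self.train_mode(was_training)
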