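"""Dual-stream token encoding: word-level and character-level context features.

Every token gets two embeddings — a word embedding looked up in a (possibly
pretrained) table, and a character-level embedding produced by a BiLSTM over
the token's characters.  Each embedding sequence is then contextualized by
its own sentence-level BiLSTM, yielding the two per-token feature streams
h^w and h^c that the complementation blocks exchange information between.
Out-of-vocabulary words share a single trainable UNK vector.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat
from .corpus import Vocabulary
from .nn import BiLSTM, Embedding, Module, reverse_padded

__all__ = ["CharEncoder", "DualStreamEncoder", "batch_to_ids"]


def batch_to_ids(sentences: list[list[str]], word_vocab: Vocabulary,
                 char_vocab: Vocabulary, max_word_len: int | None = None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pad a batch of tokenized sentences into id arrays.

    Returns ``(word_ids (B,T), lengths (B,), char_ids (B*T, C), char_lengths
    (B*T,))``.  Padding tokens are given a single PAD character so the char
    encoder can run over the full rectangle; their outputs are masked out
    downstream.
    """
    B = len(sentences)
    T = max((len(s) for s in sentences), default=1) or 1
    lengths = np.array([len(s) for s in sentences], dtype=np.int64)
    word_ids = np.full((B, T), word_vocab.pad_id, dtype=np.int64)
    C = max((len(tok) for s in sentences for tok in s), default=1) or 1
    if max_word_len is not None:
        C = min(C, max_word_len)
    char_ids = np.full((B * T, C), char_vocab.pad_id, dtype=np.int64)
    char_lengths = np.ones(B * T, dtype=np.int64)
    for b, sent in enumerate(sentences):
        for t, tok in enumerate(sent):
            if not tok:
                raise ValueError(f"empty token at sentence {b}, position {t}")
            word_ids[b, t] = word_vocab[tok]
            chars = tok[:C]
            char_lengths[b * T + t] = len(chars)
            for c, ch in enumerate(chars):
                char_ids[b * T + t, c] = char_vocab[ch]
    return word_ids, lengths, char_ids, char_lengths


class CharEncoder(Module):
    """Character BiLSTM producing one fixed-size vector per token.

    The token vector is the concatenation of the last forward hidden state
    and the backward hidden state at the first character, so its dimension
    is ``2 * hidden`` regardless of word length.
    """

    def __init__(self, n_chars: int, char_raw_dim: int, char_hidden: int,
                 rng: np.random.Generator):
        self.table = Embedding(n_chars, char_raw_dim, rng)
        self.bilstm = BiLSTM(char_raw_dim, char_hidden, rng)
        self.out_dim = 2 * char_hidden

    def __call__(self, char_ids: np.ndarray, char_lengths: np.ndarray) -> Tensor:
        x = self.table(char_ids)  # (N, C, raw)
        h = self.bilstm.fwd(x, char_lengths)  # (N, C, H) forward pass
        rev = reverse_padded(x, char_lengths)
        # backward pass over reversed characters: its state at position len-1
        # is the backward state at the first character of the original word
        h_b = self.bilstm.bwd(rev, char_lengths)
        last = np.minimum(char_lengths, h.shape[1]) - 1
        idx = last[:, None]
        fwd_last = h.take_along_time(np.broadcast_to(idx, (h.shape[0], 1)))[:, 0, :]
        bwd_first = h_b.take_along_time(np.broadcast_to(idx, (h.shape[0], 1)))[:, 0, :]
        return concat([fwd_last, bwd_first], axis=1)  # (N, 2H)


class DualStreamEncoder(Module):
    """Word stream and character stream, each with its own sentence BiLSTM."""

    def __init__(self, n_words: int, n_chars: int, *, word_dim: int,
                 char_raw_dim: int, char_hidden: int, hidden: int,
                 rng: np.random.Generator,
                 pretrained: np.ndarray | None = None):
        self.word_table = Embedding(n_words, word_dim, rng)
        if pretrained is not None:
            if pretrained.shape != (n_words, word_dim):
                raise ValueError(
                    f"pretrained table shape {pretrained.shape} != ({n_words}, {word_dim})")
            self.word_table.weight.data = pretrained.astype(np.float64).copy()
        self.char_encoder = CharEncoder(n_chars, char_raw_dim, char_hidden, rng)
        self.word_lstm = BiLSTM(word_dim, hidden, rng)
        self.char_lstm = BiLSTM(self.char_encoder.out_dim, hidden, rng)
        self.out_dim = 2 * hidden  # per stream

    def embed(self, word_ids: np.ndarray, char_ids: np.ndarray,
              char_lengths: np.ndarray) -> tuple[Tensor, Tensor]:
        """Per-token embeddings e^w (B,T,d_w) and e^c (B,T,d_c)."""
        B, T = word_ids.shape
        e_w = self.word_table(word_ids)
        e_c = self.char_encoder(char_ids, char_lengths).reshape(B, T, self.char_encoder.out_dim)
        return e_w, e_c

    def __call__(self, word_ids: np.ndarray, lengths: np.ndarray,
                 char_ids: np.ndarray, char_lengths: np.ndarray,
                 dropout=None) -> tuple[Tensor, Tensor]:
        """Context features h^w and h^c, each (B, T, 2*hidden)."""
        e_w, e_c = self.embed(word_ids, char_ids, char_lengths)
        if dropout is not None:
            e_w, e_c = dropout(e_w), dropout(e_c)
        h_w = self.word_lstm(e_w, lengths)
        h_c = self.char_lstm(e_c, lengths)
        return h_w, h_c
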