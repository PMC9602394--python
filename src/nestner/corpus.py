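"""Layered-BIO corpus handling for nested named entities.

Nested mentions are stored on disk in a CoNLL-style column format: one token
per line followed by ``n_layers`` BIO tag columns, one column per nesting
level, with layer 1 the innermost.  A protein mention inside an RNA mention
therefore occupies column 1 (``B-protein I-protein …``) while the enclosing
RNA mention occupies column 2.  Blank lines separate sentences; lines
beginning with ``#`` are comments.

Internally entities are half-open ``[start, end)`` token spans with 0-based
indices and a 1-based nesting depth (1 = innermost).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "NestedEntity",
    "Vocabulary",
    "CorpusParseError",
    "CorpusValidationError",
    "EncodingError",
    "read_layered_corpus",
    "write_layered_corpus",
    "tags_to_entities",
    "entities_to_tags",
    "validate_layered_tags",
    "assign_depths",
    "build_word_vocabulary",
    "build_char_vocabulary",
    "read_word_vectors",
]

PAD, UNK = "<pad>", "<unk>"


class CorpusParseError(ValueError):
    """Malformed corpus file (wrong field count, bad tag syntax)."""


class CorpusValidationError(ValueError):
    """Structurally invalid tag matrix (illegal BIO transition)."""


class EncodingError(ValueError):
    """Entity set that cannot be written as layered BIO (same-depth overlap)."""


@dataclass(frozen=True, order=True)
class NestedEntity:
    """A typed entity span: half-open token interval plus nesting depth."""

    start: int
    end: int
    type: str
    depth: int = 1

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def contains(self, other: "NestedEntity | tuple[int, int]") -> bool:
        """Strict containment of the other span within this one."""
        s, e = other.span if isinstance(other, NestedEntity) else other
        return self.start <= s and e <= self.end and (s, e) != (self.start, self.end)


class Vocabulary:
    """Dense symbol↔id map with reserved PAD (0) and UNK (1) entries.

    After :meth:`freeze`, lookups of unseen symbols return the UNK id, the
    behaviour applied to out-of-vocabulary words at inference time.
    """

    def __init__(self):
        self._sym2id: dict[str, int] = {PAD: 0, UNK: 1}
        self.frozen = False

    def add(self, symbol: str) -> int:
        if symbol not in self._sym2id:
            if self.frozen:
                raise RuntimeError("cannot add symbols to a frozen vocabulary")
            self._sym2id[symbol] = len(self._sym2id)
        return self._sym2id[symbol]

    def freeze(self) -> "Vocabulary":
        self.frozen = True
        return self

    def __getitem__(self, symbol: str) -> int:
        return self._sym2id.get(symbol, self.unk_id)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._sym2id

    def __len__(self) -> int:
        return len(self._sym2id)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def unk_id(self) -> int:
        return 1

    def symbols(self) -> list[str]:
        return sorted(self._sym2id, key=self._sym2id.get)

    def to_dict(self) -> dict[str, int]:
        return dict(self._sym2id)

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "Vocabulary":
        v = cls()
        v._sym2id = dict(d)
        v.frozen = True
        return v


# --------------------------------------------------------------------- tags

def _check_tag(tag: str, where: str) -> None:
    if tag == "O":
        return
    if len(tag) > 2 and tag[:2] in ("B-", "I-"):
        return
    raise CorpusParseError(f"{where}: malformed tag {tag!r} (expected O, B-X or I-X)")


def validate_layered_tags(tags: Sequence[Sequence[str]], sentence_index: int = 0) -> None:
    """Check each layer (column) is a legal BIO sequence.

    ``tags`` is row-major: ``tags[token][layer]``.
    """
    if not tags:
        return
    n_layers = len(tags[0])
    for row_i, row in enumerate(tags):
        if len(row) != n_layers:
            raise CorpusValidationError(
                f"sentence {sentence_index}, token {row_i}: ragged tag row")
    for layer in range(n_layers):
        prev = "O"
        for pos in range(len(tags)):
            tag = tags[pos][layer]
            _check_tag(tag, f"sentence {sentence_index}, layer {layer + 1}, position {pos}")
            if tag.startswith("I-"):
                if not (prev.startswith(("B-", "I-")) and prev[2:] == tag[2:]):
                    raise CorpusValidationError(
                        f"sentence {sentence_index}, layer {layer + 1}, position {pos}: "
                        f"{tag!r} cannot follow {prev!r}")
            prev = tag


def tags_to_entities(tags: Sequence[Sequence[str]]) -> set[NestedEntity]:
    """Decode a layered tag matrix into entities; depth = 1-based layer index."""
    validate_layered_tags(tags)
    entities: set[NestedEntity] = set()
    if not tags:
        return entities
    n_layers = len(tags[0])
    for layer in range(n_layers):
        start, etype = None, None
        for pos in range(len(tags) + 1):
            tag = tags[pos][layer] if pos < len(tags) else "O"
            if start is not None and not (tag.startswith("I-") and tag[2:] == etype):
                entities.add(NestedEntity(start, pos, etype, depth=layer + 1))
                start, etype = None, None
            if tag.startswith("B-"):
                start, etype = pos, tag[2:]
    return entities


def entities_to_tags(entities: Iterable[NestedEntity], length: int,
                     n_layers: int) -> list[list[str]]:
    """Encode entities into a layered BIO matrix (inverse of tags_to_entities)."""
    tags = [["O"] * n_layers for _ in range(length)]
    for ent in entities:
        if ent.end > length:
            raise EncodingError(f"entity {ent} exceeds sentence length {length}")
        if ent.depth > n_layers:
            raise EncodingError(f"entity {ent} exceeds {n_layers} layers")
        layer = ent.depth - 1
        for pos in range(ent.start, ent.end):
            if tags[pos][layer] != "O":
                raise EncodingError(
                    f"same-depth overlap at token {pos}, layer {ent.depth}")
            tags[pos][layer] = ("B-" if pos == ent.start else "I-") + ent.type
    return tags


def assign_depths(spans: Iterable[tuple[int, int, str]]) -> set[NestedEntity]:
    """Derive nesting depths from containment: innermost spans get depth 1.

    A span's depth is one more than the deepest span it strictly contains.
    Input spans must be non-crossing and pairwise distinct as intervals.
    """
    items = sorted(set(spans), key=lambda s: (s[1] - s[0], s[0]))
    depths: dict[tuple[int, int], int] = {}
    out: set[NestedEntity] = set()
    for s, e, t in items:
        inner = [d for (s2, e2), d in depths.items()
                 if s <= s2 and e2 <= e and (s2, e2) != (s, e)]
        depth = 1 + max(inner, default=0)
        depths[(s, e)] = depth
        out.add(NestedEntity(s, e, t, depth=depth))
    return out


# ----------------------------------------------------------------------- io

def read_layered_corpus(path: str | Path, n_layers: int
                        ) -> list[tuple[list[str], list[list[str]]]]:
    """Read a layered-BIO file into (tokens, tag-matrix) sentence pairs."""
    if n_layers < 1:
        raise ValueError("n_layers must be positive")
    sentences: list[tuple[list[str], list[list[str]]]] = []
    tokens: list[str] = []
    tags: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                continue
            if not line.strip():
                if tokens:
                    validate_layered_tags(tags, sentence_index=len(sentences))
                    sentences.append((tokens, tags))
                    tokens, tags = [], []
                continue
            fields = line.split()
            if len(fields) != 1 + n_layers:
                raise CorpusParseError(
                    f"{path}:{lineno}: expected {1 + n_layers} fields, got {len(fields)}")
            for tag in fields[1:]:
                _check_tag(tag, f"{path}:{lineno}")
            tokens.append(fields[0])
            tags.append(fields[1:])
    if tokens:
        validate_layered_tags(tags, sentence_index=len(sentences))
        sentences.append((tokens, tags))
    return sentences


def write_layered_corpus(path: str | Path,
                         sentences: Iterable[tuple[Sequence[str], Sequence[Sequence[str]]]]
                         ) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tokens, tags in sentences:
            for token, row in zip(tokens, tags):
                fh.write("\t".join([token, *row]) + "\n")
            fh.write("\n")


# --------------------------------------------------------------- vocabulary

def build_word_vocabulary(sentences: Iterable[Sequence[str]], min_count: int = 1) -> Vocabulary:
    """Word vocabulary over the corpus; words rarer than ``min_count`` fall to UNK."""
    counts: Counter[str] = Counter()
    n_sent = 0
    for tokens in sentences:
        n_sent += 1
        counts.update(tokens)
    if n_sent == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    vocab = Vocabulary()
    for word, c in sorted(counts.items()):
        if c >= min_count:
            vocab.add(word)
    return vocab.freeze()


def build_char_vocabulary(sentences: Iterable[Sequence[str]]) -> Vocabulary:
    """Character vocabulary covering every character seen in the corpus."""
    chars: set[str] = set()
    n_sent = 0
    for tokens in sentences:
        n_sent += 1
        for token in tokens:
            chars.update(token)
    if n_sent == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    vocab = Vocabulary()
    for ch in sorted(chars):
        vocab.add(ch)
    return vocab.freeze()


def read_word_vectors(path: str | Path, vocab: Vocabulary, dim: int, rng
                      ) -> "np.ndarray":
    """Load plain-text word vectors ("word v1 … vd") aligned to ``vocab``.

    Words absent from the file keep a random initialization in [-0.1, 0.1],
    including the shared UNK row.  An optional "count dim" header is skipped.
    """
    import numpy as np

    table = rng.uniform(-0.1, 0.1, size=(len(vocab), dim))
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        parts = first.split()
        if len(parts) != 2 or not all(p.isdigit() for p in parts):
            fh.seek(0)
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip().split(" ")
            if not parts or parts == [""]:
                continue
            word, values = parts[0], parts[1:]
            if len(values) != dim:
                raise ValueError(f"{path}:{lineno}: expected {dim} values, got {len(values)}")
            if word in vocab:
                table[vocab[word]] = [float(v) for v in values]
    table[vocab.pad_id] = 0.0
    return table
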