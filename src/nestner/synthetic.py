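"""Synthetic nested-entity corpora with controllable statistical structure.

Real nested-NER corpora (GENIA-style biomedical text, with DNA/RNA/protein/
cell mentions nested inside each other) are licensed and large; this module
generates corpora with the structural properties that matter for training
and testing a nested recognizer:

* sentences of configurable length from a finite vocabulary;
* entities of 1–6 tokens drawn from K types, separated by background tokens;
* a controllable fraction of entities that properly contain an inner entity
  of a different type, up to a configurable depth (nesting is generated
  outside-in so containment is legal by construction);
* type-conditional word distributions — each type prefers its own slice of
  the vocabulary with a tunable concentration — so entity type and extent
  are statistically learnable.

Generation is fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import NestedEntity, assign_depths, entities_to_tags

__all__ = ["GeneratorConfig", "generate_corpus", "corpus_statistics", "split_corpus"]

Sentence = tuple[list[str], set[NestedEntity]]

DEFAULT_TYPES = ("DNA", "RNA", "protein", "cell_type")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the corpus generator.

    ``nesting_probability`` is the chance that a generated outer entity
    (when long enough to host one) wraps an inner entity of a different
    type; ``concentration`` sets how strongly each entity type prefers its
    own vocabulary slice (1 = no preference; large = near-disjoint
    type-specific lexicons).
    """

    vocab_size: int = 300
    entity_types: Sequence[str] = DEFAULT_TYPES
    n_sentences: int = 1000
    sentence_length: tuple[int, int] = (5, 40)
    entity_length: tuple[int, int] = (1, 6)
    nesting_probability: float = 0.5
    max_depth: int = 2
    concentration: float = 50.0
    entity_rate: float = 0.6
    decoy_suffix_rate: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.vocab_size < 10:
            raise ValueError("vocab_size must be at least 10")
        if not self.entity_types:
            raise ValueError("at least one entity type is required")
        lo, hi = self.sentence_length
        elo, ehi = self.entity_length
        if not (1 <= lo <= hi):
            raise ValueError(f"bad sentence_length range {self.sentence_length}")
        if not (1 <= elo <= ehi):
            raise ValueError(f"bad entity_length range {self.entity_length}")
        if ehi > hi:
            raise ValueError("entities cannot be longer than the longest sentence")
        if not 0.0 <= self.nesting_probability <= 1.0:
            raise ValueError("nesting_probability must be in [0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not 0.0 <= self.decoy_suffix_rate <= 1.0:
            raise ValueError("decoy_suffix_rate must be in [0, 1]")
        if self.n_sentences < 0:
            raise ValueError("n_sentences must be >= 0")


_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aeiou"


def _word_surfaces(cfg: GeneratorConfig) -> list[str]:
    """Deterministic surface form for every vocabulary index.

    Typed words (the per-type lexicon slices) carry a type-specific suffix,
    emulating biomedical nomenclature where the mention head is morphology-
    bearing ("...ase", "...mRNA", "...cyte"); the stem encodes the word
    index as pronounceable consonant-vowel pairs.  Character composition is
    therefore informative about entity type even for words too rare for a
    useful word embedding — the situation in which character-level features
    complement word-level ones.  Conversely a ``decoy_suffix_rate`` fraction
    of the background lexicon carries a typed-looking suffix (as ordinary
    words sometimes resemble nomenclature), so morphology alone is not
    sufficient either: each stream fails in a different place, which is the
    regime the dual-stream complementation mechanism targets.
    """
    K = len(cfg.entity_types)
    V = cfg.vocab_size
    typed_part = int(0.6 * V)
    slice_size = max(1, typed_part // K)
    suffixes = []
    for k, name in enumerate(cfg.entity_types):
        suf = "".join(ch for ch in name.lower() if ch.isalpha())[:3]
        while suf in suffixes:  # disambiguate colliding type names
            suf += _CONSONANTS[k % len(_CONSONANTS)]
        suffixes.append(suf)
    surfaces = []
    for i in range(V):
        stem, n = "", i
        while True:
            stem += _CONSONANTS[n % len(_CONSONANTS)] + _VOWELS[(n // len(_CONSONANTS)) % len(_VOWELS)]
            n //= len(_CONSONANTS) * len(_VOWELS)
            if n == 0 and len(stem) >= 4:
                break
        if i < typed_part:
            k = min(i // slice_size, K - 1)
            surfaces.append(stem + suffixes[k])
        elif cfg.decoy_suffix_rate > 0 and (
                (i - typed_part) % max(1, round(1 / cfg.decoy_suffix_rate)) == 0):
            surfaces.append(stem + suffixes[i % K])
        else:
            surfaces.append(stem)
    return surfaces


def _type_distributions(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-type and background categorical distributions over the vocabulary.

    The first 60% of the vocabulary is split into disjoint slices (lexicons),
    one per type.  A type draws from its own lexicon with odds
    ``concentration : 1`` (probability c/(c+1), uniform within the lexicon)
    and from the rest of the vocabulary otherwise (uniform).  Background
    tokens are drawn uniformly from the remaining 40%.  At the default
    c = 50 an entity token is off-lexicon ~2% of the time, mirroring how
    strongly type-indicative entity tokens are in biomedical corpora.
    """
    K = len(cfg.entity_types)
    V = cfg.vocab_size
    typed_part = int(0.6 * V)
    slice_size = max(1, typed_part // K)
    c = cfg.concentration
    type_w = np.empty((K, V))
    for k in range(K):
        lo = k * slice_size
        hi = min((k + 1) * slice_size, typed_part)
        own = c / (c + 1.0)
        type_w[k, :] = (1.0 - own) / (V - (hi - lo))
        type_w[k, lo:hi] = own / (hi - lo)
    bg_w = np.zeros(V)
    bg_w[typed_part:] = 1.0
    bg_w /= bg_w.sum()
    return type_w, bg_w


def _place_entities(length: int, cfg: GeneratorConfig, rng: np.random.Generator
                    ) -> list[tuple[int, int, str]]:
    """Sample non-crossing entity spans (outer first, inner nested within)."""
    elo, ehi = cfg.entity_length
    types = list(cfg.entity_types)
    spans: list[tuple[int, int, str]] = []
    pos = int(rng.integers(0, 3))
    while pos < length:
        if rng.random() >= cfg.entity_rate:
            pos += int(rng.integers(1, 4))
            continue
        ell = int(rng.integers(elo, min(ehi, length - pos) + 1)) if length - pos >= elo else 0
        if ell == 0:
            break
        outer_type = types[rng.integers(len(types))]
        spans.append((pos, pos + ell, outer_type))
        # Nest inner entities outside-in, one per level.  Two structural
        # rules keep the corpus decodable, mirroring head-final biomedical
        # mentions ("<protein> mRNA": the type-bearing head noun is the
        # final token and an embedded mention never covers it):
        #  * an inner span lies within the outer minus its final token, so
        #    a span's type is always witnessed by its own last token;
        #  * the first nest requires an outer of >= 3 tokens, because the
        #    fine-grained division rule only sub-divides entity-word runs
        #    of length >= 3 — a nested mention inside a 2-token outer would
        #    be unrecoverable by construction.
        o_s, o_e, parent_type = pos, pos + ell, outer_type
        depth_left = cfg.max_depth - 1
        min_outer = 3
        while depth_left > 0 and (o_e - o_s) >= min_outer and rng.random() < cfg.nesting_probability:
            min_outer = 2
            if len(types) < 2:
                break
            inner_len = int(rng.integers(1, o_e - o_s))  # 1 .. outer_len-1
            i_s = int(rng.integers(o_s, o_e - inner_len))  # i_s+inner_len <= o_e-1
            inner_type = types[rng.integers(len(types))]
            while inner_type == parent_type:
                inner_type = types[rng.integers(len(types))]
            spans.append((i_s, i_s + inner_len, inner_type))
            o_s, o_e, parent_type = i_s, i_s + inner_len, inner_type
            depth_left -= 1
        pos = pos + ell + int(rng.integers(1, 4))  # gap >= 1 between outer entities
    return spans


def generate_sentence(cfg: GeneratorConfig, rng: np.random.Generator,
                      type_w: np.ndarray, bg_w: np.ndarray,
                      surfaces: list[str]) -> Sentence:
    length = int(rng.integers(cfg.sentence_length[0], cfg.sentence_length[1] + 1))
    spans = _place_entities(length, cfg, rng)
    entities = assign_depths(spans)
    type_of = {t: k for k, t in enumerate(cfg.entity_types)}
    # word choice per token: innermost covering entity wins
    owner: list[int | None] = [None] * length
    for ent in sorted(entities, key=lambda e: -(e.end - e.start)):
        for p in range(ent.start, ent.end):
            owner[p] = type_of[ent.type]
    words = []
    for p in range(length):
        dist = bg_w if owner[p] is None else type_w[owner[p]]
        words.append(surfaces[rng.choice(len(dist), p=dist)])
    return words, entities


def generate_corpus(cfg: GeneratorConfig) -> list[Sentence]:
    """Generate ``cfg.n_sentences`` labeled sentences, deterministic in the seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    type_w, bg_w = _type_distributions(cfg)
    surfaces = _word_surfaces(cfg)
    return [generate_sentence(cfg, rng, type_w, bg_w, surfaces)
            for _ in range(cfg.n_sentences)]


def corpus_statistics(corpus: Sequence[Sentence]) -> dict:
    """Per-type entity counts plus totals and the nested-entity count.

    An entity counts as nested when it is properly contained in another
    entity of the same sentence.
    """
    per_type: dict[str, int] = {}
    total = 0
    nested = 0
    n_tokens = 0
    for tokens, entities in corpus:
        n_tokens += len(tokens)
        for ent in entities:
            per_type[ent.type] = per_type.get(ent.type, 0) + 1
            total += 1
            if any(other.contains(ent) for other in entities):
                nested += 1
    return {
        "n_sentences": len(corpus),
        "n_tokens": n_tokens,
        "per_type": dict(sorted(per_type.items())),
        "total_entities": total,
        "nested_entities": nested,
    }


def split_corpus(corpus: Sequence[Sentence], ratios: tuple[float, float, float] = (8.1, 0.9, 1.0)
                 ) -> tuple[list[Sentence], list[Sentence], list[Sentence]]:
    """Split by sentence into train/dev/test with the given ratio (default 8.1:0.9:1)."""
    total = sum(ratios)
    n = len(corpus)
    n_train = int(round(n * ratios[0] / total))
    n_dev = int(round(n * ratios[1] / total))
    train = list(corpus[:n_train])
    dev = list(corpus[n_train:n_train + n_dev])
    test = list(corpus[n_train + n_dev:])
    return train, dev, test


def corpus_to_layered(corpus: Sequence[Sentence], n_layers: int
                      ) -> list[tuple[list[str], list[list[str]]]]:
    """Convert (tokens, entities) pairs to (tokens, layered-tag-matrix) pairs."""
    return [(tokens, entities_to_tags(ents, len(tokens), n_layers))
            for tokens, ents in corpus]
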