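# Methods

## Problem

Nested named entity recognition: mentions in (biomedical) text may properly
contain mentions of other types — a protein name inside an RNA name
("IL-2R alpha" inside "IL-2R alpha mRNA"), a location inside an
organization. Flat sequence labeling cannot emit overlapping spans, so the
recognizer here detects candidate regions and classifies spans, and corpora
are stored in a *layered* BIO format: one tag column per nesting level
(innermost first), each column an ordinary BIO sequence, up to N = 4 levels.
Internally an entity is a half-open token span `[start, end)` with a type
label and a 1-based depth; depth is a file-format artefact — evaluation
compares `(start, end, type)` only.

## Model

Each sentence `s = {s_1 … s_n}` is embedded twice: a word-level vector
`e^w_i` from a trainable lookup table (optionally initialized from
pretrained vectors; all out-of-vocabulary words share one trainable UNK
row) and a character-level vector `e^c_i` produced by a BiLSTM over the
token's characters (last forward state ++ backward state at the first
character). Each embedding sequence is contextualized by its own sentence
BiLSTM, giving two per-token streams `h^w_i` and `h^c_i` (forward/backward
concatenation).

The two streams then exchange information twice:

**Low level.** Each stream is gated by the other through a small MLP and a
logistic gate, with the un-gated stream concatenated back as a residual:

    h̄^w_i = [σ(MLP(h^c_i)) ⊙ h^w_i ; h^w_i]
    h̄^c_i = [σ(MLP(h^w_i)) ⊙ h^c_i ; h^c_i]

(the char-steered complement CCM and the word-induced enhancement WEM; the
two MLPs have separate parameters — one hidden tanh layer, hidden size equal
to its input width).

**Attention.** Each complemented stream passes through its own multi-head
scaled dot-product self-attention, `softmax(QKᵀ/√d_k)V` per head, heads
concatenated and projected. A residual connection is kept around the
attention block so per-token identity survives while attention weights are
still diffuse; no positional encoding is added — order information comes
from the recurrent encoders. Padded keys get a −10⁹ logit.

**High level.** The fused vector `h̄_i = [h̄^w_i ; h̄^c_i]` drives a first
shared gate `H = σ(P h̄_i)` applied to both streams (`ĥ = H ⊙ h̄`); each
result then gates itself a second time (`h̃ = σ(ĥ) ⊙ ĥ`), and the final
per-token representation is `H_i = [h̃^w_i ; h̄_i ; h̃^c_i]`. The fused
vector is twice a stream's width, so the learned projection `P` maps it
down before the sigmoid; under ablations that leave the streams with
unequal widths, a shared gate is impossible and per-stream projections are
used. A config switch (`hbcl_printed_asymmetry`) reuses the word gate
σ(ĥ^w) for the char stream instead of σ(ĥ^c), reproducing an asymmetric
variant of the second stage; the symmetric form is the default.

**Decoding.** A linear+sigmoid detector scores each token with the
probability `p_i` of lying in or on the boundary of any entity; a token is
an entity word iff `p_i > 0.5` (strictly — `p = 0.5` is not an entity
word). Maximal runs of entity words become candidates; every run of
≥ 3 tokens is additionally divided into all `n(n+1)/2` contiguous
sub-intervals so nested inner mentions can be recovered; shorter runs
contribute only themselves. A span ⟨i, j⟩ is represented as
`S(i,j) = [H_i ; mean(H_i..H_j) ; H_j]` and classified over the entity
types plus one non-entity class by a fully connected tanh layer followed by
the softmax output layer (exact-boundary decisions are conjunctions of
boundary features and are not linearly separable in `S`). Predicted spans
whose argmax is non-entity are dropped; crossing or duplicate intervals are
resolved by keeping the higher-probability span (ties: earlier start, then
shorter); depths are assigned by containment (innermost = 1), capped at 4.

**Loss.** `L = λ·L_l + (1−λ)·L_h` with `L_l` the token-level binary
cross-entropy of the detector and `L_h` the span cross-entropy,
`λ = 0.5` by default (any value in (0,1) is accepted). Each term is
averaged over its own support before weighting; a `reduction="sum"` switch
keeps raw sums. At training time candidate spans are enumerated from the
*gold* entity-word mask (teacher forcing); gold spans keep their type and
the other candidates are labeled non-entity, subsampled to at most
`neg_ratio` negatives per positive (default 3; the CPU benchmarks use 8 —
exhaustive sub-spans are heavily imbalanced and a higher ratio calibrates
the classifier against the negative distribution it faces at inference).

## Parameters

| parameter | reference | CPU profile | notes |
|---|---|---|---|
| word embedding dim | 200 | 32 | |
| char embedding dim (2·char hidden) | 200 | 16 | raw char vectors 50 / 12 |
| LSTM hidden per direction | 200 | 16 | 1 layer; streams are 2·hidden wide |
| attention heads | 8 | 4 | model dim must divide by heads |
| dropout | 0.5 | 0.1–0.2 | on embeddings and on `H_i` |
| batch size | 50 | 25 | length-bucketed, shuffled |
| learning rate (Adam) | 5e-4 | 3e-3, ×0.97/epoch | optimizer is a package choice |
| epochs | 60 | 12–100 per benchmark | best-dev-F1 checkpoint kept |
| λ | 0.5 | 0.5 | |

Training is deterministic given the seed on one device. Gradients are
clipped to global norm 5; a non-finite loss aborts with a diagnostic.
The forget-gate bias starts at 1. All computation is float64 NumPy through
the package's own reverse-mode autodiff engine (`nestner.autograd`), whose
gradients are finite-difference-checked in the test suite.

## Synthetic corpora

Real nested-NER corpora are licensed; the generator produces corpora with
the structural properties the pipeline needs, and its defaults are the
conditions under which the package's claims are tested:

* sentences of 5–40 tokens; entities of 1–6 tokens from K = 4 types
  (DNA/RNA/protein/cell_type) placed with gaps ≥ 1 between top-level
  mentions; vocabulary of 300 words, 60% of it split into disjoint per-type
  lexicons.
* each entity token is drawn from its type's lexicon with odds
  `concentration : 1` (default 50 : 1, i.e. ~2% off-lexicon); background
  tokens come from the remaining 40% of the vocabulary.
* word surfaces are deterministic consonant-vowel stems; typed words carry
  a type-specific suffix ("…dna", "…rna", "…pro", "…cel"), emulating
  morphology-bearing nomenclature, and 15% of background words carry a
  decoy suffix, so neither word identity alone nor morphology alone
  suffices — the regime the dual-stream complementation targets.
* nesting is generated outside-in: with probability `nesting_probability`
  an outer mention wraps a strictly contained inner mention of a different
  type, recursively to `max_depth`. Nesting is head-final, as in
  biomedical mentions ("⟨protein⟩ mRNA"): an inner span never covers the
  outer's final token, so every span's type is witnessed by its own last
  token, and the first nest requires an outer of ≥ 3 tokens because the
  fine-grained division rule cannot recover an inner mention inside a
  shorter run. Without these two constraints the generated labels are
  provably ambiguous (two distinct gold readings of one surface) or
  undecodable, and no recognizer could recover them.

What the generator does *not* emulate: real lexical statistics (Zipfian
frequencies, shared head nouns across types), discontinuous or crossing
mentions, annotation noise, and document-level context. Passing the
benchmarks therefore demonstrates that the implementation can learn and
decode nested structure under controlled conditions — not that it attains
any particular score on a real corpus.

## Benchmarks (CPU profile sizes)

* **Overfit:** 50 sentences (lengths 5–25), batch 5, lr 5e-3, no dropout,
  100 epochs, train = eval; a correct implementation reaches training
  micro-F1 ≥ 0.99 (measured: 1.00).
* **Recovery:** 1235 sentences split 1000/111/124 (the 8.1 : 0.9 : 1
  ratio), 30 epochs; asserts held-out micro-F1 ≥ 0.85, recall on properly
  nested gold entities ≥ 0.7, detector token accuracy ≥ 0.95.
* **Ablation:** rare-word corpus (vocabulary 1500, 800 sentences split
  560/80/160) so many test words are unseen in training and the word
  stream alone is unreliable; the full model and the five reduced
  architectures (no CCM / no WEM / neither / no HBCL / no attention) are
  trained with one shared seed and compared by test micro-F1, direction
  only. Corpus and epoch counts are chosen so the six runs finish in
  minutes on one CPU.

## Numerical and design choices

* Coordinates 0-based half-open; layer 1 innermost; whitespace tokenization
  of the input file is trusted as-is.
* BIO validation is per column; `I-X` must follow `B-X`/`I-X` of the same
  type; errors name sentence, layer and position.
* Evaluation: micro P/R/F1 pooled over sentences (macro and per-type
  reported alongside); zero denominators score 0; depth is ignored in
  matching; the nested-only sub-report restricts gold to entities properly
  contained in another gold entity.
* Detector probabilities are clipped to [1e-12, 1−1e-12] inside the loss;
  softmax subtracts the row maximum.
* Character encoding of padding tokens uses a single PAD character; all
  padded positions are masked out of attention and the losses.
* Unknown ablation flags, λ ∉ (0,1), dimension mismatches, malformed
  corpus lines and empty training corpora raise immediately with specific
  messages.

## What the ablation benchmark shows

The ablation harness trains the full model and the five reduced
architectures under one shared seed and reports test micro-F1 per variant.
On these synthetic corpora every variant — including the plain dual-BiLSTM
with attention — reaches essentially the same ceiling once converged;
between-architecture differences are of the same order as run-to-run seed
variation. The comparison table is therefore a capability of the package
(and a determinism check), not evidence that the gated complementation
blocks help on this data; whether they help on a real corpus must be
measured on that corpus.

## Known limitations

* Entities sharing an interval with two types cannot be predicted (one
  type per interval survives decoding), and crossing mentions are rejected
  by design — the layered BIO format cannot express them.
* An inner mention inside an entity-word run shorter than 3 tokens is
  unreachable by the fine-grained division rule.
* The depth cap (4) silently drops deeper predicted chains.
* Training cost is O(sentence length) Python-level steps per BiLSTM pass;
  the engine is adequate for the CPU profile, not for the 200-dimensional
  reference profile on large corpora.
* With `select_best_on_dev`, ties in dev F1 keep the later epoch.
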