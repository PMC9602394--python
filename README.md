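# nestner

Nested named entity recognition with dual-stream feature complementation.

Named entities nest: a protein mention sits inside an RNA mention
("IL-2R alpha" inside "IL-2R alpha mRNA"), a location inside an
organization ("Cambridge" inside "University of Cambridge"). Flat
BIO sequence labeling cannot emit overlapping spans. `nestner` implements a
span-based recognizer for nested mentions, aimed at GENIA-style biomedical
corpora (DNA / RNA / protein / cell-type entities, nesting depth up to 4),
together with the layered-BIO corpus format, a synthetic-corpus generator,
an exact-match evaluator and a CLI. It is self-contained NumPy: the
network, including its reverse-mode autodiff engine, lives in this package.

## Model

Every token is encoded twice — a word embedding `e^w_i` and a
character-level BiLSTM embedding `e^c_i` — and each embedding sequence is
contextualized by its own sentence BiLSTM, giving two streams `h^w_i`,
`h^c_i`. The streams then complement each other:

* low level: `h̄^w_i = [σ(MLP(h^c_i)) ⊙ h^w_i ; h^w_i]` and symmetrically
  for the character stream — each stream is gated by the other, with a
  residual concatenation;
* per-stream multi-head self-attention, `softmax(QKᵀ/√d_k)V`;
* high level: the fused vector `h̄_i = [h̄^w_i ; h̄^c_i]` drives a shared
  sigmoid gate applied to both streams, each result re-gates itself, and
  the final token representation is `H_i = [h̃^w_i ; h̄_i ; h̃^c_i]`.

Decoding is detect-then-classify: a sigmoid head marks entity words
(`p_i > 0.5`); maximal entity-word runs of ≥ 3 tokens are divided into all
contiguous sub-spans (shorter runs stand alone); each span ⟨i, j⟩ is
represented as `S(i,j) = [H_i ; mean(H_i..H_j) ; H_j]` and classified over
the entity types plus a non-entity class. Training minimizes
`L = λ·L_l + (1−λ)·L_h` (token-level BCE + span cross-entropy, λ = 0.5).
Every architectural block (CCM, WEM, attention, HBCL) is an independent
config switch, so the ablation variants are first-class configurations.

Corpora are plain-text layered BIO: one token per line, then one BIO tag
column per nesting level (innermost first), blank line between sentences:

```
IL      B-protein   B-RNA   O   O
-       I-protein   I-RNA   O   O
2R      I-protein   I-RNA   O   O
alpha   I-protein   I-RNA   O   O
mRNA    O           I-RNA   O   O
that    O           O       O   O
is      O           O       O   O
```

See `docs/methods.md` for assumptions, parameter defaults, the synthetic
generator's design and known limitations.

## Worked example

Generate a synthetic corpus, train the CPU-profile model, predict and
score (about two minutes on one CPU):

```
$ nestner generate --out-dir data --n-sentences 600 --seed 42
$ nestner train --train-file data/train.bio --dev-file data/dev.bio \
      --checkpoint model.npz --epochs 18 --batch-size 25 --learning-rate 0.003
$ nestner predict --checkpoint model.npz --input data/test.bio --output pred.bio
$ nestner evaluate --gold data/test.bio --pred pred.bio
```

On this run the final training log line and the evaluation print:

```
{"epoch": 18, "L_l": 0.0227, "L_h": 0.1114, "L": 0.0670, "seconds": 2.15, "dev_P": 0.8930, "dev_R": 0.7198, "dev_F1": 0.7971}
micro P=0.9115 R=0.8258 F1=0.8665 (gold=287 pred=260 matched=237)
macro F1=0.8653   nested recall=0.4091 (66 nested gold)
  DNA          P=0.8793 R=0.7846 F1=0.8293
  RNA          P=0.9412 R=0.8889 F1=0.9143
  cell_type    P=0.8657 R=0.8406 F1=0.8529
  protein      P=0.9552 R=0.7901 F1=0.8649
```

`L_l`/`L_h` are the detector and span-classifier losses; `micro P/R/F1`
score exact span+type matches pooled over the test sentences (237 of 287
gold mentions recovered, 260 predicted); `nested recall` is recall
restricted to gold mentions properly contained inside another mention —
the specifically *nested* part of the task, which needs more data or
epochs than this two-minute demo to saturate (the longer benchmark run in
`scripts/acceptance.py` reaches ~0.9). `nestner ablate` trains the five
reduced architectures (dropping CCM / WEM / HBCL / attention) against the
full model with a shared seed and prints a comparison table.

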