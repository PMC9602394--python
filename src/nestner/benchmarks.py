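"""Standard synthetic benchmarks for the recognizer.

Three reference experiments, each fully determined by a seed:

* **overfit** — 50 sentences, train = eval: a capacity/correctness smoke
  test; a healthy implementation drives training F1 to 1.0.
* **recovery** — 1000 training sentences (vocabulary 300, four types,
  nesting probability 0.5, depth <= 2) with held-out dev/test splits in the
  8.1 : 0.9 : 1 ratio: measures whether the full model recovers entities it
  has never seen, including properly nested ones.
* **ablation** — a rare-word variant of the corpus (vocabulary 1500, so
  many test words are unseen or nearly unseen in training) on which the
  full model and the five reduced architectures are trained with a shared
  seed and compared.

Model and optimisation sizes here are the package's CPU profile: 32/16-d
embeddings, 16 hidden units per direction, 4 heads, Adam at 3e-3 with 3%
per-epoch decay.  They are deliberately far smaller than the reference
profile in :class:`~nestner.model.ModelConfig`; the benchmark corpora are
correspondingly small.
"""

from __future__ import annotations

from .metrics import EvalReport
from .model import ModelConfig
from .synthetic import GeneratorConfig, generate_corpus, split_corpus
from .training import (RunConfig, evaluate_corpus, run_ablation, token_accuracy,
                       train)

__all__ = ["overfit_benchmark", "recovery_benchmark", "ablation_benchmark"]


def _small_run(epochs: int, seed: int, **model_overrides) -> RunConfig:
    return RunConfig(epochs=epochs, batch_size=25, learning_rate=3e-3,
                     lr_decay=0.97, seed=seed,
                     model=ModelConfig.small(**model_overrides), eval_every=3)


def overfit_benchmark(corpus_seed: int = 3, train_seed: int = 0,
                      epochs: int = 100) -> dict:
    """Train on 50 sentences and evaluate on the same 50 (memorization test)."""
    corpus = generate_corpus(GeneratorConfig(
        n_sentences=50, sentence_length=(5, 25), seed=corpus_seed))
    cfg = RunConfig(epochs=epochs, batch_size=5, learning_rate=5e-3,
                    seed=train_seed, model=ModelConfig.small(dropout=0.0))
    result = train(cfg, corpus)
    report = evaluate_corpus(result.model, corpus)
    return {"train_f1": report.f1, "train_precision": report.precision,
            "train_recall": report.recall, "n_sentences": len(corpus)}


def recovery_benchmark(corpus_seed: int = 7, train_seed: int = 0,
                       epochs: int = 30) -> dict:
    """Held-out parameter recovery on the 1000-train-sentence corpus."""
    corpus = generate_corpus(GeneratorConfig(n_sentences=1235, seed=corpus_seed))
    train_set, dev_set, test_set = split_corpus(corpus)
    cfg = _small_run(epochs, train_seed, dropout=0.2, neg_ratio=8)
    result = train(cfg, train_set, dev_set)
    report: EvalReport = evaluate_corpus(result.model, test_set)
    return {
        "test_precision": report.precision,
        "test_recall": report.recall,
        "test_f1": report.f1,
        "nested_recall": report.nested_recall,
        "token_accuracy": token_accuracy(result.model, test_set),
        "n_train": len(train_set), "n_test": len(test_set),
        "n_gold_test": report.n_gold, "n_gold_nested": report.n_gold_nested,
    }


def ablation_benchmark(corpus_seed: int = 11, train_seed: int = 0,
                       epochs: int = 30, variants=None) -> dict[str, dict]:
    """Shared-seed comparison of the full model and its reduced variants.

    Uses the rare-word corpus (vocabulary 1500, 800 sentences split
    560/80/160) so that the word stream alone is unreliable on test data
    and the streams' interaction is actually exercised.
    """
    corpus = generate_corpus(GeneratorConfig(
        n_sentences=800, vocab_size=1500, seed=corpus_seed))
    train_set, dev_set, test_set = corpus[:560], corpus[560:640], corpus[640:]
    cfg = _small_run(epochs, train_seed, dropout=0.2, neg_ratio=8)
    return run_ablation(cfg, train_set, dev_set, test_set, variants=variants)
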