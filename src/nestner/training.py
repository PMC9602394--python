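"""Training loop, evaluation harness and ablation runner."""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import NestedEntity, Vocabulary, build_char_vocabulary, build_word_vocabulary
from .metrics import EvalReport, evaluate
from .model import ModelConfig, NestedNERModel
from .nn import Adam

__all__ = ["RunConfig", "TrainResult", "train", "run_ablation", "ABLATION_VARIANTS"]

Sentence = tuple[list[str], set[NestedEntity]]

# named ablation variants: blocks left enabled besides the two BiLSTM streams
ABLATION_VARIANTS: dict[str, dict[str, bool]] = {
    "Bi-LSTM + MHSM": dict(use_ccm=False, use_wem=False, use_hbcl=False, use_mhsm=True),
    "Bi-LSTM + CCM + MHSM + HBCL": dict(use_ccm=True, use_wem=False, use_hbcl=True, use_mhsm=True),
    "Bi-LSTM + WEM + MHSM + HBCL": dict(use_ccm=False, use_wem=True, use_hbcl=True, use_mhsm=True),
    "Bi-LSTM + MHSM + HBCL": dict(use_ccm=False, use_wem=False, use_hbcl=True, use_mhsm=True),
    "Bi-LSTM + CCM + WEM + MHSM": dict(use_ccm=True, use_wem=True, use_hbcl=False, use_mhsm=True),
}


@dataclass
class RunConfig:
    """Training hyperparameters (reference profile: batch 50, lr 5e-4,
    60 epochs, dropout 0.5, λ = 0.5)."""

    epochs: int = 60
    batch_size: int = 50
    learning_rate: float = 5e-4
    lr_decay: float = 1.0   # multiplicative per-epoch decay
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    min_count: int = 1
    eval_every: int = 1
    select_best_on_dev: bool = True
    log: bool = False

    def validate(self) -> None:
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if not 0.0 <= self.model.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainResult:
    model: NestedNERModel
    log_lines: list[str]
    history: list[dict]
    best_dev_f1: float


def _batches(lengths: np.ndarray, batch_size: int, rng: np.random.Generator):
    """Length-bucketed shuffled batches: sentences of similar length are
    padded together (random tie-break within a length), batch order shuffled."""
    noise = rng.random(len(lengths))
    order = np.lexsort((noise, lengths))
    chunks = [order[i:i + batch_size] for i in range(0, len(order), batch_size)]
    for i in rng.permutation(len(chunks)):
        yield chunks[i]


def train(cfg: RunConfig, train_corpus: list[Sentence],
          dev_corpus: list[Sentence] | None = None,
          type_names: list[str] | None = None) -> TrainResult:
    """Train a recognizer; deterministic given the seed on one device.

    The best dev-F1 parameter snapshot is restored at the end when a dev
    corpus is given (otherwise the final parameters are kept).
    """
    cfg.validate()
    if not train_corpus:
        raise ValueError("training corpus is empty")
    sentences = [s for s, _ in train_corpus]
    word_vocab = build_word_vocabulary(sentences, min_count=cfg.min_count)
    char_vocab = build_char_vocabulary(sentences)
    if type_names is None:
        type_names = sorted({e.type for _, ents in train_corpus for e in ents})
    model = NestedNERModel(cfg.model, word_vocab, char_vocab, type_names, seed=cfg.seed)
    opt = Adam(list(model.parameters()), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 17)
    log_lines: list[str] = []
    history: list[dict] = []
    best_f1, best_state = -1.0, None
    for epoch in range(1, cfg.epochs + 1):
        model.train_mode(True)
        opt.lr = cfg.learning_rate * cfg.lr_decay ** (epoch - 1)
        t0 = time.time()
        tot_l = tot_h = tot = 0.0
        n_batches = 0
        for idx in _batches(np.array([len(s) for s, _ in train_corpus]),
                            cfg.batch_size, rng):
            batch = [train_corpus[i] for i in idx]
            terms = model.loss([s for s, _ in batch], [e for _, e in batch])
            if not math.isfinite(terms.total.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"L_l={terms.token_loss.item()} L_h={terms.span_loss.item()}")
            opt.zero_grad()
            terms.total.backward()
            opt.step()
            l, h, t = terms.as_floats()
            tot_l += l
            tot_h += h
            tot += t
            n_batches += 1
        entry = {"epoch": epoch, "L_l": tot_l / n_batches, "L_h": tot_h / n_batches,
                 "L": tot / n_batches, "seconds": round(time.time() - t0, 2)}
        if dev_corpus and epoch % cfg.eval_every == 0:
            report = evaluate(model.predict([s for s, _ in dev_corpus]),
                              [e for _, e in dev_corpus])
            entry.update(dev_P=report.precision, dev_R=report.recall, dev_F1=report.f1)
            if cfg.select_best_on_dev and report.f1 >= best_f1:
                best_f1 = report.f1
                best_state = [a.copy() for a in model.state_arrays()]
        history.append(entry)
        line = json.dumps(entry)
        log_lines.append(line)
        if cfg.log:
            print(line)
    if best_state is not None:
        model.load_state_arrays(best_state)
    return TrainResult(model=model, log_lines=log_lines, history=history,
                       best_dev_f1=best_f1)


def evaluate_corpus(model: NestedNERModel, corpus: list[Sentence],
                    batch_size: int = 50) -> EvalReport:
    """Predict a corpus in batches and score against its gold entities."""
    preds: list[set[NestedEntity]] = []
    for i in range(0, len(corpus), batch_size):
        preds.extend(model.predict([s for s, _ in corpus[i:i + batch_size]]))
    return evaluate(preds, [e for _, e in corpus])


def token_accuracy(model: NestedNERModel, corpus: list[Sentence],
                   batch_size: int = 50) -> float:
    """Entity-word detector accuracy against gold token labels."""
    from .classifier import entity_word_labels

    correct = total = 0
    for i in range(0, len(corpus), batch_size):
        chunk = corpus[i:i + batch_size]
        masks = model.detect_mask([s for s, _ in chunk])
        for (tokens, ents), mask in zip(chunk, masks):
            y = entity_word_labels(len(tokens), ents)
            correct += int((mask == y).sum())
            total += len(tokens)
    return correct / total if total else 0.0


def save_checkpoint(model: NestedNERModel, path: str) -> None:
    """Serialize parameters + model config + vocabularies + type set (.npz)."""
    from dataclasses import asdict

    meta = {
        "model_config": asdict(model.cfg),
        "word_vocab": model.word_vocab.to_dict(),
        "char_vocab": model.char_vocab.to_dict(),
        "type_names": model.type_names,
    }
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str) -> NestedNERModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        arrays = [data[f"param_{i}"] for i in range(len(data.files) - 1)]
    cfg = ModelConfig(**meta["model_config"])
    model = NestedNERModel(cfg, Vocabulary.from_dict(meta["word_vocab"]),
                           Vocabulary.from_dict(meta["char_vocab"]),
                           meta["type_names"])
    model.load_state_arrays(arrays)
    return model


def run_ablation(base_cfg: RunConfig, train_corpus: list[Sentence],
                 dev_corpus: list[Sentence], test_corpus: list[Sentence],
                 variants: dict[str, dict[str, bool]] | None = None,
                 include_full: bool = True) -> dict[str, dict]:
    """Train each architectural variant with shared seed/data and score it.

    Returns variant name → {P, R, F1, n_parameters}; the full model is
    reported under the key "full".
    """
    if variants is None:
        variants = ABLATION_VARIANTS
    jobs: dict[str, dict[str, bool]] = {}
    if include_full:
        jobs["full"] = {}
    jobs.update(variants)
    results: dict[str, dict] = {}
    for name, flags in jobs.items():
        unknown = set(flags) - {"use_ccm", "use_wem", "use_hbcl", "use_mhsm"}
        if unknown:
            raise ValueError(f"unknown ablation flags {sorted(unknown)} for {name!r}")
        cfg = replace(base_cfg, model=base_cfg.model.ablated(**flags))
        result = train(cfg, train_corpus, dev_corpus)
        report = evaluate_corpus(result.model, test_corpus)
        results[name] = {
            "P": report.precision, "R": report.recall, "F1": report.f1,
            "n_parameters": result.model.n_parameters(),
        }
    return results
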