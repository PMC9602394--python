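"""Exact-match evaluation of nested entity predictions.

A predicted entity is correct iff its start, end and type all equal a gold
entity's; nesting depth is not compared (layered depth is a file-format
artefact, the unit of evaluation is the typed span).  Precision is
matched/predicted, recall matched/gold, F1 their harmonic mean; a zero
denominator yields 0 by convention.  Micro averages pool counts over all
sentences; macro averages the per-type F1s.  A nested-only sub-report
restricts gold to entities properly contained in another gold entity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus import NestedEntity

__all__ = ["EvalReport", "evaluate", "prf"]


def prf(matched: int, predicted: int, gold: int) -> tuple[float, float, float]:
    p = matched / predicted if predicted else 0.0
    r = matched / gold if gold else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    n_gold: int
    n_predicted: int
    n_matched: int
    per_type: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    macro_f1: float = 0.0
    nested_recall: float = 0.0
    n_gold_nested: int = 0

    def summary(self) -> str:
        lines = [
            f"micro P={self.precision:.4f} R={self.recall:.4f} F1={self.f1:.4f} "
            f"(gold={self.n_gold} pred={self.n_predicted} matched={self.n_matched})",
            f"macro F1={self.macro_f1:.4f}   nested recall={self.nested_recall:.4f} "
            f"({self.n_gold_nested} nested gold)",
        ]
        for t, (p, r, f1) in sorted(self.per_type.items()):
            lines.append(f"  {t:12s} P={p:.4f} R={r:.4f} F1={f1:.4f}")
        return "\n".join(lines)


def _keys(entities: set[NestedEntity]) -> set[tuple[int, int, str]]:
    return {(e.start, e.end, e.type) for e in entities}


def evaluate(predictions: list[set[NestedEntity]],
             gold: list[set[NestedEntity]]) -> EvalReport:
    """Micro/macro exact-match P/R/F1 with per-type and nested-only breakdowns."""
    if len(predictions) != len(gold):
        raise ValueError(
            f"prediction/gold corpora misaligned: {len(predictions)} vs {len(gold)} sentences")
    matched = predicted = n_gold = 0
    by_type: dict[str, list[int]] = {}
    nested_gold = nested_matched = 0
    for pred_set, gold_set in zip(predictions, gold):
        pk, gk = _keys(pred_set), _keys(gold_set)
        inter = pk & gk
        matched += len(inter)
        predicted += len(pk)
        n_gold += len(gk)
        for key in pk | gk:
            t = key[2]
            row = by_type.setdefault(t, [0, 0, 0])  # matched, predicted, gold
            row[0] += key in inter
            row[1] += key in pk
            row[2] += key in gk
        for ent in gold_set:
            if any(other.contains(ent) for other in gold_set):
                nested_gold += 1
                nested_matched += (ent.start, ent.end, ent.type) in pk
    p, r, f1 = prf(matched, predicted, n_gold)
    per_type = {t: prf(*row) for t, row in by_type.items()}
    macro_f1 = (sum(v[2] for v in per_type.values()) / len(per_type)) if per_type else 0.0
    return EvalReport(
        precision=p, recall=r, f1=f1,
        n_gold=n_gold, n_predicted=predicted, n_matched=matched,
        per_type=per_type, macro_f1=macro_f1,
        nested_recall=(nested_matched / nested_gold if nested_gold else 0.0),
        n_gold_nested=nested_gold,
    )
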