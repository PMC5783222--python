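"""Accuracy / top-N evaluation and attention-heatmap export.

Top-N accuracy counts an instance as correct when the gold answer appears
among the N highest-probability candidates; top-1 equals plain accuracy and
top-N is non-decreasing in N.  The heatmap export writes every context
token with its attention weight plus the aggregated candidate
probabilities, machine-readable, for error analysis (e.g. causal-inference
and concept-hierarchy failure cases).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cloze import ClozeInstance
from .ensemble import EnsembleBundle, ensemble_predict
from .reader import AttentionResult, ReaderModel

__all__ = ["EvalReport", "evaluate", "export_attention", "read_attention"]


@dataclass
class EvalReport:
    """Exact counts over a dataset plus per-instance gold ranks."""

    n_instances: int
    accuracy: float
    top_n: dict[int, float]
    records: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {"n_instances": self.n_instances, "accuracy": self.accuracy,
                   "top_n": {str(k): v for k, v in self.top_n.items()},
                   "records": self.records}
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2)


def _score(predictor: ReaderModel | EnsembleBundle,
           instance: ClozeInstance) -> AttentionResult:
    if isinstance(predictor, EnsembleBundle):
        return ensemble_predict(instance, predictor)
    return predictor.predict(instance)


def evaluate(predictor: ReaderModel | EnsembleBundle,
             dataset: Sequence[ClozeInstance],
             ns: Sequence[int] = (1, 2, 3, 5)) -> EvalReport:
    """Compute accuracy and top-N accuracy by exact counting.

    The rank of the gold answer is its 1-based position in the ranked
    candidate list (ties already resolved by the reader's first-occurrence
    rule, so ranks are deterministic).
    """
    if not dataset:
        raise ValueError("empty dataset")
    ns = sorted(set(ns))
    records = []
    hits = {n: 0 for n in ns}
    for instance in dataset:
        result = _score(predictor, instance)
        gold_rank = result.ranked.index(instance.answer) + 1 \
            if instance.answer in result.ranked else len(result.ranked) + 1
        records.append({"source_article_id": instance.source_article_id,
                        "variant": instance.variant,
                        "predicted": result.predicted,
                        "gold": instance.answer,
                        "gold_rank": gold_rank})
        for n in ns:
            if gold_rank <= n:
                hits[n] += 1
    count = len(dataset)
    top_n = {n: hits[n] / count for n in ns}
    report = EvalReport(n_instances=count, accuracy=top_n.get(1, 0.0),
                        top_n=top_n, records=records)
    assert all(0.0 <= v <= 1.0 for v in top_n.values())
    assert all(top_n[a] <= top_n[b] for a, b in zip(ns, ns[1:]))
    return report


def export_attention(instance: ClozeInstance,
                     predictor: ReaderModel | EnsembleBundle,
                     path: str | Path) -> AttentionResult:
    """Write a line-delimited heatmap record for one instance.

    The first line holds metadata and the aggregated candidate
    probabilities; each following line is one ``{"token", "weight"}``
    record, one per context position, with weights summing to 1.
    """
    result = _score(predictor, instance)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(json.dumps({
            "source_article_id": instance.source_article_id,
            "variant": instance.variant,
            "question": list(instance.question_tokens),
            "answer": instance.answer,
            "candidate_probs": result.candidate_probs,
        }) + "\n")
        for token, weight in zip(instance.document_tokens, result.position_probs):
            handle.write(json.dumps({"token": token, "weight": float(weight)}) + "\n")
    return result


def read_attention(path: str | Path) -> tuple[dict, list[str], np.ndarray]:
    """Re-import an exported heatmap: (metadata, tokens, weights)."""
    with open(path, encoding="utf-8") as handle:
        meta = json.loads(handle.readline())
        tokens, weights = [], []
        for line in handle:
            if line.strip():
                record = json.loads(line)
                tokens.append(record["token"])
                weights.append(record["weight"])
    return meta, tokens, np.array(weights, dtype=np.float64)
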