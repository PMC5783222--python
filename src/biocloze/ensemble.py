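"""Probability-averaging ensembles of independently trained readers.

Members share the training data and architecture but differ in random
initialization; their per-candidate probability distributions are combined
by an unweighted arithmetic mean, which keeps the single-model bias while
reducing variance.  Membership follows a validation-accuracy floor (default
0.70) and a target ensemble size (default 8 members).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cloze import ClozeInstance
from .reader import AttentionResult, ReaderModel, _rank_candidates

__all__ = ["EnsembleBundle", "EmptyEnsembleError", "select_members",
           "ensemble_predict"]

#: Reference member-selection parameters.
DEFAULT_THRESHOLD = 0.70
DEFAULT_SIZE = 8


class EmptyEnsembleError(ValueError):
    """No candidate model met the validation-accuracy threshold."""


@dataclass
class EnsembleBundle:
    members: list[ReaderModel]
    threshold: float = DEFAULT_THRESHOLD
    target_size: int = DEFAULT_SIZE

    def __len__(self) -> int:
        return len(self.members)


def select_members(models: Sequence[ReaderModel],
                   threshold: float = DEFAULT_THRESHOLD,
                   target_size: int = DEFAULT_SIZE) -> EnsembleBundle:
    """Keep models whose validation accuracy meets the floor.

    Qualifying models are sorted by accuracy descending and truncated to
    ``target_size``.  Models must carry a recorded ``validation_accuracy``.
    """
    if not models:
        raise ValueError("no models supplied")
    scored = []
    for model in models:
        if model.validation_accuracy is None:
            raise ValueError("model lacks a recorded validation accuracy")
        if model.validation_accuracy >= threshold:
            scored.append(model)
    if not scored:
        raise EmptyEnsembleError(
            f"no model reached validation accuracy {threshold}")
    scored.sort(key=lambda m: -m.validation_accuracy)
    return EnsembleBundle(scored[:target_size], threshold, target_size)


def ensemble_predict(instance: ClozeInstance,
                     bundle: EnsembleBundle) -> AttentionResult:
    """Average the members' candidate distributions and rank from the mean.

    Position-level attention is averaged too (for heatmap export).  Members
    must share one vocabulary; order of members does not matter.
    """
    if not bundle.members:
        raise EmptyEnsembleError("empty ensemble")
    reference_vocab = bundle.members[0].embeddings.vocab.tokens
    for member in bundle.members[1:]:
        if member.embeddings.vocab.tokens != reference_vocab:
            raise ValueError("ensemble members use different vocabularies")
    results = [member.predict(instance) for member in bundle.members]
    k = len(results)
    mean_probs = {
        candidate: sum(r.candidate_probs[candidate] for r in results) / k
        for candidate in instance.candidates
    }
    mean_positions = sum(r.position_probs for r in results) / k
    ranked = _rank_candidates(mean_probs, instance.mention_positions)
    return AttentionResult(mean_positions, mean_probs, ranked)
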