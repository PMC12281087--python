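"""Memory-aware sentence-level semantic relevance.

A target sentence's relevance to its discourse neighbourhood is the weighted
sum of cosine similarities between its embedding and the embeddings of the
sentences in a four-sentence sliding window: the two preceding sentences
(c1 = t-1, c2 = t-2) and the one following sentence (n1 = t+1).

    relevance(t) = w_c1 * cos(t, c1) + w_c2 * cos(t, c2) + w_n1 * cos(t, n1)

The fixed recency-decay weights (default c1=1.0, c2=0.5, n1=0.3) emulate
working-memory recency: the immediately preceding sentence dominates, older
and upcoming context contribute less. The target's self-similarity is never
included. At document boundaries absent neighbours simply drop out of the sum
(no padding, no weight renormalization), which preserves two useful
properties: relevance is linear in the weights, and |value| is bounded by the
sum of the present neighbours' weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .backends import ScoringBackend, SentenceEmbedding, embed_sentence
from .corpus import Document, Sentence

__all__ = [
    "DEFAULT_WEIGHTS",
    "EQ1_LITERAL_WEIGHTS",
    "RelevanceWeights",
    "ContextWindow",
    "RelevanceResult",
    "cosine_similarity",
    "sentence_relevance",
    "document_relevance_profile",
    "relevance_profile_to_frame",
]

NEIGHBOR_SLOTS = ("c1", "c2", "n1")


@dataclass(frozen=True)
class RelevanceWeights:
    """Non-negative weights for the three neighbour slots."""

    c1: float = 1.0
    c2: float = 0.5
    n1: float = 0.3

    def __post_init__(self) -> None:
        vals = (self.c1, self.c2, self.n1)
        if any(w < 0 for w in vals):
            raise ValueError("relevance weights must be >= 0")
        if not any(w > 0 for w in vals):
            raise ValueError("at least one relevance weight must be positive")

    def as_dict(self) -> dict[str, float]:
        return {"c1": self.c1, "c2": self.c2, "n1": self.n1}

    def scaled(self, k: float) -> "RelevanceWeights":
        return RelevanceWeights(self.c1 * k, self.c2 * k, self.n1 * k)


#: Recency-decay default: immediate predecessor 1.0, two-back 0.5, next 0.3.
DEFAULT_WEIGHTS = RelevanceWeights(c1=1.0, c2=0.5, n1=0.3)

#: Alternative preset that assigns the largest weight to the two-back
#: sentence (the literal ordering some formulations list the weights in).
EQ1_LITERAL_WEIGHTS = RelevanceWeights(c2=1.0, c1=0.5, n1=0.3)

WEIGHT_PRESETS: Mapping[str, RelevanceWeights] = {
    "default": DEFAULT_WEIGHTS,
    "eq1-literal": EQ1_LITERAL_WEIGHTS,
}


@dataclass(frozen=True)
class ContextWindow:
    """Target sentence plus up to 2 preceding and 1 following sentence."""

    target: Sentence
    c1: Sentence | None = None
    c2: Sentence | None = None
    n1: Sentence | None = None

    def neighbors(self) -> dict[str, Sentence]:
        return {
            slot: s
            for slot, s in (("c1", self.c1), ("c2", self.c2), ("n1", self.n1))
            if s is not None
        }

    @classmethod
    def from_document(cls, document: Document, index: int) -> "ContextWindow":
        sents = document.sentences
        if not (0 <= index < len(sents)):
            raise IndexError(f"sentence index {index} out of range for {document.doc_id!r}")
        return cls(
            target=sents[index],
            c1=sents[index - 1] if index >= 1 else None,
            c2=sents[index - 2] if index >= 2 else None,
            n1=sents[index + 1] if index + 1 < len(sents) else None,
        )


@dataclass(frozen=True)
class RelevanceResult:
    doc_id: str
    sentence_index: int
    value: float
    similarities: Mapping[str, float]  # slot -> cosine, present neighbours only
    weights: RelevanceWeights
    backend_id: str

    def __post_init__(self) -> None:
        bound = sum(getattr(self.weights, slot) for slot in self.similarities) + 1e-12
        if abs(self.value) > bound:
            raise ValueError(
                f"relevance {self.value} exceeds weight bound {bound} "
                f"(doc {self.doc_id!r}, sentence {self.sentence_index})"
            )


def cosine_similarity(a: SentenceEmbedding, b: SentenceEmbedding) -> float:
    """Standard cosine of two equal-dimension, non-zero embeddings, in [-1, 1]."""
    va, vb = a.vector, b.vector
    if va.shape != vb.shape:
        raise ValueError(f"dimension mismatch: {va.shape} vs {vb.shape}")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("undefined cosine: zero vector")
    return float(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))


def sentence_relevance(
    window: ContextWindow,
    embedder: ScoringBackend,
    weights: RelevanceWeights = DEFAULT_WEIGHTS,
    doc_id: str = "",
) -> RelevanceResult:
    """Weighted sum of target-to-neighbour cosines over the present neighbours.

    Absent neighbours contribute 0 and their weights are *not* redistributed.
    """
    target_emb = embed_sentence(embedder, window.target)
    sims: dict[str, float] = {}
    value = 0.0
    for slot, neighbor in window.neighbors().items():
        sim = cosine_similarity(target_emb, embed_sentence(embedder, neighbor))
        sims[slot] = sim
        value += getattr(weights, slot) * sim
    return RelevanceResult(
        doc_id=doc_id,
        sentence_index=window.target.index,
        value=value,
        similarities=sims,
        weights=weights,
        backend_id=embedder.backend_id,
    )


def document_relevance_profile(
    document: Document,
    embedder: ScoringBackend,
    weights: RelevanceWeights = DEFAULT_WEIGHTS,
) -> list[RelevanceResult]:
    """One relevance value per sentence; windows truncate at the boundaries.

    Sentence 0 has only n1; the final sentence has only c1 (and c2 when the
    document is long enough); a single-sentence document scores 0.
    """
    results: list[RelevanceResult] = []
    for i in range(len(document.sentences)):
        try:
            window = ContextWindow.from_document(document, i)
            results.append(sentence_relevance(window, embedder, weights, document.doc_id))
        except Exception as exc:
            raise type(exc)(f"document {document.doc_id!r}, sentence {i}: {exc}") from exc
    return results


def relevance_profile_to_frame(results: Sequence[RelevanceResult]) -> pd.DataFrame:
    """Relevance results as a metric table with per-neighbour similarities."""
    return pd.DataFrame(
        {
            "doc_id": [r.doc_id for r in results],
            "sentence_index": [r.sentence_index for r in results],
            "method": ["relevance" for _ in results],
            "backend": [r.backend_id for r in results],
            "n_tokens": [0 for _ in results],
            "value": [r.value for r in results],
            "sim_c1": [r.similarities.get("c1", float("nan")) for r in results],
            "sim_c2": [r.similarities.get("c2", float("nan")) for r in results],
            "sim_n1": [r.similarities.get("n1", float("nan")) for r in results],
        }
    )
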