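"""Sentence surprisal: chain rule (CR), negative log-likelihood (NLL), and
next-sentence prediction (NSP).

All three quantify the unpredictability of a whole sentence given its
discourse context, as -log probability:

- **CR** factorizes the joint probability of the sentence's tokens given the
  preceding context via the chain rule and sums the per-token -log p; it is
  the joint -ln p(sentence | context).
- **NLL** is the per-token-normalized negative log-likelihood. On a causal
  backend it equals CR / n_tokens exactly; a bidirectional backend may score
  each token with full remaining context (pseudo-log-likelihood) instead.
- **NSP** is -ln of a next-sentence-prediction head's probability that the
  target follows its immediately preceding sentence (a two-sentence window).

Context is a bounded number of immediately preceding sentences (default 3),
emulating the limited window a reader holds in working memory; the document's
first sentence is scored with an empty context, no padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .backends import (
    LN2,
    ScoringBackend,
    next_sentence_prob,
    token_conditional_logprob,
)
from .corpus import Document, Sentence

__all__ = [
    "SurprisalConfig",
    "SurprisalResult",
    "chain_rule_surprisal",
    "nll_surprisal",
    "nsp_surprisal",
    "document_surprisal_profile",
    "profile_to_frame",
]

Method = Literal["CR", "NLL", "NSP"]


@dataclass(frozen=True)
class SurprisalConfig:
    """Method, context-window size (in sentences), and log base.

    NSP is inherently a two-sentence mechanism, so it forces
    ``context_sentences = 1`` regardless of what was requested.
    """

    method: Method = "CR"
    context_sentences: int = 3
    log_base: Literal["nats", "bits"] = "nats"

    def __post_init__(self) -> None:
        if self.method not in ("CR", "NLL", "NSP"):
            raise ValueError(f"unknown surprisal method {self.method!r}")
        if self.context_sentences < 0:
            raise ValueError("context_sentences must be >= 0")
        if self.method == "NSP" and self.context_sentences != 1:
            object.__setattr__(self, "context_sentences", 1)

    def _scale(self, nats: float) -> float:
        return nats / LN2 if self.log_base == "bits" else nats


@dataclass(frozen=True)
class SurprisalResult:
    doc_id: str
    sentence_index: int
    method: Method
    value: float
    n_tokens: int
    backend_id: str

    def __post_init__(self) -> None:
        if not (self.value >= 0.0):  # also rejects NaN
            raise ValueError(f"surprisal must be >= 0 and finite, got {self.value}")


def _context_tokens(context: Sequence[Sentence]) -> list[str]:
    toks: list[str] = []
    for s in context:
        toks.extend(s.words)
    return toks


def _token_scores(
    backend: ScoringBackend, context: Sequence[Sentence], target: Sentence
) -> list[float]:
    """Per-token -ln p(t_k | context + t_1..t_{k-1}), left-to-right."""
    if not target.words:
        raise ValueError("empty target sentence")
    prefix = _context_tokens(context)
    scores: list[float] = []
    for tok in target.words:
        scores.append(-token_conditional_logprob(backend, prefix, tok))
        prefix.append(tok)
    return scores


def chain_rule_surprisal(
    backend: ScoringBackend,
    context: Sequence[Sentence],
    target: Sentence,
    config: SurprisalConfig | None = None,
    doc_id: str = "",
) -> SurprisalResult:
    """Joint -ln p(target | context) via the chain rule over backend tokens."""
    config = config or SurprisalConfig(method="CR")
    scores = _token_scores(backend, context, target)
    return SurprisalResult(
        doc_id=doc_id,
        sentence_index=target.index,
        method="CR",
        value=config._scale(sum(scores)),
        n_tokens=len(scores),
        backend_id=backend.backend_id,
    )


def nll_surprisal(
    backend: ScoringBackend,
    context: Sequence[Sentence],
    target: Sentence,
    config: SurprisalConfig | None = None,
    doc_id: str = "",
) -> SurprisalResult:
    """Length-normalized NLL: (sum of per-token -ln p) / n_tokens.

    For causal backends the per-token scores are the chain-rule conditionals,
    so NLL == CR / n_tokens exactly. A backend advertising masked scoring may
    substitute pseudo-log-likelihood per-token scores behind the same call.
    """
    config = config or SurprisalConfig(method="NLL")
    scores = _token_scores(backend, context, target)
    return SurprisalResult(
        doc_id=doc_id,
        sentence_index=target.index,
        method="NLL",
        value=config._scale(sum(scores) / len(scores)),
        n_tokens=len(scores),
        backend_id=backend.backend_id,
    )


def nsp_surprisal(
    backend: ScoringBackend,
    prev: Sentence | None,
    target: Sentence,
    config: SurprisalConfig | None = None,
    doc_id: str = "",
) -> SurprisalResult:
    """-ln p(target follows prev) from an NSP-capable backend.

    ``prev=None`` (document start) is passed through: the backend's boundary
    policy decides the probability (the Jaccard toy treats it as an empty bag).
    """
    import math

    config = config or SurprisalConfig(method="NSP")
    p = next_sentence_prob(backend, prev, target)
    return SurprisalResult(
        doc_id=doc_id,
        sentence_index=target.index,
        method="NSP",
        value=config._scale(max(0.0, -math.log(p))),
        n_tokens=len(target.words),
        backend_id=backend.backend_id,
    )


def document_surprisal_profile(
    backend: ScoringBackend, document: Document, config: SurprisalConfig
) -> list[SurprisalResult]:
    """Score every sentence of a document: one result per sentence, in order.

    Context for sentence *t* is the ``config.context_sentences`` immediately
    preceding sentences (fewer near the document start). Per-sentence failures
    are re-raised with the sentence index attached.
    """
    results: list[SurprisalResult] = []
    for i, sent in enumerate(document.sentences):
        ctx = document.sentences[max(0, i - config.context_sentences) : i]
        try:
            if config.method == "CR":
                res = chain_rule_surprisal(backend, ctx, sent, config, document.doc_id)
            elif config.method == "NLL":
                res = nll_surprisal(backend, ctx, sent, config, document.doc_id)
            else:
                prev = document.sentences[i - 1] if i > 0 else None
                res = nsp_surprisal(backend, prev, sent, config, document.doc_id)
        except Exception as exc:
            raise type(exc)(
                f"document {document.doc_id!r}, sentence {i}: {exc}"
            ) from exc
        results.append(res)
    return results


def profile_to_frame(results: Sequence[SurprisalResult]) -> pd.DataFrame:
    """Surprisal results as a metric table (doc_id, sentence_index, ... value)."""
    return pd.DataFrame(
        {
            "doc_id": [r.doc_id for r in results],
            "sentence_index": [r.sentence_index for r in results],
            "method": [r.method for r in results],
            "backend": [r.backend_id for r in results],
            "n_tokens": [r.n_tokens for r in results],
            "value": [r.value for r in results],
        }
    )
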