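"""Language-model backend contract plus deterministic toy backends.

A :class:`ScoringBackend` supplies the three primitives every sentence-level
metric needs: token conditional log-probabilities, a next-sentence
probability, and sentence embeddings. The bundled toy backends (uniform,
bigram, bag-of-words embedder, Jaccard NSP) are exact, fast, and fully
deterministic, so every downstream metric is testable without model
downloads. Real multilingual LLM adapters (e.g. a masked or autoregressive
transformer) can plug in behind the same contract; a bidirectional model asked
for causal scoring should score the target with all right-context positions
masked.

All log-probabilities are natural log (nats); pass ``base="bits"`` to the
conversion helper where bits are wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .corpus import Sentence

__all__ = [
    "Capabilities",
    "ScoringBackend",
    "SentenceEmbedding",
    "UniformBackend",
    "BigramBackend",
    "CertaintyBackend",
    "ConstantNSPBackend",
    "JaccardNSPBackend",
    "BagOfWordsEmbedder",
    "token_conditional_logprob",
    "next_sentence_prob",
    "embed_sentence",
    "nats_to_bits",
    "make_backend",
]

LN2 = math.log(2.0)


def nats_to_bits(x: float) -> float:
    return x / LN2


@dataclass(frozen=True)
class Capabilities:
    causal_scoring: bool = False
    masked_scoring: bool = False
    nsp: bool = False
    embedding: bool = False


@dataclass(frozen=True)
class SentenceEmbedding:
    """A fixed-dimension sentence vector with backend provenance."""

    vector: np.ndarray
    backend_id: str
    pooling: str = "sum"

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("embedding contains non-finite entries")
        object.__setattr__(self, "vector", v)


@runtime_checkable
class ScoringBackend(Protocol):
    """Contract all backends satisfy; capability flags gate each primitive."""

    backend_id: str
    capabilities: Capabilities
    max_context_tokens: int

    def token_logprob(self, context: Sequence[str], target: str) -> float:
        """ln p(target | context), <= 0."""
        ...

    def next_sentence_prob(self, prev: Sentence | None, candidate: Sentence) -> float:
        ...

    def embed(self, sentence: Sentence) -> SentenceEmbedding:
        ...


class _BackendBase:
    """Shared plumbing: capability errors + context left-truncation."""

    backend_id = "base"
    capabilities = Capabilities()
    max_context_tokens = 512

    def _truncate(self, context: Sequence[str]) -> Sequence[str]:
        if len(context) > self.max_context_tokens:
            return context[-self.max_context_tokens :]
        return context

    def token_logprob(self, context: Sequence[str], target: str) -> float:
        raise NotImplementedError(
            f"backend {self.backend_id!r} does not support causal scoring"
        )

    def next_sentence_prob(self, prev: Sentence | None, candidate: Sentence) -> float:
        raise NotImplementedError(f"nsp unsupported by backend {self.backend_id!r}")

    def embed(self, sentence: Sentence) -> SentenceEmbedding:
        raise NotImplementedError(
            f"backend {self.backend_id!r} does not support embedding"
        )


class UniformBackend(_BackendBase):
    """Every token gets probability 1/|V| regardless of context.

    Out-of-vocabulary targets also score 1/|V| (the uniform distribution is
    over the declared vocabulary; unknown tokens are mapped onto it).
    """

    def __init__(self, vocabulary: Sequence[str]):
        if not vocabulary:
            raise ValueError("uniform backend needs a non-empty vocabulary")
        self.vocabulary = tuple(dict.fromkeys(vocabulary))
        self.backend_id = f"uniform|V|={len(self.vocabulary)}"
        self.capabilities = Capabilities(causal_scoring=True)

    def token_logprob(self, context: Sequence[str], target: str) -> float:
        self._truncate(context)
        return -math.log(len(self.vocabulary))

    def conditional_distribution(self, context: Sequence[str]) -> dict[str, float]:
        p = 1.0 / len(self.vocabulary)
        return {v: p for v in self.vocabulary}


class BigramBackend(_BackendBase):
    """Add-alpha smoothed first-order Markov model over a finite vocabulary.

    p(w | context) depends only on the last context token:
    (count(prev, w) + alpha) / (count(prev, *) + alpha*|V|). An empty context
    (or an out-of-vocabulary previous token) backs off to the start-of-text
    pseudo-token; out-of-vocabulary *targets* are remapped to ``<unk>``, which
    is always part of the vocabulary so distributions stay normalized.

    ``alpha=0`` gives the unsmoothed maximum-likelihood conditionals; querying
    an unseen (prev, target) pair then raises (probability would be 0 and the
    contract requires probabilities in (0, 1]).
    """

    BOS = "<s>"
    UNK = "<unk>"

    def __init__(
        self,
        counts: dict[tuple[str, str], float],
        alpha: float = 0.5,
        vocabulary: Sequence[str] | None = None,
    ):
        if alpha < 0:
            raise ValueError("smoothing alpha must be >= 0")
        self.alpha = alpha
        vocab = set(vocabulary or [])
        for (a, b), c in counts.items():
            if c < 0:
                raise ValueError("negative bigram count")
            vocab.add(b)
            if a != self.BOS:
                vocab.add(a)
        vocab.add(self.UNK)
        self.vocabulary = tuple(sorted(vocab))
        self._index = {w: i for i, w in enumerate(self.vocabulary)}
        self._counts = dict(counts)
        self._row_totals: dict[str, float] = {}
        for (a, _), c in counts.items():
            self._row_totals[a] = self._row_totals.get(a, 0.0) + c
        self.backend_id = f"bigram|V|={len(self.vocabulary)}"
        self.capabilities = Capabilities(causal_scoring=True)

    @classmethod
    def fit(cls, token_stream: Sequence[Sequence[str]], alpha: float = 0.5) -> "BigramBackend":
        """Count bigrams over sentences; each sentence starts from BOS."""
        counts: dict[tuple[str, str], float] = {}
        for sent in token_stream:
            prev = cls.BOS
            for tok in sent:
                counts[(prev, tok)] = counts.get((prev, tok), 0.0) + 1.0
                prev = tok
        return cls(counts, alpha=alpha)

    def _prev_token(self, context: Sequence[str]) -> str:
        context = self._truncate(context)
        if not context:
            return self.BOS
        prev = context[-1]
        if prev != self.BOS and prev not in self._index:
            return self.UNK
        return prev

    def token_logprob(self, context: Sequence[str], target: str) -> float:
        prev = self._prev_token(context)
        if target not in self._index:
            target = self.UNK
        num = self._counts.get((prev, target), 0.0) + self.alpha
        den = self._row_totals.get(prev, 0.0) + self.alpha * len(self.vocabulary)
        if num <= 0.0 or den <= 0.0:
            raise ValueError(
                f"zero conditional probability for {target!r} after {prev!r} "
                "(unsmoothed bigram); use alpha > 0"
            )
        return math.log(num / den)

    def conditional_distribution(self, context: Sequence[str]) -> dict[str, float]:
        """Full p(. | context) over the vocabulary (for enumeration checks)."""
        prev = self._prev_token(context)
        den = self._row_totals.get(prev, 0.0) + self.alpha * len(self.vocabulary)
        if den <= 0.0:
            raise ValueError(
                f"no conditional distribution after unseen token {prev!r} "
                "(unsmoothed bigram); use alpha > 0"
            )
        return {
            w: (self._counts.get((prev, w), 0.0) + self.alpha) / den
            for w in self.vocabulary
        }


class CertaintyBackend(_BackendBase):
    """Stub that returns probability 1 for every token: zero surprisal."""

    backend_id = "certainty-stub"
    capabilities = Capabilities(causal_scoring=True)

    def token_logprob(self, context: Sequence[str], target: str) -> float:
        return 0.0


class ConstantNSPBackend(_BackendBase):
    """Stub NSP head returning a fixed probability for any sentence pair."""

    def __init__(self, p: float = 0.5):
        if not (0.0 < p <= 1.0):
            raise ValueError("NSP probability must be in (0, 1]")
        self.p = p
        self.backend_id = f"nsp-const-{p}"
        self.capabilities = Capabilities(nsp=True)

    def next_sentence_prob(self, prev: Sentence | None, candidate: Sentence) -> float:
        return self.p


class JaccardNSPBackend(_BackendBase):
    """Deterministic NSP surrogate: p = eps + (1 - eps) * Jaccard(bags).

    Jaccard overlap of the two sentences' word sets (case-folded) is mapped
    affinely onto (eps, 1]: identical bags give exactly 1, disjoint bags give
    eps, so NSP surprisal is always finite. An absent previous sentence
    (document start) counts as an empty bag, i.e. overlap 0.
    """

    def __init__(self, eps: float = 0.01):
        if not (0.0 < eps < 1.0):
            raise ValueError("eps must be in (0, 1)")
        self.eps = eps
        self.backend_id = f"nsp-jaccard-eps{eps}"
        self.capabilities = Capabilities(nsp=True)

    def next_sentence_prob(self, prev: Sentence | None, candidate: Sentence) -> float:
        a = set(w.lower() for w in prev.words) if prev is not None else set()
        b = set(w.lower() for w in candidate.words)
        union = a | b
        jac = (len(a & b) / len(union)) if union else 0.0
        return self.eps + (1.0 - self.eps) * jac


class BagOfWordsEmbedder(_BackendBase):
    """Term-frequency sentence vectors over a fixed vocabulary ordering.

    Dimension = |vocabulary| + 1: the final component counts words outside the
    vocabulary, so no non-empty sentence ever maps to the zero vector.
    """

    def __init__(self, vocabulary: Sequence[str]):
        if not vocabulary:
            raise ValueError("bag-of-words embedder needs a vocabulary")
        self.vocabulary = tuple(dict.fromkeys(w.lower() for w in vocabulary))
        self._index = {w: i for i, w in enumerate(self.vocabulary)}
        self.backend_id = f"bow|V|={len(self.vocabulary)}"
        self.capabilities = Capabilities(embedding=True)

    def embed(self, sentence: Sentence) -> SentenceEmbedding:
        if not sentence.words:
            raise ValueError("cannot embed an empty sentence")
        vec = np.zeros(len(self.vocabulary) + 1, dtype=float)
        for w in sentence.words:
            vec[self._index.get(w.lower(), len(self.vocabulary))] += 1.0
        return SentenceEmbedding(vector=vec, backend_id=self.backend_id, pooling="bow-tf")


# ---------------------------------------------------------------------------
# Functional front-ends (capability checks + truncation live here)
# ---------------------------------------------------------------------------

def token_conditional_logprob(
    backend: ScoringBackend, context: Sequence[str], target: str
) -> float:
    """ln p(target | context); left-truncates context beyond the backend limit."""
    caps = backend.capabilities
    if not (caps.causal_scoring or caps.masked_scoring):
        raise ValueError(f"backend {backend.backend_id!r} cannot score tokens")
    if len(context) > backend.max_context_tokens:
        context = context[-backend.max_context_tokens :]
    lp = backend.token_logprob(context, target)
    if math.isnan(lp) or lp > 1e-12 or lp == -math.inf:
        raise ValueError(
            f"backend {backend.backend_id!r} returned invalid log-probability {lp}"
        )
    return min(lp, 0.0)


def next_sentence_prob(
    backend: ScoringBackend, prev: Sentence | None, candidate: Sentence
) -> float:
    if not backend.capabilities.nsp:
        raise ValueError("nsp unsupported")
    p = backend.next_sentence_prob(prev, candidate)
    if not (0.0 < p <= 1.0):
        raise ValueError(f"NSP probability out of (0, 1]: {p}")
    return p


def embed_sentence(backend: ScoringBackend, sentence: Sentence) -> SentenceEmbedding:
    if not backend.capabilities.embedding:
        raise ValueError(f"backend {backend.backend_id!r} cannot embed sentences")
    return backend.embed(sentence)


def make_backend(name: str, vocabulary: Sequence[str] | None = None) -> ScoringBackend:
    """Build a backend from a CLI-style name.

    Supported: ``uniform``, ``bigram:<counts.tsv>`` (3-column TSV: prev, word,
    count), ``bow``, ``nsp-jaccard``, ``nsp-const:<p>``, ``certainty``.
    ``uniform`` and ``bow`` require a vocabulary (e.g. the corpus frequency
    table's words).
    """
    if name == "uniform":
        if not vocabulary:
            raise ValueError("uniform backend requires a vocabulary")
        return UniformBackend(vocabulary)
    if name == "bow":
        if not vocabulary:
            raise ValueError("bow embedder requires a vocabulary")
        return BagOfWordsEmbedder(vocabulary)
    if name == "nsp-jaccard":
        return JaccardNSPBackend()
    if name == "certainty":
        return CertaintyBackend()
    if name.startswith("nsp-const:"):
        return ConstantNSPBackend(float(name.split(":", 1)[1]))
    if name.startswith("bigram:"):
        path = Path(name.split(":", 1)[1])
        counts: dict[tuple[str, str], float] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()  # prev, word, count
            for line in fh:
                prev, word, c = line.rstrip("\n").split("\t")
                counts[(prev, word)] = float(c)
        return BigramBackend(counts, vocabulary=vocabulary)
    raise ValueError(f"unknown backend {name!r}")
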