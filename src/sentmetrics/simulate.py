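"""Synthetic multilingual corpora and reading-behaviour tables with known truth.

The generator emulates the *shape* of a multilingual eye-tracking reading
corpus — several languages, a battery of short documents per language, tens
of participants per language, one total-fixation-duration observation per
participant x sentence — with fully synthetic content. Sentence reading
speed is generated from a known log-linear model:

    ln(speed) = b0 + b_len*len_z + b_freq*freq_z + b_surp*surp_z
                + b_rel*rel_z + language offset + participant intercept + eps

so every downstream stage (metric computation, joining, additive-model
fitting, AIC comparison) can be validated against ground truth. Predictors
are mean-centered across the corpus before entering the linear predictor, so
b0 is the log reading speed of an average sentence while differences on each
predictor translate exactly into exp(beta * difference) speed ratios.

Defaults: 3 languages x 20 participants x (10 documents x 12 sentences)
= 7,200 records; words drawn from a 500-type Zipfian vocabulary; sentence
lengths Poisson(mean 12, min 3); negative length and surprisal effects,
positive frequency and relevance effects.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .backends import BagOfWordsEmbedder, BigramBackend
from .corpus import Document, FrequencyTable, ReadingRecord, Sentence
from .relevance import DEFAULT_WEIGHTS, RelevanceWeights, document_relevance_profile, relevance_profile_to_frame
from .surprisal import SurprisalConfig, document_surprisal_profile, profile_to_frame

__all__ = [
    "EffectSizes",
    "SimConfig",
    "GroundTruth",
    "SimulatedDataset",
    "generate_corpus",
    "compute_metric_tables",
    "generate_reading_records",
    "simulate_dataset",
    "draw_independent_metrics",
]

_LANGUAGE_CODES = ("en", "nl", "es", "de", "fi", "ko", "ru", "tr", "he", "it", "no", "el", "et")


@dataclass(frozen=True)
class EffectSizes:
    """True coefficients of the generative model (per unit of each centered
    predictor)."""

    b0: float = math.log(2.0)  # baseline ~2 words/s
    b_len: float = -0.05
    b_freq: float = 0.05
    b_surp: float = -0.1
    b_rel: float = 0.1


@dataclass(frozen=True)
class SimConfig:
    n_languages: int = 3
    n_participants_per_language: int = 20
    n_documents: int = 10  # per language
    sentences_per_document: int = 12
    vocabulary_size: int = 500
    zipf_exponent: float = 1.1
    mean_sentence_length: float = 12.0
    min_sentence_length: int = 3
    effects: EffectSizes = field(default_factory=EffectSizes)
    sigma_participant: float = 0.1
    sigma_language: float = 0.05
    sigma_resid: float = 0.2
    # NLL (per-token) keeps the surprisal effect on a realistic scale; raw CR
    # grows linearly with sentence length and would swamp every other effect.
    surprisal_method: str = "NLL"
    relevance_weights: RelevanceWeights = field(default_factory=lambda: DEFAULT_WEIGHTS)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_languages",
            "n_participants_per_language",
            "n_documents",
            "sentences_per_document",
            "vocabulary_size",
            "min_sentence_length",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("sigma_participant", "sigma_language", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.vocabulary_size < self.min_sentence_length:
            raise ValueError("vocabulary_size must be >= min_sentence_length")


@dataclass
class GroundTruth:
    """Everything needed to check recovery: coefficients, random effects, and
    the per-record linear-predictor decomposition."""

    effects: EffectSizes
    predictor_stats: pd.DataFrame  # per-predictor mean (centering) and sd
    language_offsets: dict[str, float]
    participant_intercepts: dict[str, float]
    components: pd.DataFrame  # per-record: each beta*z term, offsets, eps, ln speed


@dataclass
class SimulatedDataset:
    config: SimConfig
    corpus: list[Document]
    frequencies: FrequencyTable
    surprisal: pd.DataFrame
    relevance: pd.DataFrame
    records: list[ReadingRecord]
    truth: GroundTruth


def _make_vocabulary(rng: np.random.Generator, size: int) -> list[str]:
    """Unique lowercase pseudo-words with Poisson-varied lengths."""
    letters = np.array(list(string.ascii_lowercase))
    vocab: list[str] = []
    seen: set[str] = set()
    while len(vocab) < size:
        length = 1 + int(rng.poisson(3.0))
        word = "".join(rng.choice(letters, size=length))
        while word in seen:
            word += str(rng.choice(letters))
        seen.add(word)
        vocab.append(word)
    return vocab


def _zipf_probs(size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def generate_corpus(config: SimConfig) -> tuple[list[Document], FrequencyTable]:
    """Zipfian random documents for every language; deterministic under seed.

    The frequency table holds the *generating* Zipf counts (scaled to a
    1,000,000-token normalizer), not the realized sample counts, mirroring how
    corpus-external frequency norms relate to any particular text.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_vocab, rng_text = [np.random.default_rng(s) for s in ss.spawn(2)]
    vocab = _make_vocabulary(rng_vocab, config.vocabulary_size)
    probs = _zipf_probs(config.vocabulary_size, config.zipf_exponent)
    counts = {w: max(1.0, round(p * 1_000_000)) for w, p in zip(vocab, probs)}
    freqs = FrequencyTable(counts, total=1_000_000)

    languages = [
        _LANGUAGE_CODES[i] if i < len(_LANGUAGE_CODES) else f"lang{i:02d}"
        for i in range(config.n_languages)
    ]
    vocab_arr = np.array(vocab)
    documents: list[Document] = []
    for lang in languages:
        for d in range(config.n_documents):
            sentences = []
            for s in range(config.sentences_per_document):
                n_words = max(
                    config.min_sentence_length,
                    int(rng_text.poisson(config.mean_sentence_length)),
                )
                words = tuple(rng_text.choice(vocab_arr, size=n_words, p=probs))
                sentences.append(
                    Sentence(index=s, text=" ".join(words) + ".", words=words)
                )
            documents.append(
                Document(doc_id=f"{lang}_doc{d:02d}", language=lang, sentences=tuple(sentences))
            )
    return documents, freqs


def compute_metric_tables(
    corpus: list[Document], config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score the synthetic corpus with the bundled toy backends.

    Surprisal comes from a bigram model fitted to the corpus itself (chain
    rule by default); relevance from bag-of-words embeddings under the
    configured recency weights.
    """
    all_sentences = [s.words for doc in corpus for s in doc.sentences]
    vocab = sorted({w for sent in all_sentences for w in sent})
    lm = BigramBackend.fit(all_sentences)
    embedder = BagOfWordsEmbedder(vocab)
    scfg = SurprisalConfig(method=config.surprisal_method)  # type: ignore[arg-type]

    surp_frames = [
        profile_to_frame(document_surprisal_profile(lm, doc, scfg)) for doc in corpus
    ]
    rel_frames = [
        relevance_profile_to_frame(
            document_relevance_profile(doc, embedder, config.relevance_weights)
        )
        for doc in corpus
    ]
    return (
        pd.concat(surp_frames, ignore_index=True),
        pd.concat(rel_frames, ignore_index=True),
    )


def _center(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(np.mean(x))
    sd = float(np.std(x))
    return x - mu, mu, sd


def generate_reading_records(
    corpus: list[Document],
    metrics: pd.DataFrame,
    config: SimConfig,
) -> tuple[list[ReadingRecord], GroundTruth]:
    """Simulate one observation per participant x sentence from known effects.

    ``metrics`` must carry one row per (doc_id, sentence_index) with columns
    ``surprisal`` and ``relevance``; non-finite values are rejected. Total
    fixation durations are back-computed as word_count / speed.
    """
    needed = {"doc_id", "sentence_index", "surprisal", "relevance"}
    missing = needed - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing column(s): {sorted(missing)}")
    if not np.isfinite(metrics[["surprisal", "relevance"]].to_numpy()).all():
        raise ValueError("non-finite metric value in metrics table")

    from .corpus import mean_word_length  # local import avoids cycle at module load

    sent_rows = []
    for doc in corpus:
        for s in doc.sentences:
            sent_rows.append(
                {
                    "language": doc.language,
                    "doc_id": doc.doc_id,
                    "sentence_index": s.index,
                    "word_count": len(s.words),
                    "mean_word_length": mean_word_length(s),
                }
            )
    sent = pd.DataFrame(sent_rows).merge(
        metrics[["doc_id", "sentence_index", "surprisal", "relevance"]],
        on=["doc_id", "sentence_index"],
        how="left",
    )
    if sent[["surprisal", "relevance"]].isna().any().any():
        raise ValueError("metrics do not cover every sentence in the corpus")

    # mean log word frequency is part of the metrics frame when provided,
    # otherwise it must be merged in by the caller via the 'mean_log_wordfreq'
    # column; the full pipeline (simulate_dataset) always provides it.
    if "mean_log_wordfreq" in metrics.columns:
        sent = sent.merge(
            metrics[["doc_id", "sentence_index", "mean_log_wordfreq"]],
            on=["doc_id", "sentence_index"],
            how="left",
        )
    else:
        raise ValueError("metrics table must include a mean_log_wordfreq column")

    ss = np.random.SeedSequence([config.seed, 7])
    rng_lang, rng_part, rng_eps = [np.random.default_rng(s) for s in ss.spawn(3)]

    languages = sorted({doc.language for doc in corpus})
    language_offsets = {
        lang: float(rng_lang.normal(0.0, config.sigma_language)) for lang in languages
    }
    participant_intercepts: dict[str, float] = {}
    participants_by_lang: dict[str, list[str]] = {}
    for lang in languages:
        ids = [f"{lang}_p{j:02d}" for j in range(config.n_participants_per_language)]
        participants_by_lang[lang] = ids
        for pid in ids:
            participant_intercepts[pid] = float(rng_part.normal(0.0, config.sigma_participant))

    stats_rows = []
    zcols = {}
    for col in ("mean_word_length", "mean_log_wordfreq", "surprisal", "relevance"):
        z, mu, sd = _center(sent[col].to_numpy(dtype=float))
        zcols[col] = z
        stats_rows.append({"predictor": col, "mean": mu, "sd": sd})
    predictor_stats = pd.DataFrame(stats_rows)

    eff = config.effects
    base = (
        eff.b0
        + eff.b_len * zcols["mean_word_length"]
        + eff.b_freq * zcols["mean_log_wordfreq"]
        + eff.b_surp * zcols["surprisal"]
        + eff.b_rel * zcols["relevance"]
    )

    records: list[ReadingRecord] = []
    comp_rows = []
    for lang in languages:
        lang_mask = (sent["language"] == lang).to_numpy()
        idx = np.flatnonzero(lang_mask)
        for pid in participants_by_lang[lang]:
            eps = rng_eps.normal(0.0, config.sigma_resid, size=idx.size)
            ln_speed = base[idx] + language_offsets[lang] + participant_intercepts[pid] + eps
            speed = np.exp(ln_speed)
            wc = sent["word_count"].to_numpy()[idx]
            duration_ms = wc / speed * 1000.0
            for k, i in enumerate(idx):
                records.append(
                    ReadingRecord(
                        language=lang,
                        participant=pid,
                        doc_id=sent["doc_id"].iat[i],
                        sentence_index=int(sent["sentence_index"].iat[i]),
                        word_count=int(wc[k]),
                        total_fixation_duration_ms=float(duration_ms[k]),
                    )
                )
                comp_rows.append(
                    {
                        "participant": pid,
                        "doc_id": sent["doc_id"].iat[i],
                        "sentence_index": int(sent["sentence_index"].iat[i]),
                        "term_len": eff.b_len * zcols["mean_word_length"][i],
                        "term_freq": eff.b_freq * zcols["mean_log_wordfreq"][i],
                        "term_surp": eff.b_surp * zcols["surprisal"][i],
                        "term_rel": eff.b_rel * zcols["relevance"][i],
                        "language_offset": language_offsets[lang],
                        "participant_intercept": participant_intercepts[pid],
                        "eps": float(eps[k]),
                        "ln_speed": float(ln_speed[k]),
                    }
                )

    truth = GroundTruth(
        effects=eff,
        predictor_stats=predictor_stats,
        language_offsets=language_offsets,
        participant_intercepts=participant_intercepts,
        components=pd.DataFrame(comp_rows),
    )
    return records, truth


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full pipeline: corpus -> toy-backend metrics -> reading records."""
    from .corpus import mean_log_word_frequency

    corpus, freqs = generate_corpus(config)
    surp, rel = compute_metric_tables(corpus, config)
    metrics = surp.rename(columns={"value": "surprisal"})[
        ["doc_id", "sentence_index", "surprisal"]
    ].merge(
        rel.rename(columns={"value": "relevance"})[["doc_id", "sentence_index", "relevance"]],
        on=["doc_id", "sentence_index"],
    )
    mlf = []
    for doc in corpus:
        for s in doc.sentences:
            mlf.append(
                {
                    "doc_id": doc.doc_id,
                    "sentence_index": s.index,
                    "mean_log_wordfreq": mean_log_word_frequency(s, freqs),
                }
            )
    metrics = metrics.merge(pd.DataFrame(mlf), on=["doc_id", "sentence_index"])
    records, truth = generate_reading_records(corpus, metrics, config)
    return SimulatedDataset(
        config=config,
        corpus=corpus,
        frequencies=freqs,
        surprisal=surp,
        relevance=rel,
        records=records,
        truth=truth,
    )


def draw_independent_metrics(n: int, seed: int) -> pd.DataFrame:
    """Two metric columns drawn independently of one another.

    Surprisal is lognormal (positive, right-skewed, like -log probabilities
    of variable-length sentences); relevance is Gaussian. Used to check that
    the correlation machinery reports ~0 for genuinely unrelated metrics.
    """
    if n < 3:
        raise ValueError("need at least 3 rows")
    ss = np.random.SeedSequence([seed, 101])
    r1, r2 = [np.random.default_rng(s) for s in ss.spawn(2)]
    return pd.DataFrame(
        {
            "surprisal": r1.lognormal(mean=1.0, sigma=0.5, size=n),
            "relevance": r2.normal(loc=0.8, scale=0.3, size=n),
        }
    )
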