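"""Document/sentence data model, segmentation, control predictors, and table IO.

The unit of analysis throughout the package is the *sentence*: an ordered
word-token sequence with its raw text and 0-based position inside a document.
Reading behaviour is recorded per (participant, sentence) as a total fixation
duration in milliseconds, from which reading speed (words per second) derives.
"""

from __future__ import annotations

import json
import math
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "Sentence",
    "Document",
    "FrequencyTable",
    "ReadingRecord",
    "segment_document",
    "tokenize_words",
    "mean_word_length",
    "mean_log_word_frequency",
    "compute_reading_speed",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "read_frequency_table",
    "write_frequency_table",
    "read_reading_table",
    "write_reading_table",
    "write_metric_table",
    "read_metric_table",
    "READING_TABLE_COLUMNS",
    "METRIC_TABLE_COLUMNS",
    "TableError",
]

# Sentence terminators: Latin and CJK full stops / exclamation / question marks.
_TERMINATORS = ".!?。！？"
_SENT_RE = re.compile(rf"[^{_TERMINATORS}]*[{_TERMINATORS}]+(?:\s+|$)|[^{_TERMINATORS}]+$")


class TableError(ValueError):
    """Raised when a tabular input violates the declared schema."""


@dataclass(frozen=True)
class Sentence:
    """One sentence: 0-based index, raw text, and surface word tokens."""

    index: int
    text: str
    words: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"sentence index must be >= 0, got {self.index}")
        if not self.words:
            raise ValueError(f"sentence {self.index} has no words after segmentation")


@dataclass(frozen=True)
class Document:
    """An ordered sequence of sentences sharing a doc_id and language code."""

    doc_id: str
    language: str
    sentences: tuple[Sentence, ...]

    def __post_init__(self) -> None:
        if not self.sentences:
            raise ValueError(f"document {self.doc_id!r} has no sentences")
        indices = [s.index for s in self.sentences]
        if indices != list(range(len(indices))):
            raise ValueError(
                f"document {self.doc_id!r}: sentence indices must be 0-based and "
                f"contiguous, got {indices}"
            )

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[Sentence]:
        return iter(self.sentences)


def _strip_word(token: str) -> str:
    """Strip leading/trailing punctuation & symbols from a surface token."""
    chars = list(token)
    while chars and unicodedata.category(chars[0])[0] in ("P", "S"):
        chars.pop(0)
    while chars and unicodedata.category(chars[-1])[0] in ("P", "S"):
        chars.pop()
    return "".join(chars)


def tokenize_words(text: str) -> tuple[str, ...]:
    """Whitespace-split, then strip surrounding punctuation from each token.

    Tokens that are pure punctuation vanish. CJK text must arrive pre-tokenized
    (space-delimited); this rule is declared in the corpus reader dialect.
    """
    words = []
    for tok in text.split():
        w = _strip_word(tok)
        if w:
            words.append(w)
    return tuple(words)


def segment_document(text: str, doc_id: str, language: str) -> Document:
    """Split raw text into sentences on terminal punctuation, then word-tokenize.

    Sentences end at ``. ! ?`` (or CJK 。！？) followed by whitespace or
    end-of-text; trailing text without a terminator forms a final sentence.
    Raises ``ValueError`` on empty input or if a span yields no words.
    """
    if not text or not text.strip():
        raise ValueError("empty document")
    sentences: list[Sentence] = []
    for match in _SENT_RE.finditer(text.strip()):
        raw = match.group(0).strip()
        if not raw:
            continue
        words = tokenize_words(raw)
        if not words:
            # punctuation-only span: attach nothing, skip
            continue
        sentences.append(Sentence(index=len(sentences), text=raw, words=words))
    if not sentences:
        raise ValueError("empty document")
    return Document(doc_id=doc_id, language=language, sentences=tuple(sentences))


class FrequencyTable:
    """Case-insensitive word -> count lookup with a declared total normalizer.

    Counts must be positive. Lookup lowercases (NFC-normalized) the query; the
    out-of-vocabulary policy lives with the consumer (see
    :func:`mean_log_word_frequency`).
    """

    def __init__(self, counts: Mapping[str, float], total: float | None = None):
        if not counts:
            raise ValueError("empty frequency table")
        self._counts: dict[str, float] = {}
        for word, c in counts.items():
            if c <= 0:
                raise ValueError(f"non-positive count for {word!r}: {c}")
            self._counts[self._norm(word)] = self._counts.get(self._norm(word), 0) + c
        self.total = float(total) if total is not None else float(sum(self._counts.values()))
        if self.total <= 0:
            raise ValueError("total count must be positive")

    @staticmethod
    def _norm(word: str) -> str:
        return unicodedata.normalize("NFC", word).lower()

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, word: str) -> bool:
        return self._norm(word) in self._counts

    def count(self, word: str) -> float | None:
        return self._counts.get(self._norm(word))

    def items(self):
        return self._counts.items()


def mean_word_length(sentence: Sentence) -> float:
    """Mean number of characters per (punctuation-stripped) word."""
    if not sentence.words:
        raise ValueError("sentence has no words")
    return sum(len(w) for w in sentence.words) / len(sentence.words)


def mean_log_word_frequency(
    sentence: Sentence,
    freqs: FrequencyTable,
    oov_policy: str = "laplace",
) -> float:
    """Mean natural-log relative frequency (count / total) over the words.

    ``oov_policy``:

    - ``"laplace"`` (default): unknown words get count 1 — a Laplace floor that
      keeps the log finite;
    - ``"skip"``: unknown words are dropped from the mean (error if all are
      unknown);
    - ``"error"``: unknown words raise ``KeyError``.
    """
    if not sentence.words:
        raise ValueError("sentence has no words")
    logs: list[float] = []
    for w in sentence.words:
        c = freqs.count(w)
        if c is None:
            if oov_policy == "laplace":
                c = 1.0
            elif oov_policy == "skip":
                continue
            else:
                raise KeyError(f"out-of-vocabulary word {w!r}")
        logs.append(math.log(c / freqs.total))
    if not logs:
        raise ValueError("no in-vocabulary words in sentence")
    return sum(logs) / len(logs)


@dataclass(frozen=True)
class ReadingRecord:
    """One participant x sentence observation."""

    language: str
    participant: str
    doc_id: str
    sentence_index: int
    word_count: int
    total_fixation_duration_ms: float

    def __post_init__(self) -> None:
        if self.word_count < 1:
            raise ValueError(f"word_count must be >= 1, got {self.word_count}")
        if not (self.total_fixation_duration_ms > 0) or not math.isfinite(
            self.total_fixation_duration_ms
        ):
            raise ValueError(
                f"total_fixation_duration_ms must be finite and > 0, got "
                f"{self.total_fixation_duration_ms}"
            )


def compute_reading_speed(record: ReadingRecord) -> float:
    """Reading speed in words per second: word_count / duration-in-seconds."""
    return record.word_count / (record.total_fixation_duration_ms / 1000.0)


# ---------------------------------------------------------------------------
# IO: corpus JSONL, frequency TSV, reading TSV, metric TSV
# ---------------------------------------------------------------------------

READING_TABLE_COLUMNS = (
    "language",
    "participant",
    "doc_id",
    "sentence_index",
    "word_count",
    "total_fixation_duration_ms",
)

METRIC_TABLE_COLUMNS = ("doc_id", "sentence_index", "method", "backend", "n_tokens", "value")


def read_corpus_jsonl(path: str | Path) -> list[Document]:
    """Read documents from JSONL: {doc_id, language, text} or {..., sentences}.

    A ``sentences`` record carries pre-segmented raw sentence strings (each is
    word-tokenized here); a ``text`` record is segmented by
    :func:`segment_document`.
    """
    docs: list[Document] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise TableError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
            for key in ("doc_id", "language"):
                if key not in rec:
                    raise TableError(f"{path}:{lineno}: missing required key {key!r}")
            if "sentences" in rec:
                sents = tuple(
                    Sentence(index=i, text=raw, words=tokenize_words(raw))
                    for i, raw in enumerate(rec["sentences"])
                )
                docs.append(Document(rec["doc_id"], rec["language"], sents))
            elif "text" in rec:
                docs.append(segment_document(rec["text"], rec["doc_id"], rec["language"]))
            else:
                raise TableError(f"{path}:{lineno}: need either 'text' or 'sentences'")
    return docs


def write_corpus_jsonl(documents: Iterable[Document], path: str | Path) -> None:
    """Write documents as JSONL with pre-segmented sentence strings."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in documents:
            rec = {
                "doc_id": doc.doc_id,
                "language": doc.language,
                "sentences": [s.text for s in doc.sentences],
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_frequency_table(path: str | Path) -> FrequencyTable:
    """Read a 2-column TSV (word, count) with header into a FrequencyTable."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise TableError(f"{path}: expected 2 columns (word, count), got {df.shape[1]}")
    word_col, count_col = df.columns[0], df.columns[1]
    return FrequencyTable(dict(zip(df[word_col].astype(str), df[count_col].astype(float))))


def write_frequency_table(freqs: FrequencyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("word\tcount\n")
        for word, count in sorted(freqs.items()):
            c = int(count) if float(count).is_integer() else count
            fh.write(f"{word}\t{c}\n")


def read_reading_table(path: str | Path, dialect: str = "tsv") -> list[ReadingRecord]:
    """Parse a reading-behaviour table; report every bad row with its line number.

    Raises :class:`TableError` naming any missing column, or listing each
    malformed/invalid row (1-based data line numbers, header = line 1).
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in READING_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: list[ReadingRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        lineno = int(i) + 2  # header is line 1
        try:
            records.append(
                ReadingRecord(
                    language=row["language"],
                    participant=row["participant"],
                    doc_id=row["doc_id"],
                    sentence_index=int(row["sentence_index"]),
                    word_count=int(row["word_count"]),
                    total_fixation_duration_ms=float(row["total_fixation_duration_ms"]),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise TableError(f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors))
    return records


def write_reading_table(records: Sequence[ReadingRecord], path: str | Path) -> None:
    """Write reading records as TSV in the fixed documented column order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(READING_TABLE_COLUMNS) + "\n")
        for r in records:
            dur = repr(r.total_fixation_duration_ms)  # shortest exact round-trip form
            fh.write(
                f"{r.language}\t{r.participant}\t{r.doc_id}\t{r.sentence_index}\t"
                f"{r.word_count}\t{dur}\n"
            )


def write_metric_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a per-sentence metric table (TSV, fixed column order).

    Expects at least the columns in ``METRIC_TABLE_COLUMNS``; extra columns
    (e.g. per-neighbour similarities) are appended after the fixed ones.
    """
    missing = [c for c in METRIC_TABLE_COLUMNS if c not in records.columns]
    if missing:
        raise TableError(f"metric table missing column(s): {', '.join(missing)}")
    extra = [c for c in records.columns if c not in METRIC_TABLE_COLUMNS]
    records[list(METRIC_TABLE_COLUMNS) + extra].to_csv(path, sep="\t", index=False)


def read_metric_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METRIC_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing column(s): {', '.join(missing)}")
    return df
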