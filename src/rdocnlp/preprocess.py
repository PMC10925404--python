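"""Corpus ingestion, sentence segmentation, and keyword search.

Covers the front of the extraction pipeline: stream clinical notes from
CSV/JSONL, segment note text into sentences with character offsets, and
pull out *candidate sentences* — the sentences containing at least one
keyword-dictionary phrase — that the semantic matcher will score.

Tokenization splits on non-alphanumeric characters (hyphens split), and
keyword matching is token-boundary based and case-insensitive: "art" never
matches inside "heart".  Matching is greedy left-to-right with the longest
phrase preferred at each position (maximal munch), so "panic attacks" wins
over "panic" when both are in the dictionary.

No negation handling is attempted: "denies panic attacks" still yields a
keyword hit.  This is a deliberate, documented limitation of the approach.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Iterator

from .dictionary import KeywordDictionary, normalize_phrase

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalNote",
    "SentenceRecord",
    "KeywordHit",
    "CandidateSentence",
    "CorpusStream",
    "read_corpus",
    "segment_sentences",
    "tokenize",
    "find_keywords",
    "extract_candidates",
    "CorpusFormatError",
]

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")

# Clinical abbreviations whose trailing period must not end a sentence.
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "st",
    "pt", "pts", "hx", "dx", "tx", "rx", "sx", "fx",
    "vs", "etc", "approx", "appt", "dept", "wk", "mo", "yr",
    "e.g", "i.e", "b.i.d", "t.i.d", "q.i.d", "q.d", "p.r.n", "p.o",
}


class CorpusFormatError(ValueError):
    """A corpus file is missing a required column or is structurally broken."""


@dataclass(frozen=True)
class ClinicalNote:
    patient_id: str
    note_id: str
    date: Date
    text: str


@dataclass(frozen=True)
class SentenceRecord:
    """One sentence of a note with 0-based half-open character offsets."""

    note_id: str
    sent_index: int
    text: str
    char_start: int
    char_end: int


@dataclass(frozen=True)
class KeywordHit:
    """A keyword-dictionary phrase located at half-open token indices."""

    phrase: str
    token_start: int
    token_end: int


@dataclass(frozen=True)
class CandidateSentence:
    sentence: SentenceRecord
    patient_id: str
    date: Date
    hits: tuple[KeywordHit, ...]

    @property
    def key(self) -> tuple[str, int]:
        return (self.sentence.note_id, self.sentence.sent_index)

    @property
    def text(self) -> str:
        return self.sentence.text

    def hit_phrases(self) -> frozenset[str]:
        return frozenset(h.phrase for h in self.hits)


class CorpusStream(Iterator[ClinicalNote]):
    """Iterator over notes that counts skipped malformed rows as it goes."""

    def __init__(self, gen: Iterator[ClinicalNote]):
        self._gen = gen
        self.n_skipped = 0
        self.n_empty_text = 0

    def __iter__(self) -> "CorpusStream":
        return self

    def __next__(self) -> ClinicalNote:
        return next(self._gen)


_REQUIRED_COLUMNS = ("patient_id", "note_id", "date", "text")


def read_corpus(path: str | Path, format: str | None = None) -> CorpusStream:
    """Stream ``ClinicalNote`` records from a CSV (RFC 4180) or JSONL file.

    Rows missing patient_id/note_id/date, or with an unparsable ISO date,
    are logged and skipped (see ``CorpusStream.n_skipped``); a missing
    *column* is a hard error.  Empty text is allowed — such notes are
    yielded and simply produce no sentences downstream.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson") else "csv"
    if format not in ("csv", "jsonl"):
        raise CorpusFormatError(f"unsupported corpus format {format!r}")

    stream = CorpusStream(iter(()))

    def gen() -> Iterator[ClinicalNote]:
        with open(path, newline="", encoding="utf-8") as fh:
            if format == "csv":
                reader = csv.DictReader(fh)
                header = reader.fieldnames or []
                for col in _REQUIRED_COLUMNS:
                    if col not in header:
                        raise CorpusFormatError(f"{path}: missing required column {col!r}")
                rows: Iterable[dict] = reader
            else:
                rows = (json.loads(line) for line in fh if line.strip())
            for rowno, row in enumerate(rows, start=1):
                if format == "jsonl":
                    missing = [c for c in _REQUIRED_COLUMNS if c not in row]
                    if missing:
                        raise CorpusFormatError(
                            f"{path} record {rowno}: missing required column {missing[0]!r}"
                        )
                try:
                    pid = str(row["patient_id"]).strip()
                    nid = str(row["note_id"]).strip()
                    d = Date.fromisoformat(str(row["date"]).strip())
                    if not pid or not nid:
                        raise ValueError("empty id")
                except (KeyError, ValueError, TypeError) as exc:
                    stream.n_skipped += 1
                    logger.warning("%s row %d skipped: %s", path, rowno, exc)
                    continue
                text = str(row["text"] or "")
                if not text.strip():
                    stream.n_empty_text += 1
                    logger.debug("%s row %d: empty note text", path, rowno)
                yield ClinicalNote(patient_id=pid, note_id=nid, date=d, text=text)
        if stream.n_skipped:
            logger.info("%s: skipped %d malformed row(s)", path, stream.n_skipped)

    stream._gen = gen()
    return stream


def _is_abbreviation(text: str, period_idx: int) -> bool:
    # word immediately before the period, possibly dotted (b.i.d)
    j = period_idx
    start = j
    while start > 0 and (text[start - 1].isalnum() or text[start - 1] == "."):
        start -= 1
    word = text[start:j].lower().rstrip(".")
    if not word:
        return False
    if word in _ABBREVIATIONS or word.lstrip(".") in _ABBREVIATIONS:
        return True
    tail = word.split(".")[-1]
    if len(tail) == 1:  # initials and dotted abbreviations like b.i.d
        return True
    return False


def segment_sentences(note: ClinicalNote | str, note_id: str = "") -> list[SentenceRecord]:
    """Rule-based sentence segmentation tuned for clinical text.

    Boundaries: hard newlines (notes are list-heavy) and terminal
    punctuation ``. ! ?`` followed by whitespace, with common clinical
    abbreviations (Dr., pt., hx., b.i.d., ...) protected.  Spans are
    trimmed to non-whitespace; their concatenation covers every
    non-whitespace character and spans never overlap.
    """
    if isinstance(note, ClinicalNote):
        text, nid = note.text, note.note_id
    else:
        text, nid = note, note_id

    boundaries = [0]
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c == "\n":
            boundaries.append(i + 1)
        elif c in ".!?":
            # run of terminal punctuation
            j = i
            while j + 1 < n and text[j + 1] in ".!?":
                j += 1
            nxt = j + 1
            if nxt >= n or text[nxt].isspace():
                if not (c == "." and _is_abbreviation(text, i)):
                    boundaries.append(nxt)
                i = j
        i += 1
    boundaries.append(n)

    records: list[SentenceRecord] = []
    for a, b in zip(boundaries, boundaries[1:]):
        chunk = text[a:b]
        stripped = chunk.strip()
        if not stripped:
            continue
        start = a + (len(chunk) - len(chunk.lstrip()))
        end = start + len(stripped)
        records.append(
            SentenceRecord(
                note_id=nid,
                sent_index=len(records),
                text=text[start:end],
                char_start=start,
                char_end=end,
            )
        )
    return records


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Lowercased alphanumeric tokens with character offsets."""
    return [(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _phrase_index(kd: KeywordDictionary) -> dict[str, list[tuple[str, ...]]]:
    """first-token -> phrase token tuples, longest first."""
    index: dict[str, list[tuple[str, ...]]] = {}
    for phrase in kd.all_phrases():
        toks = tuple(normalize_phrase(phrase).split())
        index.setdefault(toks[0], []).append(toks)
    for lst in index.values():
        lst.sort(key=len, reverse=True)
    return index


def find_keywords(sentence_text: str, kd: KeywordDictionary) -> list[KeywordHit]:
    """All token-boundary matches of keyword phrases (any domain), greedy
    left-to-right with the longest phrase preferred at each start position.

    Matches never overlap; output is sorted by ``token_start``.
    """
    tokens = [t for t, _, _ in tokenize(sentence_text)]
    index = _phrase_index(kd)
    hits: list[KeywordHit] = []
    i = 0
    while i < len(tokens):
        advance = 1
        for phrase_toks in index.get(tokens[i], ()):
            L = len(phrase_toks)
            if tuple(tokens[i : i + L]) == phrase_toks:
                hits.append(
                    KeywordHit(phrase=" ".join(phrase_toks), token_start=i, token_end=i + L)
                )
                advance = L
                break
        i += advance
    return hits


def extract_candidates(
    corpus: Iterable[ClinicalNote], kd: KeywordDictionary
) -> Iterator[CandidateSentence]:
    """Yield exactly the sentences containing >= 1 keyword hit."""
    phrase_counts: Counter[str] = Counter()
    any_found = False
    for note in corpus:
        if not note.text.strip():
            continue
        for rec in segment_sentences(note):
            hits = find_keywords(rec.text, kd)
            if hits:
                any_found = True
                phrase_counts.update(h.phrase for h in hits)
                yield CandidateSentence(
                    sentence=rec, patient_id=note.patient_id, date=note.date, hits=tuple(hits)
                )
    if not any_found:
        logger.warning("no keyword-bearing sentences found in corpus")
    else:
        logger.debug("keyword hit counts: %s", dict(phrase_counts))
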