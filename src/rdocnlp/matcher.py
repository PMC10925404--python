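"""Keyword-gated best-match annotation of candidate sentences.

The heart of the pipeline.  Each candidate sentence (sentence A) is
compared against the exemplar sentences of the sentence dictionary
(sentence B pool), but only against the entries that share at least one
keyword phrase with it — the *keyword gate*.  Among the gated entries the
one with maximal cosine similarity wins (ties broken by smallest
entry_id), and the match is *accepted* when its score reaches the cosine
threshold θ (default 0.3).  An accepted match assigns the matched entry's
RDoC domain to the sentence; one annotation is produced per sentence, not
per keyword hit.

``DictionarySentenceMatcher`` is a scikit-learn-style estimator: ``fit``
takes the sentence dictionary (embedding it once — the dictionary is the
hot inner loop), ``predict`` maps candidate sentences to domain labels,
and ``annotate_corpus`` returns full :class:`Annotation` records.  The
module-level functions are thin wrappers over it.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .dictionary import SentenceDictionary, SentenceDictionaryEntry
from .embedding import EmbeddingBackend, hashing_embedder
from .preprocess import CandidateSentence

logger = logging.getLogger(__name__)

__all__ = [
    "Annotation",
    "MatcherConfig",
    "DictionarySentenceMatcher",
    "gate_entries",
    "annotate_sentence",
    "annotate_corpus",
    "write_annotations",
]

NO_MATCH_SCORE = float("-inf")  # sentinel: empty keyword gate


@dataclass(frozen=True)
class Annotation:
    """One (possibly rejected) match of a note sentence to the dictionary."""

    patient_id: str
    note_id: str
    sent_index: int
    date: Date
    text: str
    matched_entry_id: int | None
    gate_keyword: str | None
    score: float
    domain: str | None
    accepted: bool

    @property
    def key(self) -> tuple[str, int]:
        return (self.note_id, self.sent_index)


@dataclass(frozen=True)
class MatcherConfig:
    threshold: float = 0.3
    tie_break: str = "entry_id"

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")


def gate_entries(
    candidate: CandidateSentence, sd: SentenceDictionary
) -> list[SentenceDictionaryEntry]:
    """Exactly the dictionary entries sharing >= 1 keyword phrase with the
    candidate's hits, ordered by entry_id."""
    phrases = candidate.hit_phrases()
    return [e for e in sd.entries if e.keywords & phrases]


class DictionarySentenceMatcher(BaseEstimator):
    """Annotate candidate sentences by keyword-gated nearest-exemplar match.

    Parameters
    ----------
    threshold : float, default=0.3
        Cosine similarity acceptance threshold θ.  The default is the
        empirically calibrated operating point for the pretrained
        768-dimensional backend; other backends or dictionaries should be
        recalibrated (see :mod:`rdocnlp.calibration`).
    tie_break : str, default="entry_id"
        Tie rule among equally similar gated entries; only "entry_id"
        (smallest id wins) is defined.
    backend : embedding backend or None
        Object with ``name``, ``dim`` and ``embed_batch``; defaults to the
        offline :func:`~rdocnlp.embedding.hashing_embedder`.

    Attributes
    ----------
    entries_ : tuple of SentenceDictionaryEntry, sorted by entry_id.
    entry_embeddings_ : ndarray of shape (n_entries, dim), L2-normalized.
    gate_index_ : dict mapping keyword phrase -> entry row positions.
    backend_ : the embedding backend in use.
    """

    def __init__(
        self,
        threshold: float = 0.3,
        tie_break: str = "entry_id",
        backend: EmbeddingBackend | None = None,
    ):
        self.threshold = threshold
        self.tie_break = tie_break
        self.backend = backend

    # -- fitting ---------------------------------------------------------

    def fit(self, X: SentenceDictionary, y=None) -> "DictionarySentenceMatcher":
        """Embed and index the sentence dictionary ``X``."""
        MatcherConfig(threshold=self.threshold, tie_break=self.tie_break)  # validate
        if self.tie_break != "entry_id":
            raise ValueError(f"unknown tie_break rule {self.tie_break!r}")
        if not isinstance(X, SentenceDictionary):
            raise TypeError("X must be a SentenceDictionary")
        self.backend_ = self.backend if self.backend is not None else hashing_embedder()
        self.sd_ = X
        self.entries_ = tuple(sorted(X.entries, key=lambda e: e.entry_id))
        emb = np.asarray(
            self.backend_.embed_batch([e.text for e in self.entries_]), dtype=float
        )
        norms = np.linalg.norm(emb, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        self.entry_embeddings_ = emb / norms
        index: dict[str, list[int]] = {}
        for pos, e in enumerate(self.entries_):
            for phrase in e.keywords:
                index.setdefault(phrase, []).append(pos)
        self.gate_index_ = {p: np.asarray(v, dtype=int) for p, v in index.items()}
        return self

    # -- matching --------------------------------------------------------

    def _gate_positions(self, candidate: CandidateSentence) -> np.ndarray:
        pos: set[int] = set()
        for phrase in candidate.hit_phrases():
            got = self.gate_index_.get(phrase)
            if got is not None:
                pos.update(got.tolist())
        return np.asarray(sorted(pos), dtype=int)

    def _best_match(
        self, candidate: CandidateSentence, vec: np.ndarray
    ) -> tuple[SentenceDictionaryEntry | None, float]:
        positions = self._gate_positions(candidate)
        if positions.size == 0:
            return None, NO_MATCH_SCORE
        nrm = float(np.linalg.norm(vec))
        if nrm == 0.0:
            sims = np.zeros(positions.size)
        else:
            sims = np.clip(self.entry_embeddings_[positions] @ (vec / nrm), -1.0, 1.0)
        # positions ascend by entry_id, argmax takes the first max -> smallest id
        best = int(np.argmax(sims))
        return self.entries_[positions[best]], float(sims[best])

    def _make_annotation(
        self, candidate: CandidateSentence, vec: np.ndarray
    ) -> Annotation:
        entry, score = self._best_match(candidate, vec)
        accepted = entry is not None and score >= self.threshold
        gate_keyword = None
        if entry is not None:
            shared = [h.phrase for h in candidate.hits if h.phrase in entry.keywords]
            gate_keyword = shared[0]
        return Annotation(
            patient_id=candidate.patient_id,
            note_id=candidate.sentence.note_id,
            sent_index=candidate.sentence.sent_index,
            date=candidate.date,
            text=candidate.text,
            matched_entry_id=entry.entry_id if entry is not None else None,
            gate_keyword=gate_keyword,
            score=score,
            domain=entry.domain if accepted else None,
            accepted=accepted,
        )

    def annotate(self, candidate: CandidateSentence) -> Annotation:
        check_is_fitted(self, "entries_")
        vec = np.asarray(self.backend_.embed_batch([candidate.text]), dtype=float)[0]
        return self._make_annotation(candidate, vec)

    def annotate_corpus(self, candidates: Iterable[CandidateSentence]) -> list[Annotation]:
        """One order-stable :class:`Annotation` per candidate sentence."""
        check_is_fitted(self, "entries_")
        cands = list(candidates)
        if not cands:
            return []
        texts = [c.text for c in cands]
        vecs = np.asarray(self.backend_.embed_batch(texts), dtype=float)
        annotations = [self._make_annotation(c, v) for c, v in zip(cands, vecs)]
        counts = Counter(a.domain for a in annotations if a.accepted)
        logger.info(
            "annotated %d candidates: %d accepted %s",
            len(annotations),
            sum(a.accepted for a in annotations),
            dict(counts),
        )
        return annotations

    def predict(self, candidates: Iterable[CandidateSentence]) -> list[str]:
        """Domain label per candidate; "none" for rejected / ungated."""
        return [a.domain or "none" for a in self.annotate_corpus(candidates)]

    def gated_scores(self, candidate: CandidateSentence) -> dict[int, float]:
        """Debug view: cosine score against every gated entry."""
        check_is_fitted(self, "entries_")
        vec = np.asarray(self.backend_.embed_batch([candidate.text]), dtype=float)[0]
        positions = self._gate_positions(candidate)
        nrm = float(np.linalg.norm(vec))
        out: dict[int, float] = {}
        for pos in positions:
            if nrm == 0.0:
                out[self.entries_[pos].entry_id] = 0.0
            else:
                out[self.entries_[pos].entry_id] = float(
                    np.clip(self.entry_embeddings_[pos] @ (vec / nrm), -1.0, 1.0)
                )
        return out


# -- thin functional wrappers -------------------------------------------


def annotate_sentence(
    candidate: CandidateSentence,
    sd: SentenceDictionary,
    backend: EmbeddingBackend | None = None,
    cfg: MatcherConfig | None = None,
) -> Annotation:
    cfg = cfg or MatcherConfig()
    m = DictionarySentenceMatcher(
        threshold=cfg.threshold, tie_break=cfg.tie_break, backend=backend
    ).fit(sd)
    return m.annotate(candidate)


def annotate_corpus(
    candidates: Iterable[CandidateSentence],
    sd: SentenceDictionary,
    backend: EmbeddingBackend | None = None,
    cfg: MatcherConfig | None = None,
) -> list[Annotation]:
    cfg = cfg or MatcherConfig()
    m = DictionarySentenceMatcher(
        threshold=cfg.threshold, tie_break=cfg.tie_break, backend=backend
    ).fit(sd)
    return m.annotate_corpus(candidates)


def write_annotations(
    annotations: Sequence[Annotation], path: str | Path, format: str = "csv"
) -> None:
    """Serialize annotations to CSV or JSONL (score blank when ungated)."""
    path = Path(path)
    fields = [
        "patient_id", "note_id", "sent_index", "date", "entry_id",
        "keyword", "score", "domain", "accepted",
    ]

    def row(a: Annotation) -> dict:
        return {
            "patient_id": a.patient_id,
            "note_id": a.note_id,
            "sent_index": a.sent_index,
            "date": a.date.isoformat(),
            "entry_id": a.matched_entry_id if a.matched_entry_id is not None else "",
            "keyword": a.gate_keyword or "",
            "score": "" if math.isinf(a.score) else f"{a.score:.6f}",
            "domain": a.domain or "",
            "accepted": int(a.accepted),
        }

    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for a in annotations:
                writer.writerow(row(a))
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for a in annotations:
                fh.write(json.dumps(row(a)) + "\n")
    else:
        raise ValueError(f"unsupported format {format!r}")
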