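"""Threshold calibration against gold sentence labels.

Annotations are evaluated per domain one-vs-rest against gold labels
(domain or explicit "none"); the calibration objective is *F1 macro*, the
unweighted mean of the six per-domain F1 scores — the "none" class is
never averaged in.  ``ThresholdCalibrator`` computes similarities once and
sweeps an ascending threshold grid (default 0.05..0.95 in steps of 0.05),
selecting the F1-macro-maximizing threshold with ties going to the
smallest value.  Micro-averaged F1 is reported alongside for reference but
never drives selection.

Evaluation is sentence-level: a gold label applies to one
(note_id, sent_index) key and exactly one annotation may cover it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .dictionary import DOMAINS, SentenceDictionary
from .embedding import EmbeddingBackend
from .matcher import Annotation, DictionarySentenceMatcher
from .preprocess import CandidateSentence

__all__ = [
    "DomainMetrics",
    "ScoreReport",
    "CalibrationResult",
    "ThresholdCalibrator",
    "score_against_gold",
    "calibrate_threshold",
    "default_grid",
    "read_gold",
    "write_gold",
]

SentenceKey = tuple[str, int]
GoldLabels = Mapping[SentenceKey, str]


def default_grid() -> tuple[float, ...]:
    """Thresholds 0.05, 0.10, ..., 0.95."""
    return tuple(round(0.05 * k, 2) for k in range(1, 20))


@dataclass(frozen=True)
class DomainMetrics:
    """One-vs-rest confusion counts and scores for a single domain."""

    domain: str
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


@dataclass(frozen=True)
class ScoreReport:
    metrics: tuple[DomainMetrics, ...]
    f1_macro: float
    f1_micro: float

    def by_domain(self, domain: str) -> DomainMetrics:
        for m in self.metrics:
            if m.domain == domain:
                return m
        raise KeyError(domain)

    @property
    def min_f1(self) -> float:
        return min(m.f1 for m in self.metrics)


@dataclass(frozen=True)
class CalibrationResult:
    grid: tuple[float, ...]
    per_threshold: dict[float, ScoreReport]
    selected: float

    @property
    def selected_report(self) -> ScoreReport:
        return self.per_threshold[self.selected]

    def to_json(self) -> str:
        obj = {
            "selected_threshold": self.selected,
            "grid": list(self.grid),
            "per_threshold": {
                f"{t:.2f}": {
                    "f1_macro": r.f1_macro,
                    "f1_micro": r.f1_micro,
                    "domains": {
                        m.domain: {
                            "tp": m.tp, "fp": m.fp, "fn": m.fn,
                            "precision": m.precision, "recall": m.recall, "f1": m.f1,
                        }
                        for m in r.metrics
                    },
                }
                for t, r in self.per_threshold.items()
            },
        }
        return json.dumps(obj, indent=2)

    def format_table(self) -> str:
        lines = [f"{'threshold':>9}  {'f1_macro':>8}  {'min_f1':>6}"]
        for t in self.grid:
            r = self.per_threshold[t]
            mark = " *" if t == self.selected else ""
            lines.append(f"{t:>9.2f}  {r.f1_macro:>8.4f}  {r.min_f1:>6.4f}{mark}")
        return "\n".join(lines)


def score_against_gold(
    annotations: Iterable[Annotation], gold: GoldLabels
) -> ScoreReport:
    """Per-domain one-vs-rest precision/recall/F1 plus macro and micro F1.

    tp: accepted annotation whose domain matches gold; fp: accepted
    annotation whose gold label is "none" or a different domain; fn: gold
    domain sentence with no accepted matching annotation.  An annotation
    whose key is absent from gold is a hard error.
    """
    anns = list(annotations)
    missing = [a.key for a in anns if a.key not in gold]
    if missing:
        raise KeyError(f"annotation keys missing from gold labels: {missing[:10]}")

    tp = {d: 0 for d in DOMAINS}
    fp = {d: 0 for d in DOMAINS}
    covered: set[SentenceKey] = set()
    for a in anns:
        if not a.accepted:
            continue
        if gold[a.key] == a.domain:
            tp[a.domain] += 1
            covered.add(a.key)
        else:
            fp[a.domain] += 1
    fn = {d: 0 for d in DOMAINS}
    for key, label in gold.items():
        if label in fn and key not in covered:
            fn[label] += 1

    metrics = tuple(DomainMetrics(d, tp[d], fp[d], fn[d]) for d in DOMAINS)
    f1_macro = float(np.mean([m.f1 for m in metrics]))
    TP, FP, FN = sum(tp.values()), sum(fp.values()), sum(fn.values())
    f1_micro = 2 * TP / (2 * TP + FP + FN) if (2 * TP + FP + FN) else 0.0
    return ScoreReport(metrics=metrics, f1_macro=f1_macro, f1_micro=f1_micro)


class ThresholdCalibrator(BaseEstimator):
    """Sweep cosine thresholds and pick the F1-macro maximizer.

    Similarities are computed exactly once (the matcher's best match for a
    candidate does not depend on the threshold); the sweep merely re-applies
    the acceptance rule, so calibration costs one matching pass plus a
    cheap loop over the grid.

    Parameters
    ----------
    sentence_dictionary : SentenceDictionary
    grid : ascending thresholds in [0, 1]; default 0.05..0.95 step 0.05.
    backend : embedding backend; default offline hashing embedder.

    Attributes
    ----------
    threshold_ : selected threshold (argmax F1 macro, ties -> smallest).
    result_ : full :class:`CalibrationResult`.
    matcher_ : ``DictionarySentenceMatcher`` refitted at ``threshold_``.
    """

    def __init__(
        self,
        sentence_dictionary: SentenceDictionary | None = None,
        grid: Sequence[float] | None = None,
        backend: EmbeddingBackend | None = None,
    ):
        self.sentence_dictionary = sentence_dictionary
        self.grid = grid
        self.backend = backend

    def fit(self, X: Iterable[CandidateSentence], y: GoldLabels) -> "ThresholdCalibrator":
        """Calibrate on candidates ``X`` against gold labels ``y``."""
        if self.sentence_dictionary is None:
            raise ValueError("sentence_dictionary is required")
        grid = tuple(self.grid) if self.grid is not None else default_grid()
        if not grid:
            raise ValueError("threshold grid must be non-empty")
        if any(not 0.0 <= t <= 1.0 for t in grid):
            raise ValueError("thresholds must lie in [0, 1]")
        grid = tuple(sorted(grid))

        base = DictionarySentenceMatcher(threshold=0.0, backend=self.backend).fit(
            self.sentence_dictionary
        )
        cands = list(X)
        scored = base.annotate_corpus(cands)
        domain_of = {e.entry_id: e.domain for e in self.sentence_dictionary.entries}

        per_threshold: dict[float, ScoreReport] = {}
        for t in grid:
            swept = [
                _apply_threshold(a, t, domain_of) for a in scored
            ]
            per_threshold[t] = score_against_gold(swept, y)

        best = max(grid, key=lambda t: (per_threshold[t].f1_macro, -t))
        self.result_ = CalibrationResult(grid=grid, per_threshold=per_threshold, selected=best)
        self.threshold_ = best
        self.matcher_ = DictionarySentenceMatcher(threshold=best, backend=self.backend).fit(
            self.sentence_dictionary
        )
        return self

    def predict(self, candidates: Iterable[CandidateSentence]) -> list[str]:
        check_is_fitted(self, "matcher_")
        return self.matcher_.predict(candidates)


def _apply_threshold(a: Annotation, threshold: float, domain_of: Mapping[int, str]) -> Annotation:
    accepted = a.matched_entry_id is not None and a.score >= threshold
    return replace(
        a,
        accepted=accepted,
        domain=domain_of[a.matched_entry_id] if accepted else None,
    )


def calibrate_threshold(
    candidates: Iterable[CandidateSentence],
    sd: SentenceDictionary,
    backend: EmbeddingBackend | None,
    gold: GoldLabels,
    grid: Sequence[float] | None = None,
) -> CalibrationResult:
    """Functional wrapper over :class:`ThresholdCalibrator`."""
    cal = ThresholdCalibrator(sentence_dictionary=sd, grid=grid, backend=backend)
    cal.fit(candidates, gold)
    return cal.result_


def read_gold(path: str | Path) -> dict[SentenceKey, str]:
    """Gold CSV: note_id, sent_index, domain ("none" allowed)."""
    out: dict[SentenceKey, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in ("note_id", "sent_index", "domain"):
            if col not in (reader.fieldnames or []):
                raise ValueError(f"{path}: missing required column {col!r}")
        for row in reader:
            label = row["domain"].strip()
            if label != "none" and label not in DOMAINS:
                raise ValueError(f"{path}: unknown gold label {label!r}")
            key = (row["note_id"].strip(), int(row["sent_index"]))
            if key in out:
                raise ValueError(f"{path}: duplicate gold label for {key}")
            out[key] = label
    return out


def write_gold(gold: GoldLabels, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["note_id", "sent_index", "domain"])
        for (note_id, sent_index), label in gold.items():
            writer.writerow([note_id, sent_index, label])
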