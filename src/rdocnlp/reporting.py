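"""Keyword-frequency tables and word-cloud export.

The word-cloud data layer: counts of the gate keyword over *accepted*
annotations (i.e. RDoC instances, not raw keyword hits — a raw mode is
available via ``accepted_only=False``), globally and split per domain.
Rendering an actual word-cloud image is deliberately out of scope; the
exported two-column CSV (keyword, count) is consumable by any standard
word-cloud tool.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .dictionary import DOMAINS
from .matcher import Annotation

__all__ = ["KeywordFrequencyTable", "keyword_frequencies", "export_wordcloud_input"]


@dataclass(frozen=True)
class KeywordFrequencyTable:
    """Rows of (keyword, domain-or-"multiple", count), sorted by count
    descending with alphabetical tie-break; ``by_domain`` keeps the
    per-domain partition the aggregate rows were built from."""

    rows: tuple[tuple[str, str, int], ...]
    by_domain: dict[str, dict[str, int]]

    @property
    def total(self) -> int:
        return sum(count for _, _, count in self.rows)


def keyword_frequencies(
    annotations: Iterable[Annotation],
    top_n: int | None = None,
    accepted_only: bool = True,
    sentence_dictionary=None,
) -> KeywordFrequencyTable:
    """Count gate-keyword occurrences over annotations.

    With ``accepted_only`` (default) only accepted annotations count and
    the domain column is the accepted domain ("multiple" when a keyword
    appears under several domains).  With ``accepted_only=False`` every
    gated annotation counts, attributed to its matched entry's domain
    (``sentence_dictionary`` required to resolve rejected matches).
    """
    domain_of_entry = {}
    if sentence_dictionary is not None:
        domain_of_entry = {e.entry_id: e.domain for e in sentence_dictionary.entries}
    per_domain: dict[str, Counter[str]] = {d: Counter() for d in DOMAINS}
    for a in annotations:
        if a.gate_keyword is None:
            continue
        if accepted_only:
            if not a.accepted:
                continue
            per_domain[a.domain][a.gate_keyword] += 1
        else:
            from_domain = a.domain or domain_of_entry.get(a.matched_entry_id)
            if from_domain is None:
                raise ValueError(
                    "accepted_only=False needs sentence_dictionary= to resolve "
                    "the domain of rejected matches"
                )
            per_domain[from_domain][a.gate_keyword] += 1

    totals: Counter[str] = Counter()
    domains_of: dict[str, set[str]] = {}
    for d, counter in per_domain.items():
        for kw, c in counter.items():
            totals[kw] += c
            domains_of.setdefault(kw, set()).add(d)

    rows = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        rows = rows[:top_n]
    out_rows = tuple(
        (kw, next(iter(domains_of[kw])) if len(domains_of[kw]) == 1 else "multiple", c)
        for kw, c in rows
    )
    kept = {kw for kw, _, _ in out_rows}
    by_domain = {
        d: {kw: c for kw, c in counter.items() if kw in kept}
        for d, counter in per_domain.items()
    }
    return KeywordFrequencyTable(rows=out_rows, by_domain=by_domain)


def export_wordcloud_input(
    table: KeywordFrequencyTable,
    path: str | Path,
    per_domain_dir: str | Path | None = None,
) -> None:
    """Write (keyword, count) CSV; optionally one file per domain whose
    counts partition the global file.  Output is byte-stable for a fixed
    table."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["keyword", "count"])
        for kw, _, count in table.rows:
            writer.writerow([kw, count])
    if per_domain_dir is not None:
        out = Path(per_domain_dir)
        out.mkdir(parents=True, exist_ok=True)
        for d in DOMAINS:
            with open(out / f"{d}.csv", "w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh)
                writer.writerow(["keyword", "count"])
                for kw, count in sorted(
                    table.by_domain[d].items(), key=lambda kv: (-kv[1], kv[0])
                ):
                    writer.writerow([kw, count])
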