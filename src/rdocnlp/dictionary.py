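"""Keyword and sentence dictionaries defining the six RDoC domains.

The extraction pipeline is dictionary-driven: a *keyword dictionary* maps
each Research Domain Criteria (RDoC) domain to a set of keyword phrases,
and a *sentence dictionary* holds labeled exemplar sentences (the "sentence
B" pool) that candidate note sentences are matched against.  This module
loads, validates and serializes both, and ships a small demo pair built
from construct names commonly used in the PTSD literature (fear, panic,
worry, anhedonia, craving, ...).  The demo dictionaries are synthetic
stand-ins for illustration and testing; they are not clinical-grade.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

__all__ = [
    "DOMAINS",
    "KeywordDictionary",
    "SentenceDictionaryEntry",
    "SentenceDictionary",
    "ValidationReport",
    "DictionaryError",
    "normalize_phrase",
    "load_keyword_dictionary",
    "load_sentence_dictionary",
    "save_dictionaries",
    "validate_sentence_dictionary",
    "load_demo_dictionaries",
    "load_synonym_map",
]

#: Canonical labels for the six RDoC domains, in fixed reporting order.
DOMAINS: tuple[str, ...] = (
    "negative_valence",
    "positive_valence",
    "cognitive",
    "arousal_regulatory",
    "social_processes",
    "sensorimotor",
)

MAX_PHRASE_TOKENS = 6


class DictionaryError(ValueError):
    """Raised when a dictionary file violates the schema or invariants."""


def normalize_phrase(phrase: str) -> str:
    """Lowercase and collapse internal whitespace.  Idempotent."""
    return " ".join(phrase.lower().split())


def _check_domain(domain: str, allow_extra_domains: bool, where: str) -> None:
    if domain not in DOMAINS and not allow_extra_domains:
        raise DictionaryError(
            f"unknown domain label {domain!r} at {where}; "
            f"expected one of {', '.join(DOMAINS)}"
        )


@dataclass(frozen=True)
class KeywordDictionary:
    """Per-domain keyword phrase sets that gate all matching.

    All six canonical domains are always present as keys; a domain may map
    to an empty set.  A phrase may legitimately appear under more than one
    domain (e.g. "stress"): the matcher resolves the domain through the
    matched dictionary sentence, never through the keyword itself.
    """

    entries: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        fixed = {d: frozenset() for d in DOMAINS}
        for domain, phrases in self.entries.items():
            normed = set()
            for p in phrases:
                np = normalize_phrase(p)
                if not np:
                    raise DictionaryError(
                        f"empty keyword phrase under domain {domain!r}"
                    )
                if len(np.split()) > MAX_PHRASE_TOKENS:
                    raise DictionaryError(
                        f"keyword phrase {np!r} exceeds {MAX_PHRASE_TOKENS} tokens"
                    )
                normed.add(np)
            fixed[domain] = frozenset(normed)
        object.__setattr__(self, "entries", fixed)

    def all_phrases(self) -> frozenset[str]:
        out: set[str] = set()
        for phrases in self.entries.values():
            out |= phrases
        return frozenset(out)

    def domains_for(self, phrase: str) -> tuple[str, ...]:
        np = normalize_phrase(phrase)
        return tuple(d for d in DOMAINS if np in self.entries.get(d, frozenset()))


@dataclass(frozen=True)
class SentenceDictionaryEntry:
    """One labeled exemplar sentence with the keywords it contains."""

    entry_id: int
    text: str
    domain: str
    keywords: frozenset[str]


@dataclass(frozen=True)
class SentenceDictionary:
    entries: tuple[SentenceDictionaryEntry, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        ids = [e.entry_id for e in self.entries]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise DictionaryError("sentence dictionary entry_ids must be strictly increasing")

    def by_id(self, entry_id: int) -> SentenceDictionaryEntry:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        raise KeyError(entry_id)

    def domains_present(self) -> frozenset[str]:
        return frozenset(e.domain for e in self.entries)


@dataclass
class ValidationReport:
    """Outcome of checking a sentence dictionary against a keyword dictionary.

    ``missing_keyword`` lists entry_ids whose text contains no keyword at
    all; ``disagreements`` maps entry_id -> (recorded, recomputed) keyword
    sets where the stored keywords differ from a fresh keyword search.
    """

    missing_keyword: list[int] = field(default_factory=list)
    disagreements: dict[int, tuple[frozenset[str], frozenset[str]]] = field(
        default_factory=dict
    )

    @property
    def ok(self) -> bool:
        return not self.missing_keyword and not self.disagreements

    @property
    def n_violations(self) -> int:
        return len(self.missing_keyword) + len(self.disagreements)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "json"):
            raise DictionaryError(f"unsupported format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "json"):
        return suffix
    raise DictionaryError(f"cannot infer format from {path.name!r}; pass format=")


def load_keyword_dictionary(
    path: str | Path,
    format: str | None = None,
    *,
    allow_extra_domains: bool = False,
) -> KeywordDictionary:
    """Load a keyword dictionary from TSV (``domain<TAB>keyword``) or JSON.

    Unknown domain labels are rejected unless ``allow_extra_domains`` is
    set.  Phrases are normalized (lowercased, whitespace collapsed) and
    deduplicated within a domain.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    entries: dict[str, set[str]] = {}
    if fmt == "tsv":
        lines = path.read_text(encoding="utf-8").splitlines()
        if not lines or lines[0].split("\t")[:2] != ["domain", "keyword"]:
            raise DictionaryError(f"{path}: expected header 'domain<TAB>keyword'")
        for i, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DictionaryError(f"{path}:{i}: expected two tab-separated columns")
            domain, keyword = parts
            _check_domain(domain, allow_extra_domains, f"{path}:{i}")
            if not normalize_phrase(keyword):
                raise DictionaryError(f"{path}:{i}: empty keyword")
            entries.setdefault(domain, set()).add(keyword)
    else:
        obj = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(obj, dict):
            raise DictionaryError(f"{path}: JSON keyword dictionary must be an object")
        for domain, phrases in obj.items():
            _check_domain(domain, allow_extra_domains, f"{path} key {domain!r}")
            if not isinstance(phrases, list):
                raise DictionaryError(f"{path}: domain {domain!r} must map to a list")
            for p in phrases:
                if not normalize_phrase(str(p)):
                    raise DictionaryError(f"{path}: empty keyword under {domain!r}")
            entries.setdefault(domain, set()).update(str(p) for p in phrases)
    return KeywordDictionary(entries=entries)


def load_sentence_dictionary(
    path: str | Path,
    kd: KeywordDictionary,
    format: str | None = None,
    *,
    require_all_domains: bool = True,
) -> SentenceDictionary:
    """Load exemplar sentences (TSV ``entry_id<TAB>domain<TAB>text`` or JSON).

    Keywords for each entry are recomputed from ``kd`` with the same
    token-boundary matching rules the pipeline uses; an entry containing no
    keyword is a hard error because it could never be gated at match time.
    """
    from .preprocess import find_keywords  # local import: avoids module cycle

    path = Path(path)
    fmt = _infer_format(path, format)
    raw: list[tuple[int, str, str]] = []
    if fmt == "tsv":  # no provenance field in the TSV schema
        lines = path.read_text(encoding="utf-8").splitlines()
        if not lines or lines[0].split("\t")[:3] != ["entry_id", "domain", "text"]:
            raise DictionaryError(f"{path}: expected header 'entry_id<TAB>domain<TAB>text'")
        for i, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise DictionaryError(f"{path}:{i}: expected three tab-separated columns")
            eid, domain, text = parts
            raw.append((int(eid), domain, text))
    provenance = str(path)
    if fmt == "json":
        obj = json.loads(path.read_text(encoding="utf-8"))
        provenance = str(obj.get("provenance", provenance))
        for item in obj.get("entries", []):
            raw.append((int(item["entry_id"]), str(item["domain"]), str(item["text"])))

    entries = []
    for eid, domain, text in raw:
        _check_domain(domain, False, f"{path} entry {eid}")
        if not text.strip():
            raise DictionaryError(f"{path} entry {eid}: empty text")
        hits = find_keywords(text, kd)
        keywords = frozenset(h.phrase for h in hits)
        if not keywords:
            raise DictionaryError(
                f"{path} entry {eid}: text contains no keyword from the keyword dictionary"
            )
        entries.append(
            SentenceDictionaryEntry(entry_id=eid, text=text, domain=domain, keywords=keywords)
        )
    entries.sort(key=lambda e: e.entry_id)
    sd = SentenceDictionary(entries=tuple(entries), provenance=provenance)
    if require_all_domains:
        missing = set(DOMAINS) - sd.domains_present()
        if missing:
            raise DictionaryError(
                f"{path}: no sentences for domain(s): {', '.join(sorted(missing))}"
            )
    return sd


def validate_sentence_dictionary(
    sd: SentenceDictionary, kd: KeywordDictionary
) -> ValidationReport:
    """Report entries whose text lacks any keyword or whose recorded
    keywords disagree with a recomputed keyword search.  Report-only: ``sd``
    is never modified."""
    from .preprocess import find_keywords

    report = ValidationReport()
    for e in sd.entries:
        recomputed = frozenset(h.phrase for h in find_keywords(e.text, kd))
        if not recomputed:
            report.missing_keyword.append(e.entry_id)
        elif recomputed != e.keywords:
            report.disagreements[e.entry_id] = (e.keywords, recomputed)
    return report


def _keyword_tsv(kd: KeywordDictionary) -> str:
    rows = ["domain\tkeyword"]
    for domain in DOMAINS:
        for phrase in sorted(kd.entries[domain]):
            rows.append(f"{domain}\t{phrase}")
    return "\n".join(rows) + "\n"


def _keyword_json(kd: KeywordDictionary) -> str:
    obj = {d: sorted(kd.entries[d]) for d in DOMAINS if kd.entries[d]}
    return json.dumps(obj, indent=2, sort_keys=False) + "\n"


def _sentence_tsv(sd: SentenceDictionary) -> str:
    rows = ["entry_id\tdomain\ttext"]
    for e in sd.entries:
        rows.append(f"{e.entry_id}\t{e.domain}\t{e.text}")
    return "\n".join(rows) + "\n"


def _sentence_json(sd: SentenceDictionary) -> str:
    obj = {
        "provenance": sd.provenance,
        "entries": [
            {"entry_id": e.entry_id, "domain": e.domain, "text": e.text}
            for e in sd.entries
        ],
    }
    return json.dumps(obj, indent=2) + "\n"


def save_dictionaries(
    kd: KeywordDictionary,
    sd: SentenceDictionary,
    directory: str | Path,
    format: str = "tsv",
) -> tuple[Path, Path]:
    """Write ``keywords.<fmt>`` and ``sentences.<fmt>`` under ``directory``.

    Serialization is canonical (domains in reporting order, phrases sorted,
    entries by id), so save -> load -> save is byte-identical.
    """
    if format not in ("tsv", "json"):
        raise DictionaryError(f"unsupported format {format!r}")
    missing = set(DOMAINS) - sd.domains_present()
    if missing:
        raise DictionaryError(
            f"cannot save sentence dictionary missing domain(s): {', '.join(sorted(missing))}"
        )
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    kw_path = directory / f"keywords.{format}"
    sent_path = directory / f"sentences.{format}"
    kw_path.write_text(
        _keyword_tsv(kd) if format == "tsv" else _keyword_json(kd), encoding="utf-8"
    )
    sent_path.write_text(
        _sentence_tsv(sd) if format == "tsv" else _sentence_json(sd), encoding="utf-8"
    )
    return kw_path, sent_path


def _data_path(name: str) -> Path:
    return Path(str(resources.files("rdocnlp").joinpath("data", name)))


def load_demo_dictionaries() -> tuple[KeywordDictionary, SentenceDictionary]:
    """The bundled demo keyword + sentence dictionaries (synthetic,
    non-clinical-grade; ~60 exemplar sentences covering all six domains)."""
    kd = load_keyword_dictionary(_data_path("keywords.tsv"))
    sd = load_sentence_dictionary(_data_path("sentences.tsv"), kd)
    return kd, replace(sd, provenance="rdocnlp demo dictionary v1 (synthetic)")


def load_synonym_map(path: str | Path | None = None) -> dict[str, str]:
    """Word -> synonym substitutions used by the synthetic-note generator."""
    p = Path(path) if path is not None else _data_path("synonyms.tsv")
    out: dict[str, str] = {}
    for i, line in enumerate(p.read_text(encoding="utf-8").splitlines()):
        if i == 0 or not line.strip():
            continue
        word, syn = line.split("\t")
        out[word.lower()] = syn.lower()
    return out
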