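"""Seeded synthetic clinical-note corpora with gold labels.

The hospital notes the extraction pipeline was designed for cannot be
shared, so this module generates corpora that emulate their statistical
structure: notes are built from three sentence populations —

* **plants**: sentence-dictionary exemplars with paraphrase noise applied
  (word dropout, synonym substitution, appended filler clause), labeled
  with their source entry's domain;
* **distractors**: keyword-bearing sentences in off-domain administrative
  context (a dictionary keyword embedded in a scheduling/billing
  template), labeled "none";
* **fillers**: keyword-free boilerplate, labeled "none".

Patient-level structure mirrors the cohort analyses the pipeline feeds:
per-domain base rates are modulated multiplicatively by gender (all six
domains), veteran status (the two valence domains), psychotherapy (notes
on/after the psychotherapy start date), and a post-PTSD-diagnosis
multiplier for trajectory analyses.  Perturbation never drops or rewrites
keyword tokens, so every plant remains extractable by the keyword gate —
matching the design in which exemplar sentences always contain their
keywords.

Everything is driven by one ``numpy`` generator seeded from
``SimulationConfig.seed``: the same config reproduces a byte-identical
corpus on any platform.
"""

from __future__ import annotations

import json
import csv
import dataclasses
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np

from .dictionary import (
    DOMAINS,
    KeywordDictionary,
    SentenceDictionary,
    load_synonym_map,
)
from .preprocess import ClinicalNote

__all__ = [
    "SimulationConfig",
    "GoldCorpus",
    "generate_corpus",
    "make_calibration_fixture",
    "FILLER_SENTENCES",
    "DISTRACTOR_TEMPLATES",
]

# Keyword-free boilerplate (verified against the demo keyword dictionary).
FILLER_SENTENCES = (
    "Patient arrived on time for the scheduled appointment.",
    "Vital signs were recorded and are within normal limits.",
    "Medication list was reviewed and updated in the chart.",
    "Follow up visit is scheduled for next month.",
    "Insurance information was verified at check in.",
    "The patient was accompanied by a family member today.",
    "Labs were ordered and results are pending.",
    "No changes were made to the current care plan.",
    "Patient declined the influenza vaccination this visit.",
    "Records were requested from the outside facility.",
)

# A dictionary keyword dropped into administrative context: shares the
# keyword with exemplar sentences but not their semantics.
DISTRACTOR_TEMPLATES = (
    "The front desk mailed the {kw} education pamphlet to the address on file.",
    "A billing code related to {kw} was added to the encounter record.",
    "The {kw} questionnaire form was left blank and will be rescanned.",
    "Scheduling called about the {kw} class offered at the community center.",
    "The intake packet includes a page about {kw} resources.",
    "A brochure on {kw} was placed in the waiting room rack.",
)

_FILLER_CLAUSES = (
    "as discussed during today's visit",
    "per the report given at intake",
    "which was reviewed with the care team",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic corpus; ``seed`` fully determines the output.

    Rates are per-sentence probabilities; cohort effects are multiplicative
    modifiers on the per-domain plant rates.
    """

    seed: int = 0
    n_patients: int = 200
    notes_per_patient: tuple[int, int] = (2, 5)
    sentences_per_note: tuple[int, int] = (4, 8)
    base_rates: Mapping[str, float] = field(
        default_factory=lambda: {d: 0.05 for d in DOMAINS}
    )
    distractor_rate: float = 0.10
    word_dropout: float = 0.10
    synonym_prob: float = 0.20
    filler_clause_prob: float = 0.15
    female_multiplier: float = 1.6
    veteran_multiplier: float = 1.4  # applied to the two valence domains
    psychotherapy_multiplier: float = 0.5
    post_index_multiplier: float = 1.5  # after first PTSD diagnosis
    p_female: float = 0.5
    p_veteran: float = 0.25
    p_psychotherapy: float = 0.4
    p_ptsd: float = 0.9
    p_sre: float = 0.3
    p_asud: float = 0.4
    study_start: Date = Date(2015, 1, 1)
    study_days: int = 2191  # six years

    def __post_init__(self) -> None:
        for name in (
            "distractor_rate", "word_dropout", "synonym_prob", "filler_clause_prob",
            "p_female", "p_veteran", "p_psychotherapy", "p_ptsd", "p_sre", "p_asud",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(r < 0 for r in self.base_rates.values()):
            raise ValueError("base rates must be non-negative")


@dataclass
class GoldCorpus:
    """Notes + sentence-level gold labels + patient metadata + manifest."""

    notes: list[ClinicalNote]
    gold: dict[tuple[str, int], str]
    metadata: dict[str, dict]
    manifest: dict

    def write(self, directory: str | Path) -> None:
        """Emit notes.csv, gold.csv, metadata.csv and manifest.json in the
        exact formats the pipeline modules consume."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "notes.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "note_id", "date", "text"])
            for n in self.notes:
                w.writerow([n.patient_id, n.note_id, n.date.isoformat(), n.text])
        with open(directory / "gold.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["note_id", "sent_index", "domain"])
            for (nid, idx), label in self.gold.items():
                w.writerow([nid, idx, label])
        with open(directory / "metadata.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow([
                "patient_id", "gender", "veteran",
                "ptsd_date", "sre_date", "asud_date", "psychotherapy_date",
            ])
            for pid, meta in self.metadata.items():
                w.writerow([
                    pid, meta["gender"], int(bool(meta["veteran"])),
                    *(
                        meta[ev].isoformat() if meta[ev] else ""
                        for ev in ("ptsd_date", "sre_date", "asud_date", "psychotherapy_date")
                    ),
                ])
        (directory / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str), encoding="utf-8"
        )


def _strip_word(word: str) -> str:
    return "".join(ch for ch in word if ch.isalnum()).lower()


def _perturb(
    text: str,
    protected: frozenset[str],
    synonyms: Mapping[str, str],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> str:
    """Paraphrase noise that never touches keyword tokens.

    ``protected`` holds the lowercase tokens of the entry's keywords;
    those words are never dropped or substituted.
    """
    words = text.split()
    out: list[str] = []
    for w in words:
        core = _strip_word(w)
        if core in protected:
            out.append(w)
            continue
        if cfg.word_dropout > 0 and rng.random() < cfg.word_dropout and len(words) > 3:
            continue
        if cfg.synonym_prob > 0 and core in synonyms and rng.random() < cfg.synonym_prob:
            trailing = w[len(w.rstrip(".,;:")):]
            out.append(synonyms[core] + trailing)
            continue
        out.append(w)
    sentence = " ".join(out) if out else text
    if cfg.filler_clause_prob > 0 and rng.random() < cfg.filler_clause_prob:
        clause = _FILLER_CLAUSES[int(rng.integers(len(_FILLER_CLAUSES)))]
        if sentence.endswith("."):
            sentence = f"{sentence[:-1]}, {clause}."
        else:
            sentence = f"{sentence}, {clause}"
    return sentence


def _rand_date(rng: np.random.Generator, start: Date, days: int) -> Date:
    return start + timedelta(days=int(rng.integers(days)))


def _keyword_tokens(keywords: frozenset[str]) -> frozenset[str]:
    toks: set[str] = set()
    for phrase in keywords:
        toks.update(phrase.split())
    return frozenset(toks)


def generate_corpus(
    kd: KeywordDictionary,
    sd: SentenceDictionary,
    cfg: SimulationConfig,
    synonyms: Mapping[str, str] | None = None,
) -> GoldCorpus:
    """Generate a patient-structured corpus with sentence-level gold labels.

    Each note sentence is independently a domain plant (per-domain rate =
    base rate x the patient's and period's multipliers), a keyword-bearing
    distractor, or keyword-free filler.  Sentences are newline-joined so
    the pipeline's segmenter recovers exactly the generated sentence
    boundaries; gold keys are ``(note_id, sent_index)``.
    """
    rng = np.random.default_rng(cfg.seed)
    synonyms = dict(synonyms) if synonyms is not None else load_synonym_map()

    entries_by_domain = {
        d: sorted(
            (e for e in sd.entries if e.domain == d), key=lambda e: e.entry_id
        )
        for d in DOMAINS
    }
    for d, rate in cfg.base_rates.items():
        if rate > 0 and not entries_by_domain.get(d):
            raise ValueError(f"base rate for {d!r} is positive but sd has no entries")
    all_phrases = sorted(kd.all_phrases())

    notes: list[ClinicalNote] = []
    gold: dict[tuple[str, int], str] = {}
    metadata: dict[str, dict] = {}

    width = max(4, len(str(cfg.n_patients)))
    for p in range(cfg.n_patients):
        pid = f"P{p + 1:0{width}d}"
        female = rng.random() < cfg.p_female
        veteran = rng.random() < cfg.p_veteran
        ptsd = (
            _rand_date(rng, cfg.study_start, cfg.study_days)
            if rng.random() < cfg.p_ptsd else None
        )
        sre = (
            _rand_date(rng, cfg.study_start, cfg.study_days)
            if rng.random() < cfg.p_sre else None
        )
        asud = (
            _rand_date(rng, cfg.study_start, cfg.study_days)
            if rng.random() < cfg.p_asud else None
        )
        psy = (
            _rand_date(rng, cfg.study_start, cfg.study_days)
            if rng.random() < cfg.p_psychotherapy else None
        )
        metadata[pid] = {
            "gender": "F" if female else "M",
            "veteran": veteran,
            "ptsd_date": ptsd,
            "sre_date": sre,
            "asud_date": asud,
            "psychotherapy_date": psy,
        }

        lo, hi = cfg.notes_per_patient
        n_notes = int(rng.integers(lo, hi + 1))
        for k in range(n_notes):
            note_date = _rand_date(rng, cfg.study_start, cfg.study_days)
            note_id = f"{pid}-N{k + 1:02d}"

            rates = {}
            for d in DOMAINS:
                r = float(cfg.base_rates.get(d, 0.0))
                if female:
                    r *= cfg.female_multiplier
                if veteran and d in ("negative_valence", "positive_valence"):
                    r *= cfg.veteran_multiplier
                if psy is not None and note_date >= psy:
                    r *= cfg.psychotherapy_multiplier
                if ptsd is not None and note_date >= ptsd:
                    r *= cfg.post_index_multiplier
                rates[d] = r
            total_plant = sum(rates.values())
            if total_plant + cfg.distractor_rate >= 1.0:
                raise ValueError(
                    "configured rates leave no room for filler sentences "
                    f"(plant {total_plant:.2f} + distractor {cfg.distractor_rate:.2f} >= 1)"
                )

            probs = [rates[d] for d in DOMAINS] + [cfg.distractor_rate]
            probs.append(1.0 - sum(probs))  # filler
            categories = len(probs)

            slo, shi = cfg.sentences_per_note
            n_sents = int(rng.integers(slo, shi + 1))
            sentences: list[str] = []
            labels: list[str] = []
            for _ in range(n_sents):
                cat = int(rng.choice(categories, p=probs))
                if cat < len(DOMAINS):
                    domain = DOMAINS[cat]
                    pool = entries_by_domain[domain]
                    entry = pool[int(rng.integers(len(pool)))]
                    text = _perturb(
                        entry.text, _keyword_tokens(entry.keywords), synonyms, cfg, rng
                    )
                    sentences.append(text)
                    labels.append(domain)
                elif cat == len(DOMAINS):
                    kw = all_phrases[int(rng.integers(len(all_phrases)))]
                    tmpl = DISTRACTOR_TEMPLATES[int(rng.integers(len(DISTRACTOR_TEMPLATES)))]
                    sentences.append(tmpl.format(kw=kw))
                    labels.append("none")
                else:
                    sentences.append(
                        FILLER_SENTENCES[int(rng.integers(len(FILLER_SENTENCES)))]
                    )
                    labels.append("none")

            notes.append(
                ClinicalNote(
                    patient_id=pid, note_id=note_id, date=note_date,
                    text="\n".join(sentences),
                )
            )
            for i, label in enumerate(labels):
                gold[(note_id, i)] = label

    manifest = {"generator": "rdocnlp.synthetic.generate_corpus",
                "config": dataclasses.asdict(cfg)}
    return GoldCorpus(notes=notes, gold=gold, metadata=metadata, manifest=manifest)


def make_calibration_fixture(
    kd: KeywordDictionary,
    sd: SentenceDictionary,
    seed: int = 0,
    n_per_class: int = 150,
    n_distractors: int = 150,
    n_fillers: int = 150,
    word_dropout: float = 0.10,
    synonym_prob: float = 0.20,
    filler_clause_prob: float = 0.15,
) -> GoldCorpus:
    """A labeled sentence set standing in for an expert-annotated sample.

    ~1,200 sentences at the defaults: ``n_per_class`` perturbed plants per
    domain (high similarity to their source entries) plus keyword-bearing
    distractors and keyword-free fillers labeled "none" (the distractors'
    shared keywords gate them into the matcher despite low similarity —
    the two similarity modes that make threshold calibration non-trivial).
    The class histogram is exact by construction.
    """
    rng = np.random.default_rng(seed)
    synonyms = load_synonym_map()
    cfg = SimulationConfig(
        seed=seed,
        word_dropout=word_dropout,
        synonym_prob=synonym_prob,
        filler_clause_prob=filler_clause_prob,
    )
    entries_by_domain = {
        d: sorted((e for e in sd.entries if e.domain == d), key=lambda e: e.entry_id)
        for d in DOMAINS
    }
    for d in DOMAINS:
        if not entries_by_domain[d]:
            raise ValueError(f"sentence dictionary has no entries for {d!r}")
    all_phrases = sorted(kd.all_phrases())

    sentences: list[tuple[str, str]] = []  # (text, label)
    for d in DOMAINS:
        pool = entries_by_domain[d]
        for _ in range(n_per_class):
            entry = pool[int(rng.integers(len(pool)))]
            text = _perturb(entry.text, _keyword_tokens(entry.keywords), synonyms, cfg, rng)
            sentences.append((text, d))
    for _ in range(n_distractors):
        kw = all_phrases[int(rng.integers(len(all_phrases)))]
        tmpl = DISTRACTOR_TEMPLATES[int(rng.integers(len(DISTRACTOR_TEMPLATES)))]
        sentences.append((tmpl.format(kw=kw), "none"))
    for _ in range(n_fillers):
        sentences.append(
            (FILLER_SENTENCES[int(rng.integers(len(FILLER_SENTENCES)))], "none")
        )

    order = rng.permutation(len(sentences))
    sentences = [sentences[i] for i in order]

    notes: list[ClinicalNote] = []
    gold: dict[tuple[str, int], str] = {}
    metadata: dict[str, dict] = {}
    per_note = 6
    for chunk_start in range(0, len(sentences), per_note):
        chunk = sentences[chunk_start : chunk_start + per_note]
        idx = chunk_start // per_note
        pid = f"C{idx + 1:04d}"
        note_id = f"{pid}-N01"
        date = _rand_date(rng, cfg.study_start, cfg.study_days)
        notes.append(
            ClinicalNote(
                patient_id=pid, note_id=note_id, date=date,
                text="\n".join(t for t, _ in chunk),
            )
        )
        metadata[pid] = {
            "gender": "F", "veteran": False,
            "ptsd_date": None, "sre_date": None, "asud_date": None,
            "psychotherapy_date": None,
        }
        for i, (_, label) in enumerate(chunk):
            gold[(note_id, i)] = label

    manifest = {
        "generator": "rdocnlp.synthetic.make_calibration_fixture",
        "seed": seed,
        "n_per_class": n_per_class,
        "n_distractors": n_distractors,
        "n_fillers": n_fillers,
        "word_dropout": word_dropout,
        "synonym_prob": synonym_prob,
        "filler_clause_prob": filler_clause_prob,
    }
    return GoldCorpus(notes=notes, gold=gold, metadata=metadata, manifest=manifest)
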