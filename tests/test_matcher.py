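"""Keyword-gated best-match annotation: gating, tie-breaks, oracle parity."""

import math

import numpy as np
import pytest

from rdocnlp.dictionary import SentenceDictionary
from rdocnlp.embedding import cosine_similarity
from rdocnlp.matcher import (
    DictionarySentenceMatcher,
    MatcherConfig,
    annotate_corpus,
    annotate_sentence,
    gate_entries,
    write_annotations,
)
from rdocnlp.preprocess import find_keywords

from conftest import make_candidate


def brute_force_annotation(candidate, sd, backend):
    """Independent double loop: gate by shared keyword, argmax cosine,
    ties to smallest entry_id."""
    gated = [e for e in sorted(sd.entries, key=lambda e: e.entry_id)
             if e.keywords & candidate.hit_phrases()]
    if not gated:
        return None, float("-inf")
    cand_vec = backend.embed_batch([candidate.text])[0]
    best, best_score = None, -math.inf
    for e in gated:
        s = cosine_similarity(cand_vec, backend.embed_batch([e.text])[0])
        if s > best_score:  # strict: keeps the smallest-id winner on ties
            best, best_score = e, s
    return best, best_score


def test_gate_is_exact_shared_keyword_set(kd, sd):
    cand = make_candidate("Reports fear of crowds.", kd)
    gated = gate_entries(cand, sd)
    assert gated  # demo dictionary has fear entries
    for e in sd.entries:
        should = bool(e.keywords & {"fear"})
        assert (e in gated) == should
    assert [e.entry_id for e in gated] == sorted(e.entry_id for e in gated)


def test_gate_empty_when_keyword_absent_from_dictionary(kd, sd):
    cand = make_candidate("Patient denies weakness.", kd)
    assert cand.hits == ()  # not even a candidate in practice
    assert gate_entries(cand, sd) == []


def test_multi_keyword_candidate_gates_union(kd, sd):
    cand = make_candidate("Fear and poor sleep persist.", kd)
    gated = {e.entry_id for e in gate_entries(cand, sd)}
    expected = {
        e.entry_id for e in sd.entries if e.keywords & {"fear", "sleep"}
    }
    assert gated == expected


def test_identity_sentence_scores_one_and_accepts(kd, sd, backend):
    entry = sd.entries[0]
    cand = make_candidate(entry.text, kd)
    ann = annotate_sentence(cand, sd, backend, MatcherConfig(threshold=0.3))
    assert ann.accepted and ann.score == pytest.approx(1.0)
    assert ann.matched_entry_id == entry.entry_id
    assert ann.domain == entry.domain


def test_threshold_one_rejects_non_identical(kd, sd, backend):
    cand = make_candidate("Completely novel fear wording here.", kd)
    ann = annotate_sentence(cand, sd, backend, MatcherConfig(threshold=1.0))
    assert not ann.accepted and ann.domain is None
    assert ann.matched_entry_id is not None  # best match still recorded


def test_empty_gate_yields_no_match_sentinel(kd, sd, backend):
    cand = make_candidate("Nothing relevant here.", kd)
    ann = annotate_sentence(cand, sd, backend)
    assert ann.matched_entry_id is None and not ann.accepted
    assert ann.score == float("-inf") and ann.gate_keyword is None


def test_randomized_corpora_match_bruteforce_oracle(kd, sd, backend):
    rng = np.random.default_rng(11)
    vocab = sorted(kd.all_phrases()) + ["the", "patient", "today", "visit", "notes"]
    for trial in range(10):
        n_entries = int(rng.integers(5, 21))
        ids = sorted(rng.choice(len(sd.entries), size=n_entries, replace=False).tolist())
        sub_sd = SentenceDictionary(entries=tuple(sd.entries[i] for i in ids))
        cands = []
        for i in range(30):
            words = rng.choice(vocab, size=int(rng.integers(3, 9)))
            cands.append(make_candidate(" ".join(words), kd, note_id=f"n{trial}", sent_index=i))
        m = DictionarySentenceMatcher(threshold=0.3, backend=backend).fit(sub_sd)
        anns = m.annotate_corpus(cands)
        for cand, ann in zip(cands, anns):
            entry, score = brute_force_annotation(cand, sub_sd, backend)
            if entry is None:
                assert ann.matched_entry_id is None
            else:
                assert ann.matched_entry_id == entry.entry_id
                assert ann.score == pytest.approx(score, abs=1e-9)


def test_accepted_set_monotone_in_threshold(kd, sd, backend):
    cands = [
        make_candidate(t, kd, sent_index=i)
        for i, t in enumerate([
            "Patient reports intense fear at night.",
            "Reports fear when leaving the house.",
            "Poor sleep with nightmares.",
            "The fear questionnaire form was left blank.",
        ])
    ]
    prev = None
    for theta in [0.1, 0.3, 0.5, 0.7, 0.9]:
        m = DictionarySentenceMatcher(threshold=theta, backend=backend).fit(sd)
        anns = m.annotate_corpus(cands)
        accepted = {a.key for a in anns if a.accepted}
        matched = {a.key: a.matched_entry_id for a in anns}
        if prev is not None:
            assert accepted <= prev[0]
            assert matched == prev[1]  # best match is threshold-independent
        prev = (accepted, matched)


def test_gate_keyword_occurs_in_both_sentences(kd, sd, backend):
    cands = [
        make_candidate(t, kd, sent_index=i)
        for i, t in enumerate([
            "Chronic stress and panic attacks.",
            "Sleep has improved with medication.",
            "Expresses guilt and shame about the event.",
        ])
    ]
    anns = annotate_corpus(cands, sd, backend, MatcherConfig(threshold=0.0))
    for cand, ann in zip(cands, anns):
        if ann.matched_entry_id is None:
            continue
        entry = sd.by_id(ann.matched_entry_id)
        assert ann.gate_keyword in cand.hit_phrases()
        assert ann.gate_keyword in entry.keywords
        # token-boundary recomputation in both texts
        assert ann.gate_keyword in {h.phrase for h in find_keywords(cand.text, kd)}
        assert ann.gate_keyword in {h.phrase for h in find_keywords(entry.text, kd)}


def test_doubling_corpus_doubles_accepted_counts(kd, sd, backend):
    cands = [
        make_candidate("Patient reports intense fear at night.", kd, note_id="a"),
        make_candidate("Poor sleep with frequent awakenings.", kd, note_id="b"),
    ]
    single = annotate_corpus(cands, sd, backend)
    double = annotate_corpus(cands * 2, sd, backend)
    assert sum(a.accepted for a in double) == 2 * sum(a.accepted for a in single)


def test_empty_candidate_stream(sd, backend):
    assert annotate_corpus([], sd, backend) == []


def test_sklearn_param_interface(sd):
    m = DictionarySentenceMatcher(threshold=0.4)
    assert m.get_params()["threshold"] == 0.4
    m.set_params(threshold=0.6)
    m.fit(sd)
    assert m.threshold == 0.6 and len(m.entries_) == len(sd.entries)


def test_invalid_threshold_rejected(sd):
    with pytest.raises(ValueError):
        DictionarySentenceMatcher(threshold=1.5).fit(sd)


def test_write_annotations_round_trip(tmp_path, kd, sd, backend):
    cands = [make_candidate("Panic attacks most mornings.", kd)]
    anns = annotate_corpus(cands, sd, backend)
    out = tmp_path / "ann.csv"
    write_annotations(anns, out)
    from rdocnlp.cli import _read_annotation_csv

    back = _read_annotation_csv(out)
    assert back[0].matched_entry_id == anns[0].matched_entry_id
    assert back[0].accepted == anns[0].accepted
    assert back[0].score == pytest.approx(anns[0].score, abs=1e-6)
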