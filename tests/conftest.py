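from datetime import date

import pytest

from rdocnlp import hashing_embedder, load_demo_dictionaries
from rdocnlp.preprocess import CandidateSentence, SentenceRecord, find_keywords


@pytest.fixture(scope="session")
def demo_dicts():
    return load_demo_dictionaries()


@pytest.fixture(scope="session")
def kd(demo_dicts):
    return demo_dicts[0]


@pytest.fixture(scope="session")
def sd(demo_dicts):
    return demo_dicts[1]


@pytest.fixture(scope="session")
def backend():
    # session-scoped so the embedding cache is shared across tests
    return hashing_embedder()


def make_candidate(
    text,
    kd,
    note_id="n1",
    sent_index=0,
    patient_id="p1",
    when=date(2020, 1, 6),
):
    """Build a CandidateSentence from raw text (hits recomputed from kd)."""
    hits = tuple(find_keywords(text, kd))
    rec = SentenceRecord(
        note_id=note_id, sent_index=sent_index, text=text, char_start=0, char_end=len(text)
    )
    return CandidateSentence(sentence=rec, patient_id=patient_id, date=when, hits=hits)
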