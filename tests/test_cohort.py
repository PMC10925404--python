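"""Patient profiles, the exact signed-rank test, cohort comparison, trajectories."""

import itertools
from datetime import date

import numpy as np
import pytest
from scipy.stats import wilcoxon

from rdocnlp.cohort import (
    PatientProfile,
    build_profiles,
    compare_cohorts,
    exact_wilcoxon_signed_rank,
    read_metadata,
    trajectory,
)
from rdocnlp.dictionary import DOMAINS
from rdocnlp.matcher import Annotation


def _ann(pid, domain, when, accepted=True, note_id=None, sent_index=0):
    return Annotation(
        patient_id=pid, note_id=note_id or f"{pid}-n", sent_index=sent_index,
        date=when, text="", matched_entry_id=1 if accepted else None,
        gate_keyword="fear" if accepted else None,
        score=0.9 if accepted else float("-inf"),
        domain=domain if accepted else None, accepted=accepted,
    )


# -- exact Wilcoxon signed-rank test ------------------------------------


def oracle_exact_p(diffs):
    """Independent full enumeration with hand-computed midranks."""
    diffs = [d for d in diffs if d != 0.0]
    n = len(diffs)
    if n == 0:
        return 0.0, 1.0
    # midranks of |d| computed by hand
    order = sorted(range(n), key=lambda i: abs(diffs[i]))
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and abs(diffs[order[j + 1]]) == abs(diffs[order[i]]):
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    w_obs = sum(r for r, d in zip(ranks, diffs) if d > 0)
    mu = sum(ranks) / 2
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return w_obs, count / 2 ** n


def test_six_same_sign_distinct_magnitudes_gives_2_over_64():
    pairs = [(0.1 + k * 0.01, 0.1) for k in range(1, 7)]
    w, p = exact_wilcoxon_signed_rank(pairs)
    assert w == 21.0  # sum of ranks 1..6
    assert p == pytest.approx(0.03125)


def test_single_pair_gives_p_one():
    assert exact_wilcoxon_signed_rank([(0.5, 0.2)]) == (1.0, 1.0)


def test_five_same_sign_gives_2_over_32():
    pairs = [(0.1, 0.1 + k * 0.01) for k in range(1, 6)]
    _, p = exact_wilcoxon_signed_rank(pairs)
    assert p == pytest.approx(0.0625)


def test_all_zero_differences_p_one():
    assert exact_wilcoxon_signed_rank([(0.3, 0.3), (0.1, 0.1)]) == (0.0, 1.0)


def test_matches_scipy_exact_on_tie_free_samples():
    rng = np.random.default_rng(3)
    for _ in range(25):
        n = int(rng.integers(3, 11))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if np.any(x == y) or len(set(np.abs(x - y))) < n:
            continue
        _, p = exact_wilcoxon_signed_rank(list(zip(x, y)))
        ref = wilcoxon(x, y, mode="exact").pvalue
        assert p == pytest.approx(float(ref), abs=1e-12)


def test_matches_full_enumeration_oracle_with_ties():
    rng = np.random.default_rng(9)
    grid_vals = [-0.2, -0.1, -0.05, 0.0, 0.05, 0.1, 0.2]  # forces ties and zeros
    for _ in range(60):
        n = int(rng.integers(1, 11))
        diffs = [grid_vals[int(rng.integers(len(grid_vals)))] for _ in range(n)]
        if all(d == 0 for d in diffs):
            continue
        w, p = exact_wilcoxon_signed_rank([(d, 0.0) for d in diffs])
        w_ref, p_ref = oracle_exact_p(diffs)
        assert w == pytest.approx(w_ref)
        assert p == pytest.approx(p_ref, abs=1e-12)
        nz = sum(d != 0 for d in diffs)
        assert round(p * 2 ** nz, 6) == round(p * 2 ** nz)  # p is k/2^n


def test_rejects_oversized_sample():
    with pytest.raises(ValueError, match="n <= 20"):
        exact_wilcoxon_signed_rank([(i + 1.0, 0.0) for i in range(25)])


# -- profiles -----------------------------------------------------------


def test_counts_flags_and_rejected_annotations():
    d0 = date(2020, 1, 1)
    anns = [
        _ann("p1", "negative_valence", d0, sent_index=0),
        _ann("p1", "negative_valence", d0, sent_index=1),
        _ann("p1", "negative_valence", d0, sent_index=2),
        _ann("p2", None, d0, accepted=False),
    ]
    profiles = {p.patient_id: p for p in build_profiles(anns)}
    assert profiles["p1"].counts["negative_valence"] == 3
    assert profiles["p1"].flags["negative_valence"] is True
    assert profiles["p2"].total == 0
    assert all(not v for v in profiles["p2"].flags.values())


def test_metadata_only_patients_get_zero_profiles():
    meta = {"p9": {"gender": "F", "veteran": False, "ptsd_date": None,
                   "sre_date": None, "asud_date": None, "psychotherapy_date": None}}
    profiles = build_profiles([], meta)
    assert len(profiles) == 1 and profiles[0].total == 0
    assert profiles[0].attributes["gender"] == "F"


def test_duplicate_metadata_patient_is_error(tmp_path):
    p = tmp_path / "meta.csv"
    p.write_text("patient_id,gender\np1,F\np1,M\n")
    with pytest.raises(ValueError, match="duplicate patient_id"):
        read_metadata(p)


# -- cohort comparison --------------------------------------------------


def _profile(pid, rates_on, gender="F"):
    prof = PatientProfile(patient_id=pid)
    for d in rates_on:
        prof.counts[d] = 1
    prof.attributes = {"gender": gender, "veteran": False}
    return prof


GENDER_SPLIT = (
    ("female", lambda p: p.attributes.get("gender") == "F"),
    ("male", lambda p: p.attributes.get("gender") == "M"),
)


def test_identical_cohorts_p_one():
    profiles = [_profile(f"f{i}", DOMAINS[:3], "F") for i in range(4)]
    profiles += [_profile(f"m{i}", DOMAINS[:3], "M") for i in range(4)]
    cmp_ = compare_cohorts(profiles, GENDER_SPLIT)
    assert cmp_.p_value == 1.0
    assert not cmp_.consistent


def test_uniform_six_domain_effect_hits_smallest_p():
    # domain i present in 6-i of 6 females vs max(3-i, 0) of 6 males:
    # every per-domain difference positive
    females, males = [], []
    for j in range(6):
        f_on = [d for i, d in enumerate(DOMAINS) if j >= i]   # rates 1/6 .. 6/6
        m_on = [d for i, d in enumerate(DOMAINS) if j >= i + 3]
        females.append(_profile(f"f{j}", f_on, "F"))
        males.append(_profile(f"m{j}", m_on, "M"))
    cmp_ = compare_cohorts(females + males, GENDER_SPLIT)
    assert all(v > 0 for v in cmp_.differences.values())
    assert cmp_.p_value == pytest.approx(0.03125)
    assert cmp_.direction == "female > male in 6/6"


def test_antisymmetry_under_cohort_swap():
    rng = np.random.default_rng(21)
    profiles = []
    for i in range(30):
        on = [d for d in DOMAINS if rng.random() < 0.4]
        profiles.append(_profile(f"f{i}", on, "F"))
    for i in range(25):
        on = [d for d in DOMAINS if rng.random() < 0.3]
        profiles.append(_profile(f"m{i}", on, "M"))
    fwd = compare_cohorts(profiles, GENDER_SPLIT)
    rev = compare_cohorts(profiles, (GENDER_SPLIT[1], GENDER_SPLIT[0]))
    assert rev.p_value == pytest.approx(fwd.p_value)
    for d in DOMAINS:
        assert rev.differences[d] == pytest.approx(-fwd.differences[d])


def test_empty_cohort_is_error():
    profiles = [_profile("f1", ["cognitive"], "F")]
    with pytest.raises(ValueError, match="empty cohort"):
        compare_cohorts(profiles, GENDER_SPLIT)


def test_degenerate_one_vs_one():
    profiles = [_profile("f1", list(DOMAINS), "F"), _profile("m1", [], "M")]
    cmp_ = compare_cohorts(profiles, GENDER_SPLIT)
    assert set(cmp_.rate_a.values()) <= {0.0, 1.0}
    assert cmp_.p_value == pytest.approx(0.03125)  # six rank-tied +1 differences


# -- trajectory ---------------------------------------------------------


def _meta(pid, ptsd=None):
    return {"gender": "F", "veteran": False, "ptsd_date": ptsd,
            "sre_date": None, "asud_date": None, "psychotherapy_date": None}


def test_annotations_before_index_excluded():
    idx = date(2020, 6, 1)
    anns = [_ann("p1", "cognitive", date(2019, 1, 1))]
    profiles = build_profiles(anns, {"p1": _meta("p1", ptsd=idx)})
    table = trajectory(profiles, anns, "ptsd_date")
    assert all(table.counts[w][d] == 0 for w in (1, 2, 4) for d in DOMAINS)


def test_half_open_window_arithmetic_18_months():
    idx = date(2020, 1, 1)
    anns = [_ann("p1", "cognitive", date(2021, 7, 1))]  # +18 months
    profiles = build_profiles(anns, {"p1": _meta("p1", ptsd=idx)})
    table = trajectory(profiles, anns, "ptsd_date")
    assert [table.counts[w]["cognitive"] for w in (1, 2, 4)] == [0, 1, 1]


def test_window_boundary_exactly_w_years_excluded():
    idx = date(2020, 1, 1)
    anns = [
        _ann("p1", "cognitive", date(2021, 1, 1), sent_index=0),   # exactly +1y: outside 1y
        _ann("p1", "cognitive", date(2020, 12, 31), sent_index=1), # inside 1y
        _ann("p1", "cognitive", idx, sent_index=2),                # index day counts
    ]
    profiles = build_profiles(anns, {"p1": _meta("p1", ptsd=idx)})
    table = trajectory(profiles, anns, "ptsd_date")
    assert table.counts[1]["cognitive"] == 2
    assert table.counts[2]["cognitive"] == 3


def test_windows_monotone_and_partition_totals():
    idx = date(2018, 3, 1)
    rng = np.random.default_rng(5)
    anns = []
    for i in range(40):
        offset = int(rng.integers(-200, 1600))
        d = DOMAINS[int(rng.integers(6))]
        anns.append(_ann("p1", d, date.fromordinal(idx.toordinal() + offset), sent_index=i))
    profiles = build_profiles(anns, {"p1": _meta("p1", ptsd=idx)})
    table = trajectory(profiles, anns, "ptsd_date")
    for d in DOMAINS:
        assert table.counts[1][d] <= table.counts[2][d] <= table.counts[4][d]
    in_4y = sum(
        1 for a in anns
        if idx <= a.date and (a.date - idx).days < (date(2022, 3, 1) - idx).days
    )
    assert sum(table.counts[4].values()) == in_4y


def test_patients_without_index_event_excluded_and_counted():
    anns = [_ann("p1", "cognitive", date(2020, 1, 1)), _ann("p2", "cognitive", date(2020, 1, 1))]
    meta = {"p1": _meta("p1", ptsd=date(2019, 1, 1)), "p2": _meta("p2")}
    table = trajectory(build_profiles(anns, meta), anns, "ptsd_date")
    assert table.n_patients == 1 and table.n_excluded == 1


def test_empty_window_list_is_error():
    with pytest.raises(ValueError, match="non-empty"):
        trajectory([], [], "ptsd_date", windows=[])
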