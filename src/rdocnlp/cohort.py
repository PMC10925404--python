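"""Patient-level aggregation, cohort comparison, and trajectory windows.

Accepted sentence annotations are aggregated into per-patient per-domain
instance counts (:class:`PatientProfile`).  Two cohorts are compared by
their six per-domain *prevalences* — the fraction of patients with at
least one accepted instance of the domain — with an exact two-sided
Wilcoxon signed-rank test over the six paired rates.  The test enumerates
all 2^n sign assignments of the realized |differences| (midranks for
ties), so with six same-sign, distinct-magnitude differences the two-sided
p is exactly 2/2^6 = 0.03125 — the smallest value this design can attain.

Trajectory tables count accepted instances inside half-open follow-up
windows anchored at a per-patient index event (first PTSD diagnosis,
first suicide-related event, first substance-use diagnosis, or
psychotherapy start): a window of w years contains annotations with
0 <= (annotation date - index date) < w years, so window counts are
cumulative and monotone in w.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dictionary import DOMAINS
from .matcher import Annotation

logger = logging.getLogger(__name__)

__all__ = [
    "PatientProfile",
    "CohortComparison",
    "TrajectoryTable",
    "build_profiles",
    "read_metadata",
    "exact_wilcoxon_signed_rank",
    "compare_cohorts",
    "trajectory",
]

EVENT_FIELDS = ("ptsd_date", "sre_date", "asud_date", "psychotherapy_date")


@dataclass
class PatientProfile:
    """Per-patient per-domain accepted-instance counts plus metadata."""

    patient_id: str
    counts: dict[str, int] = field(default_factory=lambda: {d: 0 for d in DOMAINS})
    attributes: dict[str, object] = field(default_factory=dict)
    event_dates: dict[str, Date | None] = field(
        default_factory=lambda: {e: None for e in EVENT_FIELDS}
    )

    @property
    def flags(self) -> dict[str, bool]:
        return {d: self.counts[d] > 0 for d in DOMAINS}

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class CohortComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    rate_a: dict[str, float]
    rate_b: dict[str, float]
    w_statistic: float
    p_value: float

    @property
    def differences(self) -> dict[str, float]:
        return {d: self.rate_a[d] - self.rate_b[d] for d in DOMAINS}

    @property
    def direction(self) -> str:
        """e.g. "A > B in 6/6" when every per-domain difference is positive."""
        diffs = list(self.differences.values())
        pos = sum(v > 0 for v in diffs)
        neg = sum(v < 0 for v in diffs)
        if pos == len(diffs):
            return f"{self.label_a} > {self.label_b} in {pos}/{len(diffs)}"
        if neg == len(diffs):
            return f"{self.label_b} > {self.label_a} in {neg}/{len(diffs)}"
        return f"mixed ({pos} up, {neg} down)"

    @property
    def consistent(self) -> bool:
        diffs = list(self.differences.values())
        return all(v > 0 for v in diffs) or all(v < 0 for v in diffs)


@dataclass(frozen=True)
class TrajectoryTable:
    index_event: str
    windows: tuple[int, ...]
    counts: dict[int, dict[str, int]]  # window (years) -> domain -> instances
    n_patients: int
    n_excluded: int

    def rates(self) -> dict[int, dict[str, float]]:
        """Per-patient-normalized instance rates."""
        if self.n_patients == 0:
            return {w: {d: 0.0 for d in DOMAINS} for w in self.windows}
        return {
            w: {d: self.counts[w][d] / self.n_patients for d in DOMAINS}
            for w in self.windows
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {f"{w}y": {d: self.counts[w][d] for d in DOMAINS} for w in self.windows}
        )


def read_metadata(path: str | Path) -> dict[str, dict]:
    """Metadata CSV: patient_id, gender, veteran, ptsd_date, sre_date,
    asud_date, psychotherapy_date (empty dates allowed)."""
    out: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if "patient_id" not in (reader.fieldnames or []):
            raise ValueError(f"{path}: missing required column 'patient_id'")
        for row in reader:
            pid = row["patient_id"].strip()
            if pid in out:
                raise ValueError(f"{path}: duplicate patient_id {pid!r}")
            rec: dict[str, object] = {
                "gender": row.get("gender", "").strip(),
                "veteran": row.get("veteran", "").strip().lower() in ("1", "true", "yes"),
            }
            for ev in EVENT_FIELDS:
                raw = (row.get(ev) or "").strip()
                rec[ev] = Date.fromisoformat(raw) if raw else None
            out[pid] = rec
    return out


def build_profiles(
    annotations: Iterable[Annotation], metadata: Mapping[str, Mapping] | None = None
) -> list[PatientProfile]:
    """Aggregate accepted annotations into patient profiles.

    Patients present in the annotations but absent from ``metadata`` get a
    profile with empty attributes (warned); metadata-only patients are
    included with zero counts so cohort denominators reflect the full
    population.
    """
    metadata = dict(metadata or {})
    profiles: dict[str, PatientProfile] = {}

    def get(pid: str) -> PatientProfile:
        prof = profiles.get(pid)
        if prof is None:
            prof = PatientProfile(patient_id=pid)
            meta = metadata.get(pid)
            if meta is None:
                logger.warning("patient %s has no metadata row", pid)
            else:
                prof.attributes = {
                    k: v for k, v in meta.items() if k not in EVENT_FIELDS
                }
                prof.event_dates = {e: meta.get(e) for e in EVENT_FIELDS}
            profiles[pid] = prof
        return prof

    for a in annotations:
        prof = get(a.patient_id)
        if a.accepted:
            prof.counts[a.domain] += 1
    for pid in metadata:
        get(pid)
    return sorted(profiles.values(), key=lambda p: p.patient_id)


def exact_wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test for small paired samples.

    Zero differences are dropped; |differences| are ranked with midranks
    for ties; W is the sum of ranks of positive differences.  The null
    distribution is built by enumerating all 2^n sign assignments of the
    realized ranks (a tie-respecting permutation null), and the two-sided
    p-value is P(|W* - mu| >= |W - mu|) with mu = sum(ranks)/2.

    Returns ``(W, p)``; all-zero differences give ``(0.0, 1.0)``.
    """
    diffs = np.asarray([x - y for x, y in pairs], dtype=float)
    if diffs.size == 0:
        raise ValueError("need at least one pair")
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        logger.warning("all paired differences are zero; p = 1.0")
        return 0.0, 1.0
    if n > 20:
        raise ValueError(f"exact enumeration limited to n <= 20 non-zero pairs, got {n}")

    ranks = rankdata(np.abs(diffs))  # midranks for ties
    w_obs = float(ranks[diffs > 0].sum())
    mu = float(ranks.sum()) / 2.0

    # W* over all 2^n sign vectors: bit i set -> difference i positive
    m = 1 << n
    w_all = np.zeros(m)
    codes = np.arange(m)
    for i in range(n):
        w_all += ranks[i] * ((codes >> i) & 1)
    dev_obs = abs(w_obs - mu)
    p = float(np.count_nonzero(np.abs(w_all - mu) >= dev_obs - 1e-12)) / m
    return w_obs, p


def compare_cohorts(
    profiles: Sequence[PatientProfile],
    split: tuple[tuple[str, Callable[[PatientProfile], bool]],
                 tuple[str, Callable[[PatientProfile], bool]]],
) -> CohortComparison:
    """Compare two cohorts' per-domain prevalences with the exact test.

    ``split`` is a pair of (label, predicate) defining the cohorts, e.g.
    ``(("female", lambda p: p.attributes.get("gender") == "F"),
       ("male",   lambda p: p.attributes.get("gender") == "M"))``.
    Prevalence = fraction of cohort patients with >= 1 accepted instance
    of the domain; the six paired rates feed the signed-rank test.
    """
    (label_a, pred_a), (label_b, pred_b) = split
    cohort_a = [p for p in profiles if pred_a(p)]
    cohort_b = [p for p in profiles if pred_b(p)]
    if not cohort_a or not cohort_b:
        raise ValueError(
            f"empty cohort: {label_a}={len(cohort_a)}, {label_b}={len(cohort_b)}"
        )

    def rates(cohort: list[PatientProfile]) -> dict[str, float]:
        return {
            d: sum(p.flags[d] for p in cohort) / len(cohort) for d in DOMAINS
        }

    rate_a, rate_b = rates(cohort_a), rates(cohort_b)
    w, p = exact_wilcoxon_signed_rank([(rate_a[d], rate_b[d]) for d in DOMAINS])
    return CohortComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=len(cohort_a),
        n_b=len(cohort_b),
        rate_a=rate_a,
        rate_b=rate_b,
        w_statistic=w,
        p_value=p,
    )


def trajectory(
    profiles: Sequence[PatientProfile],
    annotations: Iterable[Annotation],
    index_event: str,
    windows: Sequence[int] = (1, 2, 4),
) -> TrajectoryTable:
    """Cumulative per-domain instance counts in follow-up windows.

    A window of ``w`` years (calendar years, via pandas date offsets) is
    half-open: it contains accepted annotations dated on/after the
    patient's index event and strictly before index + w years.  Patients
    without the index event are excluded and counted in ``n_excluded``.
    """
    if index_event not in EVENT_FIELDS:
        raise ValueError(f"unknown index event {index_event!r}; one of {EVENT_FIELDS}")
    windows = tuple(sorted(int(w) for w in windows))
    if not windows:
        raise ValueError("window list must be non-empty")
    if windows[0] <= 0:
        raise ValueError("windows must be positive year offsets")

    index_dates = {
        p.patient_id: p.event_dates.get(index_event)
        for p in profiles
    }
    included = {pid for pid, d in index_dates.items() if d is not None}
    n_excluded = len(index_dates) - len(included)
    if n_excluded:
        logger.info(
            "trajectory(%s): excluded %d patient(s) without the index event",
            index_event, n_excluded,
        )

    counts = {w: {d: 0 for d in DOMAINS} for w in windows}
    for a in annotations:
        if not a.accepted or a.patient_id not in included:
            continue
        idx = index_dates[a.patient_id]
        ts, t0 = pd.Timestamp(a.date), pd.Timestamp(idx)
        if ts < t0:
            continue
        for w in windows:
            if ts < t0 + pd.DateOffset(years=w):
                counts[w][a.domain] += 1
    return TrajectoryTable(
        index_event=index_event,
        windows=windows,
        counts=counts,
        n_patients=len(included),
        n_excluded=n_excluded,
    )
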