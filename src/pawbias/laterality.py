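"""Per-subject paw-preference scoring and cohort-level laterality analyses.

A dog's motor laterality is scored from an ordered sequence of left/right
paw responses (target 50 per session).  The laterality index
``LI = (R - L) / (R + L)`` measures direction (-1 exclusively left, +1
exclusively right) and ``|LI|`` measures strength.  Whether an individual
dog is significantly lateralized is decided with the binomial z-score
``z = (R - 0.5 N) / sqrt(0.25 N)``: ``z >= 1.96`` is right-pawed,
``z <= -1.96`` left-pawed, anything strictly between is ambilateral.

Cohort-level routines test the class distribution against an equal 1/3
split (exact binomial), population-level bias of the mean LI (one-sample
t), and whether the first paw a dog uses predicts its overall LI
(between-subjects t with Cohen's d).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    DataError,
    DegenerateVarianceError,
    UnscorableSessionError,
    ValidationError,
)

Z_CUTOFF = 1.96
TARGET_TRIALS = 50
NULL_PROPORTION = 1.0 / 3.0

TESTS = ("FRT", "KT")
CONDITIONS = ("baseline", "OFT")
PREFERENCE_CLASSES = ("ambilateral", "left", "right")


@dataclass(frozen=True)
class PawEventSequence:
    """Ordered L/R paw responses for one subject x test x condition session."""

    subject_id: str
    test: str
    condition: str
    events: tuple[str, ...]

    def __post_init__(self):
        if self.test not in TESTS:
            raise ValidationError(f"unknown test {self.test!r}; expected one of {TESTS}")
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        events = tuple(self.events)
        if not events:
            raise ValidationError(
                f"empty event sequence for subject {self.subject_id!r}"
            )
        bad = sorted({e for e in events if e not in ("L", "R")})
        if bad:
            raise ValidationError(
                f"subject {self.subject_id!r}: paw codes must be 'L' or 'R', got {bad}"
            )
        object.__setattr__(self, "events", events)

    @property
    def n_right(self) -> int:
        return sum(1 for e in self.events if e == "R")

    @property
    def n_left(self) -> int:
        return sum(1 for e in self.events if e == "L")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.test, self.condition)


@dataclass(frozen=True)
class LateralityRecord:
    """Scored laterality for one session: LI, |LI|, z, class, first paw."""

    subject_id: str
    test: str
    condition: str
    n_right: int
    n_left: int
    li: float
    abs_li: float
    z: float
    preference: str
    first_paw: str
    complete: bool = True

    @property
    def n_total(self) -> int:
        return self.n_right + self.n_left


@dataclass(frozen=True)
class PreferenceDistribution:
    """Class counts for one test x condition with per-class binomial p-values."""

    test: str
    condition: str
    counts: Mapping[str, int]
    total_n: int
    p_values: Mapping[str, float]
    null_prop: float = NULL_PROPORTION

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "test": self.test,
                "condition": self.condition,
                "preference": cls,
                "count": self.counts[cls],
                "total_n": self.total_n,
                "proportion": self.counts[cls] / self.total_n,
                "p_value": self.p_values[cls],
            }
            for cls in PREFERENCE_CLASSES
        ]
        return pd.DataFrame(rows)


def compute_li(n_right: int, n_left: int) -> float:
    """Laterality index (R - L) / (R + L).

    Raises :class:`UnscorableSessionError` when there are no reaches at all.
    """
    if n_right < 0 or n_left < 0:
        raise ValidationError("paw counts must be non-negative")
    total = n_right + n_left
    if total == 0:
        raise UnscorableSessionError("session has zero paw responses")
    return (n_right - n_left) / total


def binomial_z(n_right: int, n_total: int) -> float:
    """Normal-approximation z-score (R - 0.5 N) / sqrt(0.25 N)."""
    if n_total < 1:
        raise UnscorableSessionError("session has zero paw responses")
    if not 0 <= n_right <= n_total:
        raise ValidationError(f"n_right={n_right} outside [0, {n_total}]")
    return (n_right - 0.5 * n_total) / math.sqrt(0.25 * n_total)


def classify_preference(z: float, cutoff: float = Z_CUTOFF) -> str:
    """'right' iff z >= cutoff, 'left' iff z <= -cutoff, else 'ambilateral'.

    Boundaries are inclusive for the lateralized classes.
    """
    if not math.isfinite(z):
        raise ValidationError(f"z-score must be finite, got {z}")
    if z >= cutoff:
        return "right"
    if z <= -cutoff:
        return "left"
    return "ambilateral"


def score_sequence(
    seq: PawEventSequence, target_trials: int = TARGET_TRIALS
) -> LateralityRecord:
    """Score one session into a :class:`LateralityRecord`.

    Sessions shorter than ``target_trials`` are scored but flagged
    ``complete=False`` so downstream analyses can drop them.
    """
    n_r, n_l = seq.n_right, seq.n_left
    li = compute_li(n_r, n_l)
    z = binomial_z(n_r, n_r + n_l)
    return LateralityRecord(
        subject_id=seq.subject_id,
        test=seq.test,
        condition=seq.condition,
        n_right=n_r,
        n_left=n_l,
        li=li,
        abs_li=abs(li),
        z=z,
        preference=classify_preference(z),
        first_paw=seq.events[0],
        complete=len(seq.events) >= target_trials,
    )


def score_cohort(
    sequences: Iterable[PawEventSequence], target_trials: int = TARGET_TRIALS
) -> list[LateralityRecord]:
    """Score a collection of sessions, rejecting duplicate keys."""
    sequences = list(sequences)
    keys = Counter(s.key for s in sequences)
    dups = sorted(k for k, c in keys.items() if c > 1)
    if dups:
        raise ValidationError(f"duplicate (subject, test, condition) keys: {dups}")
    return [score_sequence(s, target_trials) for s in sequences]


def exact_binomial_p(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value, 'small p-values' method.

    Sums the probabilities of all outcomes whose point probability does not
    exceed that of the observed count (with a small relative tolerance for
    floating-point ties), as scipy's binomtest does.
    """
    return sps.binomtest(k, n, p0, alternative="two-sided").pvalue


def preference_distribution_test(
    records: Sequence[LateralityRecord], null_prop: float = NULL_PROPORTION
) -> PreferenceDistribution:
    """Exact binomial test of each preference-class count against ``null_prop``.

    All records must share the same test and condition; p-values are
    two-sided exact binomial for ``count`` successes in ``total_n`` trials.
    """
    if not records:
        raise ValidationError("need at least one record")
    keys = {(r.test, r.condition) for r in records}
    if len(keys) > 1:
        raise ValidationError(
            f"records mix test/condition keys: {sorted(keys)}; pass one stratum"
        )
    if not 0.0 < null_prop < 1.0:
        raise ValidationError("null_prop must lie in (0, 1)")
    test, condition = next(iter(keys))
    n = len(records)
    counts = {cls: 0 for cls in PREFERENCE_CLASSES}
    for r in records:
        counts[r.preference] += 1
    p_values = {cls: exact_binomial_p(counts[cls], n, null_prop) for cls in counts}
    return PreferenceDistribution(
        test=test,
        condition=condition,
        counts=counts,
        total_n=n,
        p_values=p_values,
        null_prop=null_prop,
    )


@dataclass(frozen=True)
class OneSampleResult:
    """One-sample t-test of the mean LI against zero."""

    mean: float
    se: float
    t: float
    df: int
    p: float
    n: int


def population_bias_test(lis: Sequence[float]) -> OneSampleResult:
    """One-sample t-test of a collection of LIs against a zero population mean."""
    x = np.asarray(list(lis), dtype=float)
    if x.size < 2:
        raise ValidationError("need at least two LI values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DegenerateVarianceError("LI values have zero variance")
    res = sps.ttest_1samp(x, 0.0)
    se = sd / math.sqrt(x.size)
    return OneSampleResult(
        mean=float(x.mean()),
        se=float(se),
        t=float(res.statistic),
        df=x.size - 1,
        p=float(res.pvalue),
        n=x.size,
    )


@dataclass(frozen=True)
class FirstPawResult:
    """Between-subjects t comparing LI by direction of first paw use.

    Group order is (L, R): negative t means left-first dogs have lower
    (more leftward) LI.  Cohen's d uses the pooled SD.
    """

    t: float
    df: int
    p: float
    cohen_d: float
    mean_left_first: float
    mean_right_first: float
    n_left_first: int
    n_right_first: int


def cohen_d_pooled(a: np.ndarray, b: np.ndarray) -> float:
    """Classical Cohen's d with pooled SD, group order (a, b)."""
    na, nb = a.size, b.size
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0.0:
        raise DegenerateVarianceError("pooled SD is zero")
    return float((a.mean() - b.mean()) / pooled)


def first_paw_association(records: Sequence[LateralityRecord]) -> FirstPawResult:
    """Student t-test of LI between first-paw-L and first-paw-R dogs."""
    left = np.array([r.li for r in records if r.first_paw == "L"], dtype=float)
    right = np.array([r.li for r in records if r.first_paw == "R"], dtype=float)
    for name, grp in (("L", left), ("R", right)):
        if grp.size == 0:
            raise DataError(f"no dogs with first_paw={name}; both groups required")
    if left.size + right.size < 3:
        raise DataError("too few records for a two-sample t-test")
    if left.std(ddof=1) == 0.0 and right.std(ddof=1) == 0.0:
        raise DegenerateVarianceError("both first-paw groups have zero variance")
    res = sps.ttest_ind(left, right, equal_var=True)
    return FirstPawResult(
        t=float(res.statistic),
        df=left.size + right.size - 2,
        p=float(res.pvalue),
        cohen_d=cohen_d_pooled(left, right),
        mean_left_first=float(left.mean()),
        mean_right_first=float(right.mean()),
        n_left_first=int(left.size),
        n_right_first=int(right.size),
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def read_paw_events(path) -> list[PawEventSequence]:
    """Read a long-format event CSV (subject_id,test,condition,trial,paw)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "test", "condition", "trial", "paw"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"event CSV missing columns: {sorted(missing)}")
    sequences = []
    for (subject, test, condition), grp in df.groupby(
        ["subject_id", "test", "condition"], sort=True
    ):
        grp = grp.sort_values("trial")
        sequences.append(
            PawEventSequence(
                subject_id=str(subject),
                test=str(test),
                condition=str(condition),
                events=tuple(grp["paw"]),
            )
        )
    return sequences


def write_paw_events(sequences: Iterable[PawEventSequence], path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "test": s.test,
            "condition": s.condition,
            "trial": i + 1,
            "paw": paw,
        }
        for s in sequences
        for i, paw in enumerate(s.events)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def records_to_frame(records: Sequence[LateralityRecord]) -> pd.DataFrame:
    """Per-dog records table (mirrors the supplementary per-animal dataset)."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "test": r.test,
                "condition": r.condition,
                "n_right": r.n_right,
                "n_left": r.n_left,
                "li": r.li,
                "abs_li": r.abs_li,
                "z": r.z,
                "preference": r.preference,
                "first_paw": r.first_paw,
                "complete": r.complete,
            }
            for r in records
        ]
    )
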