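"""Scoring of the object-location-memory (OLM) and spatial Y-maze tasks.

Both tasks probe hippocampus-dependent spatial memory.  In OLM, a mouse
trained with two identical objects is tested 24 h later with one object
displaced; preference ratio = time exploring the displaced object / time
exploring the unmoved object, with 1 meaning no preference.  Sessions are
excluded for under-exploration (<10 s total in training, <5 s total in
testing, <1 s on any single object) or a training-phase object bias
(training ratio outside [0.5, 2.0]).

In the spatial Y-maze, one arm is blocked during training and opened at
testing; memory is read out as whether the first entry is into the novel
(previously blocked) arm and as novel- vs familiar-arm entry counts.
Arm-entry detection from trajectories is upstream of this module: a
session's entries are already an ordered token log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

TRAINING_ARMS = ("home", "familiar")
TESTING_ARMS = ("home", "familiar", "novel")
ENTRY_SEP = "|"  # token delimiter in CSV round trips

EXCLUSION_REASONS = ("low_training", "low_testing", "low_single_object", "training_bias")


@dataclass(frozen=True)
class OLMThresholds:
    """The task's exclusion cutoffs (seconds; bias as a unitless ratio).

    ``single_object_phases`` selects where the <1 s single-object rule is
    checked; both phases is the conservative default.
    """

    min_training_total: float = 10.0
    min_testing_total: float = 5.0
    min_single_object: float = 1.0
    bias_low: float = 0.5
    bias_high: float = 2.0
    single_object_phases: tuple = ("training", "testing")


@dataclass(frozen=True)
class OLMSession:
    animal_id: str
    cycle: str
    stress: str
    training_a_s: float
    training_b_s: float
    displaced_object: str  # "A" or "B", counterbalanced across animals
    testing_displaced_s: float
    testing_unmoved_s: float

    def __post_init__(self):
        if self.displaced_object not in ("A", "B"):
            raise ValueError("displaced_object must be 'A' or 'B'")
        times = (self.training_a_s, self.training_b_s,
                 self.testing_displaced_s, self.testing_unmoved_s)
        if any(t < 0 for t in times):
            raise ValueError("exploration times must be nonnegative")


@dataclass(frozen=True)
class OLMResult:
    animal_id: str
    cycle: str
    stress: str
    training_ratio: float
    preference_ratio: float
    training_total_s: float
    testing_total_s: float
    exclusion_reasons: tuple = ()
    ratio_warning: bool = False  # set when a ratio needed an inf/nan sentinel

    @property
    def excluded(self) -> bool:
        return len(self.exclusion_reasons) > 0


@dataclass(frozen=True)
class YMazeSession:
    animal_id: str
    cycle: str
    stress: str
    training_entries: tuple
    testing_entries: tuple
    distance_training_cm: float = 0.0
    distance_testing_cm: float = 0.0

    def __post_init__(self):
        bad = [t for t in self.training_entries if t not in TRAINING_ARMS]
        bad += [t for t in self.testing_entries if t not in TESTING_ARMS]
        if bad:
            raise ValueError(f"unknown arm tokens: {sorted(set(bad))}")
        if self.distance_training_cm < 0 or self.distance_testing_cm < 0:
            raise ValueError("distances must be nonnegative")


@dataclass(frozen=True)
class YMazeResult:
    animal_id: str
    cycle: str
    stress: str
    first_entry_novel: bool
    novel_entries: int
    familiar_entries: int
    home_entries: int
    total_testing_entries: int
    total_training_entries: int
    distance_training_cm: float
    distance_testing_cm: float


# ---------------------------------------------------------------------------
# scoring


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    """num/den with explicit sentinels: +inf when only den is 0, nan when
    both are (flagged in either case), never a silent drop."""
    if den == 0:
        return (math.inf, True) if num > 0 else (math.nan, True)
    return num / den, False


def olm_score(session: OLMSession, thresholds: OLMThresholds = OLMThresholds()) -> OLMResult:
    """Score one OLM session and evaluate all exclusion rules independently.

    preference_ratio = testing displaced / testing unmoved;
    training_ratio  = training time on the to-be-displaced object / time on
    the to-stay object.  Every violated rule is reported, not only the first.
    """
    t = thresholds
    if session.displaced_object == "A":
        to_move, to_stay = session.training_a_s, session.training_b_s
    else:
        to_move, to_stay = session.training_b_s, session.training_a_s
    training_total = session.training_a_s + session.training_b_s
    testing_total = session.testing_displaced_s + session.testing_unmoved_s
    training_ratio, warn1 = _safe_ratio(to_move, to_stay)
    preference_ratio, warn2 = _safe_ratio(session.testing_displaced_s,
                                          session.testing_unmoved_s)

    reasons = []
    if training_total < t.min_training_total:
        reasons.append("low_training")
    if testing_total < t.min_testing_total:
        reasons.append("low_testing")
    singles = []
    if "training" in t.single_object_phases:
        singles += [session.training_a_s, session.training_b_s]
    if "testing" in t.single_object_phases:
        singles += [session.testing_displaced_s, session.testing_unmoved_s]
    if any(s < t.min_single_object for s in singles):
        reasons.append("low_single_object")
    if not (math.isnan(training_ratio)
            or t.bias_low <= training_ratio <= t.bias_high):
        reasons.append("training_bias")

    return OLMResult(session.animal_id, session.cycle, session.stress,
                     training_ratio, preference_ratio, training_total,
                     testing_total, tuple(reasons), warn1 or warn2)


def ymaze_score(session: YMazeSession) -> YMazeResult:
    """Tally arm entries; the first non-home testing token is the first
    entry (the animal starts in the home arm)."""
    if not session.testing_entries:
        raise ValueError("testing entry sequence is empty")
    first_entry = next((t for t in session.testing_entries if t != "home"), None)
    if first_entry is None:
        raise ValueError("testing sequence contains no non-home entry")
    counts = {arm: session.testing_entries.count(arm) for arm in TESTING_ARMS}
    return YMazeResult(
        session.animal_id, session.cycle, session.stress,
        first_entry_novel=(first_entry == "novel"),
        novel_entries=counts["novel"],
        familiar_entries=counts["familiar"],
        home_entries=counts["home"],
        total_testing_entries=len(session.testing_entries),
        total_training_entries=len(session.training_entries),
        distance_training_cm=session.distance_training_cm,
        distance_testing_cm=session.distance_testing_cm,
    )


class OLMScorer(BaseEstimator, TransformerMixin):
    """sklearn-style batch scorer: sessions in, per-session results out.

    ``transform`` accepts a list of :class:`OLMSession` or a DataFrame in
    the CSV layout and returns a result DataFrame (one row per session,
    exclusion reasons joined with ';').
    """

    def __init__(self, thresholds: OLMThresholds = OLMThresholds()):
        self.thresholds = thresholds

    def fit(self, X=None, y=None) -> "OLMScorer":
        return self

    def transform(self, X) -> pd.DataFrame:
        sessions = olm_sessions_from_frame(X) if isinstance(X, pd.DataFrame) else X
        results = [olm_score(s, self.thresholds) for s in sessions]
        return olm_results_to_frame(results)


class YMazeScorer(BaseEstimator, TransformerMixin):
    """sklearn-style batch scorer for Y-maze sessions."""

    def fit(self, X=None, y=None) -> "YMazeScorer":
        return self

    def transform(self, X) -> pd.DataFrame:
        sessions = ymaze_sessions_from_frame(X) if isinstance(X, pd.DataFrame) else X
        results = [ymaze_score(s) for s in sessions]
        return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# group summaries


def group_summary(results: Sequence, by: tuple = ("cycle", "stress")) -> pd.DataFrame:
    """Per-condition means, SEMs, and ns of the task's indices.

    OLM results: excluded sessions are omitted from the statistics but
    counted; a condition left empty after exclusion is kept as a flagged
    row rather than silently dropped.  Y-maze results: entry counts plus
    the percentage of animals whose first entry was the novel arm.
    """
    if len(results) == 0:
        raise ValueError("no results to summarize")
    if isinstance(results[0], OLMResult):
        return _olm_group_summary(results, by)
    if isinstance(results[0], YMazeResult):
        return _ymaze_group_summary(results, by)
    raise TypeError("results must be OLMResult or YMazeResult records")


def _sem(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0


def _olm_group_summary(results: Sequence[OLMResult], by) -> pd.DataFrame:
    df = olm_results_to_frame(results)
    rows = []
    for key, grp in df.groupby(list(by), sort=True):
        kept = grp[~grp["excluded"]]
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update(n_total=len(grp), n_excluded=int(grp["excluded"].sum()),
                   n=len(kept), empty_after_exclusion=len(kept) == 0)
        for col in ("preference_ratio", "training_ratio",
                    "training_total_s", "testing_total_s"):
            vals = kept[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"{col}_mean"] = float(np.mean(vals)) if len(vals) else np.nan
            row[f"{col}_sem"] = _sem(vals) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _ymaze_group_summary(results: Sequence[YMazeResult], by) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    rows = []
    for key, grp in df.groupby(list(by), sort=True):
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update(
            n=len(grp),
            first_entry_novel_pct=float(grp["first_entry_novel"].mean() * 100),
        )
        for col in ("novel_entries", "familiar_entries", "total_testing_entries",
                    "total_training_entries", "distance_training_cm",
                    "distance_testing_cm"):
            vals = grp[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = float(np.mean(vals))
            row[f"{col}_sem"] = _sem(vals)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tabular IO


def olm_sessions_from_frame(df: pd.DataFrame) -> list[OLMSession]:
    return [
        OLMSession(str(r.animal_id), str(r.cycle), str(r.stress),
                   float(r.training_a_s), float(r.training_b_s),
                   str(r.displaced_object), float(r.testing_displaced_s),
                   float(r.testing_unmoved_s))
        for r in df.itertuples(index=False)
    ]


def olm_sessions_to_frame(sessions: Sequence[OLMSession]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in sessions])


def olm_results_to_frame(results: Sequence[OLMResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = vars(r).copy()
        d["exclusion_reasons"] = ";".join(r.exclusion_reasons)
        d["excluded"] = r.excluded
        rows.append(d)
    return pd.DataFrame(rows)


def ymaze_sessions_from_frame(df: pd.DataFrame) -> list[YMazeSession]:
    def _split(tokens: str) -> tuple:
        tokens = str(tokens).strip()
        return tuple(tokens.split(ENTRY_SEP)) if tokens else ()

    return [
        YMazeSession(str(r.animal_id), str(r.cycle), str(r.stress),
                     _split(r.training_entries), _split(r.testing_entries),
                     float(r.distance_training_cm), float(r.distance_testing_cm))
        for r in df.itertuples(index=False)
    ]


def ymaze_sessions_to_frame(sessions: Sequence[YMazeSession]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"animal_id": s.animal_id, "cycle": s.cycle, "stress": s.stress,
             "training_entries": ENTRY_SEP.join(s.training_entries),
             "testing_entries": ENTRY_SEP.join(s.testing_entries),
             "distance_training_cm": s.distance_training_cm,
             "distance_testing_cm": s.distance_testing_cm}
            for s in sessions
        ]
    )
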