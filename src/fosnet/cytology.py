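"""Estrous-cycle cytology, hormone, and uterine readouts.

Vaginal-smear composition (% nucleated epithelial, cornified, and leukocyte
cells) is the standard noninvasive readout of estrous-cycle phase in mice:
estrus smears are dominated by cornified cells while early proestrus smears
carry a large fraction of nucleated cells.  The study design uses only
these two phases — early proestrus as the high-estradiol (high E2) state
and estrus as the low-estradiol (low E2) state — so the classifier maps
any other composition to ``indeterminate`` rather than guessing at
metestrus/diestrus.

Also here: cycle-length extraction from daily phase series (onset = first
day of a proestrus run), the estrogen-sensitive uterine index
(uterus weight / body weight) x 100, handling of ELISA detection-limit
censoring for serum estradiol, and the hormone-vs-cytology correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .network import UndefinedCorrelationError, spearman

PHASES = ("early_proestrus", "estrus", "indeterminate")
CELL_TYPES = ("nucleated", "cornified", "leukocyte")
DETECTION_LIMIT_PG_ML = 3.0  # functional sensitivity of the estradiol ELISA kit
PCT_TOL = 1e-6


@dataclass(frozen=True)
class Smear:
    """One vaginal smear's cell-type composition, as percentages of smear."""

    animal_id: str
    day: int
    nucleated_pct: float
    cornified_pct: float
    leukocyte_pct: float

    def __post_init__(self):
        pcts = (self.nucleated_pct, self.cornified_pct, self.leukocyte_pct)
        if any(p < -PCT_TOL or p > 100 + PCT_TOL for p in pcts):
            raise ValueError(f"percentages must lie in [0, 100]: {pcts}")
        if abs(sum(pcts) - 100.0) > PCT_TOL:
            raise ValueError(f"percentages must sum to 100: {pcts}")

    @property
    def composition(self) -> tuple[float, float, float]:
        return (self.nucleated_pct, self.cornified_pct, self.leukocyte_pct)


@dataclass(frozen=True)
class PhaseCall:
    phase: str
    rule_fired: str

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")


@dataclass(frozen=True)
class PhaseSeries:
    """Ordered daily phase calls for one animal (days strictly increasing)."""

    animal_id: str
    days: tuple
    phases: tuple

    def __post_init__(self):
        if len(self.days) != len(self.phases):
            raise ValueError("days and phases differ in length")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(p not in PHASES for p in self.phases):
            raise ValueError(f"phases must come from {PHASES}")


@dataclass(frozen=True)
class HormoneSample:
    """Serum estradiol with its detection-limit censoring flag."""

    animal_id: str
    estradiol_pg_ml: float
    detection_limit: float = DETECTION_LIMIT_PG_ML

    def __post_init__(self):
        if self.estradiol_pg_ml < 0:
            raise ValueError("estradiol must be nonnegative")

    @property
    def below_limit(self) -> bool:
        return self.estradiol_pg_ml < self.detection_limit


@dataclass(frozen=True)
class UterineRecord:
    animal_id: str
    uterus_weight_g: float
    body_weight_g: float

    def __post_init__(self):
        if self.uterus_weight_g <= 0 or self.body_weight_g <= 0:
            raise ValueError("weights must be positive")

    @property
    def uterine_index(self) -> float:
        return uterine_index(self.uterus_weight_g, self.body_weight_g)


# ---------------------------------------------------------------------------
# phase classification


class EstrousPhaseClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based phase calls from smear composition.

    estrus           cornified >= ``estrus_cornified_min`` (default 75%)
                     and nucleated <= ``estrus_nucleated_max`` (default 15%)
    early_proestrus  nucleated is the strict plurality and
                     nucleated >= ``proestrus_nucleated_min`` (default 40%)
    indeterminate    otherwise (incl. metestrus/diestrus-like smears)

    The cutoffs operationalize the qualitative cytology pattern
    (cornified-dominated estrus vs nucleated-rich early proestrus) and are
    exposed as parameters.  The classifier is stateless; ``fit`` only
    records class labels so it composes with sklearn model selection.
    """

    def __init__(self, estrus_cornified_min: float = 75.0,
                 estrus_nucleated_max: float = 15.0,
                 proestrus_nucleated_min: float = 40.0):
        self.estrus_cornified_min = estrus_cornified_min
        self.estrus_nucleated_max = estrus_nucleated_max
        self.proestrus_nucleated_min = proestrus_nucleated_min

    def fit(self, X=None, y=None) -> "EstrousPhaseClassifier":
        self.classes_ = np.asarray(PHASES)
        return self

    def predict(self, X) -> np.ndarray:
        """Phase labels for rows of (nucleated, cornified, leukocyte) %."""
        X = self._as_array(X)
        return np.asarray([self._call(*row).phase for row in X], dtype=object)

    def predict_call(self, smear: Smear) -> PhaseCall:
        """Full call for one smear, recording which rule fired."""
        return self._call(*smear.composition)

    def _call(self, nucleated: float, cornified: float, leukocyte: float) -> PhaseCall:
        Smear("_", 0, nucleated, cornified, leukocyte)  # validation
        if cornified >= self.estrus_cornified_min and nucleated <= self.estrus_nucleated_max:
            return PhaseCall("estrus", "cornified_dominant")
        if (nucleated > cornified and nucleated > leukocyte
                and nucleated >= self.proestrus_nucleated_min):
            return PhaseCall("early_proestrus", "nucleated_plurality")
        return PhaseCall("indeterminate", "no_rule")

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = [f"{c}_pct" for c in CELL_TYPES]
            if all(c in X.columns for c in cols):
                X = X[cols]
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("expected an (n, 3) array of cell-type percentages")
        return X


def classify_phase(smear: Smear, classifier: EstrousPhaseClassifier = None) -> PhaseCall:
    """Classify one smear; thin wrapper over :class:`EstrousPhaseClassifier`."""
    return (classifier or EstrousPhaseClassifier()).predict_call(smear)


# ---------------------------------------------------------------------------
# cycle tracking


def cycle_lengths(series: PhaseSeries) -> list[int]:
    """Cycle durations as day gaps between successive proestrus onsets.

    An onset is the first day of a maximal consecutive early_proestrus run;
    with fewer than two onsets the list is empty (cycling cannot be timed,
    which callers treat as "not regularly cycling", not as an error).
    """
    onsets = []
    prev = None
    for day, phase in zip(series.days, series.phases):
        if phase == "early_proestrus" and not (
            prev is not None and prev == "early_proestrus"
        ):
            onsets.append(day)
        prev = phase
    return [b - a for a, b in zip(onsets, onsets[1:])]


def uterine_index(uterus_weight_g: float, body_weight_g: float) -> float:
    """(uterus weight (g) / body weight (g)) x 100 — an estrogen-sensitive
    physiological readout that is higher entering proestrus than in estrus."""
    if uterus_weight_g <= 0 or body_weight_g <= 0:
        raise ValueError("weights must be positive")
    return uterus_weight_g / body_weight_g * 100.0


# ---------------------------------------------------------------------------
# hormone handling


def apply_detection_limit(values: Sequence[float], limit: float = DETECTION_LIMIT_PG_ML,
                          mode: str = "extrapolated") -> list[float]:
    """Handle assay values below the kit's functional sensitivity.

    mode="extrapolated" keeps the standard-curve extrapolated values as-is;
    mode="zero" sets every value below ``limit`` to 0 (undetectable).  Both
    conventions are in routine use and the study reports its endocrine
    contrasts as robust to the choice.
    """
    if limit < 0:
        raise ValueError("limit must be nonnegative")
    if mode == "extrapolated":
        return [float(v) for v in values]
    if mode == "zero":
        return [0.0 if v < limit else float(v) for v in values]
    raise ValueError(f"unknown mode {mode!r}; use 'extrapolated' or 'zero'")


class HormoneCytologyCorrelation(NamedTuple):
    spearman_rho: float
    pearson_r2: float
    slope: float
    intercept: float
    n: int


def hormone_cytology_correlation(
    samples: Sequence[HormoneSample],
    smears: Sequence[Smear],
    cell_type: str = "nucleated",
) -> HormoneCytologyCorrelation:
    """Correlate serum estradiol with a smear cell-type percentage.

    Samples and smears are matched by animal_id.  Returns the Spearman
    coefficient (shared rank-correlation routine), the Pearson r² of the
    least-squares fit of estradiol on the percentage, and the fit's slope
    and intercept.  Constant inputs raise
    :class:`~fosnet.network.UndefinedCorrelationError` — an undefined
    correlation is never reported as 0.
    """
    if cell_type not in CELL_TYPES:
        raise ValueError(f"cell_type must be one of {CELL_TYPES}")
    if len(samples) != len(smears):
        raise ValueError("samples and smears differ in length")
    if len(samples) < 4:
        raise ValueError("need at least 4 matched pairs")
    by_animal = {s.animal_id: s for s in smears}
    if set(by_animal) != {h.animal_id for h in samples}:
        raise ValueError("animal_id sets of samples and smears do not match")
    e2 = np.asarray([h.estradiol_pg_ml for h in samples], dtype=float)
    pct = np.asarray(
        [getattr(by_animal[h.animal_id], f"{cell_type}_pct") for h in samples],
        dtype=float,
    )
    if np.ptp(e2) == 0 or np.ptp(pct) == 0:
        raise UndefinedCorrelationError(
            "estradiol or cell-type percentage has zero variance"
        )
    rho, _, status = spearman(pct, e2)
    if status != "ok":
        raise UndefinedCorrelationError(f"rank correlation undefined: {status}")
    slope, intercept = np.polyfit(pct, e2, 1)
    r = np.corrcoef(pct, e2)[0, 1]
    return HormoneCytologyCorrelation(float(rho), float(r**2), float(slope),
                                      float(intercept), len(samples))


# ---------------------------------------------------------------------------
# tabular IO


def smears_from_frame(df: pd.DataFrame) -> list[Smear]:
    """Smears from a table with columns animal_id, day, nucleated_pct,
    cornified_pct, leukocyte_pct."""
    return [
        Smear(str(r.animal_id), int(r.day), float(r.nucleated_pct),
              float(r.cornified_pct), float(r.leukocyte_pct))
        for r in df.itertuples(index=False)
    ]


def smears_to_frame(smears: Sequence[Smear]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"animal_id": s.animal_id, "day": s.day,
             "nucleated_pct": s.nucleated_pct, "cornified_pct": s.cornified_pct,
             "leukocyte_pct": s.leukocyte_pct}
            for s in smears
        ]
    )


def hormones_from_frame(df: pd.DataFrame,
                        detection_limit: float = DETECTION_LIMIT_PG_ML) -> list[HormoneSample]:
    return [
        HormoneSample(str(r.animal_id), float(r.estradiol_pg_ml), detection_limit)
        for r in df.itertuples(index=False)
    ]


def hormones_to_frame(samples: Sequence[HormoneSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"animal_id": h.animal_id, "estradiol_pg_ml": h.estradiol_pg_ml,
             "below_limit": h.below_limit, "detection_limit": h.detection_limit}
            for h in samples
        ]
    )
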