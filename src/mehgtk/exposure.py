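"""Dietary methylmercury exposure assessment from 24-hour recall records.

Per-subject daily intake (ug/kg bw/day) is obtained by multiplying the
consumed mass of each food item (g/day) by its methylmercury concentration
(ug/g), summing within a recall day, dividing by body weight and averaging
over the distinct recall days (two non-consecutive 24-h recalls in the
study design this emulates).

Non-detect food items are imputed at half the analytical limit of
detection (LOD/2).  The LOD is given in ug/kg while concentrations are
carried in ug/g, so a 6 ug/kg LOD becomes 0.003 ug/g after substitution.
Food items absent from the concentration table contribute zero: only the
high-mercury items were assayed, and all other foods are outside the
exposure model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FoodRecord",
    "ConcentrationEntry",
    "substitute_lod",
    "effective_concentrations",
    "daily_intake",
    "cohort_intakes",
    "read_food_records",
    "read_concentration_table",
]

logger = logging.getLogger(__name__)

#: Conversion from the LOD's ug/kg to the internal ug/g concentration unit.
_UG_PER_KG_TO_UG_PER_G = 1e-3

FOOD_RECORD_COLUMNS = ["subject_id", "recall_day", "item", "grams"]
CONCENTRATION_COLUMNS = ["item", "concentration_ug_per_g", "detected"]


@dataclass(frozen=True)
class FoodRecord:
    subject_id: str
    recall_day: int
    item: str
    grams: float

    def __post_init__(self) -> None:
        if self.grams < 0:
            raise ValueError(f"grams must be >= 0, got {self.grams}")


@dataclass(frozen=True)
class ConcentrationEntry:
    """Assayed methylmercury concentration of one food item (ug/g).

    When ``detected`` is false the measured value is ignored and LOD/2 is
    substituted.
    """

    item: str
    concentration: float
    detected: bool

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")


def substitute_lod(entry: ConcentrationEntry, lod: float) -> float:
    """Effective concentration (ug/g) after half-LOD imputation.

    ``lod`` is in ug/kg.  The detection flag, not the magnitude, governs
    substitution: a detected value at or below the LOD passes through.
    """
    if lod <= 0:
        raise ValueError(f"lod must be > 0, got {lod}")
    if entry.detected:
        return entry.concentration
    return 0.5 * lod * _UG_PER_KG_TO_UG_PER_G


def effective_concentrations(conc: Iterable[ConcentrationEntry], lod: float) -> dict[str, float]:
    """Map item -> effective concentration (ug/g) with LOD/2 substitution."""
    return {entry.item: substitute_lod(entry, lod) for entry in conc}


def daily_intake(
    records: Iterable[FoodRecord],
    conc: Iterable[ConcentrationEntry] | Mapping[str, float],
    lod: float,
    weight: float,
) -> float:
    """Mean daily methylmercury intake (ug/kg bw/day) for one subject.

    For each recall day, sums grams x effective concentration over items,
    divides by body weight, then averages over the distinct recall days
    present with equal weight.  Items missing from the concentration table
    contribute zero (logged).  An empty record set returns 0 with a warning.
    """
    if weight <= 0:
        raise ValueError(f"weight must be > 0, got {weight}")
    if isinstance(conc, Mapping):
        eff = dict(conc)
    else:
        eff = effective_concentrations(conc, lod)

    records = list(records)
    if not records:
        logger.warning("empty food-record set: intake set to 0")
        return 0.0

    skipped = sorted({r.item for r in records if r.item not in eff})
    if skipped:
        logger.warning("items absent from concentration table treated as zero: %s", skipped)

    per_day: dict[int, float] = {}
    for r in records:
        per_day.setdefault(r.recall_day, 0.0)
        per_day[r.recall_day] += r.grams * eff.get(r.item, 0.0)
    daily = [total / weight for total in per_day.values()]
    return sum(daily) / len(daily)


def cohort_intakes(
    food: pd.DataFrame,
    conc: pd.DataFrame,
    lod: float,
    weights: Mapping[str, float],
) -> pd.Series:
    """Daily intake per subject from tabular food records.

    ``food`` has columns ``subject_id, recall_day, item, grams``; ``conc``
    has ``item, concentration_ug_per_g, detected``; ``weights`` maps
    subject_id -> body weight (kg).  Returns a Series indexed by
    subject_id.  Subjects in ``weights`` with no food records get 0.
    """
    entries = [
        ConcentrationEntry(str(r.item), float(r.concentration_ug_per_g), bool(int(r.detected)))
        for r in conc.itertuples(index=False)
    ]
    eff = effective_concentrations(entries, lod)
    out = {}
    grouped = {str(k): g for k, g in food.groupby("subject_id")}
    for sid, weight in weights.items():
        g = grouped.get(str(sid))
        if g is None:
            recs: list[FoodRecord] = []
        else:
            recs = [
                FoodRecord(str(r.subject_id), int(r.recall_day), str(r.item), float(r.grams))
                for r in g.itertuples(index=False)
            ]
        out[str(sid)] = daily_intake(recs, eff, lod, float(weight))
    return pd.Series(out, name="intake_ug_per_kg_day")


def read_food_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "item": str}, float_precision="round_trip")
    missing = set(FOOD_RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"food-record file missing columns: {sorted(missing)}")
    return df


def read_concentration_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"item": str}, float_precision="round_trip")
    missing = set(CONCENTRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"concentration table missing columns: {sorted(missing)}")
    return df
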