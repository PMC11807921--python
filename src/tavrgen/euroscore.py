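"""EuroSCORE II: predicted in-hospital mortality after adult cardiac surgery.

The score is a published logistic-regression model over 18 clinical items:
``p = e^y / (1 + e^y)`` with ``y = b0 + sum b_i x_i``.  The coefficients are
shipped as a data file (``data/euroscore2_coefficients.json``) rather than
hard-coded, so they remain auditable against the publication and replaceable
if revised.  Age enters as 1 point up to 60 years and one additional point
per year thereafter; every other item is a flag or a category level.

The sampler draws a complete risk profile from documented base prevalences,
each scaled by a per-item probability multiplier so that an instructor can
bias the generated population toward particular presentations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Literal, Mapping, Optional, Union

import numpy as np
from pydantic import BaseModel, Field

from .errors import TavrgenError

_DATA_DIR = Path(__file__).parent / "data"


class EuroscoreInput(BaseModel):
    """The 18-item EuroSCORE II risk profile."""

    age: int = Field(ge=18, le=110)
    female: bool = False
    renal: Literal["normal", "moderate", "severe", "dialysis"] = "normal"
    extracardiac_arteriopathy: bool = False
    poor_mobility: bool = False
    previous_cardiac_surgery: bool = False
    chronic_lung_disease: bool = False
    active_endocarditis: bool = False
    critical_preoperative_state: bool = False
    insulin_dependent_diabetes: bool = False
    nyha: Literal["I", "II", "III", "IV"] = "I"
    ccs4: bool = False
    lv_function: Literal["good", "moderate", "poor", "very_poor"] = "good"
    recent_mi: bool = False
    pulmonary_hypertension: Literal["none", "moderate", "severe"] = "none"
    urgency: Literal["elective", "urgent", "emergency", "salvage"] = "elective"
    weight_of_intervention: Literal[
        "isolated_cabg", "single_non_cabg", "two_procedures", "three_procedures"
    ] = "isolated_cabg"
    thoracic_aorta: bool = False


@dataclass(frozen=True)
class RiskModel:
    """Logistic-model coefficients on the log-odds scale."""

    intercept: float
    age_coefficient: float
    age_threshold: int
    binary: Mapping[str, float]
    categorical: Mapping[str, Mapping[str, float]]

    @classmethod
    def from_file(cls, path) -> "RiskModel":
        data = json.loads(Path(path).read_text())
        return cls(
            intercept=data["intercept"],
            age_coefficient=data["age"]["coefficient"],
            age_threshold=int(data["age"]["threshold"]),
            binary=dict(data["binary"]),
            categorical={k: dict(v) for k, v in data["categorical"].items()},
        )


_MODEL_CACHE: Optional[RiskModel] = None


def load_risk_model(path=None) -> RiskModel:
    """Load a risk-model file; defaults to the packaged coefficient set."""
    global _MODEL_CACHE
    if path is None:
        if _MODEL_CACHE is None:
            _MODEL_CACHE = RiskModel.from_file(
                _DATA_DIR / "euroscore2_coefficients.json"
            )
        return _MODEL_CACHE
    return RiskModel.from_file(path)


def euroscore2(
    profile: EuroscoreInput, model: Optional[RiskModel] = None
) -> float:
    """Predicted mortality in percent, strictly within (0, 100)."""
    m = model if model is not None else load_risk_model()
    age_x = 1 if profile.age <= m.age_threshold else profile.age - m.age_threshold + 1
    y = m.intercept + m.age_coefficient * age_x
    data = profile.model_dump()
    for item, beta in m.binary.items():
        if item not in data:
            raise TavrgenError(f"risk model item {item!r} missing from input")
        y += beta * bool(data[item])
    for item, levels in m.categorical.items():
        level = data.get(item)
        if level is None:
            raise TavrgenError(f"risk model item {item!r} missing from input")
        if level not in levels:
            raise TavrgenError(
                f"unmapped category level {level!r} for item {item!r}"
            )
        y += levels[level]
    return 100.0 * (1.0 / (1.0 + math.exp(-y)))


# ---------------------------------------------------------------------------
# sampling risk profiles
# ---------------------------------------------------------------------------

#: documented default base prevalences of each flag and category (before
#: probability multipliers); round values for an elderly TAVR-referral
#: population
DEFAULT_BASE_FLAGS: Dict[str, float] = {
    "female": 0.40,
    "extracardiac_arteriopathy": 0.10,
    "poor_mobility": 0.08,
    "previous_cardiac_surgery": 0.10,
    "chronic_lung_disease": 0.12,
    "active_endocarditis": 0.02,
    "critical_preoperative_state": 0.03,
    "insulin_dependent_diabetes": 0.15,
    "ccs4": 0.08,
    "recent_mi": 0.12,
    "thoracic_aorta": 0.05,
}

DEFAULT_BASE_CATEGORIES: Dict[str, Dict[str, float]] = {
    "renal": {"normal": 0.70, "moderate": 0.20, "severe": 0.07, "dialysis": 0.03},
    "nyha": {"I": 0.40, "II": 0.30, "III": 0.20, "IV": 0.10},
    "lv_function": {"good": 0.60, "moderate": 0.25, "poor": 0.10, "very_poor": 0.05},
    "pulmonary_hypertension": {"none": 0.80, "moderate": 0.15, "severe": 0.05},
    "urgency": {"elective": 0.70, "urgent": 0.20, "emergency": 0.08, "salvage": 0.02},
    "weight_of_intervention": {
        "isolated_cabg": 0.15,
        "single_non_cabg": 0.60,
        "two_procedures": 0.20,
        "three_procedures": 0.05,
    },
}

#: age distribution of the generated population (years)
AGE_MEAN, AGE_SD, AGE_MIN, AGE_MAX = 72.0, 8.0, 18, 95


class MultiplierTable(BaseModel):
    """Per-item probability multipliers (>= 0) applied to the base
    prevalences; flag probabilities are clipped to [0, 1] and category
    distributions renormalised."""

    flags: Dict[str, float] = Field(default_factory=dict)
    categories: Dict[str, Dict[str, float]] = Field(default_factory=dict)

    def flag_multiplier(self, item: str) -> float:
        return self.flags.get(item, 1.0)

    def category_multiplier(self, item: str, level: str) -> float:
        return self.categories.get(item, {}).get(level, 1.0)


def sample_euroscore_inputs(
    rng: Union[int, np.random.Generator],
    multipliers: Optional[MultiplierTable] = None,
    base_flags: Optional[Mapping[str, float]] = None,
    base_categories: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> EuroscoreInput:
    """Draw one risk profile; deterministic for a given seed/generator."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mult = multipliers if multipliers is not None else MultiplierTable()
    flags = dict(base_flags or DEFAULT_BASE_FLAGS)
    cats = {k: dict(v) for k, v in (base_categories or DEFAULT_BASE_CATEGORIES).items()}

    for item, m in list(mult.flags.items()):
        if m < 0:
            raise ValueError(f"negative multiplier for flag {item!r}")
    for item, levels in mult.categories.items():
        for level, m in levels.items():
            if m < 0:
                raise ValueError(
                    f"negative multiplier for {item!r} level {level!r}"
                )

    values: Dict[str, object] = {}
    values["age"] = int(
        np.clip(round(float(rng.normal(AGE_MEAN, AGE_SD))), AGE_MIN, AGE_MAX)
    )
    for item, base in flags.items():
        p = float(np.clip(base * mult.flag_multiplier(item), 0.0, 1.0))
        values[item] = bool(rng.random() < p)
    for item, levels in cats.items():
        names = list(levels)
        probs = np.array(
            [levels[lv] * mult.category_multiplier(item, lv) for lv in names]
        )
        total = probs.sum()
        if total <= 0:
            raise ValueError(
                f"multipliers zero out every level of category {item!r}"
            )
        probs = probs / total
        values[item] = names[int(rng.choice(len(names), p=probs))]
    return EuroscoreInput(**values)
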