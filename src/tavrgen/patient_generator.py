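"""The authoring pipeline: constraint-aware random virtual patients.

A patient is a complete record: anatomical feature values drawn inside the
dynamically limited ranges, per-leaflet calcification sliders, an
EuroSCORE II risk profile with its computed mortality, and the seed that
reproduces all of it.  Records round-trip through a versioned JSON schema
and can be realised as a morphed mesh at any time.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
from pydantic import BaseModel, Field, ValidationError

from . import anatomy_mesh, morph_engine
from .errors import EmptyRangeError, GenerationError, SchemaError
from .features import (
    CALCIFICATION_FEATURES,
    GEOMETRIC_FEATURES,
    LEAFLETS,
    FeatureName,
)
from .euroscore import (
    EuroscoreInput,
    MultiplierTable,
    RiskModel,
    euroscore2,
    sample_euroscore_inputs,
)
from .parameter_space import ParameterRegistry, default_registry

FORMAT_VERSION = "1.0"

_CALC_FEATURE = {
    "left": FeatureName.LEAFLET_CALCIFICATION_LEFT,
    "right": FeatureName.LEAFLET_CALCIFICATION_RIGHT,
    "non": FeatureName.LEAFLET_CALCIFICATION_NON,
}


class CalcificationSpec(BaseModel):
    """Three sliders per leaflet: surface extent, deposit thickness and the
    seed of the random surface pattern."""

    extent: float = Field(ge=0.0, le=1.0, default=0.0)
    thickness_mm: float = Field(ge=0.0, default=1.0)
    pattern_seed: int = 0


class Vitals(BaseModel):
    """Monitor readout (stub physiology)."""

    heart_rate: float = Field(ge=30.0, le=220.0)
    systolic_mmhg: float = Field(ge=40.0, le=260.0)
    diastolic_mmhg: float = Field(ge=20.0, le=160.0)
    spo2: float = Field(ge=50.0, le=100.0)


class PatientRecord(BaseModel):
    """A complete virtual patient; JSON-serialisable and seed-reproducible."""

    format_version: str = FORMAT_VERSION
    seed: int
    anatomy: Dict[str, float]
    calcification: Dict[str, CalcificationSpec]
    euroscore_input: EuroscoreInput
    euroscore_value: float

    def anatomy_values(self) -> Dict[FeatureName, float]:
        """All registry feature values (geometry + calcification extents)."""
        vals = {FeatureName.parse(k): v for k, v in self.anatomy.items()}
        for leaf in LEAFLETS:
            vals[_CALC_FEATURE[leaf]] = self.calcification[leaf].extent
        return vals


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_MAX_RETRIES = 20


def generate_patient(
    seed: int,
    registry: Optional[ParameterRegistry] = None,
    model: Optional[RiskModel] = None,
    multipliers: Optional[MultiplierTable] = None,
) -> PatientRecord:
    """Generate one random virtual patient, fully reproducible per seed.

    Parameters are drawn uniformly in dependency order: independent
    features from their implemented ranges, dependent ones from their
    effective range given the already-drawn context.  A draw that leaves a
    later feature with an empty admissible interval restarts the anatomy
    (bounded retry count), so every emitted record validates cleanly.
    """
    reg = registry if registry is not None else default_registry()
    rng = np.random.default_rng(seed)
    order = reg.dependency_order()

    values: Dict[FeatureName, float] = {}
    for attempt in range(_MAX_RETRIES + 1):
        try:
            values = {}
            for feature in order:
                lo, hi = reg.effective_range(feature, values, strict=True)
                values[feature] = float(rng.uniform(lo, hi))
            break
        except EmptyRangeError as exc:
            if attempt == _MAX_RETRIES:
                raise GenerationError(
                    f"seed {seed}: no admissible anatomy after "
                    f"{_MAX_RETRIES} retries ({exc})"
                ) from exc

    calcification = {
        leaf: CalcificationSpec(
            extent=values[_CALC_FEATURE[leaf]],
            thickness_mm=float(rng.uniform(0.5, 2.5)),
            pattern_seed=int(rng.integers(0, 2**31 - 1)),
        )
        for leaf in LEAFLETS
    }
    anatomy = {
        f.value: values[f] for f in GEOMETRIC_FEATURES
    }
    profile = sample_euroscore_inputs(rng, multipliers)
    return PatientRecord(
        seed=int(seed),
        anatomy=anatomy,
        calcification=calcification,
        euroscore_input=profile,
        euroscore_value=euroscore2(profile, model),
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_patient(record: PatientRecord, path) -> None:
    """Write the record as deterministic (sorted-key) JSON."""
    Path(path).write_text(patient_json(record))


def patient_json(record: PatientRecord) -> str:
    return json.dumps(
        record.model_dump(mode="json"), indent=2, sort_keys=True
    ) + "\n"


def load_patient(path) -> PatientRecord:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: patient file must contain a JSON object")
    version = data.get("format_version")
    if version is None:
        raise SchemaError(f"{path}: missing required field 'format_version'")
    if version != FORMAT_VERSION:
        raise SchemaError(
            f"{path}: unsupported format_version {version!r} "
            f"(this build reads {FORMAT_VERSION!r})"
        )
    try:
        return PatientRecord(**data)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(loc) for loc in err["loc"]) for err in exc.errors()
        )
        raise SchemaError(f"{path}: invalid field(s): {fields}") from exc


# ---------------------------------------------------------------------------
# realisation
# ---------------------------------------------------------------------------


def patient_to_mesh(
    record: PatientRecord,
    base_mesh: Optional[anatomy_mesh.LabeledMesh] = None,
    registry: Optional[ParameterRegistry] = None,
) -> anatomy_mesh.LabeledMesh:
    """Morph the base mesh to the record's anatomical feature values."""
    reg = registry if registry is not None else default_registry()
    mesh = base_mesh if base_mesh is not None else anatomy_mesh.build_base_mesh()
    weights: Dict[str, float] = {}
    for key, value in record.anatomy.items():
        feature = FeatureName.parse(key)
        weights.update(morph_engine.param_to_weight(feature, value, reg))
    return morph_engine.apply_morphs(mesh, morph_engine.MorphState(weights))


# ---------------------------------------------------------------------------
# vitals stub
# ---------------------------------------------------------------------------

BASELINE_VITALS = {"heart_rate": 72.0, "systolic": 120.0, "diastolic": 80.0,
                   "spo2": 98.0}


def monitor_vitals(record: PatientRecord, t: float = 0.0) -> Vitals:
    """Deterministic baseline vitals modulated by the risk profile plus a
    seeded periodic waveform.  Stands in for a physiology engine feed."""
    p = record.euroscore_input
    hr = BASELINE_VITALS["heart_rate"]
    sys = BASELINE_VITALS["systolic"]
    dia = BASELINE_VITALS["diastolic"]
    spo2 = BASELINE_VITALS["spo2"]

    if p.critical_preoperative_state:
        sys -= 25.0
        dia -= 15.0
        hr += 15.0
    if p.lv_function == "moderate":
        sys -= 5.0
    elif p.lv_function == "poor":
        sys -= 10.0
        hr += 5.0
    elif p.lv_function == "very_poor":
        sys -= 20.0
        hr += 10.0
        spo2 -= 2.0
    if p.chronic_lung_disease:
        spo2 -= 4.0
    if p.nyha == "III":
        hr += 5.0
    elif p.nyha == "IV":
        hr += 10.0
        spo2 -= 2.0
    if p.recent_mi:
        sys -= 5.0
    if p.pulmonary_hypertension == "moderate":
        spo2 -= 1.0
    elif p.pulmonary_hypertension == "severe":
        spo2 -= 3.0

    # seeded respiratory / vasomotor waves; pure function of (seed, t)
    phase = (record.seed % 997) / 997.0 * 2.0 * math.pi
    sys += 3.0 * math.sin(2.0 * math.pi * 0.25 * t + phase)
    dia += 2.0 * math.sin(2.0 * math.pi * 0.25 * t + phase + 0.7)
    hr += 2.0 * math.sin(2.0 * math.pi * 0.1 * t + phase)

    return Vitals(
        heart_rate=float(np.clip(hr, 30.0, 220.0)),
        systolic_mmhg=float(np.clip(sys, 40.0, 260.0)),
        diastolic_mmhg=float(np.clip(dia, 20.0, 160.0)),
        spo2=float(np.clip(spo2, 50.0, 100.0)),
    )
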