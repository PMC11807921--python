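"""Anatomical parameter registry: implemented ranges, units, dependency
structure and dynamically limited effective ranges.

The registry encodes, per feature, the implemented morphing range (the span
the mesh's PVA groups realise), the literature range it was derived from
(documentation only), the list of features whose values tighten it, and the
PVA groups it drives.  Constraint rules are declarative linear bound
functions — ``lo' = max(lo, c + sum a_f * ctx_f)`` and symmetrically for
the upper bound — chosen so that every implemented range remains attainable
somewhere in the admissible anatomy space.  The registry round-trips
through a YAML config so procedure-specific ranges can replace the
defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from .errors import CycleError, EmptyRangeError, RangeError
from .features import FeatureName

__all__ = [
    "AnatomicalParameter",
    "ConstraintRule",
    "ParameterRegistry",
    "Violation",
    "default_registry",
    "dependency_order",
    "effective_range",
    "validate_patient",
]


class DegenerateRangeWarning(UserWarning):
    """Constraint rules collapsed a range to a single feasible point."""


@dataclass(frozen=True)
class AnatomicalParameter:
    """One registry row: unit, ranges, dependencies and PVA mapping."""

    feature: FeatureName
    unit: str                                  # "mm", "percent" or "fraction"
    implemented_range: Tuple[float, float]
    literature_range: Optional[Tuple[float, float]] = None
    depends_on: Tuple[FeatureName, ...] = ()
    pva_groups: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.implemented_range
        if not lo < hi:
            raise RangeError(
                f"{self.feature.value}: implemented range [{lo}, {hi}] "
                "must satisfy lo < hi"
            )
        if self.unit == "mm" and lo <= 0:
            raise RangeError(
                f"{self.feature.value}: lengths must be positive (lo={lo})"
            )


@dataclass(frozen=True)
class ConstraintRule:
    """Linear bound function tightening a target feature's range.

    ``lo_const``/``lo_coeffs`` define a lower bound
    ``max(lo, lo_const + sum coeff * context_value)``; the ``hi_*`` pair
    defines the analogous upper bound.  Either side may be absent.
    """

    name: str
    target: FeatureName
    context: Tuple[FeatureName, ...]
    lo_const: Optional[float] = None
    lo_coeffs: Mapping[FeatureName, float] = field(default_factory=dict)
    hi_const: Optional[float] = None
    hi_coeffs: Mapping[FeatureName, float] = field(default_factory=dict)

    def bounds(
        self, ctx: Mapping[FeatureName, float]
    ) -> Tuple[Optional[float], Optional[float]]:
        lo = hi = None
        if self.lo_const is not None:
            lo = self.lo_const + sum(
                a * ctx[f] for f, a in self.lo_coeffs.items()
            )
        if self.hi_const is not None:
            hi = self.hi_const + sum(
                a * ctx[f] for f, a in self.hi_coeffs.items()
            )
        return lo, hi


@dataclass
class Violation:
    """One failed range check from :func:`validate_patient`."""

    feature: FeatureName
    value: float
    effective_range: Tuple[float, float]
    rules: Tuple[str, ...]

    def __str__(self) -> str:
        lo, hi = self.effective_range
        why = ", ".join(self.rules) if self.rules else "implemented_range"
        return (
            f"{self.feature.value}={self.value:g} outside effective range "
            f"[{lo:g}, {hi:g}] (violated: {why})"
        )


class ParameterRegistry:
    """Ordered collection of parameters plus their constraint rules."""

    def __init__(
        self,
        parameters: Sequence[AnatomicalParameter],
        rules: Sequence[ConstraintRule] = (),
    ):
        self._params: Dict[FeatureName, AnatomicalParameter] = {}
        for p in parameters:
            if p.feature in self._params:
                raise ValueError(f"duplicate parameter {p.feature.value}")
            self._params[p.feature] = p
        self.rules: List[ConstraintRule] = list(rules)
        for r in self.rules:
            for f in (r.target, *r.context):
                if f not in self._params:
                    raise ValueError(
                        f"rule {r.name!r} references unknown feature {f.value}"
                    )
        self.dependency_order()  # raises CycleError early on a bad graph

    def __getitem__(self, feature: FeatureName) -> AnatomicalParameter:
        return self._params[FeatureName(feature)]

    def __iter__(self):
        return iter(self._params.values())

    def __contains__(self, feature) -> bool:
        return FeatureName(feature) in self._params

    @property
    def features(self) -> Tuple[FeatureName, ...]:
        return tuple(self._params)

    # -- ordering -----------------------------------------------------------
    def dependency_order(self) -> List[FeatureName]:
        """Stable topological order of the declared dependency graph.

        Independent parameters come first, in registration order; every
        parameter appears after everything it depends on.
        """
        indeg = {f: 0 for f in self._params}
        children: Dict[FeatureName, List[FeatureName]] = {f: [] for f in self._params}
        for p in self._params.values():
            for dep in p.depends_on:
                children[dep].append(p.feature)
                indeg[p.feature] += 1
        order: List[FeatureName] = []
        ready = [f for f in self._params if indeg[f] == 0]
        while ready:
            f = ready.pop(0)
            order.append(f)
            newly = []
            for child in children[f]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    newly.append(child)
            # keep registration order among newly ready nodes
            ready = [
                g for g in self._params
                if g in set(ready) | set(newly)
            ]
        if len(order) < len(self._params):
            cyclic = [f for f in self._params if f not in set(order)]
            raise CycleError([f.value for f in cyclic])
        return order

    # -- effective ranges ---------------------------------------------------
    def rules_for(self, feature: FeatureName) -> List[ConstraintRule]:
        feature = FeatureName(feature)
        return [r for r in self.rules if r.target == feature]

    def effective_range(
        self,
        feature: FeatureName,
        context: Mapping[FeatureName, float],
        strict: bool = False,
    ) -> Tuple[float, float]:
        """Implemented range tightened by every applicable constraint rule.

        The result is always a subset of the implemented range and never
        empty: an infeasible combination collapses, with a warning, to the
        nearest feasible point (or raises :class:`EmptyRangeError` when
        ``strict``).
        """
        feature = FeatureName(feature)
        ctx = {FeatureName(k): float(v) for k, v in context.items()}
        param = self[feature]
        missing = [f.value for f in param.depends_on if f not in ctx]
        if missing:
            raise RangeError(
                f"effective_range({feature.value}): missing context "
                "feature(s): " + ", ".join(missing)
            )
        lo, hi = param.implemented_range
        new_lo, new_hi = lo, hi
        for rule in self.rules_for(feature):
            if any(f not in ctx for f in rule.context):
                # a rule only fires once its whole context is known; this
                # lets independent features be queried with partial context
                continue
            r_lo, r_hi = rule.bounds(ctx)
            if r_lo is not None:
                new_lo = max(new_lo, r_lo)
            if r_hi is not None:
                new_hi = min(new_hi, r_hi)
        new_lo = max(new_lo, lo)
        new_hi = min(new_hi, hi)
        if new_lo > new_hi:
            if strict:
                raise EmptyRangeError(
                    f"{feature.value}: constraints leave no admissible "
                    f"interval (lo={new_lo:g} > hi={new_hi:g})"
                )
            point = min(max((new_lo + new_hi) / 2.0, lo), hi)
            warnings.warn(
                f"{feature.value}: constraints infeasible; collapsing to "
                f"degenerate point {point:g}",
                DegenerateRangeWarning,
                stacklevel=2,
            )
            return (point, point)
        return (new_lo, new_hi)

    # -- validation ---------------------------------------------------------
    def validate(
        self, values: Mapping[FeatureName, float], atol: float = 1e-9
    ) -> List[Violation]:
        """Check every value against its effective range, in dependency
        order.  Returns violations as data (empty list == valid)."""
        vals = {FeatureName(k): float(v) for k, v in values.items()}
        missing = [f.value for f in self._params if f not in vals]
        if missing:
            raise RangeError("missing feature value(s): " + ", ".join(missing))
        violations: List[Violation] = []
        for feature in self.dependency_order():
            with warnings.catch_warnings():
                # a collapsed range is reported through the violation list,
                # not as a warning
                warnings.simplefilter("ignore", DegenerateRangeWarning)
                lo, hi = self.effective_range(feature, vals)
            v = vals[feature]
            if lo - atol <= v <= hi + atol:
                continue
            fired = []
            impl_lo, impl_hi = self[feature].implemented_range
            if not (impl_lo - atol <= v <= impl_hi + atol):
                fired.append("implemented_range")
            for rule in self.rules_for(feature):
                r_lo, r_hi = rule.bounds(vals)
                if (r_lo is not None and v < r_lo - atol) or (
                    r_hi is not None and v > r_hi + atol
                ):
                    fired.append(rule.name)
            violations.append(
                Violation(feature, v, (lo, hi), tuple(fired))
            )
        return violations

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path) -> None:
        data = {
            "parameters": [
                {
                    "feature": p.feature.value,
                    "unit": p.unit,
                    "implemented_range": list(p.implemented_range),
                    "literature_range": (
                        list(p.literature_range) if p.literature_range else None
                    ),
                    "depends_on": [f.value for f in p.depends_on],
                    "pva_groups": list(p.pva_groups),
                }
                for p in self._params.values()
            ],
            "rules": [
                {
                    "name": r.name,
                    "target": r.target.value,
                    "context": [f.value for f in r.context],
                    "lo_const": r.lo_const,
                    "lo_coeffs": {f.value: a for f, a in r.lo_coeffs.items()},
                    "hi_const": r.hi_const,
                    "hi_coeffs": {f.value: a for f, a in r.hi_coeffs.items()},
                }
                for r in self.rules
            ],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ParameterRegistry":
        data = yaml.safe_load(Path(path).read_text())
        params = [
            AnatomicalParameter(
                feature=FeatureName.parse(d["feature"]),
                unit=d["unit"],
                implemented_range=tuple(d["implemented_range"]),
                literature_range=(
                    tuple(d["literature_range"])
                    if d.get("literature_range")
                    else None
                ),
                depends_on=tuple(
                    FeatureName.parse(f) for f in d.get("depends_on", [])
                ),
                pva_groups=tuple(d.get("pva_groups", [])),
            )
            for d in data["parameters"]
        ]
        rules = [
            ConstraintRule(
                name=d["name"],
                target=FeatureName.parse(d["target"]),
                context=tuple(FeatureName.parse(f) for f in d["context"]),
                lo_const=d.get("lo_const"),
                lo_coeffs={
                    FeatureName.parse(f): a
                    for f, a in (d.get("lo_coeffs") or {}).items()
                },
                hi_const=d.get("hi_const"),
                hi_coeffs={
                    FeatureName.parse(f): a
                    for f, a in (d.get("hi_coeffs") or {}).items()
                },
            )
            for d in data.get("rules", [])
        ]
        return cls(params, rules)


# ---------------------------------------------------------------------------
# module-level convenience wrappers over the default registry
# ---------------------------------------------------------------------------


def dependency_order(registry: ParameterRegistry) -> List[FeatureName]:
    return registry.dependency_order()


def effective_range(
    feature: FeatureName,
    context: Mapping[FeatureName, float],
    registry: Optional[ParameterRegistry] = None,
    strict: bool = False,
) -> Tuple[float, float]:
    reg = registry if registry is not None else default_registry()
    return reg.effective_range(feature, context, strict=strict)


def validate_patient(
    values: Mapping[FeatureName, float],
    registry: Optional[ParameterRegistry] = None,
) -> List[Violation]:
    reg = registry if registry is not None else default_registry()
    return reg.validate(values)


# ---------------------------------------------------------------------------
# the default registry
# ---------------------------------------------------------------------------

F = FeatureName

_DEFAULT_CACHE: Optional[ParameterRegistry] = None


def default_registry() -> ParameterRegistry:
    """Registry with the default implemented ranges and constraint rules.

    The leaflet effective-height default range is 7.5-12.2 mm, bracketing
    the published mean of 8.5 +/- 1.4 mm; the LCA-distance default
    (0.1-5.9 mm) is deliberately conservative and sits below published
    ostium-height measurements.  Both are plain registry entries and can
    be replaced through the YAML config.
    """
    global _DEFAULT_CACHE
    if _DEFAULT_CACHE is not None:
        return _DEFAULT_CACHE

    leaf_groups = (
        "leaflet_opening_left",
        "leaflet_opening_non",
        "leaflet_opening_right",
    )
    params = [
        AnatomicalParameter(
            F.AORTA_DIAMETER, "mm", (18.0, 32.0), (20.0, 37.0),
            depends_on=(), pva_groups=("aorta_diameter",),
        ),
        AnatomicalParameter(
            F.ST_HEIGHT, "mm", (17.3, 23.3), (17.0, 23.6),
            depends_on=(), pva_groups=("st_height",),
        ),
        AnatomicalParameter(
            F.VALVE_DIAMETER, "mm", (18.1, 28.2), (17.7, 29.3),
            depends_on=(), pva_groups=("valve_diameter",),
        ),
        AnatomicalParameter(
            F.LEAFLET_CALCIFICATION_LEFT, "fraction", (0.0, 1.0),
            depends_on=(), pva_groups=(),
        ),
        AnatomicalParameter(
            F.LEAFLET_CALCIFICATION_RIGHT, "fraction", (0.0, 1.0),
            depends_on=(), pva_groups=(),
        ),
        AnatomicalParameter(
            F.LEAFLET_CALCIFICATION_NON, "fraction", (0.0, 1.0),
            depends_on=(), pva_groups=(),
        ),
        AnatomicalParameter(
            F.RCA_DISTANCE, "mm", (7.7, 16.7), (13.9, 20.5),
            depends_on=(F.ST_HEIGHT, F.VALVE_DIAMETER),
            pva_groups=("rca_distance", "rca_up", "rca_down",
                        "rca_left", "rca_right"),
        ),
        AnatomicalParameter(
            F.LCA_DISTANCE, "mm", (0.1, 5.9), (11.5, 17.3),
            depends_on=(F.ST_HEIGHT, F.VALVE_DIAMETER),
            pva_groups=("lca_distance", "lca_up", "lca_down",
                        "lca_left", "lca_right"),
        ),
        AnatomicalParameter(
            F.LEAFLET_EFFECTIVE_HEIGHT_LEFT, "mm", (7.5, 12.2), (4.8, 14.0),
            depends_on=(F.VALVE_DIAMETER,),
            pva_groups=("leaflet_effective_height_left",),
        ),
        AnatomicalParameter(
            F.LEAFLET_EFFECTIVE_HEIGHT_RIGHT, "mm", (7.5, 12.2), (4.8, 14.0),
            depends_on=(F.VALVE_DIAMETER,),
            pva_groups=("leaflet_effective_height_right",),
        ),
        AnatomicalParameter(
            F.LEAFLET_EFFECTIVE_HEIGHT_NON, "mm", (7.5, 12.2), (4.8, 14.0),
            depends_on=(F.VALVE_DIAMETER,),
            pva_groups=("leaflet_effective_height_non",),
        ),
        AnatomicalParameter(
            F.VA_HEIGHT, "mm", (7.6, 18.9), None,
            depends_on=(
                F.VALVE_DIAMETER,
                F.LEAFLET_EFFECTIVE_HEIGHT_LEFT,
                F.LEAFLET_EFFECTIVE_HEIGHT_RIGHT,
                F.LEAFLET_EFFECTIVE_HEIGHT_NON,
            ),
            pva_groups=("va_height",),
        ),
        AnatomicalParameter(
            F.BASAL_RING_DIAMETER, "mm", (6.8, 24.4), None,
            depends_on=(
                F.VALVE_DIAMETER,
                F.LEAFLET_EFFECTIVE_HEIGHT_LEFT,
                F.LEAFLET_EFFECTIVE_HEIGHT_RIGHT,
                F.LEAFLET_EFFECTIVE_HEIGHT_NON,
                F.VA_HEIGHT,
            ),
            pva_groups=("basal_ring_diameter",),
        ),
        AnatomicalParameter(
            F.LEAFLET_OPENING_LEFT, "percent", (0.0, 100.0),
            depends_on=(F.LEAFLET_CALCIFICATION_LEFT,),
            pva_groups=("leaflet_opening_left",),
        ),
        AnatomicalParameter(
            F.LEAFLET_OPENING_RIGHT, "percent", (0.0, 100.0),
            depends_on=(F.LEAFLET_CALCIFICATION_RIGHT,),
            pva_groups=("leaflet_opening_right",),
        ),
        AnatomicalParameter(
            F.LEAFLET_OPENING_NON, "percent", (0.0, 100.0),
            depends_on=(F.LEAFLET_CALCIFICATION_NON,),
            pva_groups=("leaflet_opening_non",),
        ),
    ]

    rules = [
        # the ST junction is continuous with the aortic base, so a valve
        # wider than the aorta would mean an ST junction narrower than the
        # valve — forbidden
        ConstraintRule(
            name="st_junction_wider_than_valve",
            target=F.VALVE_DIAMETER,
            context=(F.AORTA_DIAMETER,),
            hi_const=0.0,
            hi_coeffs={F.AORTA_DIAMETER: 1.0},
        ),
        # leaflet span scales with the annulus: effective height capped by
        # valve diameter
        *[
            ConstraintRule(
                name=f"effective_height_vs_valve_{leaf}",
                target=eff,
                context=(F.VALVE_DIAMETER,),
                hi_const=0.0,
                hi_coeffs={F.VALVE_DIAMETER: 0.45},
            )
            for leaf, eff in (
                ("left", F.LEAFLET_EFFECTIVE_HEIGHT_LEFT),
                ("right", F.LEAFLET_EFFECTIVE_HEIGHT_RIGHT),
                ("non", F.LEAFLET_EFFECTIVE_HEIGHT_NON),
            )
        ],
        # the commissures must sit at or above the tallest leaflet
        *[
            ConstraintRule(
                name=f"va_height_ge_effective_height_{leaf}",
                target=F.VA_HEIGHT,
                context=(eff,),
                lo_const=0.0,
                lo_coeffs={eff: 1.0},
            )
            for leaf, eff in (
                ("left", F.LEAFLET_EFFECTIVE_HEIGHT_LEFT),
                ("right", F.LEAFLET_EFFECTIVE_HEIGHT_RIGHT),
                ("non", F.LEAFLET_EFFECTIVE_HEIGHT_NON),
            )
        ],
        ConstraintRule(
            name="va_height_vs_valve",
            target=F.VA_HEIGHT,
            context=(F.VALVE_DIAMETER,),
            hi_const=0.0,
            hi_coeffs={F.VALVE_DIAMETER: 0.75},
        ),
        ConstraintRule(
            name="basal_ring_vs_root",
            target=F.BASAL_RING_DIAMETER,
            context=(
                F.VALVE_DIAMETER,
                F.LEAFLET_EFFECTIVE_HEIGHT_LEFT,
                F.LEAFLET_EFFECTIVE_HEIGHT_RIGHT,
                F.LEAFLET_EFFECTIVE_HEIGHT_NON,
                F.VA_HEIGHT,
            ),
            hi_const=0.0,
            hi_coeffs={
                F.VALVE_DIAMETER: 0.55,
                F.LEAFLET_EFFECTIVE_HEIGHT_LEFT: 1.0 / 12.0,
                F.LEAFLET_EFFECTIVE_HEIGHT_RIGHT: 1.0 / 12.0,
                F.LEAFLET_EFFECTIVE_HEIGHT_NON: 1.0 / 12.0,
                F.VA_HEIGHT: 0.35,
            },
        ),
        # coronary ostia ride up with a taller root and larger annulus, and
        # must stay below the ST ridge
        ConstraintRule(
            name="rca_distance_shift",
            target=F.RCA_DISTANCE,
            context=(F.ST_HEIGHT, F.VALVE_DIAMETER),
            lo_const=7.7 - 0.3 * 17.3 - 0.2 * 18.1,
            lo_coeffs={F.ST_HEIGHT: 0.3, F.VALVE_DIAMETER: 0.2},
            hi_const=-1.0,
            hi_coeffs={F.ST_HEIGHT: 1.0},
        ),
        ConstraintRule(
            name="lca_distance_shift",
            target=F.LCA_DISTANCE,
            context=(F.ST_HEIGHT, F.VALVE_DIAMETER),
            lo_const=0.1 - 0.15 * 17.3 - 0.1 * 18.1,
            lo_coeffs={F.ST_HEIGHT: 0.15, F.VALVE_DIAMETER: 0.1},
        ),
        # calcified leaflets cannot open fully
        *[
            ConstraintRule(
                name=f"opening_vs_calcification_{leaf}",
                target=opening,
                context=(calc,),
                hi_const=100.0,
                hi_coeffs={calc: -80.0},
            )
            for leaf, opening, calc in (
                ("left", F.LEAFLET_OPENING_LEFT, F.LEAFLET_CALCIFICATION_LEFT),
                ("right", F.LEAFLET_OPENING_RIGHT, F.LEAFLET_CALCIFICATION_RIGHT),
                ("non", F.LEAFLET_OPENING_NON, F.LEAFLET_CALCIFICATION_NON),
            )
        ],
    ]

    _DEFAULT_CACHE = ParameterRegistry(params, rules)
    return _DEFAULT_CACHE
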