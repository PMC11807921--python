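"""Per-vertex-animation (PVA) morphing.

Each anatomical feature is realised as a named vertex group carrying a
per-vertex displacement field that spans the feature's implemented range:
weight 0 places the group at the lower range endpoint, weight 1 at the
upper endpoint, and intermediate weights interpolate linearly.  A mesh can
be built at any neutral configuration; its groups then record the neutral
weight so that an absent weight leaves the mesh untouched.

Weights outside [0, 1] are applied (the model deliberately allows morphs
beyond the implemented ranges) but emit a ``MorphRangeWarning`` so callers
can surface the risk of unrealistic anatomy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, Iterable, List, Mapping, Tuple

import numpy as np

from .errors import RangeError, UnknownGroupError
from .features import FeatureName

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .anatomy_mesh import LabeledMesh


class MorphRangeWarning(UserWarning):
    """A PVA weight lies outside the nominal [0, 1] interval."""


#: millimetres of ostium shift realised by a directional group at weight 1
OSTIUM_STEP_MM = 2.0


@dataclass
class PVAGroup:
    """A named vertex set with a displacement field and a weight.

    ``displacements`` holds, for each vertex in ``vertex_indices``, the full
    offset between the feature's lower and upper range endpoint positions.
    ``neutral_weight`` is the weight at which the mesh's stored vertices sit
    (0 for meshes built at the default, lower-endpoint configuration).
    """

    name: str
    vertex_indices: np.ndarray
    displacements: np.ndarray
    neutral_weight: float = 0.0

    def __post_init__(self) -> None:
        self.vertex_indices = np.asarray(self.vertex_indices, dtype=np.intp)
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.shape != (self.vertex_indices.size, 3):
            raise ValueError(
                f"PVA group {self.name!r}: displacements shape "
                f"{self.displacements.shape} does not match "
                f"{self.vertex_indices.size} vertex indices"
            )


@dataclass
class MorphState:
    """Mapping of PVA group name to interpolation weight.

    Missing groups default to their neutral weight (no displacement).
    """

    weights: Dict[str, float] = field(default_factory=dict)

    def merged(self, other: "MorphState") -> "MorphState":
        w = dict(self.weights)
        w.update(other.weights)
        return MorphState(w)

    def __iter__(self):
        return iter(self.weights.items())


def apply_morphs(mesh: "LabeledMesh", state: MorphState) -> "LabeledMesh":
    """Displace mesh vertices according to the PVA weights in ``state``.

    Returns a new mesh with ``vertices = base + sum_g (w_g - n_g) * d_g``
    where ``n_g`` is the group's neutral weight.  Topology, labels and
    ``base_vertices`` are unchanged.
    """
    unknown = [g for g in state.weights if g not in mesh.pva_groups]
    if unknown:
        raise UnknownGroupError(
            "unknown PVA group(s): " + ", ".join(sorted(unknown))
        )
    out_of_range = {
        g: w for g, w in state.weights.items() if not (0.0 <= w <= 1.0)
    }
    if out_of_range:
        warnings.warn(
            "PVA weight(s) outside [0, 1]: "
            + ", ".join(f"{g}={w:.3g}" for g, w in sorted(out_of_range.items())),
            MorphRangeWarning,
            stacklevel=2,
        )
    verts = mesh.base_vertices.copy()
    for name, w in state.weights.items():
        grp = mesh.pva_groups[name]
        scale = w - grp.neutral_weight
        if scale != 0.0:
            verts[grp.vertex_indices] += scale * grp.displacements
    return mesh.with_vertices(verts)


def param_to_weight(
    feature: FeatureName, value: float, registry=None
) -> Dict[str, float]:
    """Map a feature value to the weight(s) of its associated PVA group(s).

    ``w = (value - lo) / (hi - lo)`` over the feature's implemented range.
    Calcification features drive material density rather than geometry and
    map to no PVA group (empty dict).
    """
    feature = FeatureName(feature)
    lo, hi = _implemented_range(feature, registry)
    if hi == lo:
        raise RangeError(f"{feature.value}: degenerate range [{lo}, {hi}]")
    w = (value - lo) / (hi - lo)
    groups = _feature_groups(feature, registry)
    return {g: w for g in groups}


def weight_to_param(feature: FeatureName, weight: float, registry=None) -> float:
    """Exact inverse of :func:`param_to_weight`."""
    feature = FeatureName(feature)
    lo, hi = _implemented_range(feature, registry)
    if hi == lo:
        raise RangeError(f"{feature.value}: degenerate range [{lo}, {hi}]")
    return lo + weight * (hi - lo)


def ostium_shift_to_weights(
    artery: str, axial_mm: float = 0.0, lateral_mm: float = 0.0
) -> Dict[str, float]:
    """Map a signed ostium shift (mm) to directional (direction, magnitude)
    group weight pairs.

    Positive ``axial_mm`` shifts the ostium superiorly ("up"), positive
    ``lateral_mm`` circumferentially ("left" as seen from outside the root).
    """
    if artery not in ("rca", "lca"):
        raise ValueError(f"artery must be 'rca' or 'lca', got {artery!r}")
    weights: Dict[str, float] = {}
    if axial_mm:
        direction = "up" if axial_mm > 0 else "down"
        weights[f"{artery}_{direction}"] = abs(axial_mm) / OSTIUM_STEP_MM
    if lateral_mm:
        direction = "left" if lateral_mm > 0 else "right"
        weights[f"{artery}_{direction}"] = abs(lateral_mm) / OSTIUM_STEP_MM
    return weights


def _implemented_range(feature: FeatureName, registry=None) -> Tuple[float, float]:
    if registry is None:
        from .parameter_space import default_registry

        registry = default_registry()
    return registry[feature].implemented_range


def _feature_groups(feature: FeatureName, registry=None) -> List[str]:
    # geometry groups are named after the feature itself; calcification
    # features have no geometric group
    if feature.value.startswith("leaflet_calcification"):
        return []
    return [feature.value]


# ---------------------------------------------------------------------------
# heartbeat timeline
# ---------------------------------------------------------------------------


@dataclass
class HeartbeatTimeline:
    """Per-structure keyframe tracks driving the beating-heart PVA groups.

    ``tracks`` maps a track name (myocardium, left_ventricle, aorta,
    coronaries) to an ordered list of ``(phase, MorphState)`` keyframes with
    phases in [0, 1).  Tracks are independently addressable and interpolated
    separately, then merged.
    """

    tracks: Dict[str, List[Tuple[float, MorphState]]]
    heart_rate: float = 70.0

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        for name, keys in self.tracks.items():
            if not keys:
                raise ValueError(f"track {name!r} has an empty keyframe list")
            phases = [p for p, _ in keys]
            if any(not (0.0 <= p < 1.0) for p in phases):
                raise ValueError(f"track {name!r}: phases must lie in [0, 1)")
            if any(b <= a for a, b in zip(phases, phases[1:])):
                raise ValueError(
                    f"track {name!r}: phases must be strictly increasing"
                )

    @property
    def period(self) -> float:
        """Beat period in seconds."""
        return 60.0 / self.heart_rate


def sample_heartbeat(timeline: HeartbeatTimeline, t: float) -> MorphState:
    """Evaluate the heartbeat timeline at time ``t`` (seconds).

    The cardiac phase is ``(t * heart_rate / 60) mod 1``; within each track
    the group weights are linearly interpolated between the bracketing
    keyframes, wrapping around the cycle.
    """
    phase = math.fmod(t * timeline.heart_rate / 60.0, 1.0)
    if phase < 0:
        phase += 1.0
    merged: Dict[str, float] = {}
    for keys in timeline.tracks.values():
        merged.update(_interp_track(keys, phase).weights)
    return MorphState(merged)


def _interp_track(
    keys: List[Tuple[float, MorphState]], phase: float
) -> MorphState:
    phases = [p for p, _ in keys]
    states = [s for _, s in keys]
    n = len(keys)
    if n == 1:
        return MorphState(dict(states[0].weights))
    # locate bracketing keyframes (cyclic)
    for i in range(n):
        if abs(phases[i] - phase) < 1e-12:
            return MorphState(dict(states[i].weights))
    idx = 0
    while idx < n and phases[idx] < phase:
        idx += 1
    i0 = (idx - 1) % n
    i1 = idx % n
    p0, p1 = phases[i0], phases[i1]
    span = (p1 - p0) % 1.0
    if span == 0.0:
        frac = 0.0
    else:
        frac = ((phase - p0) % 1.0) / span
    names: Iterable[str] = set(states[i0].weights) | set(states[i1].weights)
    return MorphState(
        {
            g: (1 - frac) * states[i0].weights.get(g, 0.0)
            + frac * states[i1].weights.get(g, 0.0)
            for g in names
        }
    )


def default_heartbeat_timeline(heart_rate: float = 70.0) -> HeartbeatTimeline:
    """Four-keyframe beating cycle (end-diastole, peak systole, end-systole,
    diastasis) per animated structure."""

    def track(group: str, peak: float) -> List[Tuple[float, MorphState]]:
        return [
            (0.00, MorphState({group: 0.0})),
            (0.30, MorphState({group: peak})),
            (0.50, MorphState({group: 0.7 * peak})),
            (0.75, MorphState({group: 0.1 * peak})),
        ]

    return HeartbeatTimeline(
        tracks={
            "myocardium": track("heartbeat_myocardium", 1.0),
            "left_ventricle": track("heartbeat_left_ventricle", 1.0),
            "aorta": track("heartbeat_aorta", 1.0),
            "coronaries": track("heartbeat_coronaries", 1.0),
        },
        heart_rate=heart_rate,
    )
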