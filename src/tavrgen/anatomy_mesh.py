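"""Procedural labelled heart model and feature measurement.

The model is a compact, watertight stand-in for a segmented cardiac mesh:
an aortic root built as a surface of revolution with three sinus bulges,
three valve leaflets attached along crown-shaped hinge curves, coronary
stubs on the right and left sinus walls, a left ventricle and a myocardial
shell.  Coordinates are millimetres in a right-handed patient system with
the origin at the centre of the virtual basal ring (the plane through the
three lowest leaflet-hinge points), +z superior toward the aortic arch and
+x toward patient left.

Every measurable feature has an exactly affine geometric realisation: each
landmark coordinate is a linear function of its own feature value and is
independent of all others, so per-vertex-animation morphs (which are linear
by construction) recover the printed range endpoints exactly and combined
morphs never couple measurements.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import trimesh
import yaml

from .errors import MeasurementError, MeshError, RangeError
from .features import (
    CALCIFICATION_FEATURES,
    GEOMETRIC_FEATURES,
    LEAFLETS,
    FeatureName,
    StructureLabel,
)
from .morph_engine import OSTIUM_STEP_MM, PVAGroup

# ---------------------------------------------------------------------------
# geometric constants (mm unless noted)
# ---------------------------------------------------------------------------

SINUS_FLAT_FRAC = 0.08      # flat (cylindrical) margin of the sinus profile
BULGE_BASE = 0.10           # rotationally symmetric sinus bulge fraction
BULGE_LOBE = 0.10           # additional three-lobed bulge fraction
TRANS_LEN = 8.0             # ST junction -> tubular aorta transition length
TUBE_LEN = 32.0             # tubular ascending-aorta segment length
AORTA_PLANE_OFFSET = 25.0   # aorta measurement plane above the ST ridge
VALVE_PLANE_OFFSET = 0.6    # valve measurement plane above the basal ring

LEAFLET_HALF_THICKNESS = 0.3
R_CLOSED = 1.5              # coaptation-point radius of a shut leaflet
R_OPEN_REF = 6.8            # free-edge radius of a fully open leaflet

LV_DEPTH = 55.0
LV_NECK_FRAC = 0.1          # cylindrical LVOT neck fraction of LV depth
LV_BELLY_RADIUS = 24.0
LV_MEASURE_Z = -2.75        # basal-ring measurement plane (inside the neck)

MYO_TOP_Z = 6.0
MYO_DEPTH = 74.0
MYO_RADIUS = 34.0

COR_RADIUS = 1.5
COR_LEN = 14.0
COR_IN_FRAC = 0.75          # inner tube end as a fraction of valve radius

#: angular centre of each sinus / leaflet (radians); the coronary ostia sit
#: at the centres of the right and left sinuses
THETA_CENTER = {"right": 0.0, "left": 2.0 * math.pi / 3.0, "non": 4.0 * math.pi / 3.0}

LEAFLET_LABEL = {
    "left": StructureLabel.LEAFLET_LEFT,
    "right": StructureLabel.LEAFLET_RIGHT,
    "non": StructureLabel.LEAFLET_NON,
}

_EFF_FEATURE = {
    "left": FeatureName.LEAFLET_EFFECTIVE_HEIGHT_LEFT,
    "right": FeatureName.LEAFLET_EFFECTIVE_HEIGHT_RIGHT,
    "non": FeatureName.LEAFLET_EFFECTIVE_HEIGHT_NON,
}
_OPEN_FEATURE = {
    "left": FeatureName.LEAFLET_OPENING_LEFT,
    "right": FeatureName.LEAFLET_OPENING_RIGHT,
    "non": FeatureName.LEAFLET_OPENING_NON,
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def default_neutral() -> Dict[FeatureName, float]:
    """Reference pose: every feature at the lower end of its implemented
    range (so absolute morph weights coincide with range-normalised values)."""
    from .parameter_space import default_registry

    reg = default_registry()
    return {f: reg[f].implemented_range[0] for f in FeatureName}


@dataclass
class MeshConfig:
    """Mesh resolution and neutral feature values.

    ``circumferential`` x ``axial`` control the revolution grids; the other
    structure resolutions are derived from them.
    """

    circumferential: int = 64
    axial: int = 96
    neutral: Dict[FeatureName, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.circumferential < 12 or self.axial < 24:
            raise ValueError("resolution too low: need >=12 x >=24 segments")
        full = default_neutral()
        full.update({FeatureName(k): float(v) for k, v in self.neutral.items()})
        self.neutral = full

    # derived grid sizes ----------------------------------------------------
    @property
    def n_sinus(self) -> int:
        return max(8, round(self.axial / 4))

    @property
    def n_trans(self) -> int:
        return max(3, round(self.axial / 12))

    @property
    def n_tube(self) -> int:
        return max(4, round(self.axial / 8))

    @property
    def n_lv(self) -> int:
        return max(10, round(self.axial * 7 / 24))

    @property
    def n_myo(self) -> int:
        return max(8, round(self.axial / 4))

    @property
    def leaflet_ns(self) -> int:
        return max(8, 2 * round(self.circumferential * 3 / 16))

    @property
    def leaflet_nv(self) -> int:
        return max(5, round(self.axial / 10))

    @property
    def cor_circ(self) -> int:
        return max(8, self.circumferential // 4)

    @property
    def cor_ax(self) -> int:
        return 6


def save_mesh_config(cfg: MeshConfig, path) -> None:
    data = {
        "circumferential": cfg.circumferential,
        "axial": cfg.axial,
        "neutral": {f.value: float(v) for f, v in cfg.neutral.items()},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_mesh_config(path) -> MeshConfig:
    data = yaml.safe_load(Path(path).read_text())
    neutral = {
        FeatureName.parse(k): float(v)
        for k, v in (data.get("neutral") or {}).items()
    }
    return MeshConfig(
        circumferential=int(data.get("circumferential", 64)),
        axial=int(data.get("axial", 96)),
        neutral=neutral,
    )


# ---------------------------------------------------------------------------
# the labelled mesh container
# ---------------------------------------------------------------------------


@dataclass
class LabeledMesh:
    """Watertight triangle submeshes with structure labels.

    ``submeshes`` maps each :class:`StructureLabel` to the face indices of
    that structure; ``landmarks`` maps landmark names to vertex indices
    (used by :func:`measure_feature`); ``pva_groups`` holds the morph
    displacement fields.
    """

    vertices: np.ndarray
    faces: np.ndarray
    submeshes: Dict[StructureLabel, np.ndarray]
    base_vertices: np.ndarray = None
    pva_groups: Dict[str, PVAGroup] = field(default_factory=dict)
    landmarks: Dict[str, np.ndarray] = field(default_factory=dict)
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.submeshes = {
            StructureLabel(k): np.asarray(v, dtype=np.int64)
            for k, v in self.submeshes.items()
        }
        if self.base_vertices is None:
            self.base_vertices = self.vertices.copy()
        else:
            self.base_vertices = np.asarray(self.base_vertices, dtype=np.float64)

    # -- basic helpers ------------------------------------------------------
    def with_vertices(self, vertices: np.ndarray) -> "LabeledMesh":
        """Same topology/labels/groups with replaced vertex positions."""
        return dataclasses.replace(self, vertices=np.asarray(vertices, float),
                                   base_vertices=self.base_vertices)

    def copy(self) -> "LabeledMesh":
        return dataclasses.replace(
            self, vertices=self.vertices.copy(),
            base_vertices=self.base_vertices.copy()
        )

    def submesh_trimesh(self, label: StructureLabel) -> trimesh.Trimesh:
        label = StructureLabel(label)
        if label not in self.submeshes:
            raise MeshError(f"mesh has no submesh {label.value!r}")
        return trimesh.Trimesh(
            vertices=self.vertices,
            faces=self.faces[self.submeshes[label]],
            process=False,
        )

    def is_watertight(self, label: StructureLabel) -> bool:
        return bool(self.submesh_trimesh(label).is_watertight)

    def validate(self, require_all_labels: bool = True) -> None:
        """Check the type invariants; raise :class:`MeshError` on failure."""
        if require_all_labels:
            missing = set(StructureLabel) - set(self.submeshes)
            if missing:
                raise MeshError(
                    "missing submeshes: "
                    + ", ".join(sorted(m.value for m in missing))
                )
        for label in self.submeshes:
            if not self.is_watertight(label):
                raise MeshError(f"submesh {label.value!r} is not watertight")
        tri = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        if (areas < 1e-10).any():
            raise MeshError(
                f"{int((areas < 1e-10).sum())} degenerate (zero-area) triangles"
            )

    def vertex_indices(self, label: StructureLabel) -> np.ndarray:
        rng = self.meta.get("vertex_ranges", {}).get(StructureLabel(label))
        if rng is not None:
            return np.arange(rng[0], rng[1])
        return np.unique(self.faces[self.submeshes[StructureLabel(label)]])


# ---------------------------------------------------------------------------
# low-level construction helpers
# ---------------------------------------------------------------------------


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _revolve(
    rings: np.ndarray,
    bottom: Optional[np.ndarray],
    top: Optional[np.ndarray],
) -> Tuple[np.ndarray, np.ndarray]:
    """Stitch a stack of rings (K, nc, 3) into a closed triangle surface.

    ``bottom``/``top`` are optional cap/apex points appended after the ring
    vertices; the first ring is treated as the "bottom" of the stack.
    """
    K, nc, _ = rings.shape
    verts = [rings.reshape(-1, 3)]
    faces: List[Tuple[int, int, int]] = []
    for k in range(K - 1):
        a0 = k * nc
        b0 = (k + 1) * nc
        for t in range(nc):
            t1 = (t + 1) % nc
            faces.append((a0 + t, a0 + t1, b0 + t1))
            faces.append((a0 + t, b0 + t1, b0 + t))
    nxt = K * nc
    if bottom is not None:
        verts.append(np.asarray(bottom, float)[None, :])
        b = nxt
        nxt += 1
        for t in range(nc):
            faces.append((b, (t + 1) % nc, t))
    if top is not None:
        verts.append(np.asarray(top, float)[None, :])
        tp = nxt
        base = (K - 1) * nc
        for t in range(nc):
            faces.append((tp, base + t, base + (t + 1) % nc))
    return np.vstack(verts), np.asarray(faces, dtype=np.int64)


def _aorta_part(cfg: MeshConfig, vals) -> Tuple[np.ndarray, np.ndarray, Dict]:
    nc = cfg.circumferential
    r_v = vals[FeatureName.VALVE_DIAMETER] / 2.0
    r_a = vals[FeatureName.AORTA_DIAMETER] / 2.0
    H = vals[FeatureName.ST_HEIGHT]
    theta = np.linspace(0.0, 2.0 * math.pi, nc, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    lobe = BULGE_BASE + BULGE_LOBE * 0.5 * (1.0 + np.cos(3.0 * theta))

    rings = []
    # sinus segment: flat near both the annulus and the ST ridge so the
    # measurement planes cut exactly cylindrical wall
    zeta = np.linspace(0.0, 1.0, cfg.n_sinus)
    for z_frac in zeta:
        s = np.clip(
            (z_frac - SINUS_FLAT_FRAC) / (1.0 - 2.0 * SINUS_FLAT_FRAC), 0.0, 1.0
        )
        bulge = math.sin(math.pi * s) ** 2
        r = r_v * (1.0 + bulge * lobe)
        rings.append(np.column_stack([r * cos_t, r * sin_t,
                                      np.full(nc, H * z_frac)]))
    # ST junction -> tubular aorta transition
    for t in np.linspace(0.0, 1.0, cfg.n_trans + 1)[1:]:
        r = r_v + float(_smoothstep(np.array(t))) * (r_a - r_v)
        z = H + TRANS_LEN * t
        rings.append(np.column_stack([r * cos_t, r * sin_t, np.full(nc, z)]))
    # tubular segment
    for u in np.linspace(0.0, 1.0, cfg.n_tube + 1)[1:]:
        z = H + TRANS_LEN + TUBE_LEN * u
        rings.append(np.column_stack([r_a * cos_t, r_a * sin_t, np.full(nc, z)]))

    rings = np.asarray(rings)
    verts, faces = _revolve(
        rings,
        bottom=np.array([0.0, 0.0, 0.0]),
        top=np.array([0.0, 0.0, H + TRANS_LEN + TUBE_LEN]),
    )
    landmarks = {
        "valve_ring": np.arange(nc),
        "st_ring": np.arange((cfg.n_sinus - 1) * nc, cfg.n_sinus * nc),
    }
    return verts, faces, landmarks


def _leaflet_part(cfg: MeshConfig, vals, leaf: str):
    ns, nv = cfg.leaflet_ns, cfg.leaflet_nv
    th_c = THETA_CENTER[leaf]
    r_v = vals[FeatureName.VALVE_DIAMETER] / 2.0
    va = vals[FeatureName.VA_HEIGHT]
    eff = vals[_EFF_FEATURE[leaf]]
    opening = vals[_OPEN_FEATURE[leaf]]
    r_c = R_CLOSED + opening / 100.0 * (R_OPEN_REF - R_CLOSED)

    s = np.linspace(0.0, 1.0, ns + 1)
    v = np.linspace(0.0, 1.0, nv + 1)
    theta = th_c - math.pi / 3.0 + 2.0 * math.pi / 3.0 * s
    crown = 0.5 * (1.0 + np.cos(2.0 * math.pi * s))          # 1 at ends, 0 mid
    hinge = np.column_stack([r_v * np.cos(theta), r_v * np.sin(theta), va * crown])
    # the free edge sweeps the same angular fan as the hinge, dipping from
    # the commissures (wall radius, height va) to the coaptation point
    # (radius r_c, height eff) at the sector centre; keeping every grid
    # column at its own angle makes the surface injective (no pinch whose
    # offset sheets could cross)
    q = 1.0 - np.abs(1.0 - 2.0 * s)
    rho = r_v + q * (r_c - r_v)
    ez = va + q * (eff - va)
    edge = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), ez])

    P = (1.0 - v)[None, :, None] * hinge[:, None, :] + v[None, :, None] * edge[:, None, :]

    # mid-surface normals by finite differences; collapsed commissure
    # columns get the mean normal of their neighbour column
    dPds = np.gradient(P, axis=0)
    dPdv = np.gradient(P, axis=1)
    N = np.cross(dPds, dPdv)
    nrm = np.linalg.norm(N, axis=2, keepdims=True)
    radial = np.stack(
        [np.cos(theta), np.sin(theta), np.zeros(ns + 1)], axis=1
    )[:, None, :] * np.ones((1, nv + 1, 1))
    bad = (nrm < 1e-9)[:, :, 0]
    N = np.where(bad[:, :, None], radial, N / np.maximum(nrm, 1e-30))
    n_c0 = N[1].mean(axis=0)
    n_c0 /= np.linalg.norm(n_c0)
    n_c1 = N[ns - 1].mean(axis=0)
    n_c1 /= np.linalg.norm(n_c1)
    N[0, :] = n_c0
    N[ns, :] = n_c1

    def sheet(sign: float):
        pts = P + sign * LEAFLET_HALF_THICKNESS * N
        ids = np.empty((ns + 1, nv + 1), dtype=np.int64)
        verts: List[np.ndarray] = [pts[0, 0], pts[ns, 0]]
        ids[0, :] = 0
        ids[ns, :] = 1
        k = 2
        for i in range(1, ns):
            for j in range(nv + 1):
                ids[i, j] = k
                verts.append(pts[i, j])
                k += 1
        return np.asarray(verts), ids

    verts_t, ids_t = sheet(+1.0)
    verts_b, ids_b = sheet(-1.0)
    off_b = len(verts_t)
    ids_b = ids_b + off_b
    verts = np.vstack([verts_t, verts_b])

    faces: List[Tuple[int, int, int]] = []
    for i in range(ns):
        for j in range(nv):
            a, b = ids_t[i, j], ids_t[i + 1, j]
            c, d = ids_t[i + 1, j + 1], ids_t[i, j + 1]
            if len({a, b, c}) == 3:
                faces.append((a, b, c))
            if len({a, c, d}) == 3:
                faces.append((a, c, d))
            a, b = ids_b[i, j], ids_b[i + 1, j]
            c, d = ids_b[i + 1, j + 1], ids_b[i, j + 1]
            if len({a, b, c}) == 3:
                faces.append((a, c, b))
            if len({a, c, d}) == 3:
                faces.append((a, d, c))

    def boundary_loop(ids):
        loop = [ids[i, 0] for i in range(ns + 1)]
        loop += [ids[i, nv] for i in range(ns - 1, 0, -1)]
        return loop

    lt = boundary_loop(ids_t)
    lb = boundary_loop(ids_b)
    L = len(lt)
    for k in range(L):
        t0, t1 = lt[k], lt[(k + 1) % L]
        b0, b1 = lb[k], lb[(k + 1) % L]
        faces.append((t0, b1, t1))
        faces.append((t0, b0, b1))

    mid = ns // 2
    landmarks = {
        f"hinge_low_{leaf}": np.array([ids_t[mid, 0], ids_b[mid, 0]]),
        f"coaptation_{leaf}": np.array([ids_t[mid, nv], ids_b[mid, nv]]),
        f"commissures_{leaf}": np.array(
            [ids_t[0, 0], ids_t[ns, 0], ids_b[0, 0], ids_b[ns, 0]]
        ),
    }
    return verts, np.asarray(faces, dtype=np.int64), landmarks


def _lv_part(cfg: MeshConfig, vals):
    r_b = vals[FeatureName.BASAL_RING_DIAMETER] / 2.0
    zeta = np.linspace(0.0, 1.0, cfg.n_lv)[:-1]       # apex handled as a point
    u = _smoothstep((zeta - LV_NECK_FRAC) / 0.35)
    w = np.cos(
        0.5 * math.pi * np.clip((zeta - LV_NECK_FRAC) / (1.0 - LV_NECK_FRAC),
                                0.0, 1.0) ** 1.3
    )
    radii = w * ((1.0 - u) * r_b + u * LV_BELLY_RADIUS)
    zs = -LV_DEPTH * zeta
    nc = cfg.circumferential
    theta = np.linspace(0.0, 2.0 * math.pi, nc, endpoint=False)
    # rings ascend in z (apex side first) so the revolve faces point outward
    rings = np.asarray(
        [
            np.column_stack(
                [r * np.cos(theta), r * np.sin(theta), np.full(nc, z)]
            )
            for r, z in zip(radii[::-1], zs[::-1])
        ]
    )
    verts, faces = _revolve(
        rings,
        bottom=np.array([0.0, 0.0, -LV_DEPTH]),      # apex point
        top=np.array([0.0, 0.0, 0.0]),               # cap across the LVOT
    )
    n_rings = len(rings)
    basal_ring = np.arange((n_rings - 1) * nc, n_rings * nc)
    return verts, faces, {"lv_basal_ring": basal_ring}


def _myo_part(cfg: MeshConfig):
    tau = np.linspace(0.0, 1.0, cfg.n_myo + 2)[1:-1]
    radii = MYO_RADIUS * np.sin(math.pi * tau) ** 0.75
    zs = MYO_TOP_Z - MYO_DEPTH * tau
    nc = cfg.circumferential
    theta = np.linspace(0.0, 2.0 * math.pi, nc, endpoint=False)
    rings = np.asarray(
        [
            np.column_stack(
                [r * np.cos(theta), r * np.sin(theta), np.full(nc, z)]
            )
            for r, z in zip(radii[::-1], zs[::-1])
        ]
    )
    verts, faces = _revolve(
        rings,
        bottom=np.array([0.0, 0.0, MYO_TOP_Z - MYO_DEPTH]),
        top=np.array([0.0, 0.0, MYO_TOP_Z]),
    )
    return verts, faces, {}


def _coronary_part(cfg: MeshConfig, vals, artery: str):
    if artery == "rca":
        th = THETA_CENTER["right"]
        z0 = vals[FeatureName.RCA_DISTANCE]
    else:
        th = THETA_CENTER["left"]
        z0 = vals[FeatureName.LCA_DISTANCE]
    r_v = vals[FeatureName.VALVE_DIAMETER] / 2.0
    rho_in = COR_IN_FRAC * r_v
    u_hat = np.array([math.cos(th), math.sin(th), 0.0])
    v_hat = np.array([-math.sin(th), math.cos(th), 0.0])
    z_hat = np.array([0.0, 0.0, 1.0])
    nc = cfg.cor_circ
    phi = np.linspace(0.0, 2.0 * math.pi, nc, endpoint=False)
    circle = COR_RADIUS * (
        np.outer(np.cos(phi), v_hat) + np.outer(np.sin(phi), z_hat)
    )
    rings = []
    for k in range(cfg.cor_ax):
        rho = rho_in + COR_LEN * k / (cfg.cor_ax - 1)
        center = rho * u_hat + np.array([0.0, 0.0, z0])
        rings.append(center + circle)
    rings = np.asarray(rings)
    inner_center = rho_in * u_hat + np.array([0.0, 0.0, z0])
    outer_center = (rho_in + COR_LEN) * u_hat + np.array([0.0, 0.0, z0])
    verts, faces = _revolve(rings, bottom=inner_center, top=outer_center)
    n_ring_verts = cfg.cor_ax * nc
    landmarks = {f"{artery}_ostium": np.array([n_ring_verts])}
    return verts, faces, landmarks


_BUILD_ORDER = [
    StructureLabel.AORTA,
    StructureLabel.LEAFLET_LEFT,
    StructureLabel.LEAFLET_RIGHT,
    StructureLabel.LEAFLET_NON,
    StructureLabel.LEFT_VENTRICLE,
    StructureLabel.MYOCARDIUM,
    StructureLabel.LCA,
    StructureLabel.RCA,
]


def _construct(cfg: MeshConfig, vals: Dict[FeatureName, float]) -> LabeledMesh:
    """Assemble the full labelled mesh for one set of feature values."""
    parts = {
        StructureLabel.AORTA: _aorta_part(cfg, vals),
        StructureLabel.LEAFLET_LEFT: _leaflet_part(cfg, vals, "left"),
        StructureLabel.LEAFLET_RIGHT: _leaflet_part(cfg, vals, "right"),
        StructureLabel.LEAFLET_NON: _leaflet_part(cfg, vals, "non"),
        StructureLabel.LEFT_VENTRICLE: _lv_part(cfg, vals),
        StructureLabel.MYOCARDIUM: _myo_part(cfg),
        StructureLabel.LCA: _coronary_part(cfg, vals, "lca"),
        StructureLabel.RCA: _coronary_part(cfg, vals, "rca"),
    }
    verts_all: List[np.ndarray] = []
    faces_all: List[np.ndarray] = []
    submeshes: Dict[StructureLabel, np.ndarray] = {}
    landmarks: Dict[str, np.ndarray] = {}
    vertex_ranges: Dict[StructureLabel, Tuple[int, int]] = {}
    v_off = 0
    f_off = 0
    for label in _BUILD_ORDER:
        verts, faces, lms = parts[label]
        verts_all.append(verts)
        faces_all.append(faces + v_off)
        submeshes[label] = np.arange(f_off, f_off + len(faces))
        for name, ids in lms.items():
            landmarks[name] = np.asarray(ids) + v_off
        vertex_ranges[label] = (v_off, v_off + len(verts))
        v_off += len(verts)
        f_off += len(faces)
    meta = {
        "vertex_ranges": vertex_ranges,
        "lv_measure_z": LV_MEASURE_Z,
        "valve_plane_offset": VALVE_PLANE_OFFSET,
        "aorta_plane_offset": AORTA_PLANE_OFFSET,
        "r_closed": R_CLOSED,
        "r_open_ref": R_OPEN_REF,
        "neutral": {f.value: float(v) for f, v in vals.items()},
        "resolution": (cfg.circumferential, cfg.axial),
    }
    return LabeledMesh(
        vertices=np.vstack(verts_all),
        faces=np.vstack(faces_all),
        submeshes=submeshes,
        landmarks=landmarks,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# public construction API
# ---------------------------------------------------------------------------


def build_base_mesh(config: Optional[MeshConfig] = None) -> LabeledMesh:
    """Build the labelled base mesh with all PVA displacement fields.

    Deterministic pure function of its configuration.  Raises
    :class:`RangeError` if a neutral value lies outside the implemented
    range of its feature.
    """
    from .parameter_space import default_registry

    cfg = config if config is not None else MeshConfig()
    reg = default_registry()
    for feat, value in cfg.neutral.items():
        lo, hi = reg[feat].implemented_range
        if not (lo <= value <= hi):
            raise RangeError(
                f"neutral value for {feat.value} ({value}) outside "
                f"implemented range [{lo}, {hi}]"
            )

    mesh = _construct(cfg, cfg.neutral)

    # displacement fields: full-range delta per geometric feature
    groups: Dict[str, PVAGroup] = {}
    for feat in GEOMETRIC_FEATURES:
        lo, hi = reg[feat].implemented_range
        vals_lo = dict(cfg.neutral)
        vals_lo[feat] = lo
        vals_hi = dict(cfg.neutral)
        vals_hi[feat] = hi
        delta = _construct(cfg, vals_hi).vertices - _construct(cfg, vals_lo).vertices
        moved = np.flatnonzero(np.abs(delta).max(axis=1) > 1e-12)
        groups[feat.value] = PVAGroup(
            name=feat.value,
            vertex_indices=moved,
            displacements=delta[moved],
            neutral_weight=(cfg.neutral[feat] - lo) / (hi - lo),
        )

    # directional ostium shifting groups (rigid translations)
    directions = {
        "up": np.array([0.0, 0.0, 1.0]),
        "down": np.array([0.0, 0.0, -1.0]),
    }
    for artery, label in (("rca", StructureLabel.RCA), ("lca", StructureLabel.LCA)):
        th = THETA_CENTER["right" if artery == "rca" else "left"]
        v_hat = np.array([-math.sin(th), math.cos(th), 0.0])
        dirs = dict(directions)
        dirs["left"] = v_hat
        dirs["right"] = -v_hat
        idx = mesh.vertex_indices(label)
        for dname, dvec in dirs.items():
            groups[f"{artery}_{dname}"] = PVAGroup(
                name=f"{artery}_{dname}",
                vertex_indices=idx,
                displacements=np.tile(OSTIUM_STEP_MM * dvec, (idx.size, 1)),
                neutral_weight=0.0,
            )

    # heartbeat contraction fields (radial squeeze + longitudinal shortening)
    def _contraction(label: StructureLabel, radial: float, axial: float):
        idx = mesh.vertex_indices(label)
        p = mesh.vertices[idx]
        d = np.column_stack([-radial * p[:, 0], -radial * p[:, 1], -axial * p[:, 2]])
        return idx, d

    beat_spec = {
        "heartbeat_myocardium": [(StructureLabel.MYOCARDIUM, 0.08, 0.06)],
        "heartbeat_left_ventricle": [(StructureLabel.LEFT_VENTRICLE, 0.10, 0.08)],
        "heartbeat_aorta": [(StructureLabel.AORTA, 0.03, 0.0)],
        "heartbeat_coronaries": [
            (StructureLabel.LCA, 0.08, 0.0),
            (StructureLabel.RCA, 0.08, 0.0),
        ],
    }
    for gname, specs in beat_spec.items():
        idx_all = []
        d_all = []
        for label, radial, axial in specs:
            idx, d = _contraction(label, radial, axial)
            idx_all.append(idx)
            d_all.append(d)
        groups[gname] = PVAGroup(
            name=gname,
            vertex_indices=np.concatenate(idx_all),
            displacements=np.vstack(d_all),
            neutral_weight=0.0,
        )

    mesh.pva_groups = groups
    mesh.validate(require_all_labels=True)
    return mesh


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------


def _basal_plane_z(mesh: LabeledMesh) -> float:
    zs = []
    for leaf in LEAFLETS:
        key = f"hinge_low_{leaf}"
        if key not in mesh.landmarks:
            raise MeasurementError(
                "mesh lacks leaflet hinge landmarks; basal plane undefined"
            )
        zs.append(mesh.vertices[mesh.landmarks[key], 2].mean())
    return float(np.mean(zs))


def _section_diameter(mesh: LabeledMesh, label: StructureLabel, z: float) -> float:
    tm = mesh.submesh_trimesh(label)
    if not tm.is_watertight:
        raise MeasurementError(
            f"submesh {StructureLabel(label).value!r} is not watertight; "
            "measurement refused"
        )
    section = tm.section(plane_origin=[0.0, 0.0, z], plane_normal=[0.0, 0.0, 1.0])
    if section is None:
        raise MeasurementError(
            f"plane z={z:.3f} does not intersect {StructureLabel(label).value!r}"
        )
    loops = section.discrete
    loop = max(loops, key=lambda a: np.linalg.norm(np.diff(a, axis=0), axis=1).sum())
    pts = loop[:-1] if np.allclose(loop[0], loop[-1]) else loop
    xy = pts[:, :2]
    centroid = xy.mean(axis=0)
    return float(2.0 * np.linalg.norm(xy - centroid, axis=1).mean())


def _landmark_z(mesh: LabeledMesh, key: str) -> float:
    if key not in mesh.landmarks:
        raise MeasurementError(f"mesh lacks landmark {key!r}")
    return float(mesh.vertices[mesh.landmarks[key], 2].mean())


def measure_feature(mesh: LabeledMesh, feature: FeatureName) -> float:
    """Measure a feature on the (possibly morphed) mesh.

    Diameters are the mean diameter of the cross-section polygon cut by the
    feature's defining plane; heights and distances are axial distances from
    the virtual basal-ring plane; openings are the percentage of the
    free-edge excursion between the shut and fully open reference radii.
    """
    feature = FeatureName(feature)

    if feature == FeatureName.AORTA_DIAMETER:
        if "st_ring" in mesh.landmarks:
            z = _landmark_z(mesh, "st_ring") + mesh.meta.get(
                "aorta_plane_offset", AORTA_PLANE_OFFSET
            )
        else:
            # unlabelled fixture (e.g. a plain cylinder): slice mid-height
            tm = mesh.submesh_trimesh(StructureLabel.AORTA)
            z = float(tm.bounds[:, 2].mean())
        return _section_diameter(mesh, StructureLabel.AORTA, z)

    if feature == FeatureName.VALVE_DIAMETER:
        z = _landmark_z(mesh, "valve_ring") + mesh.meta.get(
            "valve_plane_offset", VALVE_PLANE_OFFSET
        )
        return _section_diameter(mesh, StructureLabel.AORTA, z)

    if feature == FeatureName.BASAL_RING_DIAMETER:
        z = mesh.meta.get("lv_measure_z", LV_MEASURE_Z)
        return _section_diameter(mesh, StructureLabel.LEFT_VENTRICLE, z)

    if feature == FeatureName.ST_HEIGHT:
        return _landmark_z(mesh, "st_ring") - _basal_plane_z(mesh)

    if feature == FeatureName.VA_HEIGHT:
        zs = [
            _landmark_z(mesh, f"commissures_{leaf}") for leaf in LEAFLETS
        ]
        return float(np.mean(zs)) - _basal_plane_z(mesh)

    if feature == FeatureName.RCA_DISTANCE:
        return _landmark_z(mesh, "rca_ostium") - _basal_plane_z(mesh)

    if feature == FeatureName.LCA_DISTANCE:
        return _landmark_z(mesh, "lca_ostium") - _basal_plane_z(mesh)

    for leaf in LEAFLETS:
        if feature == _EFF_FEATURE[leaf]:
            return _landmark_z(mesh, f"coaptation_{leaf}") - _basal_plane_z(mesh)
        if feature == _OPEN_FEATURE[leaf]:
            pts = mesh.vertices[mesh.landmarks[f"coaptation_{leaf}"]]
            r_mid = float(np.linalg.norm(pts.mean(axis=0)[:2]))
            r0 = mesh.meta.get("r_closed", R_CLOSED)
            r1 = mesh.meta.get("r_open_ref", R_OPEN_REF)
            return (r_mid - r0) / (r1 - r0) * 100.0

    raise MeasurementError(
        f"feature {feature.value!r} has no geometric definition on a mesh"
    )


def measure_all(mesh: LabeledMesh) -> Dict[FeatureName, float]:
    """Measure every geometrically defined feature."""
    return {f: measure_feature(mesh, f) for f in GEOMETRIC_FEATURES}


# ---------------------------------------------------------------------------
# OBJ / PLY export with named groups
# ---------------------------------------------------------------------------


def export_mesh(mesh: LabeledMesh, path, fmt: Optional[str] = None) -> None:
    """Write the labelled mesh as ASCII OBJ or PLY with one named group
    (OBJ) / face-label property (PLY) per structure."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "obj":
        _write_obj(mesh, path)
    elif fmt == "ply":
        _write_ply(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r} (use 'obj' or 'ply')")


def import_mesh(path, fmt: Optional[str] = None) -> LabeledMesh:
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "obj":
        return _read_obj(path)
    if fmt == "ply":
        return _read_ply(path)
    raise ValueError(f"unsupported mesh format {fmt!r} (use 'obj' or 'ply')")


def _write_obj(mesh: LabeledMesh, path: Path) -> None:
    lines = ["# tavrgen labelled mesh"]
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.10g} {v[1]:.10g} {v[2]:.10g}")
    for label in _BUILD_ORDER:
        if label not in mesh.submeshes:
            continue
        lines.append(f"g {label.value}")
        for f in mesh.faces[mesh.submeshes[label]]:
            lines.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}")
    path.write_text("\n".join(lines) + "\n")


def _read_obj(path: Path) -> LabeledMesh:
    verts: List[List[float]] = []
    faces: List[List[int]] = []
    group_faces: Dict[StructureLabel, List[int]] = {}
    current: Optional[StructureLabel] = None
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "g":
            current = StructureLabel.parse(parts[1])
            group_faces.setdefault(current, [])
        elif parts[0] == "f":
            if current is None:
                raise MeshError(f"{path}: face before any group record")
            idx = [int(p.split("/")[0]) - 1 for p in parts[1:4]]
            group_faces[current].append(len(faces))
            faces.append(idx)
    return LabeledMesh(
        vertices=np.asarray(verts, float),
        faces=np.asarray(faces, np.int64),
        submeshes={k: np.asarray(v, np.int64) for k, v in group_faces.items()},
    )


def _read_ply(path: Path) -> LabeledMesh:
    lines = path.read_text().splitlines()
    it = iter(lines)
    if next(it).strip() != "ply":
        raise MeshError(f"{path}: not a PLY file")
    n_vert = n_face = 0
    label_map: Dict[int, StructureLabel] = {}
    for line in it:
        parts = line.split()
        if parts[:1] == ["comment"] and len(parts) >= 4 and parts[1] == "label":
            label_map[int(parts[2])] = StructureLabel.parse(parts[3])
        elif parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_face = int(parts[2])
        elif parts[:1] == ["end_header"]:
            break
    verts = np.array(
        [[float(x) for x in next(it).split()[:3]] for _ in range(n_vert)]
    )
    faces = []
    group_faces: Dict[StructureLabel, List[int]] = {}
    for k in range(n_face):
        parts = next(it).split()
        n = int(parts[0])
        faces.append([int(x) for x in parts[1 : 1 + n]])
        label = label_map[int(parts[1 + n])]
        group_faces.setdefault(label, []).append(k)
    return LabeledMesh(
        vertices=verts,
        faces=np.asarray(faces, np.int64),
        submeshes={k: np.asarray(v, np.int64) for k, v in group_faces.items()},
    )


def _write_ply(mesh: LabeledMesh, path: Path) -> None:
    labels = [l for l in _BUILD_ORDER if l in mesh.submeshes]
    label_id = {label: i for i, label in enumerate(labels)}
    face_label = np.empty(len(mesh.faces), dtype=np.int64)
    for label, fidx in mesh.submeshes.items():
        face_label[fidx] = label_id[label]
    lines = [
        "ply",
        "format ascii 1.0",
        "comment tavrgen labelled mesh",
    ]
    for label, i in label_id.items():
        lines.append(f"comment label {i} {label.value}")
    lines += [
        f"element vertex {len(mesh.vertices)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "property uchar label",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}")
    for f, lab in zip(mesh.faces, face_label):
        lines.append(f"3 {f[0]} {f[1]} {f[2]} {lab}")
    path.write_text("\n".join(lines) + "\n")
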