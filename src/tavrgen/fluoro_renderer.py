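"""Simulated fluoroscopy: Beer-Lambert projection of the labelled mesh.

A point X-ray source and a flat detector sit on opposite ends of a virtual
C-arm.  For every detector pixel a ray is cast from the source; for each
watertight submesh the ray's entry/exit intersections are paired into
inside-path lengths, and the pixel intensity is ``I0 * exp(-sum mu_s L_s)``
— high attenuation renders dark, the standard fluoroscopic convention.
Contrast injection multiplies the attenuation of the injected compartment
by a time-dependent bolus factor; digital subtraction maps the mask-live
difference around mid-grey.  Scatter is not modelled (absorption only);
grain is additive zero-mean Gaussian noise.

Angulation follows catheter-lab convention: LAO positive rotates the
source-detector axis about the patient's superior (+z) axis, cranial
positive about the patient-left (+x) axis, applied LAO-then-cranial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from PIL import Image
from pydantic import BaseModel, Field, model_validator

from .anatomy_mesh import LabeledMesh
from .errors import MeshError, TavrgenError
from .features import LEAFLETS, StructureLabel
from .morph_engine import HeartbeatTimeline, MorphState, sample_heartbeat

__all__ = [
    "CArmPose",
    "MaterialDensity",
    "ContrastState",
    "FluoroImage",
    "project",
    "apply_contrast",
    "add_grain",
    "dsa",
    "render_cine",
    "calcification_patches",
    "save_png",
    "DEFAULT_MATERIALS",
]


class CArmPose(BaseModel):
    """C-arm angulation and imaging geometry."""

    lao_rao: float = 0.0            # degrees, + = LAO
    cranial_caudal: float = 0.0     # degrees, + = cranial
    sid_mm: float = 1000.0          # source-to-detector distance
    sod_mm: float = 700.0           # source-to-isocenter distance
    table_offset: Tuple[float, float, float] = (0.0, 0.0, 10.0)
    detector_mm: Tuple[float, float] = (200.0, 200.0)
    image_px: Tuple[int, int] = (96, 96)

    @model_validator(mode="after")
    def _check(self) -> "CArmPose":
        if abs(self.lao_rao) > 120.0 or abs(self.cranial_caudal) > 120.0:
            raise ValueError("C-arm angles must satisfy |angle| <= 120 deg")
        if self.sid_mm <= 0:
            raise ValueError("source-to-detector distance must be positive")
        if not (0 < self.sod_mm < self.sid_mm):
            raise ValueError("need 0 < SOD < SID")
        if min(self.image_px) <= 0 or min(self.detector_mm) <= 0:
            raise ValueError("detector and image dimensions must be positive")
        return self

    @property
    def pixel_spacing(self) -> Tuple[float, float]:
        return (
            self.detector_mm[0] / self.image_px[0],
            self.detector_mm[1] / self.image_px[1],
        )

    def rotation(self) -> np.ndarray:
        lao = math.radians(self.lao_rao)
        cran = math.radians(self.cranial_caudal)
        rz = np.array(
            [
                [math.cos(lao), -math.sin(lao), 0.0],
                [math.sin(lao), math.cos(lao), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        rx = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, math.cos(cran), -math.sin(cran)],
                [0.0, math.sin(cran), math.cos(cran)],
            ]
        )
        return rz @ rx

    def rays(self) -> Tuple[np.ndarray, np.ndarray]:
        """Source position and unit ray directions, one per pixel
        (row-major)."""
        r = self.rotation()
        iso = np.asarray(self.table_offset, float)
        source = iso + r @ np.array([0.0, -self.sod_mm, 0.0])
        det_center = iso + r @ np.array([0.0, self.sid_mm - self.sod_mm, 0.0])
        col_axis = r @ np.array([1.0, 0.0, 0.0])
        row_axis = r @ np.array([0.0, 0.0, -1.0])
        h, w = self.image_px[1], self.image_px[0]
        jj, ii = np.meshgrid(np.arange(w), np.arange(h))
        u = ((jj + 0.5) / w - 0.5) * self.detector_mm[0]
        v = ((ii + 0.5) / h - 0.5) * self.detector_mm[1]
        pix = (
            det_center[None, None, :]
            + u[:, :, None] * col_axis[None, None, :]
            + v[:, :, None] * row_axis[None, None, :]
        ).reshape(-1, 3)
        dirs = pix - source
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        return source, dirs


@dataclass(frozen=True)
class MaterialDensity:
    """Per-structure attenuation coefficients mu (per mm)."""

    mu: Mapping[StructureLabel, float]
    calc_mu: float = 0.6   # attenuation per mm of calcific deposit

    def __post_init__(self) -> None:
        for label, value in self.mu.items():
            if value < 0:
                raise ValueError(
                    f"attenuation for {StructureLabel(label).value} "
                    "must be >= 0"
                )
        if self.calc_mu < 0:
            raise ValueError("calcification attenuation must be >= 0")


DEFAULT_MATERIALS = MaterialDensity(
    mu={
        StructureLabel.AORTA: 0.018,
        StructureLabel.LEAFLET_LEFT: 0.025,
        StructureLabel.LEAFLET_RIGHT: 0.025,
        StructureLabel.LEAFLET_NON: 0.025,
        StructureLabel.LEFT_VENTRICLE: 0.020,
        StructureLabel.MYOCARDIUM: 0.022,
        StructureLabel.LCA: 0.018,
        StructureLabel.RCA: 0.018,
    }
)

#: injectable compartments and the structures they fill
COMPARTMENTS: Dict[str, Tuple[StructureLabel, ...]] = {
    "coronaries": (StructureLabel.LCA, StructureLabel.RCA),
    "ventricle_aorta": (StructureLabel.LEFT_VENTRICLE, StructureLabel.AORTA),
}


@dataclass(frozen=True)
class ContrastState:
    """One contrast injection: linear rise to peak, exponential washout."""

    compartment: str
    t0: float = 0.0
    peak: float = 8.0
    rise: float = 1.0
    washout: float = 2.0

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r}; valid: "
                + ", ".join(COMPARTMENTS)
            )
        if self.peak < 1.0:
            raise ValueError("bolus peak factor must be >= 1")
        if self.rise <= 0 or self.washout <= 0:
            raise ValueError("rise and washout times must be positive")

    def factor(self, t: float) -> float:
        """Attenuation boost factor at time t; >= 1, -> 1 as t -> inf."""
        if t < self.t0:
            return 1.0
        if t <= self.t0 + self.rise:
            return 1.0 + (self.peak - 1.0) * (t - self.t0) / self.rise
        return 1.0 + (self.peak - 1.0) * math.exp(
            -(t - self.t0 - self.rise) / self.washout
        )


@dataclass
class FluoroImage:
    """Grayscale intensity grid in [0, I0] with its producing pose."""

    intensities: np.ndarray
    pixel_spacing: Tuple[float, float]
    pose: CArmPose
    i0: float = 1.0


# ---------------------------------------------------------------------------
# ray / triangle path-length integration
# ---------------------------------------------------------------------------

_PAIR_TOL = 1e-6    # mm; intersection pairing tolerance
_EDGE_EPS = 1e-9


def _ray_hits(
    v0: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    q_const: np.ndarray,
    t_num: np.ndarray,
    origin: np.ndarray,
    dirs: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """All (ray index, t) intersections for a batch of rays against one
    triangle soup sharing a single origin (Moller-Trumbore)."""
    n = len(dirs)
    m = len(v0)
    ray_idx_parts: List[np.ndarray] = []
    t_parts: List[np.ndarray] = []
    chunk = max(1, int(5e5) // max(m, 1))
    s = origin[None, :] - v0                      # (M, 3)
    for a0 in range(0, n, chunk):
        d = dirs[a0 : a0 + chunk]                 # (Nc, 3)
        h = np.cross(d[:, None, :], e2[None, :, :])      # (Nc, M, 3)
        det = np.einsum("nmk,mk->nm", h, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / det
            u = inv * np.einsum("mk,nmk->nm", s, h)
            v = inv * np.einsum("nk,mk->nm", d, q_const)
            t = inv * t_num[None, :]
            hit = (
                (np.abs(det) > 1e-12)
                & (u >= -_EDGE_EPS)
                & (v >= -_EDGE_EPS)
                & (u + v <= 1.0 + _EDGE_EPS)
                & (t > _PAIR_TOL)
            )
        rr, mm_ = np.nonzero(hit)
        ray_idx_parts.append(rr + a0)
        t_parts.append(t[hit])
    return np.concatenate(ray_idx_parts), np.concatenate(t_parts)


def _tri_arrays(vertices: np.ndarray, faces: np.ndarray):
    tri = vertices[faces]
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    return v0, e1, e2


def _collapse(ts: np.ndarray) -> np.ndarray:
    """Merge hits closer than the pairing tolerance (shared edges/vertices
    produce duplicates)."""
    if len(ts) == 0:
        return ts
    ts = np.sort(ts)
    keep = np.empty(len(ts), dtype=bool)
    keep[0] = True
    np.greater(np.diff(ts), _PAIR_TOL, out=keep[1:])
    return ts[keep]


def path_lengths(
    vertices: np.ndarray,
    faces: np.ndarray,
    origin: np.ndarray,
    dirs: np.ndarray,
    structure: str = "mesh",
) -> np.ndarray:
    """Inside-path length of each ray through a closed triangle surface.

    Entry/exit intersections are sorted and paired; an odd intersection
    count that survives tolerance pairing and a jittered re-cast means the
    surface is not watertight and raises :class:`MeshError`.
    """
    v0, e1, e2 = _tri_arrays(np.asarray(vertices, float), np.asarray(faces))
    origin = np.asarray(origin, float)
    dirs = np.asarray(dirs, float)
    q_const = np.cross(origin[None, :] - v0, e1)
    t_num = np.einsum("mk,mk->m", e2, q_const)

    ray_idx, ts = _ray_hits(v0, e1, e2, q_const, t_num, origin, dirs)
    lengths = np.zeros(len(dirs))
    if len(ray_idx) == 0:
        return lengths
    order = np.lexsort((ts, ray_idx))
    ray_idx = ray_idx[order]
    ts = ts[order]
    boundaries = np.flatnonzero(np.diff(ray_idx)) + 1
    groups = np.split(ts, boundaries)
    rays_with_hits = ray_idx[np.concatenate([[0], boundaries])]
    for ray, group in zip(rays_with_hits, groups):
        tt = _collapse(group)
        if len(tt) % 2 == 1:
            tt = _retry_ray(v0, e1, e2, origin, dirs[ray], structure)
        lengths[ray] = (tt[1::2] - tt[0::2]).sum()
    return lengths


def _retry_ray(v0, e1, e2, origin, direction, structure: str) -> np.ndarray:
    """Re-cast a grazing ray with tiny perpendicular jitters; if the hit
    count stays odd the surface genuinely is not closed."""
    perp = np.cross(direction, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-9:
        perp = np.cross(direction, [1.0, 0.0, 0.0])
    perp /= np.linalg.norm(perp)
    for scale in (1e-4, -1e-4, 3e-4):
        o = origin + scale * perp
        q_const = np.cross(o[None, :] - v0, e1)
        t_num = np.einsum("mk,mk->m", e2, q_const)
        _, ts = _ray_hits(
            v0, e1, e2, q_const, t_num, o, direction[None, :]
        )
        tt = _collapse(ts)
        if len(tt) % 2 == 0:
            return tt
    raise MeshError(
        f"submesh {structure!r}: odd ray-intersection count; "
        "surface is not watertight"
    )


def _crossing_counts(
    vertices: np.ndarray, faces: np.ndarray, origin: np.ndarray, dirs: np.ndarray
) -> np.ndarray:
    """Number of distinct crossings of each ray through a face subset
    (no parity requirement; used for calcified surface patches)."""
    if len(faces) == 0:
        return np.zeros(len(dirs), dtype=int)
    v0, e1, e2 = _tri_arrays(np.asarray(vertices, float), np.asarray(faces))
    origin = np.asarray(origin, float)
    q_const = np.cross(origin[None, :] - v0, e1)
    t_num = np.einsum("mk,mk->m", e2, q_const)
    ray_idx, ts = _ray_hits(v0, e1, e2, q_const, t_num, origin, np.asarray(dirs))
    counts = np.zeros(len(dirs), dtype=int)
    if len(ray_idx) == 0:
        return counts
    order = np.lexsort((ts, ray_idx))
    ray_idx = ray_idx[order]
    ts = ts[order]
    boundaries = np.flatnonzero(np.diff(ray_idx)) + 1
    for ray, group in zip(
        ray_idx[np.concatenate([[0], boundaries])] if len(ray_idx) else [],
        np.split(ts, boundaries),
    ):
        counts[ray] = len(_collapse(group))
    return counts


# ---------------------------------------------------------------------------
# rendering pipeline
# ---------------------------------------------------------------------------


def project(
    mesh: LabeledMesh,
    materials: Optional[MaterialDensity] = None,
    pose: Optional[CArmPose] = None,
    i0: float = 1.0,
    calcification: Optional[Mapping[StructureLabel, Tuple[np.ndarray, float]]] = None,
) -> FluoroImage:
    """Beer-Lambert projection of every labelled submesh."""
    mats = materials if materials is not None else DEFAULT_MATERIALS
    pose = pose if pose is not None else CArmPose()
    source, dirs = pose.rays()
    atten = np.zeros(len(dirs))
    for label in mesh.submeshes:
        mu = mats.mu.get(label, 0.0)
        faces = mesh.faces[mesh.submeshes[label]]
        if mu > 0.0:
            atten += mu * path_lengths(
                mesh.vertices, faces, source, dirs, structure=label.value
            )
    if calcification:
        for label, (face_ids, thickness) in calcification.items():
            counts = _crossing_counts(
                mesh.vertices, mesh.faces[np.asarray(face_ids)], source, dirs
            )
            atten += counts * thickness * mats.calc_mu
    h, w = pose.image_px[1], pose.image_px[0]
    img = np.clip(i0 * np.exp(-atten), 0.0, i0).reshape(h, w)
    return FluoroImage(img, pose.pixel_spacing, pose, i0)


def apply_contrast(
    materials: MaterialDensity,
    states: Sequence[ContrastState],
    t: float,
) -> MaterialDensity:
    """Boost the attenuation of each injected compartment's structures by
    its bolus factor at time ``t``; other structures are untouched."""
    mu = dict(materials.mu)
    for state in states:
        f = state.factor(t)
        for label in COMPARTMENTS[state.compartment]:
            if label in mu:
                mu[label] = mu[label] * f
    return replace(materials, mu=mu)


def add_grain(image: FluoroImage, amount: float, seed: int = 0) -> FluoroImage:
    """Seeded zero-mean Gaussian grain with std ``amount * I0``."""
    if amount < 0:
        raise ValueError("grain amount must be >= 0")
    if amount == 0.0:
        return FluoroImage(
            image.intensities.copy(), image.pixel_spacing, image.pose, image.i0
        )
    rng = np.random.default_rng(seed)
    noisy = image.intensities + rng.normal(
        0.0, amount * image.i0, image.intensities.shape
    )
    return FluoroImage(
        np.clip(noisy, 0.0, image.i0), image.pixel_spacing, image.pose, image.i0
    )


def dsa(mask: FluoroImage, live: FluoroImage) -> FluoroImage:
    """Digital subtraction: mask minus live, remapped so unchanged regions
    sit at mid-grey."""
    if mask.pose != live.pose or mask.intensities.shape != live.intensities.shape:
        raise TavrgenError("DSA requires identical pose and image size")
    i0 = mask.i0
    diff = 0.5 * i0 + 0.5 * (mask.intensities - live.intensities)
    return FluoroImage(
        np.clip(diff, 0.0, i0), mask.pixel_spacing, mask.pose, i0
    )


def calcification_patches(
    mesh: LabeledMesh, record
) -> Dict[StructureLabel, Tuple[np.ndarray, float]]:
    """Seeded random surface patches realising each leaflet's calcification
    sliders: ``extent`` selects that fraction of the leaflet area around
    random seed points, ``thickness_mm`` sets the deposit path length."""
    from .anatomy_mesh import LEAFLET_LABEL

    patches: Dict[StructureLabel, Tuple[np.ndarray, float]] = {}
    for leaf in LEAFLETS:
        spec = record.calcification[leaf]
        if spec.extent <= 0.0 or spec.thickness_mm <= 0.0:
            continue
        label = LEAFLET_LABEL[leaf]
        face_ids = mesh.submeshes[label]
        tri = mesh.vertices[mesh.faces[face_ids]]
        centroids = tri.mean(axis=1)
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        rng = np.random.default_rng(spec.pattern_seed)
        seeds = centroids[rng.choice(len(centroids), size=3, replace=False)]
        dist = np.min(
            np.linalg.norm(centroids[:, None, :] - seeds[None, :, :], axis=2),
            axis=1,
        )
        order = np.argsort(dist)
        cum = np.cumsum(areas[order])
        n_take = int(np.searchsorted(cum, spec.extent * areas.sum())) + 1
        patches[label] = (face_ids[order[:n_take]], spec.thickness_mm)
    return patches


def render_cine(
    mesh: LabeledMesh,
    record,
    pose: Optional[CArmPose] = None,
    duration: float = 1.0,
    fps: float = 10.0,
    materials: Optional[MaterialDensity] = None,
    contrast: Sequence[ContrastState] = (),
    grain_amount: float = 0.0,
    timeline: Optional[HeartbeatTimeline] = None,
    seed: int = 0,
) -> List[FluoroImage]:
    """Render a frame sequence: heartbeat morph, contrast bolus, projection
    and grain per frame.  ``mesh`` is the base mesh; the record's anatomy is
    applied first and the heartbeat morphs ride on top of it."""
    from .patient_generator import patient_to_mesh

    pose = pose if pose is not None else CArmPose()
    mats = materials if materials is not None else DEFAULT_MATERIALS
    n_frames = int(round(duration * fps))
    anatomy_mesh_ = patient_to_mesh(record, mesh) if record is not None else mesh
    patches = (
        calcification_patches(anatomy_mesh_, record) if record is not None else None
    )
    frames: List[FluoroImage] = []
    for k in range(n_frames):
        t = k / fps
        frame_mesh = anatomy_mesh_
        if timeline is not None:
            frame_mesh = _morph_on_top(
                anatomy_mesh_, sample_heartbeat(timeline, t)
            )
        mats_t = apply_contrast(mats, contrast, t) if contrast else mats
        img = project(frame_mesh, mats_t, pose, calcification=patches)
        if grain_amount > 0.0:
            img = add_grain(img, grain_amount, seed=seed + k)
        frames.append(img)
    return frames


def _morph_on_top(mesh: LabeledMesh, state: MorphState) -> LabeledMesh:
    """Apply a morph state relative to the mesh's *current* vertices
    (used to layer heartbeat motion on an already-morphed anatomy)."""
    verts = mesh.vertices.copy()
    for name, w in state.weights.items():
        grp = mesh.pva_groups[name]
        scale = w - grp.neutral_weight
        if scale != 0.0:
            verts[grp.vertex_indices] += scale * grp.displacements
    return mesh.with_vertices(verts)


def save_png(image: FluoroImage, path, bits: int = 8) -> None:
    """Write the frame as an 8- or 16-bit grayscale PNG."""
    scale = (2**bits) - 1
    arr = np.clip(image.intensities / image.i0, 0.0, 1.0) * scale
    if bits == 8:
        Image.fromarray(arr.round().astype(np.uint8), mode="L").save(path)
    elif bits == 16:
        Image.fromarray(arr.round().astype(np.uint16), mode="I;16").save(path)
    else:
        raise ValueError("bits must be 8 or 16")


def save_cine(frames: Iterable[FluoroImage], directory, bits: int = 8) -> List[Path]:
    """Write numbered PNG frames into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, frame in enumerate(frames):
        p = directory / f"frame_{k:04d}.png"
        save_png(frame, p, bits=bits)
        paths.append(p)
    return paths
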