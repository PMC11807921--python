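"""Beer-Lambert projection, contrast, grain, DSA and cine rendering."""

import numpy as np
import pytest
import trimesh

from tavrgen.anatomy_mesh import LabeledMesh
from tavrgen.errors import MeshError, TavrgenError
from tavrgen.features import StructureLabel
from tavrgen.fluoro_renderer import (
    DEFAULT_MATERIALS,
    CArmPose,
    ContrastState,
    FluoroImage,
    MaterialDensity,
    add_grain,
    apply_contrast,
    calcification_patches,
    dsa,
    project,
    render_cine,
)
from tavrgen.fluoro_renderer import path_lengths
from tavrgen.morph_engine import default_heartbeat_timeline
from tavrgen.patient_generator import generate_patient, patient_to_mesh


@pytest.fixture
def slab_mesh():
    """100x10x100 mm slab, beam crossing the 10 mm dimension."""
    box = trimesh.creation.box(extents=[100.0, 10.0, 100.0])
    return LabeledMesh(
        vertices=box.vertices,
        faces=box.faces,
        submeshes={StructureLabel.AORTA: np.arange(len(box.faces))},
    )


@pytest.fixture(scope="module")
def patient_scene(small_mesh_module):
    record = generate_patient(21)
    return record, patient_to_mesh(record, small_mesh_module)


@pytest.fixture(scope="module")
def small_mesh_module():
    from tavrgen.anatomy_mesh import MeshConfig, build_base_mesh

    return build_base_mesh(MeshConfig(circumferential=32, axial=48))


class TestProject:
    def test_empty_scene_is_uniform_source_intensity(self):
        empty = LabeledMesh(np.zeros((3, 3)), np.zeros((0, 3), int), {})
        img = project(empty, DEFAULT_MATERIALS, CArmPose(image_px=(8, 8)), i0=2.0)
        assert np.allclose(img.intensities, 2.0)

    def test_slab_matches_beer_lambert_closed_form(self, slab_mesh):
        pose = CArmPose(image_px=(5, 5), detector_mm=(4.0, 4.0),
                        table_offset=(0.0, 0.0, 0.0))
        mats = MaterialDensity(mu={StructureLabel.AORTA: 0.1})
        img = project(slab_mesh, mats, pose, i0=1.0)
        # central ray is perpendicular: I = I0 * exp(-0.1 * 10)
        assert img.intensities[2, 2] == pytest.approx(np.exp(-1.0), rel=1e-6)

    def test_sphere_path_lengths_match_analytic_chords(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
        source = np.array([0.0, -700.0, 0.0])
        rng = np.random.default_rng(0)
        targets = rng.normal(size=(300, 3)) * [5, 0, 5] + [0, 300, 0]
        dirs = targets - source
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        lengths = path_lengths(sphere.vertices, sphere.faces, source, dirs)
        impact = np.linalg.norm(np.cross(-source, dirs), axis=1)
        chord = np.where(
            impact < 10.0, 2.0 * np.sqrt(np.maximum(100.0 - impact**2, 0)), 0.0
        )
        sel = chord > 5.0  # away from grazing rim, where faceting dominates
        assert np.allclose(lengths[sel], chord[sel], rtol=0.01)

    def test_open_surface_rejected_with_structure_name(self, slab_mesh):
        # remove a beam-facing triangle so central rays see an odd number
        # of crossings
        box = trimesh.creation.box(extents=[100.0, 10.0, 100.0])
        facing = np.argmax(box.face_normals @ np.array([0.0, -1.0, 0.0]))
        keep = np.delete(np.arange(len(box.faces)), facing)
        broken = LabeledMesh(
            box.vertices, box.faces, {StructureLabel.AORTA: keep}
        )
        pose = CArmPose(image_px=(21, 21), detector_mm=(220.0, 220.0),
                        table_offset=(0.0, 0.0, 0.0))
        with pytest.raises(MeshError, match="aorta"):
            project(broken, MaterialDensity(mu={StructureLabel.AORTA: 0.1}), pose)

    def test_doubling_attenuation_never_brightens_any_pixel(self, patient_scene):
        record, mesh = patient_scene
        poses = [
            CArmPose(image_px=(16, 16)),
            CArmPose(image_px=(16, 16), lao_rao=30.0),
            CArmPose(image_px=(16, 16), cranial_caudal=-20.0),
        ]
        doubled = MaterialDensity(
            mu={k: 2.0 * v for k, v in DEFAULT_MATERIALS.mu.items()}
        )
        for pose in poses:
            a = project(mesh, DEFAULT_MATERIALS, pose).intensities
            b = project(mesh, doubled, pose).intensities
            assert (b <= a + 1e-12).all()

    def test_rotating_scene_equals_counter_rotating_carm(self, patient_scene):
        record, mesh = patient_scene
        theta = np.radians(25.0)
        rz = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        rotated = mesh.with_vertices(mesh.vertices @ rz.T)
        pose0 = CArmPose(image_px=(24, 24), table_offset=(0, 0, 0))
        pose_neg = CArmPose(image_px=(24, 24), lao_rao=-25.0,
                            table_offset=(0, 0, 0))
        img_scene = project(rotated, DEFAULT_MATERIALS, pose0)
        img_carm = project(mesh, DEFAULT_MATERIALS, pose_neg)
        assert np.allclose(
            img_scene.intensities, img_carm.intensities, atol=1e-9
        )

    def test_all_pixels_within_energy_bound_through_pipeline(self, patient_scene):
        record, mesh = patient_scene
        pose = CArmPose(image_px=(16, 16))
        img = project(mesh, DEFAULT_MATERIALS, pose)
        img = add_grain(img, 0.1, seed=4)
        sub = dsa(img, img)
        for frame in (img, sub):
            assert (frame.intensities >= 0.0).all()
            assert (frame.intensities <= frame.i0).all()

    def test_pose_validation_bounds(self):
        with pytest.raises(ValueError):
            CArmPose(lao_rao=200.0)
        with pytest.raises(ValueError):
            CArmPose(sid_mm=-1.0)
        with pytest.raises(ValueError):
            CArmPose(image_px=(0, 10))


class TestContrast:
    def test_before_injection_materials_unchanged(self):
        state = ContrastState(compartment="coronaries", t0=5.0)
        out = apply_contrast(DEFAULT_MATERIALS, [state], t=1.0)
        assert out.mu == DEFAULT_MATERIALS.mu

    def test_coronary_injection_boosts_only_coronaries(self):
        state = ContrastState(compartment="coronaries", t0=0.0, rise=1.0)
        out = apply_contrast(DEFAULT_MATERIALS, [state], t=1.0)  # at peak
        assert out.mu[StructureLabel.LCA] == pytest.approx(
            DEFAULT_MATERIALS.mu[StructureLabel.LCA] * state.peak
        )
        assert out.mu[StructureLabel.RCA] > DEFAULT_MATERIALS.mu[StructureLabel.RCA]
        assert out.mu[StructureLabel.AORTA] == DEFAULT_MATERIALS.mu[
            StructureLabel.AORTA
        ]

    def test_bolus_decays_to_unity_after_washout(self):
        state = ContrastState(compartment="ventricle_aorta", t0=0.0,
                              rise=1.0, washout=2.0)
        t_late = state.t0 + state.rise + 5.0 * state.washout
        assert state.factor(t_late) == pytest.approx(1.0, abs=0.05)
        assert state.factor(t_late) >= 1.0

    def test_unknown_compartment_rejected(self):
        with pytest.raises(ValueError, match="compartment"):
            ContrastState(compartment="liver")


class TestGrain:
    def test_zero_amount_leaves_image_unchanged(self):
        img = FluoroImage(np.full((8, 8), 0.5), (1.0, 1.0), CArmPose(), 1.0)
        out = add_grain(img, 0.0, seed=1)
        assert np.array_equal(out.intensities, img.intensities)

    def test_noise_std_matches_requested_amount(self):
        img = FluoroImage(np.full((200, 200), 0.5), (1.0, 1.0), CArmPose(), 1.0)
        out = add_grain(img, 0.05, seed=2)
        noise = out.intensities - img.intensities
        assert noise.std() == pytest.approx(0.05, rel=0.05)
        assert abs(noise.mean()) < 0.002

    def test_same_seed_reproduces_grain(self):
        img = FluoroImage(np.full((16, 16), 0.5), (1.0, 1.0), CArmPose(), 1.0)
        a = add_grain(img, 0.05, seed=3)
        b = add_grain(img, 0.05, seed=3)
        assert np.array_equal(a.intensities, b.intensities)


class TestDSA:
    def test_self_subtraction_is_uniform_mid_gray(self, patient_scene):
        record, mesh = patient_scene
        img = project(mesh, DEFAULT_MATERIALS, CArmPose(image_px=(16, 16)))
        sub = dsa(img, img)
        assert np.allclose(sub.intensities, 0.5 * img.i0)

    def test_contrast_footprint_localises_difference(self, patient_scene):
        record, mesh = patient_scene
        pose = CArmPose(image_px=(32, 32))
        mask = project(mesh, DEFAULT_MATERIALS, pose)
        state = ContrastState(compartment="coronaries", t0=0.0, rise=1.0)
        live = project(mesh, apply_contrast(DEFAULT_MATERIALS, [state], 1.0), pose)
        sub = dsa(mask, live)
        # footprint oracle: project the coronaries alone
        only = MaterialDensity(
            mu={StructureLabel.LCA: 1.0, StructureLabel.RCA: 1.0}
        )
        footprint = project(mesh, only, pose).intensities < 1.0
        off = np.abs(sub.intensities - 0.5 * sub.i0) > 1e-9
        assert off.any()
        assert (off <= footprint).all()  # differences only under coronaries

    def test_swapping_arguments_mirrors_about_mid_gray(self, patient_scene):
        record, mesh = patient_scene
        pose = CArmPose(image_px=(16, 16))
        a = project(mesh, DEFAULT_MATERIALS, pose)
        state = ContrastState(compartment="ventricle_aorta", t0=0.0)
        b = project(mesh, apply_contrast(DEFAULT_MATERIALS, [state], 1.0), pose)
        ab = dsa(a, b).intensities
        ba = dsa(b, a).intensities
        assert np.allclose(ab + ba, a.i0, atol=1e-9)

    def test_pose_mismatch_rejected(self, patient_scene):
        record, mesh = patient_scene
        a = project(mesh, DEFAULT_MATERIALS, CArmPose(image_px=(8, 8)))
        b = project(mesh, DEFAULT_MATERIALS, CArmPose(image_px=(8, 8), lao_rao=5.0))
        with pytest.raises(TavrgenError, match="pose"):
            dsa(a, b)


class TestCine:
    def test_frame_count_is_duration_times_fps(self, patient_scene,
                                               small_mesh_module):
        record, _ = patient_scene
        frames = render_cine(
            small_mesh_module, record, CArmPose(image_px=(8, 8)),
            duration=1.0, fps=10.0,
        )
        assert len(frames) == 10

    def test_static_scene_gives_identical_frames(self, patient_scene,
                                                 small_mesh_module):
        record, _ = patient_scene
        frames = render_cine(
            small_mesh_module, record, CArmPose(image_px=(8, 8)),
            duration=0.3, fps=10.0, timeline=None, grain_amount=0.0,
        )
        for frame in frames[1:]:
            assert np.array_equal(frame.intensities, frames[0].intensities)

    def test_heartbeat_periodicity_across_frames(self, patient_scene,
                                                 small_mesh_module):
        record, _ = patient_scene
        timeline = default_heartbeat_timeline(heart_rate=60.0)
        frames = render_cine(
            small_mesh_module, record, CArmPose(image_px=(8, 8)),
            duration=1.1, fps=10.0, timeline=timeline,
        )
        # frame 0 (t=0) and frame 10 (t=1 s) are one full beat apart
        assert np.allclose(
            frames[0].intensities, frames[10].intensities, atol=1e-9
        )

    def test_calcification_patches_scale_with_extent(self, small_mesh_module):
        record = generate_patient(33)
        spec = record.calcification["left"].model_copy(
            update={"extent": 0.5, "thickness_mm": 1.5}
        )
        record = record.model_copy(
            update={"calcification": {**record.calcification, "left": spec}}
        )
        mesh = patient_to_mesh(record, small_mesh_module)
        patches = calcification_patches(mesh, record)
        label = StructureLabel.LEAFLET_LEFT
        assert label in patches
        face_ids, thickness = patches[label]
        assert thickness == 1.5
        frac = len(face_ids) / len(mesh.submeshes[label])
        assert 0.3 < frac < 0.7
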