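"""Quantification: sampling mesh, references, projection, regional statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asmbrain import (
    PhantomSpec,
    Uptake,
    Volume,
    asymmetry_index,
    build_surface_mesh,
    compute_reference_value,
    cortical_index,
    low_value_fraction,
    normalize_volume,
    quantify_volume,
    regional_means,
    surface_projection,
)
from asmbrain.phantom import base_landmarks, generate_brain_phantom
from asmbrain.quantify import (
    AtlasError,
    DataError,
    NormalizationResult,
    SurfaceMesh,
)
from asmbrain.regions import REGIONS, REPORT_REGIONS, label_points_geometric
from asmbrain.shape_model import LandmarkSet


def sphere_landmarks(radius=50.0, n_rings=10, n_theta=20, centre=(0.0, 0.0, 0.0)):
    phi = np.pi * (np.arange(n_rings) + 0.5) / n_rings
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    pts = np.empty((n_rings, n_theta, 3))
    pts[..., 0] = radius * np.cos(phi)[:, None] + centre[0]
    pts[..., 1] = radius * np.sin(phi)[:, None] * np.cos(theta)[None, :] + centre[1]
    pts[..., 2] = radius * np.sin(phi)[:, None] * np.sin(theta)[None, :] + centre[2]
    return LandmarkSet(pts.reshape(-1, 3)), n_theta


@pytest.fixture(scope="module")
def labelled_phantom():
    """Sharp-edged phantom + mesh built from its true landmarks with
    geometric lobe labels."""
    spec = PhantomSpec(
        counts_scale=0.0, psf_fwhm_mm=0.0,
        uptake=Uptake(cortex=100, white=0, ventricle=0, cerebellum=100, background=0),
    )
    vol, truth = generate_brain_phantom(spec)
    labels = label_points_geometric(truth.surface_landmarks.points, spec)
    mesh = build_surface_mesh(truth.surface_landmarks, labels, spec.n_theta)
    return spec, vol, truth, mesh


class TestSurfaceMesh:
    def test_default_mesh_has_3010_points(self, labelled_phantom):
        *_, mesh = labelled_phantom
        assert len(mesh) == 3010
        assert np.allclose(np.linalg.norm(mesh.inward_normals, axis=1), 1.0, atol=1e-6)
        # every atlas region is represented
        for region in REGIONS:
            assert mesh.region_indices(region).size > 0

    def test_target_equal_to_landmark_count_is_identity(self):
        lm, n_theta = sphere_landmarks()
        labels = np.zeros(len(lm), dtype=int)
        mesh = build_surface_mesh(lm, labels, n_theta, target_points=len(lm))
        assert np.array_equal(mesh.points, lm.points)

    def test_sphere_normals_point_to_centre(self):
        # landmark density of the production configuration (14 x 39)
        lm, n_theta = sphere_landmarks(radius=50.0, n_rings=14, n_theta=39)
        labels = np.zeros(len(lm), dtype=int)
        mesh = build_surface_mesh(lm, labels, n_theta, target_points=len(lm))
        to_centre = -mesh.points / np.linalg.norm(mesh.points, axis=1, keepdims=True)
        cosang = np.einsum("ij,ij->i", mesh.inward_normals, to_centre)
        assert np.all(np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 5.0)

    def test_labels_come_from_nearest_landmark(self, labelled_phantom):
        spec, _, truth, mesh = labelled_phantom
        from scipy.spatial import cKDTree

        tree = cKDTree(truth.surface_landmarks.points)
        labels = label_points_geometric(truth.surface_landmarks.points, spec)
        _, nearest = tree.query(mesh.points)
        assert np.array_equal(mesh.lobe_labels, labels[nearest])


@pytest.fixture(scope="module")
def sphere_shell():
    """Uniform 100-count spherical shell (outer 60 mm, 20 mm thick) with its
    surface landmark rings."""
    n = 64
    spacing = 4.0
    coords = (np.arange(n) - (n - 1) / 2.0) * spacing
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    data = np.where((r <= 60.0) & (r >= 40.0), 100.0, 0.0)
    vol = Volume(data, (spacing,) * 3)
    brain = r <= 60.0
    lm, n_theta = sphere_landmarks(radius=60.0, n_rings=10, n_theta=20)
    return vol, brain, lm, n_theta


class TestSurfaceProjection:
    def test_uniform_shell_projects_to_shell_value(self, sphere_shell):
        vol, _, lm, n_theta = sphere_shell
        labels = np.zeros(len(lm), dtype=int)
        mesh = build_surface_mesh(lm, labels, n_theta, target_points=600)
        values = surface_projection(vol, mesh)
        assert np.all(values >= 99.0)
        assert np.all(values <= 100.0 + 1e-9)

    def test_depth_is_nine_percent_of_brain_length(self):
        # two antipodal surface points 166.7 mm apart => search depth 15.0 mm
        # (x and z sit on a voxel-centre plane so trilinear sampling is exact)
        pts = np.array([[-2.0, 83.35, -2.0], [-2.0, -83.35, -2.0]])
        normals = np.array([[0.0, -1.0, 0.0], [0.0, 1.0, 0.0]])
        mesh = SurfaceMesh(pts, normals, np.zeros(2, dtype=int), np.zeros(2, dtype=int))
        assert mesh.brain_length_mm == pytest.approx(166.7)
        assert 0.09 * mesh.brain_length_mm == pytest.approx(15.0, abs=0.005)

        data = np.full((64, 64, 64), 10.0)
        data[31, 49, 31] = 90.0   # (-2, 70, -2) mm: 13.35 mm below the +y point
        data[31, 16, 31] = 90.0   # (-2, -62, -2) mm: 21.35 mm below the -y point
        vol = Volume(data, (4.0, 4.0, 4.0))
        values = surface_projection(vol, mesh)
        assert values[0] > 50.0    # within the 15 mm search depth
        assert values[1] == pytest.approx(10.0, abs=1.0)  # beyond it

    def test_projection_depth_scales_with_brain_length(self):
        lm, n_theta = sphere_landmarks(radius=50.0)
        labels = np.zeros(len(lm), dtype=int)
        m1 = build_surface_mesh(lm, labels, n_theta, target_points=len(lm))
        lm2 = LandmarkSet(lm.points * 1.2)
        m2 = build_surface_mesh(lm2, labels, n_theta, target_points=len(lm))
        assert m2.brain_length_mm == pytest.approx(1.2 * m1.brain_length_mm)


class TestReferenceValues:
    @pytest.fixture()
    def cerebellar_ball(self):
        """Uniform 50-count ball with an all-cerebellar surface mesh."""
        data = np.zeros((32, 32, 32))
        centre = (np.array(data.shape) - 1) / 2.0
        idx = np.indices(data.shape).reshape(3, -1).T
        r = np.linalg.norm((idx - centre) * 4.0, axis=1).reshape(data.shape)
        mask = r <= 40.0
        data[mask] = 50.0
        vol = Volume(data, (4.0, 4.0, 4.0))
        lm, n_theta = sphere_landmarks(radius=40.0, n_rings=6, n_theta=12)
        labels = np.full(len(lm), REGIONS.index("cerebellum_dx"))
        mesh = build_surface_mesh(lm, labels, n_theta, target_points=len(lm))
        return vol, mesh, mask

    def test_uniform_cerebellum_max_equals_plateau(self, cerebellar_ball):
        vol, mesh, mask = cerebellar_ball
        ref = compute_reference_value(vol, mesh, mask, "cerebellum_max")
        assert ref.reference_raw == pytest.approx(50.0)

    def test_single_hot_voxel_averaged_with_26_neighbours(self, cerebellar_ball):
        """One interior voxel at c+27 raises the 27-voxel neighbourhood mean
        by exactly 1."""
        vol, mesh, mask = cerebellar_ball
        vol.data[15, 15, 15] = 50.0 + 27.0
        ref = compute_reference_value(vol, mesh, mask, "cerebellum_max")
        assert ref.reference_raw == pytest.approx(51.0)

    def test_cortex_mean_on_uniform_shell(self, sphere_shell):
        vol, brain, lm, n_theta = sphere_shell
        labels = np.full(len(lm), REGIONS.index("parietal_dx"))
        mesh = build_surface_mesh(lm, labels, n_theta, target_points=600)
        scaled = Volume(vol.data * 0.8, vol.spacing)  # shell at 80
        ref = compute_reference_value(scaled, mesh, brain, "cortex_mean")
        assert ref.reference_raw == pytest.approx(80.0, abs=1.0)

    def test_cerebellum_mean_uses_only_cerebellar_points(self, sphere_shell):
        """Cerebellar points over a hot (doubled) hemisphere must set the
        reference from those points alone."""
        vol, brain, lm, n_theta = sphere_shell
        labels = np.where(
            lm.points[:, 2] < 0,
            REGIONS.index("cerebellum_dx"),
            REGIONS.index("frontal_dx"),
        )
        data = vol.data.copy()
        mesh = build_surface_mesh(lm, labels, n_theta, target_points=len(lm))
        ref = compute_reference_value(Volume(data, vol.spacing), mesh, brain, "cerebellum_mean")
        assert ref.reference_raw == pytest.approx(100.0, abs=1.0)
        # doubling only the inferior (cerebellar) hemisphere doubles the reference
        hot = data.copy()
        half = np.arange(64) < 32  # z < 0
        hot[:, :, half] *= 2.0
        ref2 = compute_reference_value(Volume(hot, vol.spacing), mesh, brain, "cerebellum_mean")
        assert ref2.reference_raw == pytest.approx(200.0, abs=6.0)

    def test_unknown_method_rejected(self, cerebellar_ball):
        vol, mesh, mask = cerebellar_ball
        with pytest.raises(ValueError):
            compute_reference_value(vol, mesh, mask, "whole_brain")

    def test_non_positive_reference_rejected(self):
        with pytest.raises(DataError):
            NormalizationResult(method="cortex_mean", reference_raw=0.0)


class TestNormalization:
    def test_scaling_and_idempotence(self):
        vol = Volume(np.full((8, 8, 8), 50.0))
        ref = NormalizationResult(method="cortex_mean", reference_raw=50.0)
        out = normalize_volume(vol, ref)
        assert np.allclose(out.data, 100.0)
        ref100 = NormalizationResult(method="cortex_mean", reference_raw=100.0)
        again = normalize_volume(out, ref100)
        assert np.allclose(again.data, out.data, atol=1e-6)

    def test_reference_statistic_is_100_after_normalization(self, labelled_phantom):
        spec, vol, truth, mesh = labelled_phantom
        for method in ("cerebellum_mean", "cerebellum_max", "cortex_mean"):
            ref = compute_reference_value(vol, mesh, truth.brain_mask, method)
            normed = normalize_volume(vol, ref)
            ref2 = compute_reference_value(normed, mesh, truth.brain_mask, method)
            assert ref2.reference_raw == pytest.approx(100.0, abs=1e-6)

    def test_cross_normalization_identity(self, analysis):
        """Cortex-normalized region means equal cerebellum-normalized means
        times the cerebellar value under cortex normalization / 100 - an
        algebraic identity of global rescaling."""
        rep = analysis.report
        cb = rep.methods["cerebellum_mean"].region_means
        cx = rep.methods["cortex_mean"].region_means
        factor = cx["cerebellum"] / 100.0
        for region in REPORT_REGIONS:
            assert cx[region] == pytest.approx(cb[region] * factor, abs=1e-6)


class TestRegionalStatistics:
    def test_means_match_bruteforce_oracle(self, labelled_phantom):
        *_, mesh = labelled_phantom
        rng = np.random.default_rng(0)
        values = rng.uniform(10, 200, len(mesh))
        means = regional_means(values, mesh)
        cb_labels = [REGIONS.index("cerebellum_dx"), REGIONS.index("cerebellum_sin")]
        for region in REPORT_REGIONS:
            if region == "cerebellum":
                sel = np.isin(mesh.lobe_labels, cb_labels)
            else:
                sel = mesh.lobe_labels == REGIONS.index(region)
            assert means[region] == pytest.approx(values[sel].mean())

    def test_uniform_and_single_region_offsets(self, labelled_phantom):
        *_, mesh = labelled_phantom
        values = np.full(len(mesh), 100.0)
        assert all(v == pytest.approx(100.0) for v in regional_means(values, mesh).values())
        values[mesh.region_indices("frontal_dx")] = 80.0
        means = regional_means(values, mesh)
        assert means["frontal_dx"] == pytest.approx(80.0)
        assert means["occipital"] == pytest.approx(100.0)

    def test_asymmetry_worked_example(self):
        assert asymmetry_index(110.0, 90.0) == pytest.approx(20.0)
        assert asymmetry_index(100.0, 100.0) == 0.0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(sin=st.floats(1.0, 200.0), dx=st.floats(1.0, 200.0))
    def test_asymmetry_antisymmetric(self, sin, dx):
        assert asymmetry_index(sin, dx) == pytest.approx(-asymmetry_index(dx, sin))

    def test_asymmetry_rejects_non_positive(self):
        with pytest.raises(DataError):
            asymmetry_index(0.0, 50.0)

    def test_cortical_index_thresholds(self):
        data = np.zeros((10, 10, 10))
        mask = np.zeros_like(data, dtype=bool)
        mask[:, :, :] = True
        data[:5] = 100.0
        data[5:] = 10.0
        assert cortical_index(Volume(data), mask) == pytest.approx(50.0)
        data[:] = 100.0
        assert cortical_index(Volume(data), mask) == pytest.approx(100.0)
        data[:] = 45.0  # "at least 45%" is inclusive
        assert cortical_index(Volume(data), mask) == pytest.approx(100.0)
        with pytest.raises(DataError):
            cortical_index(Volume(data), np.zeros_like(mask))

    def test_low_value_fraction(self):
        values = np.full(3010, 100.0)
        assert low_value_fraction(values) == 0.0
        values[:15] = 10.0
        assert low_value_fraction(values) == pytest.approx(100.0 * 15 / 3010)
        assert low_value_fraction(values, threshold_pct=0.0) == 0.0

    def test_empty_region_raises(self):
        lm, n_theta = sphere_landmarks(n_rings=4, n_theta=10)
        labels = np.zeros(len(lm), dtype=int)  # everything cerebellum_dx
        mesh = build_surface_mesh(lm, labels, n_theta, target_points=len(lm))
        with pytest.raises(AtlasError):
            regional_means(np.ones(len(mesh)), mesh)


class TestFullReport:
    def test_report_round_trips_through_json(self, tmp_path, analysis):
        rep = analysis.report
        path = tmp_path / "report.json"
        rep.to_json(str(path))
        from asmbrain.quantify import RegionalReport

        back = RegionalReport.from_json(str(path))
        assert back.n_points == rep.n_points
        for m in rep.methods:
            assert back.methods[m].region_means == pytest.approx(rep.methods[m].region_means)
            assert np.allclose(back.methods[m].point_values, rep.methods[m].point_values)

    def test_report_frame_covers_all_regions_and_methods(self, analysis):
        df = analysis.report.to_frame()
        assert set(df["region"]) == set(REPORT_REGIONS)
        assert set(df["normalization"]) == {
            "cerebellum_mean", "cerebellum_max", "cortex_mean",
        }
        assert len(df) == 39  # 13 regions x 3 normalizations
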