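"""End-to-end convenience wrappers: train a model + atlas on synthetic data,
and run the five analysis steps (rotate, delineate, normalize, project,
index) on a new volume."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .asm_fit import FitConfig, FitResult, fit_active_shape
from .atlas_normals import LobeAtlas, assign_lobes
from .orient import OrientConfig, RotationEstimate, estimate_rotation, rotate_volume
from .phantom import (
    PhantomSpec,
    ShapeVariation,
    base_landmarks,
    generate_lobe_phantom,
    generate_training_set,
    interior_mask,
)
from .quantify import RegionalReport, SurfaceMesh, build_surface_mesh, quantify_volume
from .regions import REGIONS
from .shape_model import (
    ShapeModel,
    align_shapes,
    build_shape_model,
    similarity_fit,
)
from .volume import Volume

DEFAULT_N_TRAINING = 29
DEFAULT_N_MODES = 5


def train_default_model(
    n_training: int = DEFAULT_N_TRAINING,
    n_modes: int = DEFAULT_N_MODES,
    seed: int = 0,
    spec: PhantomSpec | None = None,
    variation: ShapeVariation | None = None,
) -> tuple[ShapeModel, LobeAtlas]:
    """Build the point-distribution model and the symmetric lobe atlas from
    synthetic training surfaces and single-lobe phantoms."""
    spec = spec or PhantomSpec()
    shapes = generate_training_set(n_training, spec, variation, seed=seed)
    aligned, frame = align_shapes(shapes)
    model = build_shape_model(aligned, n_modes, frame=frame, n_theta=spec.n_theta)

    # register the model mean into the phantom/atlas frame before sampling
    base = base_landmarks(spec)
    s, R, t = similarity_fit(model.mean_shape.points, base.points)
    transform = (s, R, t)
    phantoms = {region: generate_lobe_phantom(spec, region) for region in REGIONS}
    atlas = assign_lobes(model, phantoms, transform=transform)
    return model, atlas


@dataclass
class AnalysisResult:
    report: RegionalReport
    fit: FitResult
    mesh: SurfaceMesh
    rotation: RotationEstimate
    brain_mask: np.ndarray
    oriented_volume: Volume


def analyze_volume(
    volume: Volume,
    model: ShapeModel,
    atlas: LobeAtlas,
    fit_config: FitConfig | None = None,
    orient_config: OrientConfig | None = None,
    rotation_deg: float | None = None,
    target_points: int = 3010,
) -> AnalysisResult:
    """Run the full automated analysis on one reconstructed volume.

    ``rotation_deg`` overrides the automatic tilt estimate (manual
    correction); pass 0 to skip rotation entirely.
    """
    est = estimate_rotation(volume, orient_config)
    angle = est.angle_deg if rotation_deg is None else rotation_deg
    oriented = rotate_volume(volume, -angle) if angle else volume
    fit = fit_active_shape(model, oriented, fit_config)
    mesh = build_surface_mesh(fit.landmarks, atlas, model.n_theta, target_points)
    mask = interior_mask(
        fit.landmarks, model.n_theta, volume.shape[0], volume.spacing[0]
    )
    report = quantify_volume(oriented, mesh, mask)
    return AnalysisResult(
        report=report,
        fit=fit,
        mesh=mesh,
        rotation=est,
        brain_mask=mask,
        oriented_volume=oriented,
    )
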