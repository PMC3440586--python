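"""Shared fixtures: a trained model/atlas and analyses of standard phantoms.

Everything is generated programmatically; session scope keeps the expensive
pieces (model training, active-shape fits) to one run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from asmbrain import (
    PhantomSpec,
    ShapeParams,
    Uptake,
    Volume,
    analyze_volume,
    base_landmarks,
    fit_active_shape,
    generate_brain_phantom,
    generate_phantom_from_landmarks,
    synthesize_shape,
    train_default_model,
)
from asmbrain.shape_model import similarity_fit


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    return PhantomSpec(counts_scale=0.0)


@pytest.fixture(scope="session")
def trained(noiseless_spec):
    """Shape model + symmetric lobe atlas trained on 29 synthetic surfaces."""
    return train_default_model(n_training=29, n_modes=5, seed=1, spec=noiseless_spec)


@pytest.fixture(scope="session")
def default_phantom(noiseless_spec):
    return generate_brain_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def analysis(trained, default_phantom):
    """Full pipeline run on the noiseless default phantom."""
    model, atlas = trained
    volume, _ = default_phantom
    return analyze_volume(volume, model, atlas)


@pytest.fixture(scope="session")
def mirrored_analysis(trained, default_phantom):
    """Same pipeline on the left-right flipped phantom volume."""
    model, atlas = trained
    volume, _ = default_phantom
    flipped = Volume(np.flip(volume.data, axis=0).copy(), volume.spacing)
    return analyze_volume(flipped, model, atlas)


@pytest.fixture(scope="session")
def uniform_analysis(trained):
    """Pipeline on a phantom with uniform brain uptake and a cold ventricle."""
    model, atlas = trained
    spec = PhantomSpec(
        counts_scale=0.0,
        uptake=Uptake(cortex=100, white=100, ventricle=0, cerebellum=100, background=0),
    )
    volume, truth = generate_brain_phantom(spec)
    return analyze_volume(volume, model, atlas), truth


@pytest.fixture(scope="session")
def recovery(trained, noiseless_spec):
    """Ground-truth surface synthesized from the model, its noiseless phantom,
    and the active-shape fit of that phantom."""
    model, _ = trained
    rng = np.random.default_rng(2)
    b_true = rng.standard_normal(5) * 0.7 * np.sqrt(model.eigenvalues)
    base = base_landmarks(noiseless_spec)
    s, R, t = similarity_fit(model.mean_shape.points, base.points)
    lm_true = synthesize_shape(
        model, ShapeParams(b=b_true, scale=s, rotation=R, translation=t)
    )
    volume, brain_mask = generate_phantom_from_landmarks(lm_true, noiseless_spec)
    fit = fit_active_shape(model, volume)
    return {
        "model": model,
        "b_true": b_true,
        "lm_true": lm_true,
        "volume": volume,
        "brain_mask": brain_mask,
        "fit": fit,
    }
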