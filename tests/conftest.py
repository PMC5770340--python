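"""Shared fixtures: full-scale synthetic fits reused across test modules.

The fits are expensive (minutes), so they are session-scoped and shared by
the structural-invariant and parameter-recovery tests.
"""

import numpy as np
import pytest

from genatlas import AtlasConfig, AtlasModel, PhantomSpec, sample_population


STANDARD_SPEC = dict(
    n_subjects=4, n_classes=3, n_channels=2, shape=(24, 24, 24),
    bias_amplitude=0.1, deformation_amplitude=1.0,
)


def run_standard_fit(noise, seed=11, max_outer=8, **cfg_kw):
    spec = PhantomSpec(noise_level=noise, **STANDARD_SPEC)
    phantom = sample_population(spec, seed=seed)
    cfg = AtlasConfig(n_classes=3, affine_warmup=2, max_outer=max_outer, **cfg_kw)
    model = AtlasModel(phantom.volumes, config=cfg)
    results = model.fit()
    return phantom, results


@pytest.fixture(scope="session")
def standard_fit():
    """4-subject, 24^3, K=3, D=2 fit at 3% noise and 10% bias amplitude."""
    return run_standard_fit(noise=0.03)


@pytest.fixture(scope="session")
def noise_sweep_fits(standard_fit):
    """Fits at 1%, 3% and 7% noise under otherwise identical conditions."""
    low = run_standard_fit(noise=0.01, max_outer=6)
    mid = run_standard_fit(noise=0.03, max_outer=6)
    high = run_standard_fit(noise=0.07, max_outer=6)
    return {0.01: low, 0.03: mid, 0.07: high}


@pytest.fixture(scope="session")
def labelled_roundtrip_fit():
    """Noise-free, bias-free, deformation-free, fully labelled population."""
    spec = PhantomSpec(
        n_subjects=4, n_classes=3, n_channels=2, shape=(24, 24, 24),
        noise_level=0.002, bias_amplitude=0.0, deformation_amplitude=0.0,
        translation_sd=0.0, rotation_sd=0.0, zoom_shear_sd=0.0,
        label_fraction=1.0,
    )
    phantom = sample_population(spec, seed=21)
    cfg = AtlasConfig(n_classes=3, affine_warmup=1, max_outer=4)
    model = AtlasModel(phantom.volumes, labels=phantom.training_labels, config=cfg)
    return phantom, model.fit()


@pytest.fixture(scope="session")
def displaced_fit():
    """Phantoms displaced by a few voxels, fitted against the frozen truth
    template with the diffeomorphism disabled (affine recovery probe)."""
    spec = PhantomSpec(
        n_subjects=2, n_classes=3, n_channels=2, shape=(24, 24, 24),
        noise_level=0.01, bias_amplitude=0.0, deformation_amplitude=0.0,
        translation_sd=1.8, rotation_sd=0.0, zoom_shear_sd=0.0,
    )
    phantom = sample_population(spec, seed=31)
    cfg = AtlasConfig(
        n_classes=3, affine_warmup=0, max_outer=10,
        update_velocity=False, update_bias=False, update_weights=False,
    )
    model = AtlasModel(phantom.volumes, config=cfg,
                       template=phantom.truth_template)
    return phantom, model.fit()
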