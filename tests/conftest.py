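"""Shared fixtures: all volumes are generated at test time by the phantom module."""

from __future__ import annotations

import numpy as np
import pytest

from pancad import PipelineConfig, generate_phantom, generate_study
from pancad.phantom import PhantomSpec


def cylinder_spec(spacing: float = 1.0) -> PhantomSpec:
    """Straight coaxial-cylinder phantom: duct r=2 mm inside parenchyma R=10 mm,
    axis length 100 mm, no noise, no tumor."""
    return PhantomSpec(
        grid_shape=tuple(int(round(n / spacing)) for n in (128, 50, 50)),
        voxel_spacing=(spacing,) * 3,
        curve_control_points=[(14, 25, 25), (114, 25, 25)],
        parenchyma_radius_profile=10.0,
        duct_radius_profile=2.0,
        surface_noise_sd=0.0,
        heatmap_noise_sd=0.0,
        n_distractor_blobs=0,
        seed=0,
    )


@pytest.fixture(scope="session")
def cylinder_case():
    spec = cylinder_spec(1.0)
    par, duct, heat, truth = generate_phantom(spec)
    return spec, par, duct, heat, truth


@pytest.fixture(scope="session")
def cylinder_case_halfmm():
    spec = cylinder_spec(0.5)
    par, duct, heat, truth = generate_phantom(spec)
    return spec, par, duct, heat, truth


@pytest.fixture(scope="session")
def diseased_case():
    """Curved cancer phantom with a 2x duct dilation at mid-organ and mild noise."""
    spec = PhantomSpec(
        tumor_present=True,
        tumor_arclength_fraction=0.5,
        dilation_factor=2.0,
        atrophy_factor=0.85,
        surface_noise_sd=0.05,
        seed=3,
    )
    par, duct, heat, truth = generate_phantom(spec)
    return spec, par, duct, heat, truth


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """Small calibration + test cohort on disk, with manifest."""
    out = tmp_path_factory.mktemp("study")
    manifest = generate_study(5, 5, 7, 7, out, seed=11)
    return out, manifest


@pytest.fixture(scope="session")
def study_report(study_dir, tmp_path_factory):
    from pancad import run_pipeline

    out_dir = tmp_path_factory.mktemp("report")
    _, manifest = study_dir
    report = run_pipeline(manifest, PipelineConfig(), out_dir=out_dir)
    return out_dir, report
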