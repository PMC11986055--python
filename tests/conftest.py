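import pytest

from fetalmrsim import (
    GHMRFConfig,
    PhantomSpec,
    build_alpha_schedule,
    build_quantitative_maps,
    extract_mask,
    fit_ghmrf,
    generate_phantom,
    merge_to_three_classes,
    sample_subject_properties,
    sequence_preset,
)


@pytest.fixture(scope="session")
def phantom48():
    """A mid-gestation phantom shared by read-only tests."""
    return generate_phantom(
        PhantomSpec(grid_shape=(48, 48, 48), ga_weeks=28.0, seed=3))


@pytest.fixture(scope="session")
def class_map48(phantom48):
    return merge_to_three_classes(phantom48)


@pytest.fixture(scope="session")
def qmaps48(phantom48, class_map48):
    wm = extract_mask(class_map48, "WM")
    pv, _, _ = fit_ghmrf(phantom48.intensity, wm,
                         GHMRFConfig(em_max_iter=40, bias_iterations=2),
                         spacing_mm=phantom48.spacing,
                         affine=phantom48.affine)
    props = sample_subject_properties(1.5, seed=11)
    schedule = build_alpha_schedule({g: 10.0 - 0.2 * (g - 21)
                                     for g in range(21, 39)})
    return build_quantitative_maps(class_map48, pv, props, schedule,
                                   phantom48.ga_weeks)


@pytest.fixture()
def small_params():
    """A miniature, fully sampled acquisition for fast series tests."""
    return sequence_preset(
        "HASTE", 1.5,
        te_eff_ms=80.0, echo_spacing_ms=10.0, etl=64, flip_refoc_deg=180.0,
        phase_oversampling_pct=0.0, fov_read_mm=40.0, base_resolution=32,
        phase_resolution_pct=100.0, recon_matrix=32, zero_fill=False,
        accel_factor=1, reference_lines=0, noise_sd=0.0)
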