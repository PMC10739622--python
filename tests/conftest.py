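import pytest

from petdenoise import (
    CountModel,
    FrameSchedule,
    default_kinetics,
    default_region_map,
    feng_aif,
    render_phantom,
)
from petdenoise.pipeline import run_demo


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def aif():
    return feng_aif()


@pytest.fixture(scope="session")
def small_phantom(schedule, aif):
    """Noise-free 20×20×14 phantom (no PSF blur, no texture) plus its regions."""
    regions = default_region_map((20, 20, 14))
    truth = default_kinetics()
    img = render_phantom(regions, truth, aif, schedule, psf_fwhm=0.0)
    return img, regions, truth


@pytest.fixture(scope="session")
def noisy_phantom(small_phantom):
    """Full-count draw plus ten 1/10-count partitions of the small phantom."""
    from petdenoise import calibrate_sensitivity, poisson_realizations

    img, regions, _ = small_phantom
    sens = calibrate_sensitivity(img, regions.brain_mask, 50.0)
    counts = CountModel(sensitivity=sens, seed=123)
    full, reduced, full_counts, reduced_counts = poisson_realizations(
        img, counts, return_counts=True
    )
    return full, reduced, full_counts, reduced_counts


@pytest.fixture(scope="session")
def demo_result():
    """One seeded end-to-end workflow run shared by the slow checks."""
    return run_demo(seed=1)


def roi_mean(table, method, parameter, target, column):
    """ROI-averaged value of one table cell group."""
    sub = table[
        (table["method"] == method)
        & (table["parameter"] == parameter)
        & (table["target"] == target)
    ]
    assert len(sub) > 0, f"no rows for {method} {parameter} {target}"
    return float(sub[column].mean())
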