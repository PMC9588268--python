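from __future__ import annotations

import numpy as np
import pytest

from bctseg import PhantomSpec, default_calibration, generate_phantom, phantom_cohort, run_pipeline


@pytest.fixture(scope="session")
def cal():
    return default_calibration()


def small_spec(**kwargs) -> PhantomSpec:
    """Reduced phantom for unit tests: 64x64x72 at 1 mm spacing.

    Voxel-defined kernels (5x5x5 erosion) require the rib rods to stay
    thicker than two voxels, hence the larger rib radius.
    """
    base = dict(
        shape=(64, 64, 72),
        spacing_mm=1.0,
        breast_radius_mm=20.0,
        breast_length_mm=50.0,
        muscle_thickness_mm=9.0,
        fold_length_mm=22.0,
        rib_radius_mm=3.5,
        implant_radius_mm=16.0,
    )
    base.update(kwargs)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_phantom():
    """Mid-density phantom with muscle for shared read-only use."""
    return generate_phantom(small_spec(glandular_fraction=0.3, include_muscle=True, rng_seed=5))


@pytest.fixture(scope="session")
def cohort_results():
    """The standard 10-phantom evaluation cohort, fully segmented.

    Session-scoped: generation plus the four-stage pipeline run once and
    are shared by the acceptance tests.
    """
    import time

    cohort = phantom_cohort(10, seed=1)
    results = []
    for volume, truth in cohort:
        t0 = time.perf_counter()
        res = run_pipeline(volume)
        results.append((volume, truth, res, time.perf_counter() - t0))
    return results


def component_dscs(truth, result) -> dict[str, float]:
    """Per-component DSC of predicted vs ground-truth labels (0 when one
    side is empty and the other is not)."""
    from bctseg import dsc

    out = {}
    for name in ("skin", "muscle", "skinfold", "rib", "implant", "gland"):
        a = result.labels.mask(name)
        b = truth.labels.mask(name)
        if a.any() and b.any():
            out[name] = dsc(a, b)
        elif a.any() != b.any():
            out[name] = 0.0
    return out
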