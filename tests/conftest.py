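import numpy as np
import pytest

from fluorad import pipeline, segmentation, synthdata


@pytest.fixture(scope="session")
def default_study():
    """One full default study replica (8+8 pairs per phantom, 2 in-vivo
    subjects, full filter bank) at a fixed master seed; shared by all tests
    that inspect study-level behavior."""
    return pipeline.run_study(pipeline.StudyConfig(master_seed=1))


@pytest.fixture()
def phantom_scan_pair():
    """A segmented intrasession phantom pair at moderate noise."""
    spec = synthdata.default_phantom()
    acq = synthdata.default_acquisition()
    test, retest = synthdata.simulate_test_retest(
        spec, acq, "intrasession", seeds=(11, 12)
    )
    noise = synthdata.acquire_noise_scan(acq, 13)
    profile = segmentation.estimate_noise(noise)
    priors = [
        segmentation.RegionPrior(t.center, f"tube{i + 1}")
        for i, t in enumerate(spec.tubes)
        if t.f19_mm > 0
    ]
    masks = [
        segmentation.delineate_rois(
            segmentation.threshold_mask(v, profile), priors, acq.spacing
        )
        for v in (test, retest)
    ]
    return (test, retest), masks, spec, acq


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
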