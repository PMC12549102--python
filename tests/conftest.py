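import pytest

from fetalcwas import synthetic


@pytest.fixture(scope="session")
def small_labels():
    return synthetic.roi_labels(30)


@pytest.fixture(scope="session")
def small_null_cohort():
    """30-ROI, 5-module cohort with no planted effect (seeded)."""
    spec = synthetic.CohortSpec(
        n_subjects=40,
        n_rois=30,
        n_modules=5,
        n_volumes=110,
        motion_spike_prob=0.0,
        seed=123,
    )
    return synthetic.generate_cohort(spec)
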