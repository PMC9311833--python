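import pytest

from perfuse_sudep import default_atlas, generate_roi_cohort, paperlike_config
from perfuse_sudep.pipeline import RunConfig, stage_quantify


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def noisefree_cohort(atlas):
    """Paperlike cohort with zero observation noise: planted point-mass levels."""
    return generate_roi_cohort(paperlike_config(seed=42, noise_sd=0.0), atlas)


@pytest.fixture(scope="session")
def noisy_cohort(atlas):
    """Paperlike cohort at the default observation noise (sd 0.02)."""
    return generate_roi_cohort(paperlike_config(seed=42, noise_sd=0.02), atlas)


@pytest.fixture(scope="session")
def noisefree_vectors(noisefree_cohort, atlas):
    cfg = RunConfig(seed=42, noise_sd=0.0)
    return stage_quantify(noisefree_cohort.tables, noisefree_cohort.clinical, atlas, cfg)


@pytest.fixture(scope="session")
def noisy_vectors(noisy_cohort, atlas):
    cfg = RunConfig(seed=42)
    return stage_quantify(noisy_cohort.tables, noisy_cohort.clinical, atlas, cfg)
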