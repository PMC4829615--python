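import pytest

from slowosc.bands import make_band_scheme
from slowosc.ica import GroupICAConfig
from slowosc.simulate import GroundTruthSpec, default_components, simulate_cohort

TR = 2.6
N_VOLUMES = 230
NYQUIST = 0.5 / TR


@pytest.fixture(scope="session")
def scheme():
    return make_band_scheme(NYQUIST)


@pytest.fixture(scope="session")
def small_components():
    """Five planted networks on a reduced 10x12x10 grid."""
    return default_components(grid=(10, 12, 10))


@pytest.fixture(scope="session")
def small_cohort(small_components):
    """12-subject volumetric cohort on the reduced grid, with ground truth."""
    spec = GroundTruthSpec(
        n_subjects_per_group={g: 3 for g in ("young", "old", "stroke_early", "stroke_late")},
        components=small_components,
        seed=11,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_ica_config():
    return GroupICAConfig(n_components=6, subject_pca_dim=9, seed=0, n_stability_runs=5)
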