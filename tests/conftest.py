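import numpy as np
import pytest

from stainshift.synthetic_cohort import CohortConfig, make_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def small_cohort_config(**overrides) -> CohortConfig:
    """Desk-scale cohort for unit tests; photometric effects kept on."""
    defaults = dict(
        n_train=40,
        n_validation=12,
        n_internal_test=20,
        n_external_test=40,
        seed=7,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def clean_cohort_config(**overrides) -> CohortConfig:
    """As above but with neutral gain/offset/noise, for estimation tests."""
    return small_cohort_config(
        brightness_scale=0.0,
        gain_scale=0.0,
        noise_sd_range=(0.0, 0.0),
        external_noise_sd_range=(0.0, 0.0),
        **overrides,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One shared small cohort (records + manifest) for read-only tests."""
    config = small_cohort_config()
    records, manifest = make_cohort(config)
    return config, records, manifest


def stain_assignment_error(estimate, truth):
    """Worst-row angular error under the best row assignment (the H/E
    labeling of an arbitrary random stain pair is not identifiable)."""
    import numpy as _np

    direct = estimate.angular_distance(truth).max()
    from stainshift.stain_model import StainMatrix

    swapped = StainMatrix(estimate.rows[::-1]).angular_distance(truth).max()
    return float(_np.minimum(direct, swapped))


def random_stain_matrix(rng, min_separation_deg=20.0):
    """Random unit-row non-negative stain matrix with separated rows."""
    from stainshift.stain_model import StainMatrix

    while True:
        rows = rng.uniform(0.05, 1.0, size=(2, 3))
        rows /= np.linalg.norm(rows, axis=1, keepdims=True)
        cosang = np.clip(np.dot(rows[0], rows[1]), -1, 1)
        if np.degrees(np.arccos(cosang)) >= min_separation_deg:
            return StainMatrix(rows)
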