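import dataclasses

import pytest

from gaitmix import CohortConfig, simulate_cohort
from gaitmix.gmm import GMMSpec, fit_gmm


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized cohort (41 HC, 47 LRP, 15 HRP), fixed seed."""
    return simulate_cohort(CohortConfig(seed=1234))


@pytest.fixture(scope="session")
def ms_cohort():
    """MS subjects only (47 LRP / 15 HRP) for baseline clustering."""
    return simulate_cohort(CohortConfig(n_hc=0, seed=77))


@pytest.fixture(scope="session")
def ms_fit2(ms_cohort):
    """A converged two-class mixture fit on the MS cohort."""
    subjects, gait, _ = ms_cohort
    return fit_gmm(gait, subjects, GMMSpec(n_classes=2, n_starts=5, seed=5))


def separated_config(seed=0, n_per_class=10, noise=1e-3):
    """Two far-apart classes with no BMI effect and no random intercept,
    for degenerate-recovery tests (bmi_effect=0 keeps the noiseless speeds
    exactly on the group mean curves while BMI still varies, so the
    covariate coefficient stays identifiable)."""
    from gaitmix.synthetic import GroupCurve

    return dataclasses.replace(
        CohortConfig(n_hc=0, n_lrp=n_per_class, n_hrp=n_per_class, seed=seed),
        curves={
            "HC": GroupCurve(357.0, -12.2, 2.2, 0.0),
            "LRP": GroupCurve(320.0, -10.0, 2.0, 0.0),
            "HRP": GroupCurve(245.0, -5.0, 0.5, 0.0),
        },
        bmi_effect=0.0,
        sd_random_intercept=0.0,
        sd_residual=noise,
    )
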