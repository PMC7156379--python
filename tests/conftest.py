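import numpy as np
import pytest

from icbsex import synth
from icbsex.dataio import TrialRecord

COVARIATES = ["age", "purity", "race", "smoking", "stage", "histology"]


def make_trial(trial_id="t1", hr_f=0.8, hr_m=0.6, width=1.5, **kw):
    """A valid TrialRecord with symmetric multiplicative CI bounds."""
    fields = dict(
        trial_id=trial_id,
        cancer_type=kw.pop("cancer_type", "melanoma"),
        therapy_class=kw.pop("therapy_class", "anti-PD-1/PD-L1"),
        control_arm=kw.pop("control_arm", "chemotherapy"),
        hr_female=hr_f,
        ci_female_lo=hr_f / width,
        ci_female_hi=hr_f * width,
        hr_male=hr_m,
        ci_male_lo=hr_m / width,
        ci_male_hi=hr_m * width,
        n_female=100,
        n_male=150,
    )
    fields.update(kw)
    return TrialRecord(**fields)


@pytest.fixture(scope="session")
def trial_panel():
    """The frozen synthetic 27-trial panel (deterministic)."""
    return synth.synthetic_trial_panel()


@pytest.fixture(scope="session")
def confounded_cohort():
    """One confounded cohort with 45 null + 5 signal features."""
    spec = synth.default_cohort_spec(seed=11)
    return synth.simulate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
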