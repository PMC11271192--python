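import numpy as np
import pytest

import metscore as ms

#: boosted-prevalence map used where per-profile/per-cell statistics need
#: enough MetS-positive samples to be estimable
BOOSTED_PREVALENCE = {
    "0000": 0.40, "0010": 0.10, "0110": 0.10, "1000": 0.10,
    "1011": 0.10, "1101": 0.05, "1110": 0.05, "1111": 0.10,
}


@pytest.fixture(scope="session")
def default_cfg():
    return ms.default_config(n_samples=2000, seed=11)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    return ms.generate_cohort(default_cfg)


@pytest.fixture(scope="session")
def fitted(cohort):
    return ms.MetScorePipeline().fit(cohort)


@pytest.fixture(scope="session")
def boosted_cohort():
    cfg = ms.default_config(n_samples=1200, seed=5)
    prev = {c: 0.0 for c in ms.ALL_CODES}
    prev.update(BOOSTED_PREVALENCE)
    cfg.profile_prevalence = prev
    return ms.generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    cfg = ms.default_config(n_samples=4000, seed=3, effect_scale=0.0)
    return ms.generate_cohort(cfg)
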