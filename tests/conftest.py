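import warnings

import numpy as np
import pandas as pd
import pytest

from ccmicrobiota import CohortConfig, SampleMetadata, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (49+49 infants, 130 taxa)."""
    return generate_cohort(CohortConfig(seed=123))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast model fits."""
    return generate_cohort(
        CohortConfig(seed=7, n_per_group=10, n_taxa=15,
                     bf_missing_cc=1, bf_missing_home=1)
    )


@pytest.fixture(scope="session")
def small_complete_cohort():
    """Reduced cohort with no missing breastfeeding data."""
    return generate_cohort(
        CohortConfig(seed=7, n_per_group=10, n_taxa=15,
                     bf_missing_cc=0, bf_missing_home=0)
    )


def tiny_metadata() -> SampleMetadata:
    """Hand-built 3-infant metadata table."""
    rows = []
    for k, (grp, sib, csec) in enumerate(
        [("CC", True, False), ("CC", False, False), ("HOME", False, True)]
    ):
        iid = f"I{k}"
        for tp, age in (("PRE", 80.0 + k), ("POST", 110.0 + k)):
            rows.append(
                dict(
                    sample_id=f"{iid}_{tp}",
                    infant_id=iid,
                    group=grp,
                    timepoint=tp,
                    age_days=age,
                    bf_rate=5.0 - k,
                    bf_rate_prior_period=6.0 - k,
                    sibling=sib,
                    csection=csec,
                )
            )
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture()
def tiny_meta():
    return tiny_metadata()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
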