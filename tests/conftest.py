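import numpy as np
import pytest

import eegnld


@pytest.fixture(scope="session")
def default_recording():
    """One standard synthetic recording: 19 channels, 250 Hz, 30 s."""
    spec = eegnld.CohortSpec(seed=5)
    return eegnld.generate_recording("ASD", 8.0, spec, 501, age_months=6.0)

@pytest.fixture(scope="session")
def default_features(default_recording):
    return eegnld.extract_features(default_recording)


@pytest.fixture(scope="session")
def separable_cohort():
    """Featurized strongly separable cohort: 20 ASD + 20 controls + 6 HRA.

    The expensive shared fixture behind the end-to-end protocol tests.
    Returns (table, outcomes) where table rows parallel the outcomes.
    """
    spec = eegnld.CohortSpec(
        n_per_group=20, groups=("LRC-", "ASD"), effect_size=1.0, seed=11,
    )
    recs, outs = eegnld.generate_cohort(spec)
    hra_spec = eegnld.CohortSpec(
        n_per_group=6, groups=("HRA-",), effect_size=1.0, seed=12,
    )
    h_recs, h_outs = eegnld.generate_cohort(hra_spec)
    recs += h_recs
    outs += h_outs
    table = eegnld.feature_table(recs, outs)
    return table, outs


def feature_matrix(table):
    names = eegnld.feature_names()
    return table[names].to_numpy(dtype=float)
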