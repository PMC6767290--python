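"""Shared fixtures: simulated cohorts and their LOTO evaluations.

The default cohort (40 subjects x 1 trial at the default noise levels,
seed 0) is expensive enough to share session-wide; the noiseless trial
fixtures are cheap but reused across modules.
"""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import siptrack as st

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_cfg() -> st.SimConfig:
    return st.SimConfig(n_subjects=3, trials_per_subject=1, seed=11).noiseless()


@pytest.fixture(scope="session")
def noiseless_trials(noiseless_cfg):
    return st.simulate_cohort(noiseless_cfg)


@pytest.fixture(scope="session")
def default_cfg() -> st.SimConfig:
    return st.SimConfig()  # 40 subjects x 1 trial, default noise, seed 0


@pytest.fixture(scope="session")
def default_cohort(default_cfg):
    return st.simulate_cohort(default_cfg)


@pytest.fixture(scope="session")
def cohort_df(default_cohort) -> pd.DataFrame:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return st.drink_table([(tr.recording, tr.labels) for tr in default_cohort])


def _loto(df, spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return st.evaluate_spec(df, spec)


@pytest.fixture(scope="session")
def volume_svm_eval(cohort_df):
    return _loto(cohort_df, st.ModelSpec(target="volume", model="svm", kernel="medium"))


@pytest.fixture(scope="session")
def volume_duration_lr_eval(cohort_df):
    return _loto(
        cohort_df,
        st.ModelSpec(target="volume", model="lr_single", lr_feature="sip_duration_s"),
    )


@pytest.fixture(scope="session")
def fill_ratio_svm_eval(cohort_df):
    return _loto(
        cohort_df, st.ModelSpec(target="fill_ratio", model="svm", kernel="coarse")
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
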