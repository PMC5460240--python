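import numpy as np
import pytest

from translearn.drugs import midazolam_mean_model, torsemide_mean_model
from translearn.pbpk import default_physiology
from translearn.synth import Administration, STUDY_DOSES_MG, STUDY_TIMES


@pytest.fixture(scope="session")
def midazolam_pair():
    return midazolam_mean_model()


@pytest.fixture(scope="session")
def torsemide_pair():
    return torsemide_mean_model()


@pytest.fixture(scope="session")
def midazolam_adm(midazolam_pair):
    return Administration(*midazolam_pair, STUDY_DOSES_MG["midazolam"])


@pytest.fixture(scope="session")
def torsemide_adm(torsemide_pair):
    return Administration(*torsemide_pair, STUDY_DOSES_MG["torsemide"])


@pytest.fixture(scope="session")
def mean_physiology():
    return default_physiology()


@pytest.fixture(scope="session")
def study_times():
    return np.array(STUDY_TIMES)
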