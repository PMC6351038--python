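import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mitosyn import Feature, study_feature, study_fixture

HEADER = "subject_id\tstatus\tsex\tmt_1719\tmt_7028\tmt_9055\tmt_10398\tmt_12308"


def make_tsv(rows, loci=()):
    header = HEADER + ("".join("\t" + l for l in loci))
    return "\n".join([header] + list(rows)) + "\n"


@pytest.fixture(scope="session")
def ccl5_cohort():
    return study_fixture("ccl5")


@pytest.fixture(scope="session")
def pvt1_cohort():
    return study_fixture("pvt1")


@pytest.fixture(scope="session")
def feature_j():
    return Feature.haplogroup("J")


@pytest.fixture(scope="session")
def feature_ccl5():
    return study_feature("ccl5")
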