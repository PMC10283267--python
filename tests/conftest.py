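import pytest

from clinselect import (
    TaskConfig,
    fast_roster,
    load_dataset,
    parse_metadata,
)
from clinselect.simulate import SyntheticSpec, generate_case_study_like

METADATA_TEXT = """name,type,min,max,legend
Outcome,binary,0,1,0=no;1=yes
Sex,binary,,,0=female;1=male
Severity,categorical,0,2,0=mild;1=moderate;2=severe
NumCaries,integer_bounded,0,12,
NumVisits,integer_unbounded,,,
Age,continuous,,,
ListTreated,toothlist,,,
"""

DATASET_TEXT = """Outcome,Sex,Severity,NumCaries,NumVisits,Age,ListTreated
1,0,2,3,5,6.5,51;55
0,1,0,0,1,12.0,
0,0,1,2,2,NA,61;62;63
1,1,2,12,9,4.25,85
"""


@pytest.fixture
def schema():
    return parse_metadata(METADATA_TEXT)


@pytest.fixture
def table(schema):
    return load_dataset(DATASET_TEXT, schema)


@pytest.fixture(scope="session")
def sim230():
    """A 230-record synthetic cohort with moderate planted effects."""
    spec = SyntheticSpec(seed=7)
    return generate_case_study_like(spec) + (spec,)


@pytest.fixture(scope="session")
def small_signal():
    """Small mixed dataset with two strongly planted scalar effects,
    cheap enough for search and explanation tests."""
    spec = SyntheticSpec(
        seed=11,
        n_binary=3,
        n_categorical=1,
        n_integer=2,
        n_continuous=1,
        n_toothlist=1,
        planted_effects={"Num1": 2.0, "Bin2": 1.5},
    )
    return generate_case_study_like(spec) + (spec,)


@pytest.fixture
def task_config():
    return TaskConfig(target="SecondSedation", class_of_interest=1, seed=5)


@pytest.fixture
def roster2():
    return fast_roster(5)
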