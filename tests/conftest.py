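import pytest

import vurscore as vs


@pytest.fixture(scope="session")
def fixture_set():
    return vs.load_fixtures()


@pytest.fixture(scope="session")
def reference_cohort():
    return vs.reconstruct_reference_cohort()


@pytest.fixture(scope="session")
def reference_screen(fixture_set):
    """Association screen run on the packaged per-variable counts."""
    return vs.screen_counts(fixture_set.table1_contingencies())


@pytest.fixture(scope="session")
def reference_weights(reference_screen):
    """The fitted weight spec: {1,1,1,2,2} over the five model variables."""
    return vs.assign_weights(vs.select_variables(reference_screen))


@pytest.fixture(scope="session")
def table2_dist(fixture_set):
    return fixture_set.table2


@pytest.fixture
def tiny_rows():
    """Three hand-written valid records covering missing/observed DMSA."""
    return [
        dict(patient_id="p1", age_lt2=1, male=1, uti=1, recurrent_uti=0,
             non_ecoli=1, usg_abnormal=1, hydronephrosis=1, utd_p3=1,
             dmsa_done=1, any_scar=1, multiple_scars=1, severe_vur=1),
        dict(patient_id="p2", age_lt2=0, male=0, uti=0, recurrent_uti=0,
             non_ecoli=0, usg_abnormal=0, hydronephrosis=0, utd_p3=0,
             dmsa_done=0, any_scar=None, multiple_scars=None, severe_vur=0),
        dict(patient_id="p3", age_lt2=1, male=0, uti=1, recurrent_uti=1,
             non_ecoli=0, usg_abnormal=1, hydronephrosis=0, utd_p3=0,
             dmsa_done=1, any_scar=0, multiple_scars=0, severe_vur=0),
    ]


@pytest.fixture
def tiny_cohort(tiny_rows):
    return vs.cohort.cohort_from_rows(tiny_rows, provenance="test:tiny")
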