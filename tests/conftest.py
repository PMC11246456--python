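import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pvsignal import simulate  # noqa: E402
from pvsignal.cohort import CohortConfig  # noqa: E402
from pvsignal.faers import (  # noqa: E402
    CaseReport,
    DemoRecord,
    DrugRecord,
    OutcRecord,
    ReacRecord,
    TherRecord,
)
from pvsignal._dates import parse_faers_date  # noqa: E402


def make_case(
    primaryid="1001",
    caseid="100",
    fda_dt="20200115",
    event_dt=None,
    sex="F",
    age=None,
    age_cod="YR",
    wt=None,
    wt_cod="KG",
    occp_cod="MD",
    pts=(),
    outcomes=(),
    drugs=(),
    therapies=(),
):
    """Hand-build a CaseReport for unit tests."""
    demo = DemoRecord(
        primaryid=primaryid,
        caseid=caseid,
        fda_dt=parse_faers_date(fda_dt),
        event_dt=parse_faers_date(event_dt),
        sex=sex,
        age=age,
        age_cod=age_cod,
        wt=wt,
        wt_cod=wt_cod,
        occp_cod=occp_cod,
    )
    return CaseReport(
        demo=demo,
        drugs=[DrugRecord(primaryid, seq, role, name, ai)
               for seq, role, name, ai in drugs],
        reactions=[ReacRecord(primaryid, pt) for pt in pts],
        outcomes=[OutcRecord(primaryid, code) for code in outcomes],
        therapies=[TherRecord(primaryid, seq, parse_faers_date(start),
                              parse_faers_date(end))
                   for seq, start, end in therapies],
    )


@pytest.fixture
def lacosamide_config():
    return CohortConfig(
        generic_names=["LACOSAMIDE"],
        trade_names=["VIMPAT"],
        pt_to_soc={
            "Bradycardia": "10007541",
            "Cardiac arrest": "10007541",
            "Atrial fibrillation": "10007541",
            "Nausea": "10017947",
            "Headache": "10029205",
        },
        target_soc_code="10007541",
        excluded_pt_classes={
            "off_label": frozenset({"Off label use"}),
            "epilepsy": frozenset({"Seizure"}),
        },
    )


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """The deterministic miniature FAERS file set plus its ground truth."""
    root = tmp_path_factory.mktemp("faers_fixture")
    paths, truth = simulate.make_fixture_small(root, seed=0)
    return root, paths, truth
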