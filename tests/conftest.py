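import pytest

from lopdkit.clinical_records import bundled_fixture
from lopdkit.severity_index import (
    M_S,
    VM_M,
    GradingScheme,
    SeverityResult,
    classify_severity,
)


@pytest.fixture(scope="session")
def table1():
    return bundled_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return bundled_fixture("table2_grades")


@pytest.fixture(scope="session")
def overrides():
    return bundled_fixture("table2_overrides")


@pytest.fixture(scope="session")
def table6():
    return bundled_fixture("table6")


@pytest.fixture(scope="session")
def scheme():
    return GradingScheme.default()


@pytest.fixture(scope="session")
def printed_results(table2):
    """Severity results taken from the published SI row (the published
    dichotomy, which differs from the recomputed one for one patient)."""
    return [
        SeverityResult(
            patient_id=pid,
            si=si,
            severity_class=classify_severity(si),
            group=M_S if si > 20 else VM_M,
        )
        for pid, si in table2.printed_si.items()
    ]
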