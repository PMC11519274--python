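import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lungstage.findings import (
    InvasionDescriptor,
    LungLobe,
    NodalFinding,
    PrimaryTumorFinding,
    Side,
    StructuredReport,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def pleural_invasion_reports():
    """Pleural-invasion scenario: same small tumor, reader omits the
    visceral-pleura call the reference asserts."""
    reference = StructuredReport(
        case_id="pleural-case",
        primary=PrimaryTumorFinding(
            lobe=LungLobe.RUL,
            diameter_cm=2.9,
            descriptors=frozenset({InvasionDescriptor.VISCERAL_PLEURA_INVASION}),
        ),
    )
    reader = StructuredReport(
        case_id="pleural-case",
        primary=PrimaryTumorFinding(lobe=LungLobe.RUL, diameter_cm=2.9),
    )
    return reader, reference


@pytest.fixture
def size_mismeasure_reports():
    """Size-mismeasurement scenario: axial 3.9 cm vs multiplanar 4.9 cm."""
    reference = StructuredReport(
        case_id="size-case", primary=PrimaryTumorFinding(lobe=LungLobe.LUL, diameter_cm=4.9)
    )
    reader = StructuredReport(
        case_id="size-case", primary=PrimaryTumorFinding(lobe=LungLobe.LUL, diameter_cm=3.9)
    )
    return reader, reference


@pytest.fixture
def axillary_node_report():
    """Right primary with a single malignant right axillary node — the
    node is outside the IASLC map, so it is distant disease (M1b), not N3."""
    return StructuredReport(
        case_id="axillary-node-case",
        primary=PrimaryTumorFinding(lobe=LungLobe.RUL, diameter_cm=2.5),
        nodes=(NodalFinding(station="axillary", side=Side.RIGHT, judged_malignant=True),),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
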