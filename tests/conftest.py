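import pytest

from mcidnorm import datasets
from mcidnorm.audit import AuditLog
from mcidnorm.normalize import normalize_measurements
from mcidnorm.prioritize import prioritize_all


@pytest.fixture(scope="session")
def registry():
    return datasets.default_registry()


@pytest.fixture(scope="session")
def ranking():
    return datasets.default_ranking()


@pytest.fixture(scope="session")
def incidence():
    return datasets.incidence_matrix()


@pytest.fixture(scope="session")
def demo_records():
    return datasets.demo_measurements()


@pytest.fixture(scope="session")
def demo_normalized(demo_records, registry):
    return normalize_measurements(demo_records, registry, AuditLog())


@pytest.fixture(scope="session")
def demo_unified(demo_normalized, ranking):
    return prioritize_all(demo_normalized, ranking, AuditLog())


# Printed one-decimal MCID-unit values (mean, SD) for every populated cell of
# the demonstration dataset, keyed by (study, arm, prom).  These are the
# frozen worked-example expectations the normalization stage must reproduce.
EXPECTED_TABLE_CELLS = {
    ("study-1", "1", "mHHS"): (8.9, 1.2),
    ("study-1", "1", "iHOT-12"): (6.2, 1.0),
    ("study-1", "2", "mHHS"): (8.8, 1.3),
    ("study-1", "2", "iHOT-12"): (6.0, 1.2),
    ("study-2", "1", "iHOT-33"): (7.1, 1.6),
    ("study-2", "2", "iHOT-33"): (6.6, 1.8),
    ("study-3", "1", "HOS-ADL"): (9.3, 0.9),
    ("study-3", "2", "HOS-ADL"): (9.0, 1.1),
    ("study-4", "1", "NAHS"): (9.6, 1.6),
    ("study-4", "1", "HOS-ADL"): (8.8, 1.2),
    ("study-4", "2", "NAHS"): (9.4, 1.7),
    ("study-4", "2", "HOS-ADL"): (8.7, 1.3),
    ("study-5", "1", "iHOT-12"): (5.8, 0.9),
    ("study-5", "1", "HOS-SSS"): (6.7, 1.3),
    ("study-5", "1", "HOS-ADL"): (8.4, 1.4),
    ("study-5", "2", "iHOT-12"): (5.4, 1.0),
    ("study-5", "2", "HOS-SSS"): (6.0, 1.5),
    ("study-5", "2", "HOS-ADL"): (8.2, 1.5),
    ("study-6", "1", "iHOT-12"): (5.8, 1.0),
    ("study-6", "2", "iHOT-12"): (5.0, 1.2),
    ("study-7", "1", "HOS-ADL"): (8.0, 1.6),
    ("study-7", "2", "HOS-ADL"): (7.7, 1.7),
}

#: Instrument each study retains after frequency-based prioritization.
EXPECTED_RETAINED = {
    "study-1": "mHHS",
    "study-2": "iHOT-33",
    "study-3": "HOS-ADL",
    "study-4": "NAHS",
    "study-5": "iHOT-12",
    "study-6": "iHOT-12",
    "study-7": "HOS-ADL",
}
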