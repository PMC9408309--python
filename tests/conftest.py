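import pytest

from oipnkit import (
    ANCHOR_DRUG,
    CohortConfig,
    ExposureDefinition,
    Role,
    SpontaneousReport,
    generate_cohort,
)


def make_report(rid, drugs=(), reactions=(), anchor=True):
    """Build a report; ``drugs`` is an iterable of names or (name, role) pairs."""
    pairs = set()
    if anchor:
        pairs.add((ANCHOR_DRUG, Role.SUSPECT))
    for d in drugs:
        if isinstance(d, tuple):
            pairs.add((d[0], d[1]))
        else:
            pairs.add((d, Role.CONCOMITANT))
    return SpontaneousReport(report_id=rid, drugs=frozenset(pairs), reactions=frozenset(reactions))


@pytest.fixture(scope="session")
def omeprazole_exposure():
    return ExposureDefinition(name="omeprazole", members=("OMEPRAZOLE",))


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-report cohort with a protective planted drug and fillers."""
    cfg = CohortConfig(
        n_reports=2000,
        baseline_event_prob=0.0648,
        exposures={"OMEPRAZOLE": 0.10, "PANTOPRAZOLE": 0.05},
        odds_multipliers={"OMEPRAZOLE": 0.456, "PANTOPRAZOLE": 0.54},
        seed=20220809,
    )
    return cfg, generate_cohort(cfg)
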