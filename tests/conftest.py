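import numpy as np
import pandas as pd
import pytest

from bipolarnet.lifechart import N_MONTHS, LifeChart
from bipolarnet.panel import ALL_ITEMS, SymptomPanel
from bipolarnet.simulate import CohortSpec, simulate_cohort


def make_chart(patient_id="p", dep=(), man=()):
    """Chart with dep/man severities placed in disjoint leading months.

    ``dep``/``man`` are (count, severity) pairs or lists of severities.
    """
    months = [[0, 0] for _ in range(N_MONTHS)]
    i = 0
    for sev in dep:
        months[i][0] = sev
        i += 1
    for sev in man:
        months[i][1] = sev
        i += 1
    return LifeChart(patient_id, tuple(tuple(m) for m in months))


def make_mixed_chart(patient_id="p", n=12, dep=1, man=1):
    months = [(dep, man) if i < n else (0, 0) for i in range(N_MONTHS)]
    return LifeChart(patient_id, tuple(months))


def panel_from_rows(rows):
    """SymptomPanel from dicts; unspecified items default to 0."""
    full = []
    for row in rows:
        r = {code: 0 for code in ALL_ITEMS}
        r.update(row)
        full.append(r)
    return SymptomPanel.from_tidy(pd.DataFrame(full))


@pytest.fixture(scope="session")
def sim_cohort():
    """One deterministic default-sized synthetic cohort, shared read-only."""
    return simulate_cohort(CohortSpec(seed=123))


@pytest.fixture(scope="session")
def small_cohort():
    """A small (10/10/10) cohort for fast pipeline tests."""
    from bipolarnet.lifechart import CourseLabel

    spec = CohortSpec(
        group_sizes={CourseLabel.MILDLY_IMPAIRED: 10,
                     CourseLabel.DEPRESSED: 10,
                     CourseLabel.CYCLING: 10},
        seed=7,
    )
    return simulate_cohort(spec)
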