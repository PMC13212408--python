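"""Shared fixtures: published summary counts and small synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from neurovuln import synthetic_cohort as sc

#: published group x vulnerability-category counts (NMT row, MT row)
TABLE2 = np.array([[52, 29, 9], [34, 36, 15]])

#: published screening counts within the exposed follow-up subsample:
#: 27 participants increased (10 of them high-vulnerability), 30 were
#: stable/decreasing (1 of them high-vulnerability); category sizes 23/23/11.
MT_SCREENING = {
    "high_increase": 10,
    "high_total": 11,
    "increase_total": 27,
    "stable_total": 30,
    "n_low": 23,
    "n_medium": 23,
    "n_high": 11,
}


@pytest.fixture(scope="session")
def table2():
    return TABLE2.copy()


@pytest.fixture(scope="session")
def table2_participants():
    """Participant-level (group, category) labels whose crosstab is TABLE2."""
    groups, cats = [], []
    for gi, g in enumerate(["NMT", "MT"]):
        for ci, c in enumerate(["low", "medium", "high"]):
            groups += [g] * int(TABLE2[gi, ci])
            cats += [c] * int(TABLE2[gi, ci])
    return np.array(groups), np.array(cats)


@pytest.fixture(scope="session")
def default_cohort():
    cfg = sc.default_config(seed=20)
    return cfg, sc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def mt_outcome_table():
    """An exposed-group outcome table consistent with every published
    aggregate (category sizes 23/23/11; 27 increases of which 10 high; 30
    stable of which 1 high).  The low/medium split of the 17 non-high
    increases is not published; this synthetic reconstruction fixes it at
    8/9, which no screening metric depends on."""
    from neurovuln.screening import OutcomeTable

    counts = {
        "low": {"increase": 8, "stable": 15},
        "medium": {"increase": 9, "stable": 14},
        "high": {"increase": 10, "stable": 1},
    }
    return OutcomeTable(counts=counts, subgroup="MT")
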